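"""Candidate-gene selection and PubMed query construction.

Candidate genes are human–dog ortholog pairs whose human member appears in
a somatic-mutation catalog and whose sequence similarity is at or above a
threshold (75% by default, inclusive).  For each candidate a synonym table
is assembled from gene_info-style rows plus HGNC/OMIM/Ensembl identifiers,
and a left-nested boolean OR query is emitted for PubMed retrieval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologPair",
    "CandidateGene",
    "DEFAULT_SIMILARITY_THRESHOLD",
    "select_candidates",
    "build_synonym_table",
    "build_pubmed_query",
]

#: Minimum percent similarity for a candidate gene (inclusive).
DEFAULT_SIMILARITY_THRESHOLD = 75.0


@dataclass(frozen=True)
class OrthologPair:
    human_gene_id: str
    dog_gene_id: str
    similarity: float
    description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 100.0:
            raise ValueError(f"similarity {self.similarity} outside [0, 100]")


@dataclass
class CandidateGene:
    """An ortholog pair passing the somatic-mutation cross-reference."""

    symbol: str
    human_gene_id: str
    dog_gene_id: str
    similarity: float
    entrez_id: str
    hgnc_id: str | None = None
    omim_id: str | None = None
    synonyms: list[str] = field(default_factory=list)


def _as_pairs(orthologs) -> list[OrthologPair]:
    if isinstance(orthologs, pd.DataFrame):
        return [
            OrthologPair(
                str(r.human_gene_id),
                str(r.dog_gene_id),
                float(r.similarity),
                str(getattr(r, "description", "")),
            )
            for r in orthologs.itertuples()
        ]
    return list(orthologs)


def select_candidates(
    orthologs,
    somatic_catalog: Sequence[tuple[str, str]] | pd.DataFrame,
    id_map: Mapping[str, str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> list[CandidateGene]:
    """Cross-reference orthologs with a somatic-mutation catalog.

    Parameters
    ----------
    orthologs:
        Ortholog pairs, as a DataFrame with columns ``human_gene_id``,
        ``dog_gene_id``, ``similarity``, ``description`` or a sequence of
        :class:`OrthologPair`.
    somatic_catalog:
        (symbol, entrez_id) pairs of genes with somatic mutations, or a
        DataFrame with those columns.
    id_map:
        Entrez GeneID -> Ensembl human gene id mapping.  Catalog entries
        with no mapping are logged and excluded, never guessed.
    threshold:
        Inclusive minimum percent similarity.

    Returns the candidates sorted by symbol.  When several ortholog rows
    share a human gene, the row with the highest similarity is kept
    (ties broken by lexicographic dog gene id).
    """
    pairs = _as_pairs(orthologs)
    if isinstance(somatic_catalog, pd.DataFrame):
        catalog = [(str(r.symbol), str(r.entrez_id)) for r in somatic_catalog.itertuples()]
    else:
        catalog = [(str(s), str(e)) for s, e in somatic_catalog]

    # one row per human gene: highest similarity, then lexicographic dog id
    best: dict[str, OrthologPair] = {}
    for p in pairs:
        cur = best.get(p.human_gene_id)
        if (
            cur is None
            or p.similarity > cur.similarity
            or (p.similarity == cur.similarity and p.dog_gene_id < cur.dog_gene_id)
        ):
            best[p.human_gene_id] = p

    unmapped = 0
    out: list[CandidateGene] = []
    seen_human: set[str] = set()
    for symbol, entrez_id in catalog:
        human_id = id_map.get(entrez_id)
        if human_id is None:
            unmapped += 1
            logger.warning("somatic-catalog gene %s (Entrez %s) has no Ensembl mapping",
                           symbol, entrez_id)
            continue
        pair = best.get(human_id)
        if pair is None or pair.similarity < threshold or human_id in seen_human:
            continue
        seen_human.add(human_id)
        out.append(
            CandidateGene(
                symbol=symbol,
                human_gene_id=pair.human_gene_id,
                dog_gene_id=pair.dog_gene_id,
                similarity=pair.similarity,
                entrez_id=entrez_id,
            )
        )
    if unmapped:
        logger.info("%d somatic-catalog gene(s) excluded as unmapped", unmapped)
    out.sort(key=lambda c: c.symbol)
    return out


def build_synonym_table(
    gene_info_rows,
    hgnc_ids: Mapping[str, str] | None = None,
    omim_ids: Mapping[str, str] | None = None,
    ensembl_ids: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, list[str]]:
    """Build the per-symbol list of PubMed query terms.

    ``gene_info_rows`` is a DataFrame (or iterable of records) with columns
    ``symbol`` and ``synonyms`` (pipe-separated, ``-`` meaning none).  Terms
    are, in order: the synonyms in source order (case-insensitive
    duplicates dropped, first occurrence kept), then ``HGNC: <id>``,
    ``MIM:<id>``, ``Ensembl: <human id>`` and ``Ensembl:<dog id>`` where
    those identifiers are known.  The identifier spellings (space after
    ``HGNC:`` and after the human ``Ensembl:``, none elsewhere) follow the
    query format the pipeline submits to PubMed.
    """
    hgnc_ids = hgnc_ids or {}
    omim_ids = omim_ids or {}
    ensembl_ids = ensembl_ids or {}

    if isinstance(gene_info_rows, pd.DataFrame):
        rows = [(str(r.symbol), str(r.synonyms)) for r in gene_info_rows.itertuples()]
    else:
        rows = [(str(s), str(syn)) for s, syn in gene_info_rows]

    table: dict[str, list[str]] = {}
    for symbol, syn_field in rows:
        terms: list[str] = []
        seen: set[str] = set()
        if syn_field and syn_field != "-":
            for syn in syn_field.split("|"):
                syn = syn.strip()
                if not syn or syn == "-":
                    continue
                key = syn.casefold()
                if key in seen:
                    continue
                seen.add(key)
                terms.append(syn)
        if symbol in hgnc_ids:
            terms.append(f"HGNC: {hgnc_ids[symbol]}")
        if symbol in omim_ids:
            terms.append(f"MIM:{omim_ids[symbol]}")
        if symbol in ensembl_ids:
            human_id, dog_id = ensembl_ids[symbol]
            if human_id:
                terms.append(f"Ensembl: {human_id}")
            if dog_id:
                terms.append(f"Ensembl:{dog_id}")
        table[symbol] = terms
    return table


def build_pubmed_query(terms: Sequence[str]) -> str:
    """Assemble the left-nested boolean OR query for a term list.

    For terms t1..tn the result is ``"(" * (n-1)`` followed by
    ``"t1) OR t2) OR ... OR tn)"`` — the exact shape the pipeline submits
    to PubMed.  A single term yields ``"(t1)"``.
    """
    if not terms:
        raise ValueError("at least one query term is required")
    if len(terms) == 1:
        return f"({terms[0]})"
    head, *rest = terms
    parts = ["(" * (len(terms) - 1), head, ")"]
    for term in rest:
        parts.append(f" OR {term})")
    return "".join(parts)
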