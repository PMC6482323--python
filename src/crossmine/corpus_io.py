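"""Readers and writers for the pipeline's on-disk formats.

The pipeline consumes Medline/PubMed XML article sets and tab-separated
tables (orthologs, somatic-mutation catalogs, synonym tables, drug
lexicons) and emits tab-separated result tables.  Only the fields the
pipeline actually uses are read from the XML: PMID, ArticleTitle and
AbstractText.  Text is kept as-is at read time (UTF-8, no normalization);
normalization is a :mod:`crossmine.text_prep` concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Article",
    "Corpus",
    "SchemaError",
    "read_medline_xml",
    "write_medline_xml",
    "read_table",
    "write_results",
    "read_results",
]


class SchemaError(ValueError):
    """A table does not conform to the requested column specification."""


@dataclass(frozen=True)
class Article:
    """One PubMed record: identifier, title and (possibly empty) abstract."""

    article_id: str
    title: str
    abstract: str = ""
    language: str | None = None

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space (classification text)."""
        if not self.abstract:
            return self.title
        return f"{self.title} {self.abstract}"


class Corpus:
    """An ordered collection of :class:`Article` with unique identifiers.

    Iteration order is input order.  Duplicate article ids raise at
    construction time, mirroring the uniqueness PubMed guarantees for PMIDs.
    """

    def __init__(self, articles: Iterable[Article], source: str = "") -> None:
        self._articles: list[Article] = list(articles)
        self.source = source
        self._by_id: dict[str, Article] = {}
        for art in self._articles:
            if art.article_id in self._by_id:
                raise ValueError(f"duplicate article_id {art.article_id!r}")
            self._by_id[art.article_id] = art

    def __iter__(self) -> Iterator[Article]:
        return iter(self._articles)

    def __len__(self) -> int:
        return len(self._articles)

    def __getitem__(self, article_id: str) -> Article:
        return self._by_id[article_id]

    def __contains__(self, article_id: str) -> bool:
        return article_id in self._by_id

    @property
    def articles(self) -> list[Article]:
        return list(self._articles)

    def ids(self) -> list[str]:
        return [a.article_id for a in self._articles]


def _byte_offset(path: Path, line: int, column: int) -> int:
    """Best-effort byte offset for a 1-based (line, column) position."""
    try:
        raw = path.read_bytes()
    except OSError:
        return -1
    lines = raw.split(b"\n")
    if line < 1 or line > len(lines):
        return -1
    return sum(len(l) + 1 for l in lines[: line - 1]) + max(column - 1, 0)


def read_medline_xml(path: str | Path) -> Corpus:
    """Read a Medline/PubMed XML article set into a :class:`Corpus`.

    Accepts a ``PubmedArticleSet`` or bare ``ArticleSet`` root, or a single
    ``PubmedArticle``.  The abstract is the concatenation of all
    ``AbstractText`` sections in document order, joined by single spaces;
    a record with no ``Abstract`` element yields an empty abstract.
    Records without a PMID are skipped with a warning.

    Raises
    ------
    ValueError
        If the file is not well-formed XML; the message names the byte
        offset of the first error.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        offset = _byte_offset(path, line, column)
        raise ValueError(
            f"malformed XML in {path}: {exc.msg} (byte offset {offset})"
        ) from exc

    root = tree.getroot()
    if root.tag == "PubmedArticle":
        records = [root]
    else:
        records = root.findall(".//PubmedArticle")

    articles: list[Article] = []
    for rec in records:
        pmid_el = rec.find(".//MedlineCitation/PMID")
        if pmid_el is None:
            pmid_el = rec.find(".//PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        if not pmid:
            logger.warning("skipping PubmedArticle with missing PMID in %s", path)
            continue
        title_el = rec.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        sections = [
            " ".join("".join(el.itertext()).split())
            for el in rec.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(s for s in sections if s)
        lang_el = rec.find(".//Language")
        language = lang_el.text.strip() if lang_el is not None and lang_el.text else None
        articles.append(Article(pmid, title, abstract, language))
    return Corpus(articles, source=str(path))


def write_medline_xml(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus as a PubmedArticleSet XML file (deterministic)."""
    root = etree.Element("PubmedArticleSet")
    for art in corpus:
        pa = etree.SubElement(root, "PubmedArticle")
        mc = etree.SubElement(pa, "MedlineCitation")
        pmid = etree.SubElement(mc, "PMID")
        pmid.text = art.article_id
        node = etree.SubElement(mc, "Article")
        title = etree.SubElement(node, "ArticleTitle")
        title.text = art.title
        if art.abstract:
            ab = etree.SubElement(node, "Abstract")
            abt = etree.SubElement(ab, "AbstractText")
            abt.text = art.abstract
        if art.language:
            lang = etree.SubElement(node, "Language")
            lang.text = art.language
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


#: Recognized scalar types for :func:`read_table` column specs.
_CASTS = {
    "str": lambda s: s,
    "int": int,
    "float": float,
}


def read_table(path: str | Path, schema: Mapping[str, str]) -> pd.DataFrame:
    """Read a tab-separated table with a header row and type its columns.

    ``schema`` maps required column names to one of ``str``, ``int``,
    ``float`` or ``percent``; ``percent`` parses as float and validates the
    range [0, 100].  Extra columns in the file are preserved as strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col, kind in schema.items():
        if kind == "str":
            continue
        if kind == "percent":
            values = df[col].astype(float)
            bad = df.loc[(values < 0) | (values > 100), col]
            if not bad.empty:
                raise SchemaError(
                    f"{path}: column {col!r} has value(s) outside [0, 100]: "
                    f"{', '.join(bad.head(5))}"
                )
            df[col] = values
        elif kind in _CASTS:
            df[col] = df[col].map(_CASTS[kind])
        else:
            raise ValueError(f"unknown schema type {kind!r} for column {col!r}")
    return df


_RESULT_COLUMNS = ["article_id", "rule_id", "drugs", "control_phrase"]


def write_results(records, path: str | Path) -> None:
    """Write combination records as a deterministic tab-separated table.

    One row per record: article id, rule id, drug names sorted
    lexicographically and joined by ``|``, and the control phrase.  Rows are
    sorted by (article_id, rule_id, drug string) so repeated writes of the
    same records are byte-identical.
    """
    rows = []
    for rec in records:
        drugs = "|".join(sorted(rec.drugs))
        rows.append((rec.article_id, rec.rule_id, drugs, rec.control_phrase))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_results(path: str | Path) -> list[tuple[str, int, frozenset[str]]]:
    """Re-read a results table as (article_id, rule_id, drug set) triples."""
    df = read_table(path, {"article_id": "str", "rule_id": "int", "drugs": "str"})
    return [
        (row.article_id, row.rule_id, frozenset(row.drugs.split("|")))
        for row in df.itertuples()
    ]
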