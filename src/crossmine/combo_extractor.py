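"""Drug/therapy combination extraction around cue-phrase matches.

For every cue-rule match in an abstract a small context structure is
built: the control phrase (the matched cue extended by up to five tokens
on each side) at the root, and left/right child nodes holding up to five
tokens preceding/following the control phrase.  Drug mentions falling in
any of those regions are collected; two or more distinct drugs yield one
combination record.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .corpus_io import Corpus
from .drug_ner import ConfigurationError, DrugMention
from .text_prep import Token, TokenizedDoc, canonical_name, tokenize_doc

__all__ = [
    "CombinationRule",
    "ContextTree",
    "CombinationRecord",
    "DEFAULT_WINDOW",
    "load_combination_rules",
    "find_matches",
    "build_context",
    "extract_combinations",
    "extract_all",
    "explode_pairs",
]

#: Number of words recovered on each side of a cue match (and again for
#: each child node).
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class CombinationRule:
    rule_id: int
    pattern: str
    label: str = ""


@dataclass
class ContextTree:
    """Root control phrase plus left/right context nodes (token lists)."""

    control: list[Token]
    left_context: list[Token]
    right_context: list[Token]

    def regions(self, include_control: bool = True) -> list[tuple[int, int]]:
        """Character spans of the occupied nodes."""
        nodes = [self.left_context, self.right_context]
        if include_control:
            nodes.insert(0, self.control)
        return [(n[0].start, n[-1].end) for n in nodes if n]


@dataclass(frozen=True)
class CombinationRecord:
    """An unordered set of >= 2 distinct drugs extracted from one window."""

    article_id: str
    rule_id: int
    drugs: frozenset[str]
    control_phrase: str
    evidence_span: tuple[int, int]


def load_combination_rules(path: str | None = None) -> list[CombinationRule]:
    """Load cue rules from YAML; the packaged default set has 27 rules."""
    if path is None:
        text = resources.files("crossmine.data").joinpath("combo_rules.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or []
    rules = []
    seen_ids = set()
    for entry in raw:
        rule = CombinationRule(int(entry["rule_id"]), entry["pattern"], entry.get("label", ""))
        if rule.rule_id in seen_ids:
            raise ConfigurationError(f"duplicate combination rule_id {rule.rule_id}")
        seen_ids.add(rule.rule_id)
        try:
            re.compile(rule.pattern)
        except re.error as exc:
            raise ConfigurationError(
                f"combination rule {rule.rule_id}: pattern does not compile: {exc}"
            ) from exc
        rules.append(rule)
    return rules


def find_matches(
    doc: TokenizedDoc, rules: Sequence[CombinationRule]
) -> list[tuple[int, tuple[int, int]]]:
    """All cue matches in a document as (rule_id, token index span) pairs.

    Per rule, non-overlapping leftmost matches over the document text;
    matches from different rules may overlap.  The returned list is
    ordered by start position, then rule_id.
    """
    tokens = doc.tokens
    matches: list[tuple[int, tuple[int, int]]] = []
    for rule in rules:
        for m in re.finditer(rule.pattern, doc.text):
            lo = hi = None
            for i, t in enumerate(tokens):
                if t.end > m.start() and t.start < m.end():
                    if lo is None:
                        lo = i
                    hi = i
            if lo is None:
                continue
            matches.append((rule.rule_id, (lo, hi + 1)))
    matches.sort(key=lambda x: (x[1][0], x[0]))
    return matches


def build_context(
    doc: TokenizedDoc,
    match: tuple[int, int],
    window: int = DEFAULT_WINDOW,
    extend_control: bool = True,
) -> ContextTree:
    """Build the control-phrase context structure for one cue match.

    ``match`` is a token index span.  The control phrase is the match
    extended by up to ``window`` tokens on each side (set
    ``extend_control=False`` to store the cue alone at the root);
    left/right child nodes hold the next up-to-``window`` tokens beyond
    the control phrase.  Truncation at document edges yields shorter
    nodes, never an error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens = doc.tokens
    lo, hi = match
    if lo < 0 or hi > len(tokens) or lo >= hi:
        raise ValueError(f"match span {match} outside document of {len(tokens)} tokens")
    ext = window if extend_control else 0
    c_lo = max(lo - ext, 0)
    c_hi = min(hi + ext, len(tokens))
    l_lo = max(c_lo - window, 0)
    r_hi = min(c_hi + window, len(tokens))
    return ContextTree(
        control=tokens[c_lo:c_hi],
        left_context=tokens[l_lo:c_lo],
        right_context=tokens[c_hi:r_hi],
    )


def extract_combinations(
    tree: ContextTree,
    drug_mentions: Sequence[DrugMention],
    article_id: str,
    rule_id: int,
    text: str,
    include_control: bool = True,
) -> list[CombinationRecord]:
    """Collect distinct drugs whose mention spans intersect the context.

    Distinctness is judged after case-insensitive canonicalization; the
    first-seen surface form is reported.  Fewer than two distinct drugs
    yield no record.
    """
    regions = tree.regions(include_control=include_control)
    if not regions:
        return []
    drugs: dict[str, str] = {}
    for m in drug_mentions:
        if any(m.start < e and m.end > s for s, e in regions):
            drugs.setdefault(canonical_name(m.surface), m.surface)
    if len(drugs) < 2:
        return []
    lo = min(s for s, _ in regions)
    hi = max(e for _, e in regions)
    control_phrase = (
        text[tree.control[0].start : tree.control[-1].end] if tree.control else ""
    )
    return [
        CombinationRecord(
            article_id=article_id,
            rule_id=rule_id,
            drugs=frozenset(drugs.values()),
            control_phrase=control_phrase,
            evidence_span=(lo, hi),
        )
    ]


def extract_all(
    corpus: Corpus,
    rules: Sequence[CombinationRule],
    mentions_by_article: Mapping[str, Sequence[DrugMention]],
    window: int = DEFAULT_WINDOW,
    extend_control: bool = True,
    include_control: bool = True,
) -> list[CombinationRecord]:
    """Run combination extraction over a whole corpus.

    Identical (article_id, drug set) records from different rules are
    deduplicated keeping the lowest rule_id.  Output ordering is
    deterministic: (article_id, rule_id, sorted drug names).
    """
    best: dict[tuple[str, frozenset[str]], CombinationRecord] = {}
    for article in corpus:
        mentions = mentions_by_article.get(article.article_id, [])
        if not mentions:
            continue
        doc = tokenize_doc(article.article_id, article.text, keep_punct=True)
        for rule_id, span in find_matches(doc, rules):
            tree = build_context(doc, span, window=window, extend_control=extend_control)
            for rec in extract_combinations(
                tree, mentions, article.article_id, rule_id,
                article.text, include_control=include_control,
            ):
                key = (
                    rec.article_id,
                    frozenset(canonical_name(d) for d in rec.drugs),
                )
                cur = best.get(key)
                if cur is None or rec.rule_id < cur.rule_id:
                    best[key] = rec
    records = list(best.values())
    records.sort(key=lambda r: (r.article_id, r.rule_id, "|".join(sorted(r.drugs))))
    return records


def explode_pairs(records: Sequence[CombinationRecord]) -> list[CombinationRecord]:
    """Explode records of arity > 2 into one record per drug pair."""
    out: list[CombinationRecord] = []
    for rec in records:
        if len(rec.drugs) <= 2:
            out.append(rec)
            continue
        for a, b in itertools.combinations(sorted(rec.drugs), 2):
            out.append(
                CombinationRecord(
                    rec.article_id, rec.rule_id, frozenset({a, b}),
                    rec.control_phrase, rec.evidence_span,
                )
            )
    return out
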