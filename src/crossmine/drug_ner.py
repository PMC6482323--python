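"""Drug/therapy named-entity recognition with false-positive filtering.

Two complementary recognizers are exposed:

* a trainable per-token tagger in the maximum-entropy (log-linear) family
  — logistic regression over lexical features of the token and its
  neighbors — whose positive runs become mentions;
* exact longest-match lexicon lookup against a drug-name table.

Model output is noisy in a characteristic way: statistics expressions
("P≤0.001"), percentages and generic pharmacology words ("inhibitor") are
recognized alongside real drugs.  A dictionary of regular-expression
filter rules removes such false positives; a mention is dropped iff some
rule matches its full surface form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .corpus_io import Corpus
from .text_prep import Token, tokenize

__all__ = [
    "DrugMention",
    "FilterRule",
    "NerModel",
    "ConfigurationError",
    "load_filter_rules",
    "train_ner",
    "tag",
    "filter_false_positives",
    "harvest_lexicon_mentions",
    "merge_mentions",
    "evaluate_entities",
]


class ConfigurationError(ValueError):
    """A rule file entry is invalid (e.g. a non-compiling pattern)."""


@dataclass(frozen=True)
class DrugMention:
    """A recognized drug/therapy span; ``text[start:end] == surface``."""

    article_id: str
    surface: str
    start: int
    end: int
    source: str = "model"  # "model" | "lexicon"


@dataclass(frozen=True)
class FilterRule:
    rule_id: str
    pattern: str
    description: str = ""


def load_filter_rules(path: str | None = None) -> list[FilterRule]:
    """Load false-positive filter rules from YAML (packaged set by default).

    Each entry is ``{rule_id, pattern, description?}``; every pattern must
    compile, otherwise a :class:`ConfigurationError` is raised at load time.
    """
    if path is None:
        text = resources.files("crossmine.data").joinpath("filter_rules.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or []
    rules = []
    for entry in raw:
        rule = FilterRule(
            str(entry["rule_id"]), entry["pattern"], entry.get("description", "")
        )
        try:
            re.compile(rule.pattern)
        except re.error as exc:
            raise ConfigurationError(
                f"filter rule {rule.rule_id}: pattern does not compile: {exc}"
            ) from exc
        rules.append(rule)
    return rules


# ---------------------------------------------------------------------------
# per-token tagger

def _shape(s: str) -> str:
    out = []
    for c in s:
        if c.isupper():
            out.append("X")
        elif c.islower():
            out.append("x")
        elif c.isdigit():
            out.append("d")
        else:
            out.append(c)
    return "".join(out)


def _collapse(shape: str) -> str:
    out = []
    for c in shape:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def _token_features(tokens: Sequence[Token], i: int) -> dict[str, int]:
    tok = tokens[i].surface
    low = tok.lower()
    feats = {
        f"w={tok}": 1,
        f"lw={low}": 1,
        f"shape={_shape(tok)}": 1,
        f"cshape={_collapse(_shape(tok))}": 1,
    }
    for k in (2, 3, 4):
        if len(low) >= k:
            feats[f"pre{k}={low[:k]}"] = 1
            feats[f"suf{k}={low[-k:]}"] = 1
    for off in (-2, -1, 1, 2):
        j = i + off
        if 0 <= j < len(tokens):
            feats[f"n{off}={tokens[j].surface.lower()}"] = 1
        else:
            feats[f"n{off}=<pad>"] = 1
    return feats


@dataclass
class NerModel:
    vectorizer: DictVectorizer
    classifier: LogisticRegression


def _token_labels(tokens: Sequence[Token], spans: Iterable[tuple[int, int]]) -> np.ndarray:
    spans = list(spans)
    y = np.zeros(len(tokens), dtype=int)
    for i, t in enumerate(tokens):
        for s, e in spans:
            if t.start >= s and t.end <= e:
                y[i] = 1
                break
    return y


def train_ner(
    corpus: Corpus,
    entities: dict[str, list[tuple[int, int]]],
    seed: int = 0,
) -> NerModel:
    """Train the per-token tagger on stand-off entity annotations.

    ``entities`` maps article ids to (start, end) character spans into the
    article's title+abstract text; spans must align to token boundaries.
    Features per token: identity, lowercase form, 2-4 character prefixes
    and suffixes, word shape, and neighboring tokens within distance 2.
    Deterministic given ``seed``.
    """
    X_dicts: list[dict] = []
    y_all: list[int] = []
    n_entities = 0
    for article in corpus:
        spans = entities.get(article.article_id, [])
        n_entities += len(spans)
        tokens = tokenize(article.text, keep_punct=True)
        y = _token_labels(tokens, spans)
        for i in range(len(tokens)):
            X_dicts.append(_token_features(tokens, i))
        y_all.extend(y.tolist())
    if n_entities == 0 or sum(y_all) == 0:
        raise ValueError("training data contains no entity annotations")
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(X_dicts)
    clf = LogisticRegression(
        solver="lbfgs", max_iter=500, random_state=seed, C=10.0
    )
    clf.fit(X, np.array(y_all))
    return NerModel(vectorizer, clf)


def tag(model: NerModel, text: str, article_id: str = "") -> list[DrugMention]:
    """Tag raw text; maximal runs of positive tokens become one mention."""
    tokens = tokenize(text, keep_punct=True)
    if not tokens:
        return []
    X = model.vectorizer.transform(
        [_token_features(tokens, i) for i in range(len(tokens))]
    )
    y = model.classifier.predict(X)
    mentions: list[DrugMention] = []
    i = 0
    while i < len(tokens):
        if y[i]:
            j = i
            while j + 1 < len(tokens) and y[j + 1]:
                j += 1
            start, end = tokens[i].start, tokens[j].end
            mentions.append(DrugMention(article_id, text[start:end], start, end, "model"))
            i = j + 1
        else:
            i += 1
    return mentions


def filter_false_positives(
    mentions: Sequence[DrugMention], rules: Sequence[FilterRule]
) -> list[DrugMention]:
    """Drop every mention whose full surface matches some rule's pattern.

    Order is preserved; with an empty rule set this is the identity, and
    filtering is idempotent.
    """
    compiled = [re.compile(r.pattern) for r in rules]
    return [
        m for m in mentions if not any(c.fullmatch(m.surface) for c in compiled)
    ]


# ---------------------------------------------------------------------------
# lexicon lookup

_BOUNDARY_L = r"(?<![A-Za-z0-9-])"
_BOUNDARY_R = r"(?![A-Za-z0-9-])"


def harvest_lexicon_mentions(
    text: str,
    lexicon: Iterable[str],
    article_id: str = "",
) -> list[DrugMention]:
    """Longest-match, case-insensitive, token-boundary-anchored lexicon scan.

    ``lexicon`` is an iterable of drug names (a ``name`` column works).
    Overlapping candidates resolve to the longest name at the leftmost
    position; substring hits inside longer words are rejected by the
    boundary anchors (no match of "carboplatin" inside "carboplatinum").
    """
    names = sorted({n for n in lexicon if n}, key=lambda n: (-len(n), n))
    if not names:
        return []
    pattern = re.compile(
        _BOUNDARY_L + "(?:" + "|".join(re.escape(n) for n in names) + ")" + _BOUNDARY_R,
        re.IGNORECASE,
    )
    return [
        DrugMention(article_id, m.group(0), m.start(), m.end(), "lexicon")
        for m in pattern.finditer(text)
    ]


def merge_mentions(
    model_mentions: Sequence[DrugMention],
    lexicon_mentions: Sequence[DrugMention],
) -> list[DrugMention]:
    """Union of model and lexicon mentions, deduplicated by span.

    On an exact span tie the model-sourced mention is preferred.  Output is
    sorted by span.
    """
    by_span: dict[tuple[int, int], DrugMention] = {}
    for m in lexicon_mentions:
        by_span[(m.start, m.end)] = m
    for m in model_mentions:
        by_span[(m.start, m.end)] = m
    return [by_span[k] for k in sorted(by_span)]


def evaluate_entities(
    gold: dict[str, list[tuple[int, int]]],
    predicted: dict[str, list[DrugMention]],
) -> tuple[float, float, float]:
    """Entity-level precision/recall/F by exact span match per article."""
    tp = fp = fn = 0
    ids = set(gold) | set(predicted)
    for aid in ids:
        g = set(map(tuple, gold.get(aid, [])))
        p = {(m.start, m.end) for m in predicted.get(aid, [])}
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f
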