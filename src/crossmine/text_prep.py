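"""Shared text preprocessing for classification and entity recognition.

Two tokenization profiles are used downstream:

* entity-recognition mode keeps punctuation tokens and treats comparison
  expressions such as ``P≤0.001`` or ``IC50=20`` as single tokens, because
  the false-positive filter and the combination-window rules need them;
* classification mode keeps only word tokens and pushes them through
  lowercasing, character normalization, stopword removal and Porter
  suffix-stripping before trigram features are counted.

The Porter stemmer is the classic 1980 suffix-stripping algorithm,
implemented here in full.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Token",
    "TokenizedDoc",
    "TermDocumentMatrix",
    "PorterStemmer",
    "tokenize",
    "segment_sentences",
    "tokenize_doc",
    "preprocess",
    "build_tdm",
    "load_stopwords",
    "normalize_token",
    "canonical_name",
]


@dataclass(frozen=True)
class Token:
    """A surface form with its 0-based half-open span in the source text."""

    surface: str
    start: int
    end: int


@dataclass
class TokenizedDoc:
    """Sentence-segmented, tokenized view of one article's text."""

    article_id: str
    text: str
    sentences: list[list[Token]]

    @property
    def tokens(self) -> list[Token]:
        return [t for sent in self.sentences for t in sent]


@dataclass
class TermDocumentMatrix:
    """Documents x n-gram terms raw count matrix."""

    vocabulary: list[str]
    counts: sparse.csr_matrix
    doc_ids: list[str]


# Letter-initial comparison expressions (P≤0.001, IC50=20) are one token;
# hyphenated names (ABT-737) are one token; other punctuation is a token
# of its own in entity-recognition mode.
_COMPARISON = r"[A-Za-z][A-Za-z0-9-]*(?:<=|>=|[<>=≤≥])[0-9][0-9.]*%?"
_NUMBER = r"[0-9]+(?:\.[0-9]+)*%?"
_WORD = r"[A-Za-z0-9Ͱ-Ͽ]+(?:[-'][A-Za-z0-9Ͱ-Ͽ]+)*"
_PUNCT = r"[^\sA-Za-z0-9]"

_TOKEN_RE = re.compile(f"({_COMPARISON})|({_NUMBER})|({_WORD})|({_PUNCT})")
_WORDLIKE_RE = re.compile(f"^(?:{_COMPARISON}|{_NUMBER}|{_WORD})$")


def tokenize(text: str, keep_punct: bool = True, offset: int = 0) -> list[Token]:
    """Tokenize ``text``; spans are relative to the original string.

    With ``keep_punct=False`` punctuation-only tokens are dropped
    (classification mode).
    """
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        if not keep_punct and not _WORDLIKE_RE.match(surface):
            continue
        tokens.append(Token(surface, offset + m.start(), offset + m.end()))
    return tokens


_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "al", "fig", "figs", "dr", "prof",
    "no", "st", "approx", "ca", "cf", "resp",
}
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Abbreviation-safe sentence spans covering the text without overlap.

    A split happens after sentence-final punctuation followed by
    whitespace and an upper-case letter, digit or opening quote, unless
    the punctuation terminates a known abbreviation or a single capital
    initial.  Decimal points never split because they are not followed by
    whitespace.
    """
    if not text.strip():
        return []
    splits: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        before = text[: m.start()]
        word = re.search(r"([A-Za-z][A-Za-z.]*)$", before)
        if m.group(0) == "." and word is not None:
            w = word.group(1).rstrip(".")
            if w.lower() in _ABBREVIATIONS or (len(w) == 1 and w.isupper()):
                continue
        after = text[m.end():].lstrip()
        if after and not (after[0].isupper() or after[0].isdigit() or after[0] in "\"'(["):
            continue
        splits.append(m.end())
    spans: list[tuple[int, int]] = []
    start = 0
    for split in splits:
        spans.append((start, split))
        # trailing whitespace belongs to the following sentence's lead-in
        start = split
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def tokenize_doc(article_id: str, text: str, keep_punct: bool = True) -> TokenizedDoc:
    """Segment and tokenize one article text; token spans are global."""
    sentences = []
    for s, e in segment_sentences(text):
        toks = tokenize(text[s:e], keep_punct=keep_punct, offset=s)
        if toks:
            sentences.append(toks)
    return TokenizedDoc(article_id, text, sentences)


class PorterStemmer:
    """The classic Porter (1980) suffix-stripping stemmer."""

    def stem(self, word: str) -> str:
        w = word.lower()
        if len(w) <= 2 or not w.isalpha():
            return w
        w = self._step1ab(w)
        w = self._step1c(w)
        w = self._step2(w)
        w = self._step3(w)
        w = self._step4(w)
        w = self._step5(w)
        return w

    # -- letter classes -------------------------------------------------
    @staticmethod
    def _cons(w: str, i: int) -> bool:
        c = w[i]
        if c in "aeiou":
            return False
        if c == "y":
            return i == 0 or not PorterStemmer._cons(w, i - 1)
        return True

    @classmethod
    def _measure(cls, stem: str) -> int:
        """Number of VC sequences in [C](VC)^m[V]."""
        m = 0
        prev_vowel = False
        for i in range(len(stem)):
            vowel = not cls._cons(stem, i)
            if not vowel and prev_vowel:
                m += 1
            prev_vowel = vowel
        return m

    @classmethod
    def _has_vowel(cls, stem: str) -> bool:
        return any(not cls._cons(stem, i) for i in range(len(stem)))

    @classmethod
    def _double_cons(cls, w: str) -> bool:
        return len(w) >= 2 and w[-1] == w[-2] and cls._cons(w, len(w) - 1)

    @classmethod
    def _cvc(cls, w: str) -> bool:
        if len(w) < 3:
            return False
        return (
            cls._cons(w, len(w) - 3)
            and not cls._cons(w, len(w) - 2)
            and cls._cons(w, len(w) - 1)
            and w[-1] not in "wxy"
        )

    # -- steps ----------------------------------------------------------
    def _step1ab(self, w: str) -> str:
        if w.endswith("sses"):
            w = w[:-2]
        elif w.endswith("ies"):
            w = w[:-2]
        elif not w.endswith("ss") and w.endswith("s"):
            w = w[:-1]

        flag = False
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        elif w.endswith("ed") and self._has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif self._double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif self._measure(w) == 1 and self._cvc(w):
                w += "e"
        return w

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
            w = w[:-1] + "i"
        return w

    _STEP2 = [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
        ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
        ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
        ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
        ("biliti", "ble"),
    ]
    _STEP3 = [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]
    _STEP4 = [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]

    def _replace_list(self, w: str, rules) -> str:
        for suffix, repl in rules:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if self._measure(stem) > 0:
                    return stem + repl
                return w
        return w

    def _step2(self, w: str) -> str:
        return self._replace_list(w, self._STEP2)

    def _step3(self, w: str) -> str:
        return self._replace_list(w, self._STEP3)

    def _step4(self, w: str) -> str:
        for suffix in self._STEP4:
            if w.endswith(suffix):
                stem = w[: -len(suffix)]
                if self._measure(stem) > 1:
                    if suffix == "ion" and (not stem or stem[-1] not in "st"):
                        return w
                    return stem
                return w
        return w

    def _step5(self, w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._cvc(stem)):
                w = stem
        if self._measure(w) > 1 and self._double_cons(w) and w.endswith("l"):
            w = w[:-1]
        return w


_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "κ": "kappa", "λ": "lambda", "μ": "mu", "π": "pi", "σ": "sigma",
    "τ": "tau", "ω": "omega",
}
_HYPHENS = dict.fromkeys("‐‑‒–—−", "-")


def normalize_token(token: str) -> str:
    """Character normalization: Unicode NFKC, Greek letters spelled out,
    hyphen variants unified.  Deterministic, no edit-distance correction."""
    t = unicodedata.normalize("NFKC", token)
    t = "".join(_HYPHENS.get(c, _GREEK.get(c, c)) for c in t)
    return t


def canonical_name(name: str) -> str:
    """Canonical form for drug-name comparison.

    Unicode NFKC, casefold, hyphen/space unification and whitespace
    collapsing — so "ABT-737", "ABT 737" and "abt-737" compare equal.
    """
    t = normalize_token(name).casefold()
    t = t.replace("-", " ")
    return " ".join(t.split())


def load_stopwords(path: str | None = None) -> frozenset[str]:
    """Load the stopword list (packaged English list by default),
    one token per line, ``#`` comments ignored."""
    if path is None:
        text = resources.files("crossmine.data").joinpath("stopwords.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


_DEFAULT_STEMMER = PorterStemmer()


def preprocess(
    text: str,
    stopwords: frozenset[str] | None = None,
    stem: bool = True,
) -> list[str]:
    """Classification-mode preprocessing of raw text to a token list.

    Pipeline order: tokenize (word tokens only) -> lowercase ->
    character normalization -> stopword removal -> Porter stemming.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    out: list[str] = []
    for tok in tokenize(text, keep_punct=False):
        t = normalize_token(tok.surface.lower())
        if t in stopwords:
            continue
        if stem:
            t = _DEFAULT_STEMMER.stem(t)
        if t:
            out.append(t)
    return out


def build_tdm(
    docs: Sequence[Sequence[str]],
    n: int = 3,
    doc_ids: Sequence[str] | None = None,
    vocabulary: Sequence[str] | None = None,
) -> TermDocumentMatrix:
    """Raw-count term-document matrix over word n-grams (trigrams by default).

    Terms are contiguous n-grams joined by single spaces; vocabulary order
    is first-occurrence order across the corpus unless a fixed
    ``vocabulary`` is supplied (prediction with a training vocabulary).
    Documents shorter than ``n`` tokens contribute an all-zero row.
    """
    if n < 1:
        raise ValueError(f"n-gram size must be >= 1, got {n}")
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(docs))]

    fixed = vocabulary is not None
    vocab_index: dict[str, int] = (
        {t: i for i, t in enumerate(vocabulary)} if fixed else {}
    )
    rows, cols, vals = [], [], []
    for d, tokens in enumerate(docs):
        counts: dict[int, int] = {}
        for i in range(len(tokens) - n + 1):
            term = " ".join(tokens[i : i + n])
            j = vocab_index.get(term)
            if j is None:
                if fixed:
                    continue
                j = len(vocab_index)
                vocab_index[term] = j
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(d)
            cols.append(j)
            vals.append(c)
    vocab = list(vocabulary) if fixed else list(vocab_index)
    mat = sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(docs), len(vocab)),
        dtype=np.int64,
    )
    return TermDocumentMatrix(vocab, mat, list(doc_ids))
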