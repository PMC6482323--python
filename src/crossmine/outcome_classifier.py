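"""Binary treatment-outcome classification of article abstracts.

Each article is labeled 1 (treatment success) or 0 (treatment failure).
A random forest over raw trigram counts of the preprocessed title+abstract
text is trained and evaluated with stratified k-fold cross-validation;
precision/recall/F are reported for the positive (success) class from the
pooled out-of-fold predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .corpus_io import Article, Corpus
from .text_prep import TermDocumentMatrix, build_tdm, load_stopwords, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "EvalMetrics",
    "OutcomeModel",
    "train",
    "predict",
    "evaluate_kfold",
    "prf_from_confusion",
]


@dataclass
class ClassifierConfig:
    """Training/evaluation parameters.

    ``n_trees`` is the random-forest size (default 300) and ``k_folds``
    the cross-validation fold count (default 10).
    """

    n_trees: int = 300
    k_folds: int = 10
    seed: int = 0
    ngram: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class EvalMetrics:
    """Positive-class precision/recall/F plus the pooled 2x2 confusion table.

    ``confusion`` is [[tn, fp], [fn, tp]] with class 1 (success) positive.
    """

    precision: float
    recall: float
    f_score: float
    confusion: np.ndarray


@dataclass
class OutcomeModel:
    """A trained forest together with its training vocabulary."""

    forest: RandomForestClassifier
    vocabulary: list[str]
    ngram: int
    stopwords: frozenset[str]


def _features(articles, config: ClassifierConfig, stopwords, vocabulary=None):
    docs = [preprocess(a.text, stopwords=stopwords) for a in articles]
    return build_tdm(
        docs,
        n=config.ngram,
        doc_ids=[a.article_id for a in articles],
        vocabulary=vocabulary,
    )


def train(
    corpus: Corpus,
    labels: dict[str, int],
    config: ClassifierConfig | None = None,
    tdm: TermDocumentMatrix | None = None,
) -> OutcomeModel:
    """Fit the random forest on a labeled corpus.

    Every article must carry a label in {0, 1} and both classes must be
    present.  A precomputed term-document matrix may be passed to avoid
    refeaturizing; otherwise features are trigram counts of the
    preprocessed title+abstract text.  Deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    stopwords = load_stopwords()
    articles = corpus.articles
    y = np.array([labels[a.article_id] for a in articles], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training corpus must contain both outcome classes")
    if tdm is None:
        tdm = _features(articles, config, stopwords)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    forest.fit(tdm.counts, y)
    return OutcomeModel(forest, tdm.vocabulary, config.ngram, stopwords)


def predict(model: OutcomeModel, article: Article) -> tuple[int, float]:
    """Classify one article; returns (label, success score in [0, 1]).

    Features use the training vocabulary; unseen trigrams are ignored.  An
    article whose text shares no trigram with the vocabulary is still
    classified (from the forest's priors) with a warning.
    """
    docs = [preprocess(article.text, stopwords=model.stopwords)]
    tdm = build_tdm(docs, n=model.ngram, vocabulary=model.vocabulary)
    if tdm.counts.nnz == 0:
        logger.warning(
            "article %s shares no features with the training vocabulary",
            article.article_id,
        )
    score = float(model.forest.predict_proba(tdm.counts)[0, 1])
    return int(score >= 0.5), score


def prf_from_confusion(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """Positive-class precision, recall and F1 from a 2x2 confusion table.

    Undefined ratios (empty denominator) are reported as 0.0.
    """
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f


def evaluate_kfold(
    corpus: Corpus,
    labels: dict[str, int],
    config: ClassifierConfig | None = None,
) -> EvalMetrics:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring.

    All out-of-fold predictions are pooled into one confusion table and
    scored once for the positive class; macro-averaged metrics are logged
    additionally.  Deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    articles = corpus.articles
    if len(articles) < config.k_folds:
        raise ValueError(
            f"need at least k_folds={config.k_folds} articles, got {len(articles)}"
        )
    y = np.array([labels[a.article_id] for a in articles], dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < config.k_folds:
        raise ValueError(
            f"minority class has {counts.min()} member(s), fewer than "
            f"k_folds={config.k_folds}; use a smaller k"
        )

    stopwords = load_stopwords()
    docs = [preprocess(a.text, stopwords=stopwords) for a in articles]
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed
    )
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        tdm = build_tdm([docs[i] for i in train_idx], n=config.ngram)
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
        )
        forest.fit(tdm.counts, y[train_idx])
        test = build_tdm(
            [docs[i] for i in test_idx], n=config.ngram, vocabulary=tdm.vocabulary
        )
        y_pred[test_idx] = forest.predict(test.counts)

    conf = confusion_matrix(y, y_pred, labels=[0, 1])
    tn, fp, fn, tp = conf.ravel()
    precision, recall, f = prf_from_confusion(tp, fp, fn, tn)
    neg_p, neg_r, neg_f = prf_from_confusion(tn, fn, fp, tp)
    logger.info(
        "macro-averaged precision=%.4f recall=%.4f F=%.4f",
        (precision + neg_p) / 2, (recall + neg_r) / 2, (f + neg_f) / 2,
    )
    return EvalMetrics(precision, recall, f, conf)
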