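"""Labeled synthetic corpora for end-to-end pipeline testing.

Generates Medline-style abstracts with planted drug mentions, one
combination cue phrase per combination article (two distinct drugs placed
inside the extraction windows), success/failure outcome language drawn
from two cue vocabularies whose disjointness is tunable, and statistical
distractor tokens (``P≤0.001``, ``IC50=20``) that exercise the
false-positive filter.  Every planted fact is returned as ground truth:
outcome labels, stand-off entity spans into the title+abstract text, and
the planted drug combinations.

The defaults mirror the corpus statistics the pipeline assumes: ~17% of
articles report treatment failure, and the drug lexicon splits across
sources as DrugBank 50%, PubChem 35%, ChemSpider 8% and 7% new
substances.  Everything is deterministic per seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus_io import Article, Corpus, write_medline_xml
from .drug_crossref import DrugDatabaseTable

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "generate_lexicon",
    "tables_from_lexicon",
    "write_corpus_files",
    "load_ground_truth",
]


@dataclass
class GeneratorConfig:
    n_articles: int = 200
    failure_rate: float = 0.17
    combo_rate: float = 0.3
    lexicon_size: int = 60
    vocab_separation: float = 1.0
    seed: int = 0
    source_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "drugbank": 0.50,
            "pubchem": 0.35,
            "chemspider": 0.08,
            "new": 0.07,
        }
    )

    def __post_init__(self) -> None:
        for name in ("failure_rate", "combo_rate", "vocab_separation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if self.lexicon_size < 2 and self.combo_rate > 0:
            raise ValueError(
                "lexicon_size must be >= 2 when combo_rate > 0 "
                "(a combination needs two distinct drugs)"
            )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by article id."""

    labels: dict[str, int]
    entities: dict[str, list[tuple[int, int, str]]]
    combinations: set[tuple[str, frozenset[str], str]]


# ---------------------------------------------------------------------------
# lexicon

_ANCHOR_DRUGS = [
    ("ABT-737", ["ABT 737"]),
    ("paclitaxel", ["taxol"]),
    ("imatinib", ["Gleevec", "Glivec"]),
]

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z"]
_VOWELS = ["a", "e", "i", "o", "u"]
_SUFFIXES = [
    "tinib", "parib", "mab", "citabine", "rubicin", "tecan", "platin",
    "fenib", "lisib", "zomib", "mycin", "setron", "prazole", "degib",
]
_ID_PREFIX = {"drugbank": "DB", "pubchem": "CID", "chemspider": "CS", "new": "NEW"}


def _allocate(total: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder rounding of ``total * proportion`` per source."""
    raw = {k: total * v for k, v in proportions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (counts[k] - raw[k], k))[:short]:
        counts[k] += 1
    return counts


def _synthetic_name(rng: random.Random, taken: set[str]) -> str:
    while True:
        if rng.random() < 0.15:
            name = (
                "".join(rng.choice("ABCDEFGHJKLMNPQRSTVWXYZ") for _ in range(2))
                + "-"
                + str(rng.randint(100, 999))
            )
        else:
            syllables = "".join(
                rng.choice(_ONSETS) + rng.choice(_VOWELS)
                for _ in range(rng.randint(2, 3))
            )
            name = syllables + rng.choice(_SUFFIXES)
        if name.lower() not in taken:
            return name


def generate_lexicon(config: GeneratorConfig) -> pd.DataFrame:
    """Drug-name table with a planted per-source split.

    Columns: ``name``, ``source_db``, ``db_id``, ``synonyms``
    (pipe-separated, ``-`` for none).  Real anchor names (ABT-737,
    paclitaxel, imatinib/Gleevec) are always included, so in-corpus worked
    examples run against generated lexicons.  Deterministic per seed.
    """
    rng = random.Random(config.seed * 2 + 1)
    size = config.lexicon_size
    counts = _allocate(size, config.source_proportions)

    names: list[tuple[str, list[str]]] = list(_ANCHOR_DRUGS[:size])
    taken = {n.lower() for n, _ in names}
    while len(names) < size:
        n = _synthetic_name(rng, taken)
        taken.add(n.lower())
        names.append((n, []))

    rows = []
    order = [s for s in ("drugbank", "pubchem", "chemspider", "new") if s in counts]
    order += [s for s in counts if s not in order]
    i = 0
    serial = {s: 0 for s in counts}
    for source in order:
        for _ in range(counts[source]):
            name, synonyms = names[i]
            serial[source] += 1
            rows.append(
                {
                    "name": name,
                    "source_db": source,
                    "db_id": f"{_ID_PREFIX.get(source, 'X')}{serial[source]:05d}",
                    "synonyms": "|".join(synonyms) if synonyms else "-",
                }
            )
            i += 1
    return pd.DataFrame(rows, columns=["name", "source_db", "db_id", "synonyms"])


def tables_from_lexicon(lexicon: pd.DataFrame) -> list[DrugDatabaseTable]:
    """Build priority-ordered cross-reference tables (``new`` excluded)."""
    tables = []
    for source in ("drugbank", "pubchem", "chemspider"):
        sub = lexicon[lexicon.source_db == source]
        entries = [
            (name, db_id, [s for s in syn.split("|") if s and s != "-"])
            for name, db_id, syn in sub[["name", "db_id", "synonyms"]].itertuples(index=False)
        ]
        tables.append(DrugDatabaseTable(source, entries))
    return tables


# ---------------------------------------------------------------------------
# article templates
#
# Template vocabulary deliberately avoids every shipped combination cue
# ("plus", "combined", "together", "followed", "added", ...) so planted
# cues are the only cue matches, keeping ground truth unambiguous.

_TITLES = [
    "Clinical evaluation of targeted regimens in canine oncology models.",
    "A prospective veterinary oncology report on novel therapeutic strategies.",
    "Outcomes of experimental treatment protocols in spontaneous canine malignancies.",
    "Comparative assessment of systemic therapies across tumor histologies.",
]

_SUCCESS_SENTENCES = [
    "Durable remission was achieved with excellent tolerability throughout.",
    "Marked shrinkage of every measurable lesion was documented at restaging.",
    "The animals recovered fully and meaningful clinical benefit persisted.",
]

_FAILURE_SENTENCES = [
    "Rapid disease progression occurred despite uninterrupted scheduled dosing.",
    "Severe toxicity forced early withdrawal from the assigned protocol.",
    "Resistance emerged quickly and the enrolled cohort deteriorated steadily.",
]

_FILLER_SENTENCES = [
    "The retrospective chart review covered eleven consecutive referral caseloads.",
    "Baseline staging employed thoracic radiographs and abdominal ultrasound imaging.",
    "Histopathology confirmed the diagnosis before any intervention was initiated.",
    "Owners provided informed consent under the institutional ethics framework.",
    "Laboratory monitoring included weekly hematology and serum biochemistry panels.",
]

_DISTRACTOR_SENTENCES = [
    "Statistical review reported P≤0.001 for the primary endpoint comparison.",
    "The measured IC50=20 value matched historical laboratory expectations.",
    "An exploratory model estimated HR=0.44 across the stratified subgroups.",
]

_DRUG_SENTENCE_TEMPLATES = [
    ["Weekly", "dosing", "of", None, "produced", "measurable", "activity", "in", "this", "model."],
    ["Subjects", "received", None, "at", "the", "standard", "schedule", "without", "interruption."],
    ["Pharmacokinetic", "sampling", "characterized", None, "exposure", "across", "the", "cohort."],
]

_CUE_PHRASES = [
    "combined with",
    "combination of",
    "co-administration of",
    "co-administered with",
    "in combination with",
    "in conjunction with",
    "plus",
    "followed by",
]

_COMBO_LEFT = [
    ["The", "trial", "protocol", "evaluated", "an", "experimental", "regimen",
     "for", "refractory", "disease", "using"],
    ["Investigators", "designed", "a", "dose", "escalation", "schedule",
     "around", "the", "backbone", "agent", "namely"],
]

_COMBO_RIGHT = [
    ["across", "multiple", "independent", "veterinary", "centers", "over",
     "three", "consecutive", "enrollment", "years."],
    ["during", "an", "extended", "observation", "period", "spanning",
     "several", "sequentially", "recruited", "cohorts."],
]


def _join_words(words: list[str]) -> tuple[str, list[tuple[int, int]]]:
    spans = []
    pos = 0
    for w in words:
        spans.append((pos, pos + len(w)))
        pos += len(w) + 1
    return " ".join(words), spans


def generate(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its complete ground truth.

    Combination articles contain exactly one cue phrase, with one drug
    immediately before and one immediately after it; at least ten tokens
    of in-sentence padding on each side keep every other drug mention
    outside the extraction windows, so the planted combinations are
    exactly the recoverable ones.
    """
    rng = random.Random(config.seed)
    lexicon = generate_lexicon(config)
    drug_names = list(lexicon.name)

    articles: list[Article] = []
    labels: dict[str, int] = {}
    entities: dict[str, list[tuple[int, int, str]]] = {}
    combinations: set[tuple[str, frozenset[str], str]] = set()

    for i in range(config.n_articles):
        article_id = str(100001 + i)
        label = 0 if rng.random() < config.failure_rate else 1
        is_combo = rng.random() < config.combo_rate

        own = _SUCCESS_SENTENCES if label == 1 else _FAILURE_SENTENCES
        pooled = _SUCCESS_SENTENCES + _FAILURE_SENTENCES

        # each sentence is (word list, indices of drug words)
        sentences: list[tuple[list[str], list[int]]] = []
        for _ in range(2):
            if rng.random() < config.vocab_separation:
                sent = rng.choice(own)
            else:
                sent = rng.choice(pooled)
            sentences.append((sent.split(), []))

        n_drug_sents = rng.randint(1, 2)
        for _ in range(n_drug_sents):
            template = list(rng.choice(_DRUG_SENTENCE_TEMPLATES))
            slot = template.index(None)
            template[slot] = rng.choice(drug_names)
            sentences.append((template, [slot]))

        if is_combo:
            drug_a, drug_b = rng.sample(drug_names, 2)
            cue = rng.choice(_CUE_PHRASES)
            left = list(rng.choice(_COMBO_LEFT))
            right = list(rng.choice(_COMBO_RIGHT))
            words = left + [drug_a] + cue.split() + [drug_b] + right
            ia = len(left)
            ib = ia + 1 + len(cue.split())
            sentences.append((words, [ia, ib]))
            combinations.add((article_id, frozenset({drug_a, drug_b}), cue))

        if rng.random() < 0.4:
            sentences.append((rng.choice(_DISTRACTOR_SENTENCES).split(), []))
        target = rng.randint(3, 8)
        while len(sentences) < target:
            sentences.append((rng.choice(_FILLER_SENTENCES).split(), []))
        rng.shuffle(sentences)

        title = rng.choice(_TITLES)
        offset = len(title) + 1  # spans index into title + " " + abstract
        abstract_parts: list[str] = []
        spans_out: list[tuple[int, int, str]] = []
        for words, drug_idx in sentences:
            text, spans = _join_words(words)
            for j in drug_idx:
                s, e = spans[j]
                spans_out.append((offset + s, offset + e, words[j]))
            abstract_parts.append(text)
            offset += len(text) + 1
        abstract = " ".join(abstract_parts)

        articles.append(Article(article_id, title, abstract, "eng"))
        labels[article_id] = label
        entities[article_id] = sorted(spans_out)

    corpus = Corpus(articles, source=f"synthetic(seed={config.seed})")
    return corpus, GroundTruth(labels, entities, combinations)


# ---------------------------------------------------------------------------
# file emission / loading

def write_corpus_files(
    corpus: Corpus, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the corpus XML and the three tab-separated truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.xml",
        "labels": outdir / "labels.tsv",
        "entities": outdir / "entities.tsv",
        "combinations": outdir / "combinations.tsv",
    }
    write_medline_xml(corpus, paths["corpus"])
    with open(paths["labels"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("article_id\tlabel\n")
        for aid in corpus.ids():
            fh.write(f"{aid}\t{truth.labels[aid]}\n")
    with open(paths["entities"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("article_id\tstart\tend\tsurface\n")
        for aid in corpus.ids():
            for s, e, surface in truth.entities.get(aid, []):
                fh.write(f"{aid}\t{s}\t{e}\t{surface}\n")
    with open(paths["combinations"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("article_id\tdrugs\tcue\n")
        for aid, drugs, cue in sorted(
            truth.combinations, key=lambda t: (t[0], "|".join(sorted(t[1])))
        ):
            fh.write(f"{aid}\t{'|'.join(sorted(drugs))}\t{cue}\n")
    return paths


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    """Re-read the three truth files written by :func:`write_corpus_files`."""
    from .corpus_io import read_table

    outdir = Path(outdir)
    labels_df = read_table(outdir / "labels.tsv", {"article_id": "str", "label": "int"})
    labels = dict(zip(labels_df.article_id, labels_df.label))
    ent_df = read_table(
        outdir / "entities.tsv",
        {"article_id": "str", "start": "int", "end": "int", "surface": "str"},
    )
    entities: dict[str, list[tuple[int, int, str]]] = {}
    for aid, s, e, surface in ent_df[["article_id", "start", "end", "surface"]].itertuples(index=False):
        entities.setdefault(aid, []).append((s, e, surface))
    comb_df = read_table(
        outdir / "combinations.tsv", {"article_id": "str", "drugs": "str", "cue": "str"}
    )
    combinations = {
        (aid, frozenset(drugs.split("|")), cue)
        for aid, drugs, cue in comb_df[["article_id", "drugs", "cue"]].itertuples(index=False)
    }
    return GroundTruth(labels, entities, combinations)
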