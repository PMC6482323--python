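"""Cross-referencing of extracted drug names against drug-database tables.

Each extracted name is looked up (case-insensitively, after name
canonicalization) in an ordered list of offline database tables emulating
DrugBank / PubChem / ChemSpider name lists; the first table listing the
name (or one of its synonyms) wins.  Names found in no table are flagged
as new drugs/substances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .text_prep import canonical_name

__all__ = [
    "DrugDatabaseTable",
    "CrossRefResult",
    "load_drug_table",
    "cross_reference",
    "summarize",
]


@dataclass
class DrugDatabaseTable:
    """One offline drug-name table: (name, db_id, synonyms) entries."""

    db_name: str
    entries: list[tuple[str, str, list[str]]]

    def __post_init__(self) -> None:
        ids = [db_id for _, db_id, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"duplicate db_id in table {self.db_name!r}: {', '.join(dupes[:5])}"
            )
        index: dict[str, str] = {}
        for name, db_id, synonyms in self.entries:
            for alias in [name, *synonyms]:
                index.setdefault(canonical_name(alias), db_id)
        self._index = index

    def lookup(self, name: str) -> str | None:
        return self._index.get(canonical_name(name))


@dataclass
class CrossRefResult:
    """Partition of the input names into mapped and unmapped."""

    mapped: dict[str, tuple[str, str]]  # name -> (db_name, db_id)
    unmapped: list[str]


def load_drug_table(path: str, db_name: str) -> DrugDatabaseTable:
    """Read a TSV drug table (name, db_id, pipe-separated synonyms)."""
    from .corpus_io import read_table

    df = read_table(path, {"name": "str", "db_id": "str", "synonyms": "str"})
    entries = [
        (name, db_id, [s for s in syn.split("|") if s and s != "-"])
        for name, db_id, syn in df[["name", "db_id", "synonyms"]].itertuples(index=False)
    ]
    return DrugDatabaseTable(db_name, entries)


def cross_reference(
    drugs: Iterable[str],
    tables: Sequence[DrugDatabaseTable],
) -> CrossRefResult:
    """Attribute each drug name to the first table that lists it.

    Tables are consulted in the given priority order; unmatched names go
    to ``unmapped``.  Mapped and unmapped always partition the input set.
    """
    mapped: dict[str, tuple[str, str]] = {}
    unmapped: list[str] = []
    for drug in sorted(set(drugs)):
        for table in tables:
            db_id = table.lookup(drug)
            if db_id is not None:
                mapped[drug] = (table.db_name, db_id)
                break
        else:
            unmapped.append(drug)
    return CrossRefResult(mapped, unmapped)


def summarize(result: CrossRefResult) -> dict[str, int]:
    """Per-source counts plus ``new`` for unmapped names.

    The counts always sum to the size of the input name set.
    """
    counts: dict[str, int] = {}
    for db_name, _ in result.mapped.values():
        counts[db_name] = counts.get(db_name, 0) + 1
    counts["new"] = len(result.unmapped)
    return counts
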