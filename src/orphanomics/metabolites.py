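"""KEGG compound annotation of GC-MS metabolites and chemical-family grouping.

Identified metabolites arrive as names (with optional retention time, m/z and
extraction phase); this module resolves them to KEGG compound identifiers
(C#####) through a compound map and groups them into the chemical families
used for small-molecule surveys of plant tissue: amino acids, organic acids,
carbohydrates, polyols, fatty acids, phenolic compounds, and a catch-all
"others".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FAMILIES",
    "KEGG_ID_PATTERN",
    "MetaboliteRecord",
    "CompoundMap",
    "assign_compound",
    "family_counts",
    "read_metabolite_table",
]

KEGG_ID_PATTERN = re.compile(r"^C\d{5}$")

#: Fixed family vocabulary, in reporting order.
FAMILIES: tuple[str, ...] = (
    "amino acids",
    "organic acids",
    "carbohydrates",
    "polyols",
    "fatty acids",
    "phenolic compounds",
    "others",
)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One identified metabolite; kegg_id/family are filled by annotation."""

    name: str
    kegg_id: str | None = None
    retention_time: float | None = None
    mz: float | None = None
    phase: str | None = None
    family: str | None = None
    matched: bool | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("metabolite name must be non-empty")
        if self.kegg_id is not None and not KEGG_ID_PATTERN.match(self.kegg_id):
            raise ValueError(f"{self.name!r}: invalid KEGG compound id {self.kegg_id!r}")
        if self.phase is not None and self.phase not in ("polar", "apolar"):
            raise ValueError(f"{self.name!r}: phase must be polar or apolar")


def _canon(name: str) -> str:
    return " ".join(name.casefold().split())


class CompoundMap:
    """Name/synonym -> KEGG id and KEGG id -> family lookups.

    Loaded from a TSV with columns ``name``, ``kegg_id``, ``family`` and an
    optional semicolon-separated ``synonyms`` column.  Matching is
    case-insensitive on whitespace-normalized names.  Conflicting duplicate
    names or synonyms (same key, different compound) are a load-time error.
    """

    def __init__(self) -> None:
        self.name_to_kegg: dict[str, str] = {}
        self.kegg_to_family: dict[str, str] = {}
        self.kegg_to_name: dict[str, str] = {}

    def _add_name(self, name: str, kegg_id: str, kind: str) -> None:
        key = _canon(name)
        existing = self.name_to_kegg.get(key)
        if existing is not None and existing != kegg_id:
            raise ValueError(
                f"conflicting {kind} {name!r}: maps to both {existing} and {kegg_id}"
            )
        self.name_to_kegg[key] = kegg_id

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompoundMap":
        cmap = cls()
        for _, row in df.iterrows():
            kegg_id = str(row["kegg_id"]).strip()
            if not KEGG_ID_PATTERN.match(kegg_id):
                raise ValueError(f"invalid KEGG id {kegg_id!r} for {row['name']!r}")
            family = str(row["family"]).strip()
            if family not in FAMILIES:
                raise ValueError(f"unknown family {family!r} for {row['name']!r}")
            name = str(row["name"]).strip()
            cmap._add_name(name, kegg_id, "name")
            cmap.kegg_to_family[kegg_id] = family
            cmap.kegg_to_name.setdefault(kegg_id, name)
            for syn in str(row.get("synonyms", "") or "").split(";"):
                if syn.strip():
                    cmap._add_name(syn.strip(), kegg_id, "synonym")
        return cmap

    @classmethod
    def load(cls, path: str | Path) -> "CompoundMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        return cls.from_frame(df)

    def lookup_name(self, name: str) -> str | None:
        return self.name_to_kegg.get(_canon(name))

    def family_of(self, kegg_id: str) -> str | None:
        return self.kegg_to_family.get(kegg_id)


def assign_compound(record: MetaboliteRecord, cmap: CompoundMap) -> MetaboliteRecord:
    """Resolve a metabolite to its KEGG compound id and family.

    A record already carrying a kegg_id keeps it (the operation is
    idempotent); otherwise the name is matched case-insensitively against the
    map's names and synonyms.  Unmatched records are returned flagged
    (``matched=False``) with family "others" — never dropped.
    """
    kegg_id = record.kegg_id or cmap.lookup_name(record.name)
    if kegg_id is None:
        return replace(record, matched=False, family=record.family or "others")
    family = cmap.family_of(kegg_id) or record.family or "others"
    return replace(record, kegg_id=kegg_id, family=family, matched=True)


def family_counts(
    records: Sequence[MetaboliteRecord], cmap: CompoundMap
) -> dict[str, int]:
    """Count metabolites per chemical family; totals conserve the record count.

    Every record lands in exactly one family; records that cannot be resolved
    (or whose compound has no family in the map) are counted under "others".
    """
    counts = {family: 0 for family in FAMILIES}
    for record in records:
        assigned = assign_compound(record, cmap)
        counts[assigned.family or "others"] += 1
    return counts


def read_metabolite_table(path: str | Path, sep: str = "\t") -> list[MetaboliteRecord]:
    """Read a metabolite identification table (name, optional kegg_id/rt/mz/phase)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    records: list[MetaboliteRecord] = []
    for _, row in df.iterrows():
        def opt(col: str) -> str | None:
            val = str(row[col]).strip() if col in df.columns else ""
            return val or None

        def opt_float(col: str) -> float | None:
            val = opt(col)
            return float(val) if val is not None else None

        records.append(
            MetaboliteRecord(
                name=str(row["name"]).strip(),
                kegg_id=opt("kegg_id"),
                retention_time=opt_float("retention_time"),
                mz=opt_float("mz"),
                phase=opt("phase"),
                family=opt("family"),
            )
        )
    return records
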