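"""Interspecies comparison: enzyme-set algebra and BLAST-tabular ingestion.

An orphan species' enzyme complement is put in context by contrasting its EC
set against the in-silico proteomes of sequenced reference species (Venn
partition of shared/unique enzymes) and by measuring, per reference
proteome, the fraction of query sequences with a homology hit below an
e-value cutoff.  BLAST itself runs upstream; its standard 12-column tabular
output is consumed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence, Set

import pandas as pd

__all__ = [
    "SpeciesEnzymeSet",
    "VennPartition",
    "ec_venn",
    "ingest_blast_tab",
    "similarity_percent",
    "read_species_ec_sets",
    "BLAST_COLUMNS",
]

BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class SpeciesEnzymeSet:
    species: str
    ecs: frozenset[str]


@dataclass
class VennPartition:
    """Exact membership-pattern partition of an EC universe over 2-5 species.

    ``regions`` maps each non-empty species subset to the number of enzymes
    present in exactly those species; region counts sum to the union size.
    """

    species: tuple[str, ...]
    regions: dict[frozenset[str], int]
    pairwise_shared: dict[frozenset[str], int]
    unique_counts: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def to_jsonable(self) -> dict:
        return {
            "species": list(self.species),
            "regions": {
                "&".join(sorted(k)): v for k, v in sorted(
                    self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                )
            },
            "pairwise_shared": {
                "&".join(sorted(k)): v for k, v in sorted(
                    self.pairwise_shared.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "unique_counts": dict(sorted(self.unique_counts.items())),
            "union_size": self.union_size,
        }


def ec_venn(sets: Sequence[SpeciesEnzymeSet]) -> VennPartition:
    """Partition the union of 2-5 enzyme sets by exact presence pattern.

    Also reports pairwise shared counts (plain intersections) and per-species
    unique counts (enzymes in that species only).
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError(f"ec_venn supports 2-5 species, got {len(sets)}")
    names = [s.species for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("species names must be unique")
    by_species: dict[str, frozenset[str]] = {s.species: s.ecs for s in sets}
    universe = frozenset().union(*by_species.values())
    regions: dict[frozenset[str], int] = {}
    for ec in universe:
        pattern = frozenset(n for n in names if ec in by_species[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    pairwise = {
        frozenset((a, b)): len(by_species[a] & by_species[b])
        for a, b in combinations(names, 2)
    }
    unique = {n: regions.get(frozenset((n,)), 0) for n in names}
    return VennPartition(tuple(names), regions, pairwise, unique)


class BlastFormatError(ValueError):
    """A BLAST tabular line is malformed; the message carries the line number."""


def ingest_blast_tab(
    path: str | Path, evalue_max: float = 1e-10
) -> pd.DataFrame:
    """Parse 12-column BLAST tabular output and keep the best hit per query.

    Hits with evalue above ``evalue_max`` are discarded; per query the hit
    with the highest bitscore is retained (ties broken by lowest evalue, then
    first occurrence in the file).  Comment lines (``#``) are ignored.
    """
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastFormatError(
                    f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                rows.append(
                    {
                        "query_id": fields[0],
                        "subject_id": fields[1],
                        "percent_identity": float(fields[2]),
                        "alignment_length": int(fields[3]),
                        "mismatches": int(fields[4]),
                        "gap_opens": int(fields[5]),
                        "q_start": int(fields[6]),
                        "q_end": int(fields[7]),
                        "s_start": int(fields[8]),
                        "s_end": int(fields[9]),
                        "evalue": float(fields[10]),
                        "bitscore": float(fields[11]),
                        "_order": lineno,
                    }
                )
            except ValueError as exc:
                raise BlastFormatError(f"line {lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=list(BLAST_COLUMNS) + ["_order"])
    if df.empty:
        return df.drop(columns=["_order"])
    df = df[df["evalue"] <= evalue_max]
    if df.empty:
        return df.drop(columns=["_order"])
    df = df.sort_values(
        ["query_id", "bitscore", "evalue", "_order"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = df.groupby("query_id", sort=True).head(1).reset_index(drop=True)
    return best.drop(columns=["_order"])


def similarity_percent(best_hits: pd.DataFrame | int, n_queries_total: int) -> float:
    """Percentage of queries with at least one passing hit, to one decimal."""
    if n_queries_total <= 0:
        raise ValueError("n_queries_total must be positive")
    n_hit = (
        int(best_hits)
        if isinstance(best_hits, int)
        else best_hits["query_id"].nunique() if not best_hits.empty else 0
    )
    if n_hit > n_queries_total:
        raise ValueError("more queries with hits than total queries")
    return round(100.0 * n_hit / n_queries_total, 1)


def read_species_ec_sets(path: str | Path) -> list[SpeciesEnzymeSet]:
    """Read species EC sets from a TSV with columns species, ecs (semicolon list)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    sets = []
    for _, row in df.iterrows():
        ecs = frozenset(
            token.strip() for token in str(row["ecs"]).split(";") if token.strip()
        )
        sets.append(SpeciesEnzymeSet(str(row["species"]).strip(), ecs))
    return sets
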