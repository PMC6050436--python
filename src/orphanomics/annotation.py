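"""Ingestion of functional annotation tables: EC numbers, GO terms, MapMan bins.

Annotation engines (UniRef90 searches, MERCATOR bin assignment) run upstream;
this module consumes their tabular output, normalizes Enzyme Commission
numbers into a canonical form, filters the enzyme subset, and computes
functional-category (bin) distributions of the kind shown as pie charts in
plant omics surveys.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EC_PATTERN",
    "AnnotationRecord",
    "BinCode",
    "parse_ec",
    "is_canonical_ec",
    "ec_sort_key",
    "bin_distribution",
    "enzyme_subset",
    "read_annotations",
]

# Canonical EC form: three positive integers plus an integer or '-' wildcard
# in the fourth field.  Partial classes are expressed only via trailing '-'.
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(?:\d+|-)$")

_EC_TOKEN = re.compile(r"(?:EC[:\s]?)?(\d+\.\d+\.\d+\.(?:\d+|-))", re.IGNORECASE)
_EC_SHORT = re.compile(r"EC[:\s]?(\d+(?:\.\d+){0,2})(?![\d.])", re.IGNORECASE)

NOT_ASSIGNED = "not assigned"


@dataclass(frozen=True)
class BinCode:
    """A hierarchical MapMan/MERCATOR functional bin, e.g. code 1.3 'PS.calvin cycle'."""

    code: str
    name: str = ""

    def truncated(self, level: int) -> str:
        return ".".join(self.code.split(".")[:level])


@dataclass
class AnnotationRecord:
    """One annotated sequence: description, EC numbers, GO terms, functional bins."""

    seq_id: str
    gene_name: str | None = None
    description: str | None = None
    ec_numbers: list[str] = field(default_factory=list)
    go_terms: list[str] = field(default_factory=list)
    bins: list[BinCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        for ec in self.ec_numbers:
            if not is_canonical_ec(ec):
                raise ValueError(f"{self.seq_id}: invalid EC number {ec!r}")


def is_canonical_ec(text: str) -> bool:
    return bool(EC_PATTERN.match(text))


def ec_sort_key(ec: str) -> tuple:
    """Numeric sort key for canonical ECs; '-' sorts after any integer."""
    parts = ec.split(".")
    return tuple((1, 0) if p == "-" else (0, int(p)) for p in parts)


def parse_ec(text: str, strict: bool = False) -> list[str]:
    """Extract all EC numbers from free text, normalized and de-duplicated.

    Accepts "EC:2.7.1.40", "EC 2.7.1.40", "EC2.7.1.40" and bare "2.7.1.40"
    tokens, including trailing '-' wildcards such as 2.4.1.-.  Order of first
    occurrence is preserved.  In strict mode an EC-prefixed token with fewer
    than four fields (e.g. "EC:2.7") raises instead of being ignored.
    """
    if not text:
        return []
    found: list[str] = []
    seen: set[str] = set()
    for match in _EC_TOKEN.finditer(text):
        ec = match.group(1)
        if ec not in seen:
            seen.add(ec)
            found.append(ec)
    if strict:
        for match in _EC_SHORT.finditer(text):
            token = match.group(1)
            if token.count(".") < 3 and token not in seen:
                raise ValueError(f"truncated EC token {token!r} in {text!r}")
    return found


def enzyme_subset(annotations: Iterable[AnnotationRecord]) -> list[AnnotationRecord]:
    """Records carrying at least one EC number, in stable input order."""
    return [rec for rec in annotations if rec.ec_numbers]


def bin_distribution(
    annotations: Sequence[AnnotationRecord],
    level: int = 1,
    multi: str = "fractional",
) -> dict[str, tuple[float, float]]:
    """Distribution of records over functional bins at a hierarchy level.

    Returns ``{category: (count, percent)}``.  Records without bins fall into
    a "not assigned" category.  With ``multi="fractional"`` (default) a record
    with k distinct level-``level`` bins contributes 1/k to each, so counts
    sum to the number of records; ``multi="all"`` counts the record once per
    bin (the double-counting convention of some published pie charts).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if multi not in ("fractional", "all"):
        raise ValueError("multi must be 'fractional' or 'all'")
    counts: dict[str, float] = {}
    total_records = len(annotations)
    if total_records == 0:
        return {}
    for rec in annotations:
        cats = sorted({b.truncated(level) for b in rec.bins}) or [NOT_ASSIGNED]
        weight = 1.0 if multi == "all" else 1.0 / len(cats)
        for cat in cats:
            counts[cat] = counts.get(cat, 0.0) + weight
    denom = sum(counts.values())
    return {
        cat: (count, 100.0 * count / denom)
        for cat, count in sorted(counts.items(), key=lambda kv: _cat_key(kv[0]))
    }


def _cat_key(cat: str) -> tuple:
    if cat == NOT_ASSIGNED:
        return (1,)
    try:
        return (0, tuple(int(p) for p in cat.split(".")))
    except ValueError:
        return (0, (float("inf"),), cat)


_DEFAULT_COLUMNS: Mapping[str, str] = {
    "seq_id": "seq_id",
    "gene_name": "gene_name",
    "description": "description",
    "ec_numbers": "ec_numbers",
    "go_terms": "go_terms",
    "bins": "bins",
}


def read_annotations(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[AnnotationRecord]:
    """Read an annotation table (TSV) into records.

    ``columns`` maps the logical field names (seq_id, gene_name, description,
    ec_numbers, go_terms, bins) to the file's column headers; fields whose
    column is absent are left empty.  EC numbers and GO terms are
    semicolon-separated; bins are semicolon-separated ``code`` or
    ``code:name`` tokens.  EC cells pass through :func:`parse_ec`, so free
    text such as "(EC:2.7.1.40)" is tolerated.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")

    def cell(row: pd.Series, key: str) -> str:
        col = colmap[key]
        return str(row[col]).strip() if col in df.columns else ""

    records: list[AnnotationRecord] = []
    for _, row in df.iterrows():
        bins = []
        for token in filter(None, (t.strip() for t in cell(row, "bins").split(";"))):
            code, _, name = token.partition(":")
            bins.append(BinCode(code.strip(), name.strip()))
        records.append(
            AnnotationRecord(
                seq_id=cell(row, "seq_id"),
                gene_name=cell(row, "gene_name") or None,
                description=cell(row, "description") or None,
                ec_numbers=parse_ec(cell(row, "ec_numbers")),
                go_terms=[
                    t.strip()
                    for t in cell(row, "go_terms").split(";")
                    if t.strip()
                ],
                bins=bins,
            )
        )
    return records
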