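"""Pathway-coverage integration of metabolite, protein, and transcript layers.

The integration key is deliberately simple: metabolites join pathways through
KEGG compound identifiers, enzymes join through EC numbers detected at the
protein and/or transcript level.  Per pathway this yields the coverage
counts of a reconstruction table (matched metabolites, detected enzymes per
omics layer, completeness fractions, missing enzymes) and — where reaction
triples are defined — the number of "full reactions": reactions whose enzyme
is detected at BOTH the protein and transcript level and whose substrate and
product metabolites are both detected.  A MapMan mapping-file exporter turns
bin-annotated sequences into the tab-delimited input of that visualization
tool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Set, TextIO

from .annotation import AnnotationRecord, ec_sort_key, is_canonical_ec
from .metabolites import KEGG_ID_PATTERN

__all__ = [
    "PathwayDefinition",
    "ReactionTriple",
    "CoverageRow",
    "ReactionStatus",
    "FullReactionReport",
    "load_pathway_definitions",
    "pathway_coverage",
    "completeness_report",
    "full_reactions",
    "export_mapman_mapping",
    "write_coverage_tsv",
]

NOT_ASSIGNED_BIN = "35"


class PathwayLoadError(ValueError):
    """A pathway-definition file is malformed; the message carries the line."""


@dataclass(frozen=True)
class ReactionTriple:
    """One enzymatic conversion: EC, substrate compound, product compound."""

    ec: str
    substrate: str
    product: str

    def __post_init__(self) -> None:
        if self.substrate == self.product:
            raise ValueError(f"reaction {self.ec}: substrate equals product")


@dataclass
class PathwayDefinition:
    """A reference pathway: member compounds, member enzymes, optional reactions."""

    pathway_id: str
    name: str
    compounds: frozenset[str]
    enzymes: frozenset[str]
    reactions: tuple[ReactionTriple, ...] = ()

    def __post_init__(self) -> None:
        for r in self.reactions:
            if r.ec not in self.enzymes:
                raise ValueError(
                    f"{self.pathway_id}: reaction EC {r.ec} not in enzyme set"
                )


@dataclass
class CoverageRow:
    """Per-pathway coverage of the three omics layers."""

    pathway_id: str
    name: str
    matched_metabolites: list[str]
    n_metabolites: int
    n_compounds_total: int
    n_protein_enzymes: int
    n_transcript_enzymes: int
    n_enzymes_total: int
    completeness_protein: float
    completeness_transcript: float
    missing_enzymes: list[str]
    n_full_reactions: int | None


@dataclass(frozen=True)
class ReactionStatus:
    """Layer-by-layer detection status of one reaction."""

    reaction: ReactionTriple
    protein: bool
    transcript: bool
    substrate: bool
    product: bool

    @property
    def full(self) -> bool:
        return self.protein and self.transcript and self.substrate and self.product


@dataclass
class FullReactionReport:
    pathway_id: str
    computable: bool
    n_full: int | None
    statuses: tuple[ReactionStatus, ...]


def _parse_list(cell: str) -> list[str]:
    return [token.strip() for token in cell.split(";") if token.strip()]


def load_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Load pathway definitions from the documented TSV dialect.

    Columns: pathway_id, name, compounds (semicolon list of C#####), enzymes
    (semicolon list of ECs), optional reactions ("ec:substrate>product"
    semicolon list).  Malformed identifiers raise with the line number;
    duplicate pathway ids are rejected.
    """
    defs: list[PathwayDefinition] = []
    seen: set[str] = set()
    with open(path) as handle:
        header: list[str] | None = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                required = {"pathway_id", "name", "compounds", "enzymes"}
                missing = required - set(header)
                if missing:
                    raise PathwayLoadError(
                        f"line {lineno}: missing column(s) {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            pid = row.get("pathway_id", "").strip()
            if not pid:
                raise PathwayLoadError(f"line {lineno}: empty pathway_id")
            if pid in seen:
                raise PathwayLoadError(f"line {lineno}: duplicate pathway_id {pid!r}")
            seen.add(pid)
            compounds = _parse_list(row.get("compounds", ""))
            for c in compounds:
                if not KEGG_ID_PATTERN.match(c):
                    raise PathwayLoadError(
                        f"line {lineno}: malformed compound id {c!r}"
                    )
            enzymes = _parse_list(row.get("enzymes", ""))
            for ec in enzymes:
                if not is_canonical_ec(ec):
                    raise PathwayLoadError(f"line {lineno}: malformed EC {ec!r}")
            reactions: list[ReactionTriple] = []
            for token in _parse_list(row.get("reactions", "") or ""):
                m = re.match(r"^([^:]+):(C\d{5})>(C\d{5})$", token)
                if not m:
                    raise PathwayLoadError(
                        f"line {lineno}: malformed reaction {token!r}"
                    )
                ec, sub, prod = m.groups()
                if not is_canonical_ec(ec):
                    raise PathwayLoadError(f"line {lineno}: malformed EC {ec!r}")
                reactions.append(ReactionTriple(ec, sub, prod))
            try:
                defs.append(
                    PathwayDefinition(
                        pathway_id=pid,
                        name=row.get("name", "").strip(),
                        compounds=frozenset(compounds),
                        enzymes=frozenset(enzymes),
                        reactions=tuple(reactions),
                    )
                )
            except ValueError as exc:
                raise PathwayLoadError(f"line {lineno}: {exc}") from exc
    return defs


def _match_ecs(
    pathway_ecs: frozenset[str], detected: Set[str], wildcards: bool
) -> set[str]:
    """Detected members of a pathway's enzyme set.

    Exact canonical matching by default.  With ``wildcards=True`` a detected
    partial EC like 2.4.1.- also claims pathway entries sharing its concrete
    prefix, and vice versa.
    """
    if not wildcards:
        return set(pathway_ecs) & set(detected)
    hits: set[str] = set()
    for ec in pathway_ecs:
        for det in detected:
            if ec == det or _wild_match(ec, det) or _wild_match(det, ec):
                hits.add(ec)
                break
    return hits


def _wild_match(pattern: str, concrete: str) -> bool:
    if not pattern.endswith("-"):
        return False
    prefix = pattern[: pattern.rindex("-")]
    return concrete.startswith(prefix)


def pathway_coverage(
    metabolite_ids: Set[str],
    protein_ecs: Set[str],
    transcript_ecs: Set[str],
    definitions: Sequence[PathwayDefinition],
    wildcards: bool = False,
) -> list[CoverageRow]:
    """Join detected compounds and ECs against every pathway definition.

    Rows are sorted by pathway_id; pathways with all-zero coverage are kept —
    they are exactly the gaps of the reconstruction.
    """
    rows: list[CoverageRow] = []
    for d in sorted(definitions, key=lambda d: d.pathway_id):
        matched = sorted(d.compounds & set(metabolite_ids))
        prot = _match_ecs(d.enzymes, protein_ecs, wildcards)
        trans = _match_ecs(d.enzymes, transcript_ecs, wildcards)
        detected = prot | trans
        missing = sorted(d.enzymes - detected, key=ec_sort_key)
        n_total = len(d.enzymes)
        report = None
        if d.reactions:
            report = full_reactions(d, metabolite_ids, protein_ecs, transcript_ecs)
        rows.append(
            CoverageRow(
                pathway_id=d.pathway_id,
                name=d.name,
                matched_metabolites=matched,
                n_metabolites=len(matched),
                n_compounds_total=len(d.compounds),
                n_protein_enzymes=len(prot),
                n_transcript_enzymes=len(trans),
                n_enzymes_total=n_total,
                completeness_protein=len(prot) / n_total if n_total else 0.0,
                completeness_transcript=len(trans) / n_total if n_total else 0.0,
                missing_enzymes=missing,
                n_full_reactions=report.n_full if report else None,
            )
        )
    return rows


def completeness_report(
    definitions: Sequence[PathwayDefinition],
    detected_ecs: Set[str],
    wildcards: bool = False,
) -> dict[str, list[str]]:
    """Per-pathway list of enzymes NOT detected in the given EC set.

    Missing enzymes are reported in numeric EC order.
    """
    report: dict[str, list[str]] = {}
    for d in sorted(definitions, key=lambda d: d.pathway_id):
        found = _match_ecs(d.enzymes, detected_ecs, wildcards)
        report[d.pathway_id] = sorted(d.enzymes - found, key=ec_sort_key)
    return report


def full_reactions(
    definition: PathwayDefinition,
    metabolite_ids: Set[str],
    protein_ecs: Set[str],
    transcript_ecs: Set[str],
) -> FullReactionReport:
    """Classify each reaction of a pathway by omics-layer support.

    A reaction is FULL iff its EC is detected at both the protein and the
    transcript level and both its substrate and product compounds are
    detected.  A definition without reactions yields an explicitly
    non-computable report (``computable=False``), never a zero count.
    """
    if not definition.reactions:
        return FullReactionReport(definition.pathway_id, False, None, ())
    statuses = tuple(
        ReactionStatus(
            reaction=r,
            protein=r.ec in protein_ecs,
            transcript=r.ec in transcript_ecs,
            substrate=r.substrate in metabolite_ids,
            product=r.product in metabolite_ids,
        )
        for r in definition.reactions
    )
    return FullReactionReport(
        definition.pathway_id,
        True,
        sum(1 for s in statuses if s.full),
        statuses,
    )


MAPMAN_COLUMNS = ("BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION", "TYPE")


def export_mapman_mapping(
    annotations: Iterable[AnnotationRecord],
    handle_or_path: str | Path | TextIO,
    seq_type: str = "T",
) -> int:
    """Write a MapMan mapping file: one row per (record, bin).

    Tab-delimited columns BINCODE, NAME, IDENTIFIER, DESCRIPTION, TYPE;
    identifiers are lower-cased and rows sorted by BINCODE then IDENTIFIER.
    Records without bins are emitted under the not-assigned bin code (35),
    never dropped.  Returns the number of data rows written.
    """
    rows: list[tuple[str, str, str, str, str]] = []
    for rec in annotations:
        if rec.bins:
            for b in rec.bins:
                rows.append(
                    (b.code, b.name, rec.seq_id.lower(), rec.description or "", seq_type)
                )
        else:
            rows.append(
                (NOT_ASSIGNED_BIN, "not assigned", rec.seq_id.lower(),
                 rec.description or "", seq_type)
            )
    rows.sort(key=lambda r: (_bincode_key(r[0]), r[2]))

    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle: TextIO = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        handle.write("\t".join(MAPMAN_COLUMNS) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()
    return len(rows)


def _bincode_key(code: str) -> tuple:
    try:
        return (0, tuple(int(p) for p in code.split(".")))
    except ValueError:
        return (1, code)


def write_coverage_tsv(rows: Sequence[CoverageRow], handle_or_path: str | Path | TextIO) -> None:
    """Write coverage rows as a TSV mirroring a reconstruction-table layout."""
    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle: TextIO = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        handle.write(
            "pathway_id\tname\tmatched_metabolites\tn_metabolites\tn_compounds_total"
            "\tn_protein_enzymes\tn_transcript_enzymes\tn_enzymes_total"
            "\tcompleteness_protein\tcompleteness_transcript\tmissing_enzymes"
            "\tn_full_reactions\n"
        )
        for r in rows:
            nfull = "" if r.n_full_reactions is None else str(r.n_full_reactions)
            handle.write(
                f"{r.pathway_id}\t{r.name}\t{';'.join(r.matched_metabolites)}"
                f"\t{r.n_metabolites}\t{r.n_compounds_total}"
                f"\t{r.n_protein_enzymes}\t{r.n_transcript_enzymes}"
                f"\t{r.n_enzymes_total}\t{r.completeness_protein:.4f}"
                f"\t{r.completeness_transcript:.4f}"
                f"\t{';'.join(r.missing_enzymes)}\t{nfull}\n"
            )
    finally:
        if close:
            handle.close()
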