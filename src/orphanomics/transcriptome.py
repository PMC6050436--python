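"""Transcriptome preprocessing and six-frame protein search-database construction.

For an orphan species with no sequenced genome, protein identification has to
run against a database derived from the species' own transcriptome.  This
module provides the steps of that route: read trimming, redundancy reduction
of assembled transcripts by greedy identity clustering, six-frame translation
under the standard genetic code, extraction of stop-free peptide segments
above a minimum length, and assembly of the resulting FASTA search database
with a provenance sidecar that maps every database entry back to its source
transcript, reading frame and frame-local coordinates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import edlib
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SeqReadRecord",
    "TranscriptRecord",
    "OrfPeptide",
    "Cluster",
    "TrimStats",
    "FRAMES",
    "trim_reads",
    "global_identity",
    "cluster_redundancy",
    "six_frame_translate",
    "extract_orf_peptides",
    "iter_orf_peptides",
    "build_search_db",
    "parse_peptide_id",
    "read_fasta_transcripts",
    "read_fastq_reads",
    "write_fastq_reads",
]

#: Reading frames in canonical order: forward offsets 0/1/2 then the reverse
#: complement at offsets 0/1/2.
FRAMES: tuple[int, ...] = (1, 2, 3, -1, -2, -3)

_VALID_BASES = frozenset("ACGTN")

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
# Codon -> residue for the 64 unambiguous codons; anything else (i.e. a codon
# containing N) falls through to 'X'.
_CODON_TO_AA: dict[str, str] = dict(_TABLE1.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _TABLE1.stop_codons})


class MalformedRecordError(ValueError):
    """A sequence record violates its structural invariants."""


class AlphabetError(ValueError):
    """A nucleotide sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class SeqReadRecord:
    """A sequencing read with optional per-base Phred qualities."""

    id: str
    bases: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise MalformedRecordError("read id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise MalformedRecordError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled transcript (contig) with a unique id."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise MalformedRecordError("transcript id must be non-empty")
        if not self.bases:
            raise MalformedRecordError(f"transcript {self.id!r} has empty sequence")


@dataclass(frozen=True)
class OrfPeptide:
    """A stop-free translated segment with full provenance.

    Coordinates are 0-based half-open within the translation of the peptide's
    reading frame; reverse-strand frames are indexed on the translation of the
    reverse complement.
    """

    peptide_id: str
    transcript_id: str
    frame: int
    aa_start: int
    aa_end: int
    residues: str

    def __post_init__(self) -> None:
        if self.aa_end - self.aa_start != len(self.residues):
            raise MalformedRecordError(
                f"{self.peptide_id}: coordinate span does not match residue count"
            )
        if "*" in self.residues:
            raise MalformedRecordError(f"{self.peptide_id}: residues contain a stop")


@dataclass
class Cluster:
    """A redundancy cluster: longest member is the representative."""

    representative_id: str
    member_ids: list[str]
    identity_threshold: float


@dataclass
class TrimStats:
    """Bookkeeping for a trimming pass."""

    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    @property
    def bases_removed(self) -> int:
        return self.bases_in - self.bases_out

    def to_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "bases_in": self.bases_in,
            "bases_out": self.bases_out,
            "bases_removed": self.bases_removed,
        }


# ---------------------------------------------------------------------------
# read trimming
# ---------------------------------------------------------------------------

def trim_reads(
    reads: Iterable[SeqReadRecord],
    min_quality: int = 0,
    max_n: int | float = math.inf,
    trim5: int = 0,
    trim3: int = 0,
    min_len: int = 1,
) -> tuple[list[SeqReadRecord], TrimStats]:
    """Trim reads by fixed base removal and low-quality end clipping.

    Per read, in order: (1) remove ``trim5`` bases from the 5' end and
    ``trim3`` from the 3' end; (2) remove the maximal prefix and suffix in
    which every base has quality below ``min_quality``; (3) discard the read
    if more than ``max_n`` ambiguous bases remain or fewer than ``min_len``
    bases survive.
    """
    if trim5 < 0 or trim3 < 0:
        raise ValueError("trim5 and trim3 must be non-negative")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")

    stats = TrimStats()
    kept: list[SeqReadRecord] = []
    for read in reads:
        stats.reads_in += 1
        stats.bases_in += len(read.bases)
        if min_quality > 0 and read.qualities is None:
            raise ValueError(
                f"read {read.id!r} has no qualities but min_quality={min_quality}"
            )
        stop = len(read.bases) - trim3
        start = min(trim5, max(stop, 0))
        bases = read.bases[start:stop]
        quals = read.qualities[start:stop] if read.qualities is not None else None

        if min_quality > 0 and quals:
            lo = 0
            while lo < len(quals) and quals[lo] < min_quality:
                lo += 1
            hi = len(quals)
            while hi > lo and quals[hi - 1] < min_quality:
                hi -= 1
            bases = bases[lo:hi]
            quals = quals[lo:hi]

        if len(bases) < min_len or bases.upper().count("N") > max_n:
            continue
        kept.append(SeqReadRecord(read.id, bases, quals))
        stats.reads_out += 1
        stats.bases_out += len(bases)
    return kept, stats


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global pairwise alignment.

    The alignment is the minimum-edit-distance (Needleman-Wunsch) alignment;
    identity = (alignment columns - edit distance) / alignment columns, i.e.
    matches counted over the full alignment length including gap columns.
    """
    if not a or not b:
        return 0.0
    result = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    columns = sum(int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", result["cigar"]))
    return (columns - result["editDistance"]) / columns


def cluster_redundancy(
    transcripts: Sequence[TranscriptRecord], identity_threshold: float = 0.95
) -> list[Cluster]:
    """Greedy longest-first redundancy clustering at a global-identity threshold.

    Sequences are visited longest first (ties broken by id); each joins the
    first existing cluster whose representative it matches at or above the
    threshold, otherwise it founds a new cluster.  Clusters are returned with
    representatives in descending length order.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(transcripts, key=lambda t: (-len(t.bases), t.id))
    clusters: list[Cluster] = []
    reps: list[TranscriptRecord] = []
    for t in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            # identity <= min(len)/max(len): skip hopeless comparisons
            if len(t.bases) < identity_threshold * len(rep.bases):
                continue
            if global_identity(t.bases, rep.bases) >= identity_threshold:
                cluster.member_ids.append(t.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(t.id, [t.id], identity_threshold))
            reps.append(t)
    return clusters


# ---------------------------------------------------------------------------
# six-frame translation and ORF extraction
# ---------------------------------------------------------------------------

def _translate_inframe(seq: str) -> str:
    """Translate a nucleotide string codon by codon; N-codons give 'X'."""
    return "".join(
        _CODON_TO_AA.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def six_frame_translate(transcript: TranscriptRecord) -> dict[int, str]:
    """Translate a transcript in all six reading frames (standard code).

    Frames +1/+2/+3 translate the sequence at offsets 0/1/2; frames -1/-2/-3
    translate the reverse complement at offsets 0/1/2.  Stop codons emit '*',
    codons containing N emit 'X', and trailing partial codons are dropped.
    """
    seq = transcript.bases.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise AlphabetError(
            f"transcript {transcript.id!r}: invalid characters {sorted(bad)}"
        )
    rc = str(Seq(seq).reverse_complement())
    frames: dict[int, str] = {}
    for offset in range(3):
        frames[offset + 1] = _translate_inframe(seq[offset:])
        frames[-(offset + 1)] = _translate_inframe(rc[offset:])
    return frames


def _frame_tag(frame: int) -> str:
    return f"{frame:+d}"


def extract_orf_peptides(
    translations: dict[int, str], transcript_id: str = "seq", min_len: int = 51
) -> list[OrfPeptide]:
    """Extract maximal stop-free segments of at least ``min_len`` residues.

    The default of 51 keeps peptides strictly longer than 50 amino acids.
    Segments need no initiator methionine ('X' residues count toward length);
    ordering is deterministic: frames +1,+2,+3,-1,-2,-3, then position.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    peptides: list[OrfPeptide] = []
    for frame in FRAMES:
        translation = translations.get(frame, "")
        ordinal = 0
        pos = 0
        for segment in translation.split("*"):
            if len(segment) >= min_len:
                ordinal += 1
                peptides.append(
                    OrfPeptide(
                        peptide_id=f"{transcript_id}|{_frame_tag(frame)}|{ordinal}",
                        transcript_id=transcript_id,
                        frame=frame,
                        aa_start=pos,
                        aa_end=pos + len(segment),
                        residues=segment,
                    )
                )
            pos += len(segment) + 1
    return peptides


def parse_peptide_id(peptide_id: str) -> tuple[str, int, int]:
    """Invert the peptide-id encoding -> (transcript_id, frame, ordinal)."""
    transcript_id, tag, ordinal = peptide_id.rsplit("|", 2)
    return transcript_id, int(tag), int(ordinal)


def iter_orf_peptides(
    transcripts: Iterable[TranscriptRecord], min_len: int = 51
) -> Iterator[OrfPeptide]:
    """Translate every transcript in six frames and yield its ORF peptides."""
    seen: set[str] = set()
    for t in transcripts:
        if t.id in seen:
            raise MalformedRecordError(f"duplicate transcript id {t.id!r}")
        seen.add(t.id)
        yield from extract_orf_peptides(six_frame_translate(t), t.id, min_len=min_len)


def build_search_db(
    transcripts: Sequence[TranscriptRecord],
    fasta_path: str | Path,
    provenance_path: str | Path,
    min_len: int = 51,
) -> int:
    """Write the protein search database (FASTA) and its provenance TSV.

    Returns the number of database entries.  Output is byte-identical for
    identical input: transcripts are processed in the order given, frames and
    peptides in their canonical order.
    """
    n = 0
    with open(fasta_path, "w") as fasta, open(provenance_path, "w") as prov:
        prov.write("peptide_id\ttranscript_id\tframe\taa_start\taa_end\tlength\n")
        for pep in iter_orf_peptides(transcripts, min_len=min_len):
            fasta.write(f">{pep.peptide_id}\n")
            for i in range(0, len(pep.residues), 60):
                fasta.write(pep.residues[i : i + 60] + "\n")
            prov.write(
                f"{pep.peptide_id}\t{pep.transcript_id}\t{_frame_tag(pep.frame)}"
                f"\t{pep.aa_start}\t{pep.aa_end}\t{len(pep.residues)}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# sequence file I/O
# ---------------------------------------------------------------------------

def read_fasta_transcripts(path: str | Path) -> list[TranscriptRecord]:
    records = [
        TranscriptRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise MalformedRecordError(f"duplicate transcript ids: {dup}")
    return records


def read_fastq_reads(path: str | Path) -> list[SeqReadRecord]:
    return [
        SeqReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq_reads(reads: Iterable[SeqReadRecord], handle_or_path: str | Path | TextIO) -> None:
    close = False
    if isinstance(handle_or_path, (str, Path)):
        handle: TextIO = open(handle_or_path, "w")
        close = True
    else:
        handle = handle_or_path
    try:
        for read in reads:
            quals = read.qualities or tuple([40] * len(read.bases))
            qline = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{qline}\n")
    finally:
        if close:
            handle.close()
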