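"""Synthetic-data generators with planted ground truth.

Two generators drive testing and demonstration: a transcriptome simulator
that plants stop-free open reading frames of known frame and length into
random nucleotide background, and a quantification simulator that draws
feature baselines from a log-uniform distribution and multiplies log-normal
replicate noise calibrated to a target coefficient of variation.  Every
draw goes through one seeded NumPy generator, so outputs are reproducible
from (parameters, seed) and each generator returns the exact truth of what
it planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import QuantTable
from .transcriptome import FRAMES, TranscriptRecord, _CODON_TO_AA

__all__ = [
    "PlantedOrf",
    "SyntheticTruth",
    "simulate_transcriptome",
    "simulate_quant",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
# Synonymous-codon lists for the 20 standard residues, used to encode planted
# ORFs with random codon usage (fixed codon choices would starve shifted
# frames of stop codons and create spurious long ORFs).
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon in sorted(c for c, aa in _CODON_TO_AA.items() if aa != "*"):
    _AA_TO_CODONS.setdefault(_CODON_TO_AA[codon], []).append(codon)
_AMINO_ACIDS = sorted(_AA_TO_CODONS)


@dataclass(frozen=True)
class PlantedOrf:
    transcript_id: str
    frame: int
    aa_length: int
    residues: str


@dataclass
class SyntheticTruth:
    """Exact description of what a generator planted, keyed by the seed used."""

    seed: int
    planted_orfs: list[PlantedOrf] = field(default_factory=list)
    target_cv: float | None = None
    missing_mask: pd.DataFrame | None = None


def _scan_long_segments(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Naive six-frame scan for stop-free segments >= min_len (frame, length)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = seq.translate(comp)[::-1]
    hits = []
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        sub = src[abs(frame) - 1 :]
        translation = "".join(
            _CODON_TO_AA.get(sub[i : i + 3], "X") for i in range(0, len(sub) - 2, 3)
        )
        for segment in translation.split("*"):
            if len(segment) >= min_len:
                hits.append((frame, len(segment)))
    return hits


def _background(rng: np.random.Generator, length: int) -> str:
    """Random background with stop anchors in every frame.

    Stretches of random bases are interleaved with 12-nt CTAG tiles.  A
    CTAG-repeat is its own reverse complement and three tandem copies place a
    TAG stop at every codon phase on both strands, so chance stop-free runs
    in the background cannot exceed ~35 residues — safely below the default
    ORF cutoff.
    """
    parts: list[str] = []
    remaining = length
    while remaining > 0:
        chunk = min(90, remaining)
        parts.append("".join(rng.choice(_BASES, size=chunk)))
        remaining -= chunk
        if remaining > 0:
            tile = "CTAGCTAGCTAG"[: min(12, remaining)]
            parts.append(tile)
            remaining -= len(tile)
    return "".join(parts)


def simulate_transcriptome(
    n: int,
    length_range: tuple[int, int] = (300, 900),
    n_planted_orfs: int = 1,
    orf_length: int = 60,
    seed: int = 0,
    min_len: int = 51,
    max_tries: int = 200,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Simulate transcripts with planted stop-free ORFs of known provenance.

    ``n_planted_orfs`` transcripts (cycled over the first transcripts) each
    receive one planted ORF of ``orf_length`` residues on a random frame,
    flanked by in-frame stop codons so the planted segment is maximal.
    Backgrounds are re-drawn (up to ``max_tries``) whenever an unplanted
    segment of length >= ``min_len`` arises in any frame, so the returned
    truth lists exactly the ORFs that survive the default length cutoff.
    """
    lo, hi = length_range
    if lo < 150:
        raise ValueError("transcript lengths must be >= 150")
    if n == 0:
        return [], SyntheticTruth(seed=seed)
    if n_planted_orfs > n:
        raise ValueError("cannot plant more ORFs than transcripts")
    # insert = stop + coding + stop, and up to 2 nt of frame offset
    needed = 3 * (orf_length + 2) + 2
    if n_planted_orfs > 0 and needed > hi:
        raise ValueError(
            f"a {orf_length}-aa ORF needs {needed} nt but transcripts are <= {hi} nt"
        )
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptRecord] = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n):
        tid = f"contig{i + 1:05d}"
        plant = i < n_planted_orfs
        length = int(rng.integers(lo, hi + 1))
        if plant and length < needed:
            length = needed
        for attempt in range(max_tries):
            bases = _background(rng, length)
            planted: PlantedOrf | None = None
            if plant:
                frame = int(rng.choice(FRAMES))
                residues = "".join(rng.choice(_AMINO_ACIDS, size=orf_length))
                coding = "".join(
                    _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
                    for aa in residues
                )
                insert = (
                    _STOPS[int(rng.integers(3))] + coding + _STOPS[int(rng.integers(3))]
                )
                offset = abs(frame) - 1
                start_max = (length - offset - len(insert)) // 3
                codon_start = int(rng.integers(0, start_max + 1))
                pos = offset + 3 * codon_start
                if frame > 0:
                    bases = bases[:pos] + insert + bases[pos + len(insert):]
                else:
                    comp = str.maketrans("ACGT", "TGCA")
                    rc_insert = insert.translate(comp)[::-1]
                    end = length - pos
                    bases = bases[: end - len(insert)] + rc_insert + bases[end:]
                planted = PlantedOrf(tid, frame, orf_length, residues)
            segments = _scan_long_segments(bases, min_len)
            expected = (
                [(planted.frame, planted.aa_length)] if planted and orf_length >= min_len else []
            )
            if sorted(segments) == sorted(expected):
                break
        else:
            raise RuntimeError(
                f"could not generate clean background for {tid} in {max_tries} tries"
            )
        transcripts.append(TranscriptRecord(tid, bases))
        # truth describes outputs at the default cutoff exactly
        if planted and orf_length >= min_len:
            truth.planted_orfs.append(planted)
    return transcripts, truth


def simulate_quant(
    n_features: int,
    n_replicates: int = 3,
    target_cv: float = 15.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[QuantTable, SyntheticTruth]:
    """Simulate a peak-area table with log-normal replicate noise.

    Feature baselines are log-uniform over [1e4, 1e7]; each replicate area is
    baseline x LogNormal(-sigma^2/2, sigma) with sigma set from
    sigma^2 = ln(1 + cv^2).  Because the sample standard deviation over few
    replicates underestimates the population SD (by the c4(n) factor, ~0.886
    at n = 3), the calibration divides the target CV by c4(n) so that the
    MEASURED mean sample CV is centered on ``target_cv`` percent.  Cells are
    masked missing independently at ``missing_rate``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    # c4(n): expectation of the sample SD relative to the population SD
    c4 = math.sqrt(2.0 / (n_replicates - 1)) * (
        math.gamma(n_replicates / 2.0) / math.gamma((n_replicates - 1) / 2.0)
    )
    cv = target_cv / 100.0 / c4
    sigma = math.sqrt(math.log1p(cv * cv))
    baselines = 10.0 ** rng.uniform(4, 7, size=n_features)
    noise = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma,
                          size=(n_features, n_replicates))
    areas = baselines[:, None] * noise
    feature_ids = [f"feat{i + 1:05d}" for i in range(n_features)]
    replicate_ids = [f"rep{j + 1}" for j in range(n_replicates)]
    data = pd.DataFrame(areas, index=feature_ids, columns=replicate_ids)
    mask = pd.DataFrame(
        rng.random((n_features, n_replicates)) < missing_rate,
        index=feature_ids,
        columns=replicate_ids,
    )
    data = data.mask(mask)
    truth = SyntheticTruth(seed=seed, target_cv=target_cv, missing_mask=mask)
    return QuantTable(data), truth
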