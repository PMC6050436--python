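"""Sequence preprocessing, six-frame translation, and search-database tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orphanomics.transcriptome import (
    AlphabetError,
    MalformedRecordError,
    OrfPeptide,
    SeqReadRecord,
    TranscriptRecord,
    build_search_db,
    cluster_redundancy,
    extract_orf_peptides,
    global_identity,
    iter_orf_peptides,
    parse_peptide_id,
    six_frame_translate,
    trim_reads,
)
from conftest import random_reads

# Independent codon-lookup oracle: standard genetic code laid out over the
# classical TCAG codon ordering; codons containing N translate to 'X'.
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_TCAG = "TCAG"
_ORACLE_TABLE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def oracle_translate(seq: str) -> str:
    return "".join(
        _ORACLE_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


dna = st.text(alphabet="ACGTN", min_size=3, max_size=400)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

class TestTrimReads:
    def test_clean_read_is_unchanged(self):
        read = SeqReadRecord("r1", "ACGT" * 10, tuple([35] * 40))
        kept, stats = trim_reads([read], min_quality=20)
        assert kept == [read]
        assert stats.bases_removed == 0

    def test_fixed_base_trim_arithmetic(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=100))
        read = SeqReadRecord("r1", bases, tuple([40] * 100))
        kept, _ = trim_reads([read], trim5=10, trim3=5)
        assert kept[0].bases == bases[10:95]

    def test_matches_per_base_scan_oracle(self, rng):
        """Retained intervals equal an independent per-read end scan."""
        reads = random_reads(rng, 1000)
        min_q, max_n, t5, t3, min_len = 20, 3, 2, 1, 40
        kept, _ = trim_reads(reads, min_q, max_n, t5, t3, min_len)
        expected = {}
        for read in reads:
            b = read.bases[t5 : len(read.bases) - t3]
            q = read.qualities[t5 : len(read.bases) - t3]
            lo, hi = 0, len(q)
            while lo < hi and q[lo] < min_q:
                lo += 1
            while hi > lo and q[hi - 1] < min_q:
                hi -= 1
            if hi - lo >= min_len and b[lo:hi].count("N") <= max_n:
                expected[read.id] = b[lo:hi]
        assert {r.id: r.bases for r in kept} == expected

    def test_never_lengthens_and_identity_configuration(self, rng):
        reads = random_reads(rng, 50)
        kept, _ = trim_reads(reads, min_quality=25, trim5=3, min_len=10)
        lengths = {r.id: len(r.bases) for r in reads}
        assert all(len(r.bases) <= lengths[r.id] for r in kept)
        same, stats = trim_reads(reads, min_quality=0, max_n=math.inf)
        assert same == reads and stats.bases_removed == 0

    def test_quality_requirement_without_qualities_errors(self):
        with pytest.raises(ValueError, match="min_quality"):
            trim_reads([SeqReadRecord("r", "ACGT")], min_quality=20)

    def test_length_mismatch_is_malformed(self):
        with pytest.raises(MalformedRecordError):
            SeqReadRecord("r", "ACGT", (40, 40))


# ---------------------------------------------------------------------------
# six-frame translation
# ---------------------------------------------------------------------------

class TestSixFrameTranslate:
    def test_forward_codon_table(self):
        assert six_frame_translate(TranscriptRecord("t", "ATGAAA"))[1] == "MK"

    def test_reverse_frame_reads_reverse_complement(self):
        # revcomp(TTACAT) = ATGTAA -> Met then stop
        assert six_frame_translate(TranscriptRecord("t", "TTACAT"))[-1] == "M*"

    def test_n_codons_emit_x(self):
        frames = six_frame_translate(TranscriptRecord("t", "CTNATG"))
        assert frames[1] == "XM"  # CTN is ambiguous-by-rule even though all CTx are Leu

    def test_matches_codon_loop_oracle_on_random_sequences(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGTN"), size=999))
            frames = six_frame_translate(TranscriptRecord("t", seq))
            rc = oracle_revcomp(seq)
            for off in range(3):
                assert frames[off + 1] == oracle_translate(seq[off:])
                assert frames[-(off + 1)] == oracle_translate(rc[off:])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_symmetry(self, seq):
        forward = six_frame_translate(TranscriptRecord("t", seq))
        flipped = six_frame_translate(TranscriptRecord("t", oracle_revcomp(seq)))
        for k in (1, 2, 3):
            assert flipped[k] == forward[-k]

    def test_rejects_bad_alphabet(self):
        with pytest.raises(AlphabetError, match="bad"):
            six_frame_translate(TranscriptRecord("bad", "ACGU"))


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

class TestExtractOrfPeptides:
    def test_length_boundary_is_strictly_greater_than_50(self):
        frames = {1: "A" * 50, 2: "C" * 51, 3: "", -1: "", -2: "", -3: ""}
        peptides = extract_orf_peptides(frames, "t")
        assert [p.residues for p in peptides] == ["C" * 51]

    def test_split_on_stops(self):
        frames = {1: "MKT*AAAA", 2: "", 3: "", -1: "", -2: "", -3: ""}
        peptides = extract_orf_peptides(frames, "t", min_len=1)
        assert [p.residues for p in peptides] == ["MKT", "AAAA"]
        assert [(p.aa_start, p.aa_end) for p in peptides] == [(0, 3), (4, 8)]

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX*", max_size=300),
           st.integers(min_value=1, max_value=60))
    def test_matches_split_oracle(self, translation, min_len):
        frames = {f: "" for f in (1, 2, 3, -1, -2, -3)}
        frames[2] = translation
        got = [p.residues for p in extract_orf_peptides(frames, "t", min_len=min_len)]
        assert got == [s for s in translation.split("*") if len(s) >= min_len]

    def test_peptide_ids_round_trip(self):
        frames = {1: "A" * 60 + "*" + "M" * 60, 2: "", 3: "", -1: "", -2: "C" * 70, -3: ""}
        for pep in extract_orf_peptides(frames, "contig_1|x"):
            assert parse_peptide_id(pep.peptide_id) == (
                pep.transcript_id,
                pep.frame,
                int(pep.peptide_id.rsplit("|", 1)[1]),
            )

    def test_peptides_contain_no_stop_and_conserve_residues(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2001))
        frames = six_frame_translate(TranscriptRecord("t", seq))
        peptides = extract_orf_peptides(frames, "t", min_len=1)
        assert all("*" not in p.residues for p in peptides)
        total = sum(len(p.residues) for p in peptides)
        assert total <= sum(len(f) for f in frames.values())


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

def _mutate(rng, seq, rate):
    bases = list(seq)
    for i in range(len(bases)):
        if rng.random() < rate:
            bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    return "".join(bases)


def brute_force_greedy(transcripts, threshold):
    """Reference greedy assignment over an exhaustively computed identity matrix."""
    ordered = sorted(transcripts, key=lambda t: (-len(t.bases), t.id))
    ident = {
        (a.id, b.id): global_identity(a.bases, b.bases)
        for a in ordered
        for b in ordered
    }
    clusters: list[list] = []
    for t in ordered:
        for members in clusters:
            rep = members[0]
            if ident[(t.id, rep.id)] >= threshold:
                members.append(t)
                break
        else:
            clusters.append([t])
    return [[m.id for m in members] for members in clusters]


class TestClusterRedundancy:
    def test_identical_pair_merges(self):
        a = TranscriptRecord("a", "ACGT" * 50)
        b = TranscriptRecord("b", "ACGT" * 50)
        clusters = cluster_redundancy([a, b], 0.95)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b"]

    def test_unrelated_sequences_stay_apart(self, rng):
        a = TranscriptRecord("a", "".join(rng.choice(list("ACGT"), size=200)))
        b = TranscriptRecord("b", "".join(rng.choice(list("ACGT"), size=200)))
        assert len(cluster_redundancy([a, b], 0.95)) == 2

    def test_templated_set_matches_brute_force_oracle(self, rng):
        templates = [
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(250, 400))))
            for _ in range(5)
        ]
        transcripts = []
        for i in range(50):
            template = templates[i % 5]
            transcripts.append(
                TranscriptRecord(f"s{i:02d}", _mutate(rng, template, 0.01))
            )
        clusters = cluster_redundancy(transcripts, 0.95)
        assert len(clusters) == 5
        expected = brute_force_greedy(transcripts, 0.95)
        got = [c.member_ids for c in clusters]
        assert got == expected
        # members really match their representative at >= threshold
        by_id = {t.id: t.bases for t in transcripts}
        for c in clusters:
            assert all(
                global_identity(by_id[m], by_id[c.representative_id]) >= 0.95
                for m in c.member_ids
            )

    def test_threshold_one_groups_exact_duplicates(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(6)]
        transcripts = [
            TranscriptRecord(f"t{i}", seqs[i % 6]) for i in range(12)
        ]
        clusters = cluster_redundancy(transcripts, 1.0)
        by_hash = {}
        for t in transcripts:
            by_hash.setdefault(t.bases, set()).add(t.id)
        assert {frozenset(c.member_ids) for c in clusters} == {
            frozenset(v) for v in by_hash.values()
        }

    def test_rejects_bad_threshold_and_empty_input(self):
        assert cluster_redundancy([], 0.9) == []
        with pytest.raises(ValueError):
            cluster_redundancy([], 1.5)

    def test_representatives_sorted_by_descending_length(self, rng):
        transcripts = [
            TranscriptRecord(f"t{i}", "".join(rng.choice(list("ACGT"), size=100 + 17 * i)))
            for i in range(6)
        ]
        clusters = cluster_redundancy(transcripts, 0.99)
        lengths = [
            len(next(t.bases for t in transcripts if t.id == c.representative_id))
            for c in clusters
        ]
        assert lengths == sorted(lengths, reverse=True)


# ---------------------------------------------------------------------------
# search-database construction
# ---------------------------------------------------------------------------

class TestBuildSearchDb:
    def test_empty_input(self, tmp_path):
        n = build_search_db([], tmp_path / "db.fasta", tmp_path / "prov.tsv")
        assert n == 0
        assert (tmp_path / "db.fasta").read_text() == ""
        assert (tmp_path / "prov.tsv").read_text().startswith("peptide_id\t")

    def test_planted_orf_on_reverse_frame(self, tmp_path):
        from orphanomics.simulate import simulate_transcriptome

        for seed in range(40):
            transcripts, truth = simulate_transcriptome(
                1, n_planted_orfs=1, orf_length=60, seed=seed
            )
            if truth.planted_orfs[0].frame == -2:
                break
        else:
            pytest.fail("no seed planted a frame -2 ORF")
        n = build_search_db(transcripts, tmp_path / "db.fasta", tmp_path / "prov.tsv")
        assert n == 1
        prov = (tmp_path / "prov.tsv").read_text().splitlines()
        assert len(prov) == 2 and prov[1].split("\t")[2] == "-2"

    def test_byte_identical_on_rerun(self, tmp_path, rng):
        transcripts = [
            TranscriptRecord(f"t{i}", "".join(rng.choice(list("ACGT"), size=700)))
            for i in range(10)
        ]
        for tag in ("a", "b"):
            build_search_db(
                transcripts, tmp_path / f"db_{tag}.fasta", tmp_path / f"p_{tag}.tsv"
            )
        assert (tmp_path / "db_a.fasta").read_bytes() == (tmp_path / "db_b.fasta").read_bytes()
        assert (tmp_path / "p_a.tsv").read_bytes() == (tmp_path / "p_b.tsv").read_bytes()

    def test_provenance_round_trips_to_source_transcript(self, rng):
        transcripts = [
            TranscriptRecord(f"t{i}", "".join(rng.choice(list("ACGT"), size=900)))
            for i in range(5)
        ]
        frames_by_id = {t.id: six_frame_translate(t) for t in transcripts}
        for pep in iter_orf_peptides(transcripts, min_len=20):
            frame_aa = frames_by_id[pep.transcript_id][pep.frame]
            assert frame_aa[pep.aa_start : pep.aa_end] == pep.residues

    def test_duplicate_transcript_id_is_fatal(self):
        dup = [TranscriptRecord("t", "ATG" * 60), TranscriptRecord("t", "ATG" * 60)]
        with pytest.raises(MalformedRecordError, match="t"):
            list(iter_orf_peptides(dup))
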