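# Methods

This note documents the models and procedures implemented in `orphanomics`,
the defaults chosen where the underlying workflow admits several reasonable
formalizations, and what the synthetic generators do and do not emulate.

## Six-frame search-database construction

Without gene models, the protein search space of an orphan species is the
six-frame translation of its transcriptome.  Frames +1/+2/+3 translate the
transcript at offsets 0/1/2; frames −1/−2/−3 translate the reverse
complement at the same offsets.  Translation uses the standard genetic code,
codon by codon: stop codons emit `*`, any codon containing `N` emits `X`,
and trailing partial codons are dropped.  The codon-by-codon rule is
deliberate — ambiguity-resolving translators map codons like `CTN` to `L`,
but for a search database an ambiguous base should not silently assert a
residue, so every N-containing codon is masked to `X`.

Database entries are **stop-to-stop segments**: each frame's translation is
split on `*` and every maximal stop-free segment of at least 51 residues
(strictly longer than 50; parameter `min_len`) is kept.  No initiator
methionine is required — the transcripts are assembled fragments whose true
5′ ends are unreliable, and a translate-then-filter database aims for
sensitivity, not gene prediction.  `X` residues count toward segment length.
Coordinates are 0-based half-open and frame-local (reverse frames indexed on
the reverse-complement string), and orderings (frames +1,+2,+3,−1,−2,−3,
then position) are fixed so the FASTA/provenance outputs are byte-stable.

## Read trimming

Per read, in order: fixed removal of `trim5`/`trim3` bases; removal of the
maximal prefix and suffix in which *every* base has Phred quality below
`min_quality`; rejection if more than `max_n` ambiguous bases or fewer than
`min_len` bases remain.  This simple end-trimming rule is transparent and
exactly testable; the thresholds are parameters because published
preprocessing rarely states them.

## Redundancy clustering

Assembled transcript sets contain near-duplicate contigs.  Reduction uses
greedy longest-first clustering: sequences are visited in descending length
(ties by id), each joins the first cluster whose representative it matches
at ≥ `identity_threshold` (default 0.95) global identity, else founds a new
cluster.  Identity is computed from a minimum-edit-distance (Needleman–
Wunsch) global alignment via edlib: identity = (alignment columns − edit
distance) / alignment columns, with gap columns counted.  A length-ratio
bound (identity ≤ min/max length) short-circuits hopeless comparisons.  This
is a documented simplification of heuristic production clusterers — exact
pairwise identity, no k-mer prefilter — appropriate at the scales the
package targets; it is not intended for multi-million-contig assemblies.

## Replicate quality control

The QC route, in its documented default order: **consistency filter** (keep
features with a positive, non-missing area in all replicates; zeros count as
missing, because a zero peak area means "not observed"), **unique-peptide
filter** for proteins (≥ 1 unique peptide), **total-area normalization**
(each replicate column scaled so its sum equals the mean of the raw column
sums, conserving the grand total; median normalization available),
**imputation** by half the feature's minimum observed value (half-global-
minimum available), and **statistics**: per-feature mean, sample SD (n−1,
the spreadsheet convention; switchable via `ddof`), CV% = 100·SD/mean, and a
summary mean CV as the unweighted average over features.  Features with zero
mean or fewer than two observed replicates are flagged, excluded from the
summary, and counted in the report.  CVs are scale-invariant, so the summary
does not depend on normalization level — only on its per-column ratios.

## Metabolite annotation

Metabolite names are resolved to KEGG compound identifiers (C#####) through
a compound map with case-insensitive, whitespace-normalized matching; exact
names are tried before synonyms, and stereo-prefix variants (D-/L-) are
handled through explicit synonym entries rather than blanket stripping.
Unmatched records are flagged, never dropped, and count under the "others"
family.  The packaged reference table carries 61 named compounds across
seven families (amino acids, organic acids, carbohydrates, polyols, fatty
acids, phenolic compounds, others), with family membership following the
source table as printed even where chemically debatable (e.g. mannitol under
carbohydrates).  The table's own accompanying text cites 62 compounds for 61
printed rows; the fixture preserves the table and does not invent a
reconciliation.

## Pathway coverage and full reactions

Integration keys are deliberately minimal: compounds match by exact KEGG id,
enzymes by exact canonical EC number.  Wildcard ECs (`2.4.1.-`) match only
other wildcards unless wildcard mode is enabled, in which case they claim
entries sharing the concrete prefix — off by default so that set
cardinalities remain interpretable.  Per pathway the coverage row reports
matched metabolites, detected enzymes per layer, completeness
(detected/total), and the missing-enzyme list; all-zero pathways are kept,
as they are exactly the gaps of the reconstruction.

A reaction triple (EC, substrate, product) is **full** iff four conditions
hold: the EC is detected at the protein level AND at the transcript level,
and both the substrate and the product compound are detected.  Published
figure annotations use the notion without defining it; this four-condition
rule is the package's formalization, and the per-reaction status output
(protein/transcript/substrate/product booleans) lets users apply
alternatives.  A pathway without reaction triples yields an explicit
"not computable" report, never a zero.

Pathway definitions ship as an editable TSV (id, name, compound list, EC
list, optional reaction list) — a mini KEGG-style reference covering
fourteen central pathways, with no live database dependency.  The demo
detection sets are constructed fixtures: 6 of 8 citrate-cycle enzymes and
8 of 10 glycolytic enzymes at the protein level, everything at the
transcript level.  Under the four-condition rule this yields exactly two
full citrate-cycle reactions (citrate → cis-aconitate, fumarate → malate).

The MapMan export writes one row per (sequence, bin) with columns BINCODE,
NAME, IDENTIFIER, DESCRIPTION, TYPE, identifiers lower-cased, rows sorted by
bin code then identifier; sequences without bins are emitted under the
conventional not-assigned code 35.

## Interspecies comparison

Enzyme sets of 2–5 species are partitioned by exact membership pattern
(region counts sum to the union size); pairwise intersections and
per-species unique counts are emitted alongside.  BLAST tabular ingestion
keeps, per query, the hit with the highest bitscore among those passing the
e-value cutoff, breaking ties by lower e-value then file order — a fixed,
documented rule.  The similarity percentage is 100 × (queries with ≥ 1
passing hit) / (total queries), to one decimal; the ≥ 1-hit definition is
the package's documented choice.

## Synthetic generators

`simulate_transcriptome` plants stop-free ORFs of known frame and length
into random background and guarantees the truth is exact: backgrounds
interleave random stretches with 12-nt CTAG tiles (a CTAG repeat is its own
reverse complement and places a TAG stop at every codon phase on both
strands), planted ORFs are encoded with random synonymous codons and flanked
by in-frame stops, and each transcript is re-drawn (bounded retries) if an
unplanted segment above the cutoff survives a naive six-frame scan.  The
CTAG anchoring makes background composition unrealistic for, e.g., codon-
usage studies — it exists purely so that planted truth is provable.

`simulate_quant` draws feature baselines log-uniform over [1e4, 1e7]
(emulating the dynamic range of peak-area tables) and multiplies log-normal
noise with σ² = ln(1 + cv²).  Because the sample SD over n replicates
underestimates the population SD by the factor c4(n) (≈ 0.886 at n = 3), the
calibration divides the target CV by c4(n), so the *measured* mean sample CV
is centered on the target; at 1000 features the measured summary lies within
a fraction of a point of it.  Missing cells are masked independently at a
configurable rate.  The generator emulates multiplicative replicate noise
only — no feature correlation, no intensity-dependent variance, no
systematic batch shifts — so passing QC tests demonstrate the statistics and
filters, not robustness to structured artefacts of real instruments.

Problem sizes used by the tests and the acceptance script (1000 random
sequences for translation cross-checks, 50 sequences / 5 templates for
clustering, 1000 features for CV calibration, 25 transcripts / 10 planted
ORFs for database recovery) were chosen as the smallest scales at which the
checked properties are statistically unambiguous.

## Known limitations

- Clustering is exact-pairwise greedy; no heuristic prefilter for very large
  assemblies.
- Translation supports the standard code only (table 1).
- EC-based joining cannot distinguish isozymes or compartments; coverage
  counts are enzyme-activity counts, not gene counts.
- The replicate-CV comparison against externally deposited supplementary
  tables requires those downloads; the packaged data cannot stand in for
  them.
- Venn partitions are numeric outputs (JSON/TSV); no diagram rendering.
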