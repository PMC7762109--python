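# Methods

This note records the models, rules and numerical choices behind each
analysis stage, the assumptions of the synthetic-data generator, and the
limits of what the test suite demonstrates.

## Study design assumed throughout

Samples are keyed by patient and timepoint (baseline, week 2, week 12),
with each patient assigned to one diet arm (SCD, MSCD, WF). The default
pipeline comparisons reflect the emulated trial: every patient follows the
strict specific carbohydrate diet for the first two weeks, so the
baseline→week-2 comparison pools all patients; week-2→week-12 comparisons
run within arm (two WF patients: P001, P015; three MSCD patients: P005,
P007, P010). Metagenomic sequencing exists at baseline and week 12 only,
so the taxon screen compares those.

## Metaproteomic quantification

Inputs are per-sample PSM tables from two target-decoy searches: the
sample-specific metagenome database and a human reference, both spiked
with common contaminants (trypsin, keratins).

1. **FDR filter.** Records with q-value strictly below 0.01 are kept, per
   search, before merging. The threshold is exclusive because the q-value
   is the minimal FDR at which a match is accepted: "below 1 %" means
   q < 0.01.
2. **Spectrum-level merge.** When both searches identify the same MS2
   spectrum, the identification with the higher search-engine score wins;
   an exact tie goes to the metagenome search, which is the primary,
   sample-specific reference. Ties are rare in real data (continuous
   scores); the rule exists for determinism.
3. **Parsimony grouping.** Shared peptides are assigned to a single
   representative protein by greedy maximum coverage: repeatedly pick the
   protein covering the most unassigned peptides, breaking ties
   lexicographically by accession. Greedy parsimony is the standard
   reading of "representative protein" in metaproteomics and is fully
   deterministic. Groups with fewer than two distinct peptides are
   discarded from quantification (configurable, default 2).
4. **EC roll-up.** A group's EC annotation is that of its representative.
   A group with *k* EC numbers contributes its full PSM count to each of
   them — no fractional splitting, so per-EC counts stay integral.
   Contaminant groups are excluded. Per-sample EC relative abundances are
   normalized over EC-assigned PSMs only, not all PSMs; this makes the
   downstream screen insensitive to the unannotated fraction, which in
   practice varies considerably between samples (roughly 40–60 % of
   microbial groups carry no EC).
5. **Profile summary.** Per sample the package reports both the total
   number of inferred groups and the number supported by ≥ 2 peptides
   (whether a headline "proteins identified" figure refers to the
   pre-filter or post-filter count is genuinely ambiguous in practice, so
   both are emitted); human groups; the EC coverage of the non-human
   fraction; the number of EC families observed; and the inverse Simpson
   diversity of the EC profile.

## The consistency screen

Per-patient fold changes between two timepoints are computed on the log2
scale as `log2((a2 + c) / (a1 + c))` with pseudocount *c* defaulting to
half the smallest non-zero value in the matrix — deterministic,
data-scaled, and finite even when a feature appears or disappears. A
feature absent at both timepoints scores exactly 0.

The screen itself has three rules, all evaluated on log2 fold changes:

1. at least `min_patients_hit` patients at or beyond the fold threshold,
   all such patients agreeing in direction;
2. no patient at or beyond the threshold in the opposite direction;
3. (optional) |mean| > sample SD (ddof 1) across all patients in the
   group.

Choices worth recording:

- **Log2 scale for rule 3.** On the raw ratio scale "magnitude of the mean
  larger than the SD" is ill-behaved — a feature with all ratios near 1
  passes trivially because the mean sits near 1 while the SD is small —
  and increases and decreases are asymmetric. The log scale fixes both.
  The ratio-scale variant remains available (`crit3_scale="ratio"`), and
  the choice is an explicit argument.
- **Inclusive boundary.** "At least F-fold" includes exactly F-fold; the
  comparison carries a 1e-9 absolute slack so that float log2 arithmetic
  cannot exclude an exactly-F-fold change.
- **Sign agreement in rule 1.** Hits in both directions mean there is no
  candidate direction; such features fail rules 1 and 2 by construction.
- **Single patient.** The SD is undefined for n = 1, so rule 3 passes
  vacuously; with the default arms this arises only in user data.
- **k-of-n variant.** The taxon screen is the same machinery with rule 3
  off, a 10-fold threshold and 4 concordant patients required (the
  decrease side can be given its own count).

## Taxonomic filtering and diversity

The species filter is *global*: a taxon is retained when its mean read
count across all samples in the run is at least 100 (inclusive), it is
classified at species rank, and it is not human (detected by a
configurable name set, default "Homo sapiens"; name-based because report
tables commonly carry names, not taxids). A global filter keeps the
retained-taxon set identical across samples, which is why run-level
richness figures are near-constant; the per-sample positive-count richness
and the global retained count are both reported. Unclassified reads are
excluded by the rank filter before proportions are formed.

Inverse Simpson is 1/Σpᵢ² over the column's proportions; it is
depth-invariant, equals the number of positive entries exactly on uniform
columns, and equals 1 when a single taxon dominates. The implementation is
the direct formula; the test suite cross-checks it against scikit-bio's
independent implementation.

## Metabolite statistics

The global-fraction test is a two-sided pooled-variance (equal-variance)
two-sample t-test on log2 areas, missing values dropped per metabolite so
group sizes may differ between metabolites. This specific form was
identified by recomputation against the bundled reference table: it
reproduces the published p-values (including the unequal-n row) where
Welch, paired, and raw-scale tests do not. The implementation is
vectorized over metabolites and verified against scipy's `ttest_ind` to
machine precision. Significance uses an inclusive p ≤ α boundary
(default α = 0.05; the pipeline also reports the p ≤ 0.1 count, a looser
band sometimes used for trend-level reporting). The bundled reference
table prints inputs to two decimals; recomputed p-values therefore carry
up to ~1e-3 of input-rounding error on some rows, which is inherent to the
printed data, not to the test.

Volatile areas are normalized per patient to percent of baseline
(100 × area / baseline area; 0/0 → 0; a zero baseline with later signal
becomes missing, with a warning). Trends between two timepoints are
labelled by strict cross-patient majority among patients with both
measurements — a deliberate, recorded choice where "showed a trend" has no
unique formalization; mean-change labelling is a reasonable alternative.
The paired baseline test is a two-sided paired t on per-patient changes;
an exactly constant non-zero change has zero variance and is reported as
p = 0 with a degenerate-variance flag rather than an exception.

## Synthetic-data generator

One global seed fans out to per-table substreams by CRC32 hashing of the
table name, so adding a table never perturbs another's draws, and the same
seed reproduces byte-identical tables.

**PSM tables.** Each EC class is carried by two homologous proteins.
Per-sample spectral counts follow
`round(2^(offset_ec + patient_effect + planted_shift + N(0, noise_sd)))`
with EC offsets log-uniform over roughly 8–45 counts (planted ECs are
placed in a higher 45–128 band so a 2.5-fold decrease stays above the
integer counting floor). Planted arm-level shifts switch on at week 2 and
persist to week 12; per-patient overrides can contradict them. Each
protein's first two PSMs pin two protein-specific peptides, so every true
protein survives the two-peptide filter and the merge/group/normalize path
is provably lossless: the pipeline's EC matrix equals the emitted truth
matrix exactly (a test asserts equality to 1e-12). Shared peptides (default
rate 0.2) map to both homologs of one EC; unannotated microbial proteins
(about two per EC), human-search records, spectra identified in both
searches (the correct identification scoring higher), contaminant records
and ~1 % junk records with q ≥ 0.01 provide the nuisance structure.

**Taxon tables.** Per patient, baseline species proportions are Dirichlet
(α = 0.7, strongly individual); counts are multinomial at a desk-scale
depth of 1e5 reads (the emulated studies sequence ~1e8; depth only scales
counting noise, and the ≥ 100-mean-reads filter is applied at whatever
depth is configured). A human species, an unclassified bin (30 %) and a
genus-rank row exercise the filters. Planted taxa start at detectable
proportions (0.2 % for increases, 2 % for decreases) and change
*at least* the stated fold — deterministically in count space with a 5 %
margin — in the first `n_patients_affected` patients at week 12. The
margin exists because both integer rounding and the screening pseudocount
attenuate an observed ratio; planting exactly at the screen's threshold
would make recovery a coin flip on numerical noise rather than a test of
the screen. "Planted 10-fold" therefore means "changed 10-fold or more",
matching the structure being emulated.

**Metabolite tables.** Global log2 areas are
`metabolite_offset + patient_baseline + planted_shift + N(0, noise_sd)`
with offsets in the observed 17–28 range, noise_sd defaulting to 0.5 and
the per-patient baseline offset to 0.15 (the within-group SDs of the
reference table average ≈ 0.55, consistent with this split; the patient
offset is kept small because global-fraction intensities are normalized
during processing). Because the same patients appear in both groups, a
shared patient offset makes the unpaired test slightly conservative; with
these defaults the null rejection rate at α = 0.05 is ≈ 0.043 rather than
0.050, which the calibration test measures directly. Cells go missing
completely at random at rate 0.01. Volatile raw areas are log-normal and
strictly positive with every baseline defined.

What the generator does **not** emulate: compositional correlation between
features, longitudinal autocorrelation beyond the planted shifts,
peptide-level FDR miscalibration, chimeric or mis-assigned spectra,
batch/run-order effects, and non-normal metabolite noise. Passing
recovery tests therefore show the pipeline implements its rules correctly
and losslessly — not that the rules are powerful or calibrated on real
stool data.

## Problem sizes used in automated checks

Recovery and calibration checks run at desk scale chosen as the package's
own test sizes: 120 EC classes for the end-to-end EC screen recovery, 150
species at 1e5 reads for the taxon screen, and 2000 replicates of 170
metabolites for the null calibration. The generator's defaults (700 ECs,
400 taxa, 170 metabolites, 5 patients × 3 timepoints) mirror the emulated
study's scale and are exercised by the CLI.

## Known limitations

- Representative-protein choice is greedy, not optimal set cover; ties
  beyond lexicographic order are not explored.
- EC annotation comes from the representative only; a group whose members
  disagree in EC is quantified under the representative's annotation.
- The consistency screen provides no error control; it is a transparency
  heuristic for tiny cohorts, and its output should be read as candidate
  lists, not discoveries.
- The volatile-fraction statistics (percent-of-baseline scale, majority
  trends) are descriptive; the paired test's scale (raw vs normalized) is
  a user choice and materially affects p-values.
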