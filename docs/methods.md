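# Methods

## Molecular readout

### Marker model

A marker is an amplicon over a locus whose CpGs are unmethylated in colon
epithelium and methylated in the leukocyte background that dominates plasma
cfDNA. Coordinates are 0-based, intervals half-open, and the amplicon is
stored in sequencing orientation; reverse-strand logic is deliberately
absent because an amplicon assay reads a fixed strand. Panel validation
enforces: every declared CpG sits on a CG dinucleotide outside the primer
spans, positions are strictly increasing, each primer contains at least four
CH cytosines (cytosines not followed by G — the design rule that makes
amplification specific to bisulfite-converted templates, since unconverted
DNA retains those Cs and no longer matches the primer), at least one CpG
lies between the primers, and barcodes/names are unique.

The shipped 8-marker panel carries the assay's marker names (FGFRL1, Col1,
ECH1 and five cg-identified loci) over deterministic synthetic sequences
(4–8 CpGs each, produced by a fixed-seed generator), because the real
amplicon sequences are not publicly deposited. The fixture is a stand-in for
testing, not a claim about the real loci. Fixture barcodes are 8-mers over
A/G/T with pairwise Hamming distance ≥ 3: containing no cytosine, they are
inert to bisulfite chemistry, and distance ≥ 3 keeps single-error reads
uniquely assignable.

### Read simulation

Each simulated molecule is colon-derived with probability `colon_fraction`
(default 0.05 — the order of magnitude of tumor-derived signal in plasma).
Colon molecules are unmethylated at every marker CpG, background molecules
methylated at every one; partially methylated background is outside the
default model because the markers were selected for bimodal tissue
specificity. Noise: each unmethylated C (CH everywhere, plus CpG on colon
molecules) converts to T with probability `conversion_efficiency` (default
0.995, typical of commercial bisulfite kits); methylated CpG Cs convert
wrongly at `inappropriate_conversion_rate` (default 0.002); substitution
sequencing error is applied per base at `seq_error_rate` (default 0.001);
an optional 1-bp indel rate (default 0) exists for stress tests, off so the
alignment-score arithmetic stays analytic. Errors apply to the insert, after
which the barcode is prepended. Base qualities are constant dummies because
the pipeline never consults them. Default depth is 5,000 molecules per
marker, chosen for statistical power at the fractions of interest rather
than as a claim about real run depth (per-sample coverage tables for the
real assay are not available).

What the simulator does *not* model: PCR duplicates and amplification bias,
UMIs, quality-dependent errors, strand asymmetries, and partially methylated
background molecules. Passing recovery tests therefore demonstrates the
correctness of the estimator under the mixture model, not robustness to
every artifact of real sequencing.

### Alignment and calling

Reads are demultiplexed by barcode prefix (Hamming distance ≤ 1 by default;
a tie between barcodes is never guessed — the read is binned unassigned).
Each read is aligned end-to-end to its marker's *unconverted* reference with
a conversion-tolerant asymmetry: read T opposite reference C scores as a
match (C→T chemistry on the sequenced strand), read C opposite reference T
is a mismatch. Scoring is match 0, mismatch −6, gap open −5, gap extend −3;
a read is accepted iff its score is ≥ −0.2 × read length, boundary
inclusive ("minimum score" read as attainable). The threshold is from the
assay's published pipeline convention; the penalty constants are this
package's documented choice of the scoring regime in which that threshold is
conventionally expressed, and they are configurable. Reads shorter than 30
bases are rejected as too short. The affine-gap DP is Biopython's
`PairwiseAligner` with an asymmetric substitution matrix; tie-breaking among
co-optimal paths follows Biopython's deterministic first-alignment order
(the score, acceptance decision, and CpG readout are tie-invariant in
practice, and end-to-end determinism is tested).

Because amplicon reads without indels have exactly the reference length, the
implementation scores those reads gaplessly in a vectorized batch and only
falls back to the full DP for length-discordant reads and for reads the
gapless score rejects (a gapped alignment can only raise the score, so the
acceptance decision is identical to running the DP on everything).

Each marker CpG is read from the aligned dinucleotide: CG → methylated,
TG → unmethylated, anything else (N, gap, uncovered position, other
dinucleotides) → ambiguous, never silently dropped. A molecule is fully
unmethylated iff every call is unmethylated; ambiguous calls keep the
molecule in the denominator but out of the numerator, which can only deflate
the colon-derived estimate — the conservative direction for a
positive-finding score. An optional conversion-QC filter
(`max_retained_ch`) can drop accepted reads with many retained CH cytosines;
it is off by default since the primer design already selects converted
templates.

### Quantification

Per marker: fraction = fully-unmethylated / accepted; zero accepted
molecules makes the fraction undefined (flagged, never coerced to 0).
Copies/ml = fraction × total cfDNA (ng/ml) × 303, the ng→haploid-genome-
equivalent factor implied by the 3.3 pg haploid genome mass. The per-sample
c-cfDNA score is the arithmetic mean of copies/ml over markers with defined
fractions, with the contributing-marker count reported; the mean (rather
than pooling molecules across markers first) is a documented choice — the
published value is described only as an "average copies/ml" — and is robust
to a failed amplicon. QC per sample reports per-marker totals, acceptance,
rejection reasons, ambiguous-call rate and unassigned reads, and the counts
are conserved: accepted + rejected + unassigned equals input reads.

## Cohort simulation

Patients (default n = 37) draw pathCR with probability 7/37 and, if not
pathCR, a TRG 1/2/3 split of 11:11:8 — the composition of the motivating
cohort. Combined c-cfDNA at each weekly first-day timepoint (W1D1…W5D1) is
log-normal, log-SD 1.0, with group medians defaulting to 8.6 (pathCR) vs
57.7 (residual) copies/ml at W2D1; baselines (30 vs 45) differ modestly, and
later weeks drift upward in both groups, reflecting treatment-induced
normal-tissue damage. These off-W2D1 medians are free parameters of the
simulator (no published per-week values exist to emulate); log-normality itself
is a modeling choice — strictly positive, heavy-tailed, consistent with the
order-of-magnitude spread between group medians.

The W1D1→W2D1 *increase* indicator is coupled to relapse directly (increase
probability 1 for relapsers, 7/17 for non-relapsers) because that indicator
is the analyzed quantity. Coupling applies within the residual-disease
group, the population of the recurrence analysis; pathCR patients keep their
unconditional week-2 marginal, which their low median already drives toward
a decrease. Mechanically, the coupled week-2 value is drawn from the group
log-normal truncated above/below the patient's baseline by inverse-CDF
sampling, so the configured increase probabilities hold exactly while the
marginal stays close to its configured shape. Exact marginals and arbitrary
increase probabilities cannot hold simultaneously (probability 1 of increase
is incompatible with overlapping marginals), so the configured medians are
exact for the unconditional draws (baseline, pathCR week 2, later weeks) and
approximate for the coupled residual week 2; a `couple_increase=False`
switch restores pure marginals everywhere, and is what the null-calibration
tests use to make the two groups distributionally identical. At zero
dispersion every value equals its group median exactly.

Relapse probability is 1/7 in the pathCR group and 8/30 otherwise; relapse
times are log-normal with median 20 months (log-SD 0.5), right-censored at a
follow-up drawn uniformly on 15–35.6 months (median 25.3). A relapse beyond
follow-up is recorded censored. Adjuvant therapy (20/37) and a
baseline-KRAS-detected flag (6/37) are carried as inert covariates.

## Statistics

* **Mann-Whitney U**: midranks for ties; exact enumeration p when the
  smaller group has ≤ 8 observations and the pooled sample is untied,
  otherwise normal approximation with tie and continuity correction
  (delegated to `scipy.stats.mannwhitneyu`; validated against a full
  rank-assignment enumeration oracle). One-sided use requires the caller to
  fix the direction; the built-in baseline TRG analysis pre-registers
  "responders lower".
* **Fisher's exact**: two-sided p as the sum of same-margin table
  probabilities ≤ the observed table's (scipy's convention, verified against
  an exact `math.comb` hypergeometric enumeration for all margins ≤ 12).
  This convention reproduces p = .019 from the printed 7/7 vs 7/17 table.
* **ROC/AUC**: AUC is the concordance probability with ties at ½
  (equivalently the trapezoidal area); the CI is DeLong by default
  (deterministic) with a seeded stratified bootstrap as an option; the
  reported p tests AUC = 0.5 via the DeLong variance. Curves always include
  (0,0) and (1,1).
* **Survival**: Kaplan-Meier per group and the log-rank test, via
  `lifelines`; with no censoring the KM estimate equals the empirical
  survival function (tested).
* **Dynamics**: INCREASE iff value(W2D1) > value(W1D1) strictly; ties are
  NO_INCREASE — conservative toward the negative-prognosis call, which the
  source dichotomy leaves undefined. Patients missing either timepoint are
  excluded with a logged reason.
* The report runs: healthy-vs-patient baseline comparison and ROC (when
  controls are given), baseline TRG 0–1 vs 2–3 (one-tailed), W2D1 pathCR vs
  residual (two-tailed, with ROC), increase × relapse Fisher (subgroup
  selectable — the published subgroup denominator is ambiguous, so it is an
  explicit argument rather than hard-coded), and KM/log-rank by dynamics
  group. Arms with < 2 observations (or a missing relapse arm) skip the test
  with an explicit reason. P-values are unadjusted, mirroring the published
  analyses; the count of tests performed is part of the report.

## Reproducibility and numerics

All randomness flows from integer seeds through `numpy.random.default_rng`;
the CLI derives named substreams (reads/cohort/roc) from one global seed, and
identical configuration reproduces every output byte for byte. Cohort CSVs
are written with `%.17g` and parsed with round-trip float precision so a
write/read cycle loses nothing. Undefined quantities are NaN plus an explicit
QC flag, never silent zeros. Fisher float ties are compared with a 1e-7
relative tolerance inside the enumeration oracle; the production path uses
scipy's exact computation.

Problem sizes used by the test-suite properties are the package's own
choices: 50,000 molecules/marker × 20 seeds for parameter recovery (mean
absolute error under twice the binomial SE), 2,000 null cohorts for type-I
calibration of the W2D1 comparison ([0.03, 0.07] at α = .05), 1,000 cohorts
for the power regression guard (> 60% rejection under the default effect),
and 10,000 patients/group (averaged over 5 seeds) for median calibration
within 2%.

## Known limitations

* Fixture marker sequences are synthetic; absolute per-marker fractions on
  real data depend on locus-specific context the fixtures do not carry.
* The read simulator's background is fully methylated; real plasma contains
  low-level partially methylated molecules that would enter the denominator
  but (by the all-CpG rule) essentially never the numerator.
* The cohort simulator reproduces the *structure* of the clinical analyses
  (group sizes, medians, coupling, censoring), not patient-level biology;
  published patient-level results (e.g. baseline AUCs) are not reproducible
  from synthetic data and are not claimed.
* Only two-group log-rank comparisons are exercised by the built-in report;
  the k-sample generalization is available but untuned.
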