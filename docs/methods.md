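# Methods

This note documents the models, defaults and design choices behind
`metabosig`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator (`metabosig.simcohort`) emulates a longitudinal disease
surveillance cohort profiled by DI-MS. Its defaults describe the cohort
structure such a study reports:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 200 | unique patients |
| `visits_per_subject` | (1, 3) | visits drawn uniformly from this range |
| `case_prevalence` | 0.08 | subject-level probability of the phenotype |
| `confounder_rate_in_cases` | 0.82 | fraction of cases on the treatment (UDCA analogue) |
| `confounder_rate_in_controls` | 0.0 | treatment is absent among controls |
| `sex_ratio` | 0.5 | P(female) |
| `n_features` | 1000 | m/z features, uniform in [70, 1000] Da with ≥ 2 ppm spacing |
| `n_planted` | 50 | differential features |
| `planted_log2fc` | 1.0 | per-feature case effect on the log₂ scale |
| `planted_frac_up` | 1.0 | fraction of planted effects that are increases |
| `batch_count` | 5 | day-of-run batches (contiguous in injection order) |
| `batch_shift_sd` | 0.3 | SD of the per-(batch, feature) log₂ shift |
| `replicate_count` | 3 | technical replicates per sample |
| `replicate_noise_sd` | 0.2 | log₂ technical noise |
| `biological_sd` | 0.8 | log₂ between-sample biological variation |
| `missing_rate_base` | 0.10 | target marginal missing fraction |

A cell's log₂ intensity is feature baseline (uniform 10–20) + planted class
effect + batch shift + biological term + replicate noise; the stored
intensity is 2 to that power. Missingness follows the dominant DI-MS
mechanism, low-abundance censoring: the probability a cell is missing is a
logistic function decreasing in the latent log₂ intensity, whose location
is calibrated by bisection so the realised marginal rate matches
`missing_rate_base`. Class is fixed per subject (no mid-follow-up onset);
visits beyond repeated sampling carry no time structure.

For the enrichment path, `planted_compound_frac` anchors that fraction of
the planted features at the [M+H]⁺ m/z of real small-molecule formulas from
a built-in catalogue of 120 plasma/gut metabolites, and
`background_compound_features` anchors additional null features at further
catalogue compounds, so that annotation has both signal and a detectable
background universe. The association-table generator draws taxon–compound
rows whose pass/fail status under the downstream inclusion filter
(adjusted p < 0.05 and ϱ > 0) is set by construction, making
database-builder recovery exactly checkable; an optional planted taxon
contains a chosen compound list with all rows passing.

What the generator does **not** emulate: raw spectra, scan merging or peak
calling; chromatographic or chemical realism beyond formulas; correlated
feature blocks (features are independent given class/batch); drift along
injection order within a batch; multiple ionisation modes (a mode tag is
carried but unused). Passing tests therefore demonstrate correctness of the
statistical machinery under these idealised conditions, not performance on
real spectra.

## Preprocessing

Default order: missingness filter → quantile normalisation → autoscaling →
per-batch median centering → replicate averaging, with the applied steps
recorded as provenance. Decisions worth noting:

- **20% rule at sample level.** A feature counts as present in a sample if
  at least one technical replicate recorded a signal; a feature is removed
  iff its missing-sample fraction strictly exceeds the threshold (a
  2-of-10 feature survives at 0.20).
- **Quantile normalisation** aligns each replicate spectrum's order
  statistics to their across-spectrum means; tied values receive the mean
  of their tied reference quantiles; incomplete rows map through
  interpolated reference quantiles.
- **Batch correction** is per-feature, per-batch median centering (the
  global median is restored). This removes day-of-run location shifts —
  the role batch correction plays in this workflow — without requiring an
  ICA decomposition; injection order is carried in the metadata but unused
  by default.
- **Averaging then re-scaling.** Replicates are averaged after
  normalisation; because averaging shrinks variance, autoscaling is
  re-applied at the sample level so the unit-variance contract holds on
  the matrix models actually consume.
- **Two scales.** Statistical tests run on the fully processed
  (autoscaled) matrix; fold changes are computed on the positive,
  quantile-normalised intensity scale (log-ratios are undefined on
  mean-zero data), with residual missing values imputed at half the
  feature's minimum observed value — the common metabolomics floor
  convention.

## Splitting

Assignment is by subject throughout. The stratified grouped k-fold uses
the standard greedy bin-packing heuristic: subjects in decreasing
sample-count order, each placed in the fold currently lightest in the
subject's stratum (then lightest overall, then lowest index). On small
instances this matches the best achievable per-fold class balance found by
brute-force enumeration (checked in the tests). The dual-variable scheme
stratifies case subjects on the treatment variable and reduces the fold
count to the rarest category's subject count, so each fold receives
exactly one rare-category case when the two are equal; with fewer than two
rare-category subjects it falls back to plain class stratification with a
warning. The 80/20 holdout applies the same secondary stratification, so
rare untreated cases appear in both fractions. Splits are re-drawn per
classification question (label name + seed key the plan).

## Classification

- Forests use 500 trees by default (the common default; only mtry is
  dictated by the workflow, as ⌊√p⌋) and derive per-fold random states
  from a seed sequence, so fits are reproducible.
- AUROC is computed from the rank statistic with ties counted half; AUPRC
  by step-wise precision–recall integration (average precision).
- The label permutation for the negative control acts at subject level:
  each subject receives another subject's label, keeping all of a
  subject's samples concordant and subject-level class counts exact.
- The DeLong comparison is one-sided (experimental > control), as the
  question is whether the real labels add signal; a zero-variance
  difference (identical scores) short-circuits to p = 1 with a degeneracy
  flag.
- The bootstrap subgroup test draws matched-size subsets *without*
  replacement from the pooled scores (with-replacement is available behind
  a flag), redraws single-class subsets, and applies a two-sided
  one-sample t-test of the bootstrap AUROC distribution against the
  subgroup's observed AUROC. If every draw yields the same AUROC (a
  saturated classifier) the t statistic is undefined and the degenerate
  answer (p = 1 if equal, else 0) is reported instead of NaN.

## Ranking

The t-test is Welch's (unequal variances) — the safer default when case
and control groups differ in size and spread. p = 0 underflows are clipped
to the smallest positive float with a warning so V stays finite.
Zero-variance features get p = 1, V = 0 and a flag. Ranking is by |V|
descending with ties broken by smaller p, then lower m/z, making the order
total and deterministic. The logistic alternative fits each feature by
Newton–IRLS (identical to a standard ML logistic fit; verified against
statsmodels in the tests); fits that separate or fail to converge are
refitted with a tiny ridge (1e-6) on the slope and flagged, which caps |Z|
at a large finite value instead of diverging. Fold-change direction is
fixed as case mean ÷ control mean everywhere.

## Signature determination

Per fold, the top-k features of that fold's own training ranking are
independently permuted across samples (methods-level permutation, not
removal; removal of columns would change p and hence mtry), the fold's
forest is retrained, and held-out scores are pooled. The random arm
accumulates its permuted set so exactly k features are disturbed at grid
point k; the label-shuffled arm applies the same ranked permutation under
subject-permuted labels. The grid advances by `step` (default 50) and may
stop early once the ranked arm sits within a noise band (default 0.05
AUROC) of the shuffled arm for three consecutive points — but never before
five grid points exist, the minimum for elbow detection.

The elbow is the grid point minimising |d(smoothed AUROC)/dk|, with the
smoother a local-linear lowess fit (tricube weights, span 0.75 by default;
pass a smaller span for low-noise curves), the derivative taken by central
differences, k = 0 excluded, minimisation by discrete descent from multiple
starts, and near-ties (within 1e-9) resolved toward smaller k so the
earliest flat point wins. A curve whose smoothed decline is below
`flat_tol` (0.02 AUROC) carries no signal: the size is reported as 0 with
a no-signal flag rather than an arbitrary elbow.

## Enrichment

The 19 default adducts are the common ESI set ([M+H]⁺, [M+Na]⁺, [M+K]⁺,
[M+NH₄]⁺, [M+2H]²⁺, [2M+H]⁺, [M+H−H₂O]⁺, [M+ACN+H]⁺, [M+CH₃OH+H]⁺, [M−H]⁻,
[M+Cl]⁻, [M+FA−H]⁻, [M−2H]²⁻, [2M−H]⁻, [M−H−H₂O]⁻, [M+Na−2H]⁻, [M+K−2H]⁻,
[M+Br]⁻, [M+HAc−H]⁻), with exact electron-mass bookkeeping; the table is a
user-replaceable default, not a fixed canon. Matching tolerance defaults to
5 ppm — typical for high-resolution annotation and deliberately distinct
from the 2 ppm bin width of the upstream peak tables; both are knobs.

EASE is the analytic hypergeometric tail at overlap − 1 (k ≤ 1 ⇒ p = 1);
no permutation-based empirical p-values are computed. The universe N is
the number of database compounds matchable to the *full* measured feature
list, so enrichment conditions on detectability rather than on the whole
database. A compound matched by several m/z or adducts counts once.
Pathway exclusion removes sets whose names pair an essential amino acid
(histidine, isoleucine, leucine, lysine, methionine, phenylalanine,
threonine, tryptophan, valine) with "synthesis"/"biosynthesis"
(case-insensitive substring match) — humans cannot synthesise these, so
their biosynthesis pathways are uninterpretable in plasma — while
degradation sets are retained. The microbe database builder keeps rows
with adjusted p strictly below α, ϱ strictly positive, and a resolvable
compound id + formula; empty taxa are dropped.

## Orchestration and problem sizes

`workbench.run_pipeline` chains the eight stages and writes a manifest
with per-stage output checksums; identical config + seeds reproduce the
checksums bit for bit. The acceptance script runs the pipeline at 200
subjects × 1000 features with 100-tree forests and a 100-feature grid step
— sizes chosen so a complete desk-scale replication finishes in minutes on
a single core while keeping every stage's statistical behaviour visible.
The heaviest test (three-arm elimination curves at 2000 features × 5
seeds) uses a 200-feature step and 100 trees for the same reason.

## Known limitations

- Independent features in the generator mean co-selection effects
  (correlated metabolites entering the signature together) are not
  exercised.
- The elbow of a permutation curve is only defined up to the grid step;
  reported signature sizes inherit that granularity.
- Per-feature logistic fits ignore within-subject correlation of repeated
  visits, exactly as the univariate t-test does; both are screening
  statistics, not inference.
- The EASE tail is conservative by construction; calibrated false-positive
  rates below nominal are expected and observed in the null simulations.
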