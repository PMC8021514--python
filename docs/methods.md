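# Methods

This note records the statistical conventions, the synthetic-data model,
and the design decisions behind `methylpanel`, in enough detail to audit or
re-derive any number the package produces.

## Data model

Methylation is represented as the Infinium beta value — methylated signal
over total signal, a fraction in [0, 1] — in a probes × samples matrix
with an optional, identically shaped detection p-value matrix. The
canonical internal scale is the fraction; the percent scale appears only
at I/O boundaries and in marker cut-off display (clinical pyrosequencing
reports percents). Missing betas are allowed and are excluded pairwise per
probe per test. Probe annotation uses the closed manifest vocabularies:
chromosome 1–22/X/Y, CpG-island relation {Island, N_Shore, S_Shore,
N_Shelf, S_Shelf, OpenSea} and gene-region class {TSS1500, TSS200, 5'UTR,
FirstExon, FirstIntron, GeneBody, Intergenic}, with common manifest
aliases ("Body", "Open sea", "1stExon", …) normalized on read. Probe
coordinates are treated as 1-based manifest positions and passed through
untouched.

## Statistical conventions

* **Sidedness.** Every p-value is two-sided.
* **Welch's t.** Unequal-variance t statistic with Welch–Satterthwaite
  degrees of freedom (scipy). Two degenerate inputs are documented rather
  than fatal: both groups constant with equal means gives statistic 0,
  p = 1; both constant with unequal means gives ±∞, p = 0.
* **Bonferroni.** min(1, m·p), with m equal to the number of probes
  actually tested in that screen (the post-QC analysis set), not the
  array's nominal probe count. The selection rule "adjusted p < α" is used
  throughout; it is equivalent to raw p < α/m.
* **Fisher's exact test.** Two-sided by the probability-mass rule: the sum
  of hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed the observed table's (scipy's
  convention; implementations differ, so the rule is stated). A zero
  margin gives p = 1.
* **ROC curves.** Threshold candidates are the midpoints between
  consecutive distinct pooled values plus ∓∞ sentinels, so calls are
  stable under measurement jitter and no observed value sits exactly on a
  threshold. AUC is the trapezoid over the resulting curve, which equals
  the tie-corrected rank statistic P(positive on the positive side) +
  ½ P(tie); the equivalence is enforced by test against a pairwise
  enumeration oracle.
* **Youden cut-offs.** The threshold maximizing J = sensitivity +
  specificity − 1; ties break toward higher sensitivity, then toward the
  more permissive threshold (the one admitting more positive calls). A
  value exactly at the cut-off is **not** called positive: the directional
  rules are strict ("lower than the cut-off").
* **Kaplan–Meier / log-rank.** Product-limit estimate (lifelines); the
  median is the first time with S(t) ≤ 0.5, absent if never reached.
  The two-group log-rank chi-square (1 df) is computed after sorting each
  group by (time, event), which makes results bit-identical under input
  permutation; symmetry under group swap holds to floating-point
  round-off.

Welch, Fisher, Pearson, KM and log-rank are delegated to scipy/lifelines
behind this module's surface; ROC/Youden machinery and all pipeline logic
above it are implemented here. Every primitive is tested against an
independent brute-force oracle (enumeration over fixed-margin tables,
pairwise rank counting, exhaustive threshold scans, hand-worked O−E/V and
product-limit tables).

## Probe QC

A probe is *called* in a sample when its detection p-value is below 0.01.
Probes called in fewer than 90% of samples are removed first (low call
proportions suggest polymorphism at the probe CpG); X/Y probes are removed
second (sex-specific methylation bias). The precedence matters for
bookkeeping: a probe failing both criteria is counted once, under
`low_call`, so exclusion totals partition the input. Both thresholds and
the sex-probe drop are parameters.

## Differential screens

Each screen is a per-probe Welch test plus an effect-size filter
|Δβ| > 0.1, where Δβ is the difference of group means (group A − group B).
The tissue contrasts (T-vs-C, T-vs-N) apply Bonferroni; the ER marker
screen deliberately uses raw p — this asymmetry is preserved from the
analysis the package reimplements, where the genome-wide contrasts guard
the family-wise error but the 82-patient marker screen trades strictness
for recall and relies on the downstream AUC filter and external
validation. Probes with fewer than two non-missing values in a group are
skipped and logged, and do not enter the Bonferroni factor.

## Epigenotyping

PCA mean-centers per probe without variance scaling (betas share a scale,
and variance scaling would up-weight noise in invariant probes), computes
scores by SVD, and fixes signs so each component's largest-magnitude
loading is positive. Hierarchical clustering implements the classical
Ward objective on Euclidean distances (the "Ward.D2" convention) directly
via the Lance–Williams recurrence; the variant is recorded in the output
(`ward.D2-euclidean`) because the two common Ward variants differ and the
choice affects cluster boundaries. Tie-breaking is deterministic — among
equal-cost merges, the pair containing the smallest sample index wins —
so the partition is invariant to sample input order. The flat cut takes
exactly k clusters by merge order; k defaults to 4 but is a parameter.
Post-hoc merging of clusters into super-groups (e.g. high-risk vs
low-risk) is an explicit user-supplied mapping, never inferred. The O(n³)
implementation is deliberate: target cohorts have at most a few hundred
samples, and determinism is worth more than asymptotics here.

## ER definition and marker panels

ER is relapse within `er_window_days` of surgery, default 183 days (six
months is nowhere defined in days; 183 is the parameterized choice).
Patients without recurrence are non-ER; a non-recurrent patient whose
follow-up is shorter than the window is logged as indeterminate but
counted non-ER, a tolerable simplification when recurrence ascertainment
is near-complete. Marker direction derives from the screen's Δβ sign (ER
mean below non-ER mean ⇒ ER_below) and is never refit at transfer; cut-offs
are frozen at discovery. Panel evaluation reports sensitivity and
specificity in percent (one decimal) for every voting threshold k, and
asserts the voting monotonicity (sensitivity non-increasing, specificity
non-decreasing in k) as a post-check. On synthetic data the top-n panel is
chosen by AUC rank with probe-id tie-break; real panels are additionally
constrained by assay feasibility, which is not modeled.

Pyrosequencing replicates merge by the duplicate mean; a discordance of
more than 10 *percentage points* (absolute, per the wording "more than
10%") requires a third replicate and the triplicate mean. Calibration
fits a least-squares line through measurements of 0/50/100% methylated
controls and passes when the slope lies in [0.9, 1.1] with no residual
above 5 points (a conventional linearity tolerance; both bounds are
visible in the result object, not hidden).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
fixed to the study conditions: 17 normal-control (C), 34 non-cancerous
(N) and 82 tumor (T) samples; 22 of 82 tumors ER; 5,000 probes; 50
planted probes per tissue contrast at Δ = 0.30; 3 planted ER markers at
Δβ = 0.15; 1% planted QC failures; 2% X/Y probes.

* **Background.** Each probe draws i.i.d. from one of two Beta components,
  Beta(2, 8) or Beta(8, 2) (means 0.2 / 0.8, sd ≈ 0.115), reproducing the
  bimodality of array betas.
* **Planted shifts.** A shifted group draws from Beta(c₁m₁, c₁(1 − m₁)),
  whose mean is exactly the target m₁; the concentration
  c₁ = max(c₀, m₁(1 − m₁)/v₀ − 1) caps the planted group's variance at
  the background component's v₀. This is a pure shape re-parameterization:
  no additive offsets, no clipping, zero mean bias (verified to < 0.02
  averaged over seeds). Tissue-contrast probes shift all T samples from
  the component with room for the shift; ER markers shift ER tumors
  toward the nearest boundary (near-complete methylation loss or gain),
  which is what usable clinical markers look like and what keeps their
  within-group spread tight.
* **QC failures.** Good probes have detection p ~ U(0, 0.005); each
  planted QC-fail probe gets detection p in (0.02, 0.5) in just over 10%
  of samples (exact count, so the call-proportion filter provably catches
  every planted failure at every seed).
* **Clinical records.** ER tumors relapse at U(60, 180) days and die at
  RFS + U(30, 240); non-ER tumors relapse at U(200, 1500) with death
  probability 0.6 (censored otherwise). All tumor patients recur — the
  modeled cohort had near-complete recurrence — and RFS ≤ OS always
  holds. N samples carry their patient's clinical record; C samples have
  no survival data.
* **Reproducibility.** One seed fixes every byte of the written fixture
  bundle. A separate `layout_seed` (defaulting to the seed) governs probe
  roles, mixture components and annotation, so a validation cohort can
  share the discovery cohort's generative layout (same planted probe
  identities) while drawing independent samples — without this, frozen
  panels could not meaningfully transfer between synthetic cohorts.

**What the generator does not emulate**, hence what passing tests do not
show about real data: Infinium I/II chemistry bias, batch effects,
copy-number contamination, correlated probes (each probe is independent,
so there is no planted tumor-subtype cluster structure and no built-in
association between epigenomic clusters and ER), partial tumor-cell
content, or formalin-fixation artifacts — the very effects that made the
original validation cohort harder than its discovery cohort. Synthetic
transfer results are therefore optimistic relative to FFPE reality.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to make every stochastic bound sharp but cheap: 5,000-probe
cohorts for the screen and end-to-end checks (50 seeds for marker
recovery and panel transfer), 10,000 simulated tests for the null
uniformity of Welch p-values, exhaustive Fisher enumeration for all 2×2
tables with total ≤ 24, and 200 random instances for the AUC/rank-statistic
equivalence. The derived acceptance bounds (e.g. ≥ 48/50 planted probes
recovered per seed; ≥ 80% of seeds recovering ≥ 2 of 3 planted markers)
were computed from the generative model with independent oracles before
being frozen into tests.

## Known limitations

* Bonferroni is the only multiplicity correction offered; no FDR.
* No Cox or multivariable survival modeling; the survival module is
  strictly the two-group contrast.
* The Ward implementation is O(n³) and intended for cohort-scale n (≤ a
  few hundred samples), not single-cell scale.
* GEO series-matrix parsing covers the beta-table dialect (metadata lines
  plus the sentinel-delimited table), not supplementary IDAT or raw
  intensity formats.
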