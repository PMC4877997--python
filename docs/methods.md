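# Methods

## The mixture model

A bulk expression profile of a sorted cell population is modelled as a
convex combination on the TPM scale,

    x = (1 − Σ_c α_c) · t + Σ_c α_c · r_c ,

with `t` the (unobserved) pure target profile, `r_c` a pure reference
profile of contaminating cell type `c` and `α_c ∈ [0, 1)` the fraction of
transcript mass it contributes. The model is deliberately targeted: it
corrects a sorted population for a small number of known contaminant types
(two or three populations in practice), not a full compositional
deconvolution into arbitrary many cell types. Reference purity is an input
assumption (in the motivating application it is verified by flow
cytometry); references are single pure profiles or means of several.

### Marker selection

For each (target, contaminant) pair, candidate markers must satisfy, on the
reference profiles:

* contaminant TPM ≥ `min_contam_tpm` (default **30**) — strong signal so the
  observed/reference ratio is stable;
* target TPM ≤ `max_target_tpm` (default **1**) — near-silence so the target
  contributes (almost) nothing at the marker;
* TPM ≤ `max_target_tpm` in **every other** reference profile, so each
  panel reads out one contaminant specifically in three-population
  settings.

Candidates are ranked by `(contaminant + pseudocount)/(target +
pseudocount)` (pseudocount **1**), ties broken lexicographically by gene id
for reproducibility, and the top `panel_size` (default **17**) kept. If
fewer are eligible, all are returned with a warning; zero eligible genes is
an error advising threshold relaxation. The thresholds make markers behave
as near-binary indicators; all are configurable.

### Estimation and adjustment

For each panel, `α_c = median_g clip(x_g / r_{c,g}, 0, cap)` over the
panel's marker genes. The **median** is robust to the occasional marker the
target does express; the **cap of 0.6** bounds the influence of a single
aberrant marker and of genuinely extreme mixtures. Estimation is
single-pass: because markers are near-silent in the target, iterating
estimate→adjust changes nothing at first order.

Adjustment subtracts all contaminants jointly, `max(0, x − Σ_c α_c · r_c)`,
then renormalises once to 10⁶. Clipping at zero is the minimal repair for a
quantity that is non-negative by definition; renormalisation redistributes
the removed mass from contaminant-derived to target-derived genes, so
target markers rise while contaminant markers fall. Samples with
`Σ_c α_c >` **0.20** are flagged `excluded` — the threshold separates the
contamination regime the correction handles well (up to roughly 17 %) from
heavily contaminated samples (roughly 25 % and above) whose corrected
profiles should not be trusted; flagged samples are still adjusted and
retained so the exclusion decision stays with the analyst.

Exactness: when the target is exactly silent at the markers and the true
contaminant profile is used as reference, mix → estimate → adjust is an
identity up to floating-point error, which the round-trip tests assert at
1e-9 (fraction) and 1e-6 TPM (profile).

## In-silico validation

The benchmark mixes pairs of purified samples of different cell types at a
uniform random fraction in [0, 0.5]. Read resampling is realised as a
gene-level multinomial draw: `round((1−f)·N)` reads with probabilities
proportional to the target's gene counts plus `round(f·N)` proportional to
the contaminant's, with `N` the smaller library size — the exact sufficient
equivalent of read-level resampling for gene-count statistics. References
are the mean TPM of all non-mixed samples of each cell type; marker panels
are re-selected per simulation from those references. MAE is computed on
raw TPM across all genes (a log2(TPM+1) variant of the profiles can be
compared by the caller); the ground truth is the unmixed target resampled
to `N`, so resampling noise affects both arms equally. One global seed
drives per-simulation seeds drawn from a single generator, making the full
record table bit-reproducible.

The synthetic generator emulates multi-cell-type count profiles: a shared
log-normal expression programme, per-type blocks of exclusive high
(log-normal, median TPM in the thousands) marker-like genes that are exactly
silent in the other types, per-sample log-normal biological variability
(CV 0.3) and multinomial sampling of 200 000 reads over 500 genes (4
samples per type). What it does **not** emulate: overdispersion beyond the
log-normal–multinomial hierarchy, gene–gene correlation structure, partial
marker expression by the target (real lineage markers are rarely exactly
zero), library-size variation, or mapping artefacts. Passing tests
therefore demonstrate the estimator's correctness and its robustness to
sampling and biological noise at realistic magnitudes, not performance on
any particular real dataset. Benchmark and test problem sizes (500 genes,
200 simulations, 200–500 cohort replicates) are the package's desk-scale
defaults; all scale up by argument.

## Expression filters and network rules

* **Expression call**: TPM ≥ 3 in ≥ 65 % of a cell type's samples, both
  comparisons inclusive (13 of 20 samples passes). The rule is evaluated
  per cell type; a flag on the classification routine is the place to
  change that.
* **Tiers** by median TPM: none < 3, low [3, 20), moderate [20, 100],
  high > 100. The published bands overlap at 20 and 100; the boundary at
  20 is assigned to the higher class, while exactly 100 stays moderate
  because "high" is strictly > 100.
* **Selectivity**: ratio of medians (ε = 0.01 TPM added to both sides to
  stabilise zero medians) must clear threefold, and at most one value from
  the higher-expressing cell type may lie at or below the lower side's
  maximum ("one outlier"). The outlier definition operationalises a stated
  concept that has no published formula. 95 % CI by seeded percentile
  bootstrap, 2000 resamples (B unstated in the source setting; 2000 is the
  usual percentile-bootstrap default).
* **Ligand source**: tenfold rule on the median ratio (ε-stabilised) →
  tumor / tam / both. Note the ε makes an exactly-tenfold ratio fall just
  short, a deliberate conservative convention.
* **Subset genes**: strictly > 3 TPM in ≥ 2 samples while failing the 65 %
  rule; disjoint from the common network by construction.
* **Edges**: a curated ligand→receptor map is an input, never derived.
  An edge requires the ligand to pass the common or the subset criterion
  (the latter marks the edge patient-specific) and the receptor to be
  commonly expressed in ≥ 1 cell type; unknown genes skip the pair with a
  warning.

## Survival association

* **Dichotomization** at an empirical quantile, type-7 (linear)
  interpolation, "high" strictly above the threshold; both conventions are
  fixed because the source setting does not state them. A constant vector
  is a degenerate split and errors.
* **Best-fit quantile**: the logrank p is scanned over the grid
  {0.20, 0.25, 0.33, 0.50, 0.66, 0.75, 0.80} — the quantiles that actually
  occur in the motivating analyses — rather than all cutpoints, trading an
  unbounded optimism for reproducibility. Every grid result carries a
  multiple-cutpoint caveat, and the test suite asserts the inflation is
  real: under the null the grid search rejects more often than a fixed
  quantile.
* **Logrank**: the Mantel–Cox O/E table is computed in-package because the
  reported hazard ratio is the logrank HR `(O1/E1)/(O2/E2)`, which
  off-the-shelf implementations do not expose; the p-value is χ²(1). The
  implementation is cross-checked against lifelines' `logrank_test` and
  against an exhaustive permutation oracle on small cohorts (mid-p
  convention for the discrete permutation distribution). KM medians come
  from lifelines' `KaplanMeierFitter`.
* **Trichotomization** composes two dichotomizations into both-high /
  one-high / both-low with pairwise logrank comparisons.
* **BH gate**: significant iff p < 0.05 **and** p < its Benjamini–Hochberg
  step-up critical value at FDR 0.10 (statsmodels `multipletests` inside;
  the brute-force definition is kept as a test oracle).
* **Inclusion rule**: patients censored before 12 months are excluded
  before analysis; patients with an observed event before 12 months are
  kept by default (an early relapse is an informative, complete
  observation), with `drop_early_events` to switch. Missing mediator
  values drop a patient from that mediator's analysis only, so per-mediator
  n varies.
* **Synthetic cohorts**: mediator concentrations are log-normal (σ = 1
  around a median of 100, optionally equi-correlated on the log scale);
  RFS is exponential with baseline median 24 months — a realistic
  relapse-free-survival scale for high-grade serous ovarian carcinoma —
  multiplied by the specified hazard ratio above each spec'd mediator
  quantile; censoring is exponential, calibrated to the requested marginal
  rate, with administrative censoring at 60 months. `censor_rate ≥ 1`
  censors everyone at a uniform time past the inclusion window.

## Numerical conventions and degenerate inputs

TPM columns are 64-bit and serialised at 10 significant digits; matrix
round-trips are identity to 1e-9 relative. TPM validity is enforced at
1e-6 relative on column sums. Duplicated gene or sample ids, negative
values, missing gene lengths and all-zero count columns are hard errors
naming the offender. Ratio ties in marker ranking break lexicographically;
bootstrap and simulation seeds default to fixed values so every stochastic
output is reproducible.

## Known limitations

The correction assumes the contaminant reference matches the contaminating
cells' actual expression; polarization differences between the reference
and the admixed cells bias α in proportion to the mismatch at the markers.
Markers that the target genuinely expresses at low level bias α upward,
bounded by the median's robustness. The linear model ignores
transcript-length and capture-efficiency differences between cell types,
which cancel only on the TPM scale it operates on. The best-fit quantile
search inflates type-I error by design and is reported with a caveat
rather than corrected; the logrank HR is a crude effect estimate compared
with a Cox model and is biased toward the null under heavy censoring —
both are kept because they are the conventions of the analyses being
reproduced.
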