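# Methods

## The analysis in brief

The package targets a common situation in early-phase dermatology trials:
a three-arm randomized comparison (placebo, low dose, high dose) whose
arm-level primary endpoint — percent change from baseline in EASI at week
4 — is unremarkable, while baseline plasma proteomics suggests that a
subset of patients responds strongly to the high dose. The workflow
quantifies a targeted protein panel, labels EASI50 responders
(ΔEASI ≤ −50%), screens proteins whose baseline level discriminates
responders from non-responders in the active arm, fixes a per-protein
cut-off, and then asks whether the marker-favorable stratum shows a
*treatment* benefit: active vs placebo contrasts of ΔEASI and ΔIGA within
the stratum, odds ratios for response, and predictive values. Combinations
of two or three markers are explored through logistic predicted
probabilities and boolean unions of single-marker strata.

Everything is exercised end to end on a synthetic trial generator, because
patient-level data for this design are typically not public. The generator
is first-class, tested code: its latent truth (who is drug-responsive,
which proteins were planted) is the oracle for the recovery and
calibration experiments in `admarker.validation`.

## Quantification model

Targeted MRM-MS quantification follows stable-isotope dilution: a labeled
standard (SIS) peptide spiked at a known amount gives

    endogenous amount (fmol) = PAR × SIS spiked,

with PAR the endogenous/SIS peak-area ratio. QC removes transitions with
SIS intensity < 100 counts, non-co-eluting SIS peaks, or asymmetric peaks
(first-failing-rule attribution, in that order); co-elution and symmetry
arrive as boolean flags because peak integration happens upstream in the
vendor tool. Calibration series over {50, 100, 200, 400} fmol must keep
PAR strictly inside (0.1, 1) at every level and reach R² ≥ 0.9 (the R²
bound is this package's tightening of a qualitative linearity requirement;
it is a parameter). Collision energies are linear in precursor m/z with
charge-specific slopes (2+: 0.031·mz + 1; 3+: 0.036·mz − 4.8); other
charges raise rather than extrapolate.

## Statistical conventions

* **AUROC** is computed as the Mann–Whitney pairwise statistic (ties count
  ½), identical to the trapezoidal area under the empirical ROC. The
  screening step keeps proteins with max(AUROC, 1 − AUROC) strictly
  greater than 0.7, so markers informative in either direction survive.
* **Cut-offs** maximize Youden's J over candidate thresholds placed at
  midpoints between consecutive sorted unique levels. Both directions are
  scanned; because J flips sign between directions, the reported J is
  always ≥ 0. Ties resolve to the lowest threshold, direction "hi" first.
  Values exactly equal to the cut-off fall on the favorable side.
  Constant levels yield J = 0 with an undefined direction.
* **Contingency statistics.** With a = favorable responders,
  b = favorable non-responders, c, d their unfavorable counterparts:
  PPV = a/(a+b), NPV = d/(c+d). The odds ratio applies the
  Haldane–Anscombe correction — add 0.5 to *all four* cells when any cell
  is zero — and a log-scale Wald CI with SE = √Σ1/cellᵢ and the exact
  0.975 normal quantile (1.959964; the rounded 1.96 visibly moves the
  upper bound of wide intervals). The Fisher exact p is always computed on
  the uncorrected table: the correction exists to make the OR finite, not
  to change the evidence.
* **Benefit indicator.** B = I[Y(0) ≤ Y(1)] is operationalized as both
  within-stratum contrasts (ΔEASI and ΔIGA, active − placebo) reaching
  p < 0.05 strictly. A stratum missing either arm reports missing
  contrasts and B = false.
* **Between-arm contrasts** use the two-sample t test with pooled variance
  by default. The strata this analysis produces routinely hold 3–8
  patients per arm; Welch's correction collapses the degrees of freedom
  there and is materially more conservative, while pooled Student's t is
  the reporting convention for such tables. Welch remains available
  (`equal_var=False`). Within-arm change tests gate on Shapiro–Wilk at
  α = 0.05 (configurable): non-rejection → one-sample t, otherwise
  Wilcoxon signed-rank; an all-zero change vector reports p = 1 with no
  test. IGA percent change treats the ordinal grade as numeric, matching
  how such tables are reported.
* **Logistic combinations** are fitted by IRLS (log-likelihood tolerance
  1e−8, ≤ 100 iterations). Separation — fitted probabilities that
  perfectly split the classes, or divergence — is frequent at n ≈ 20 with
  strong markers; it is flagged and the model refit with a ridge of
  λ = 1e−4 on the slopes so predicted probabilities stay usable for
  ranking and thresholding. Covariates can enter on the natural-log scale
  per a per-marker flag (the convention for the keratin-type marker).
  The predicted-probability threshold reuses the midpoint Youden scan;
  with a single untransformed predictor and a positive slope it selects
  exactly the same stratum as the level-based cut-off (the logistic link
  is monotone) — a property test pins this.
* **Preranked GSEA** ranks proteins by log2 fold change (responders over
  non-responders) and runs the weighted Kolmogorov–Smirnov-style sum with
  weight exponent p = 1; ES is the extremum (earliest index on exact
  ties). Because the input is a preranked list, the null permutes *set
  membership* (random same-size sets from the universe), not sample
  labels. NES divides ES by the mean |null ES| of the same sign; the
  permutation p is one-sided within sign with a +1 correction; FDR q
  follows the standard NES-based pooled-null ratio, clipped to 1 and
  reported descriptively. Leading edge: members at or before the extremum
  (at or after, for negative ES).
* **Clustering / PCA / volcano.** Biomarkers are z-scored before
  clustering (Canberra distance, complete linkage; zero-variance columns
  dropped with a warning); merge ties follow the deterministic
  lowest-index behaviour of the condensed-distance implementation. PCA
  standardizes columns and fixes each component's sign so its largest
  loading is positive. Volcano fold changes are ratios of group means on
  the log2 scale (undefined, and reported missing, when a group mean is
  non-positive) with equal-variance t p-values.

## The synthetic trial generator

`admarker.synth` emulates the study conditions the analysis assumes:
80 patients (27/27/26) over 5 sites, stratified permuted-block
randomization with blocks of 3 and 6 (per-site arm imbalance therefore
below the largest block), baseline EASI from a truncated normal
8.27 ± 4.36 on (0, 72], IGA grade 3 with probability 0.405, enrollment
dates spanning a late-summer-to-summer year with the season derived from
the month, and a 469-protein panel whose log10 medians are uniform over
[−1, 6] (span ≈ 7 orders of magnitude; ~90% of proteins within 5 orders)
with within-protein log10 SD 0.2.

A single latent responsiveness score z ~ N(0,1) drives everything
correlated: the top 20% of the cohort by z is drug-responsive; each
planted marker's favorable stratum is the top `favorable_fraction` by z
(so strata nest, as the real markers' strata did); and marker abundance is
shifted between strata by `effect_size` within-protein SDs, upward for
"hi" markers, downward for "lo". Abundance never depends on arm, so the
panel is arm-balanced at baseline.

Week-4 percent change in EASI is normal per outcome cell:
placebo (−2.9, 47), low dose (−12.2, 46), high-dose unmatched (8.4, 40),
matched — i.e. high-dose *and* latently responsive — (−95, 8). The cells
were calibrated jointly so that (i) arm-level means land near
−2.9 / −12.2 / −11.9 percent, (ii) the high-dose EASI50 rate is ≈ 24%
with essentially every matched patient clearing EASI50, and (iii) the
favorable-stratum contrast of the strongest marker is ≈ −90 percent
points — the regime in which a 20%-of-cohort stratum with ~4–5 patients
per arm yields the printed-table pattern of significant dual contrasts
and near-perfect predictive values. Default planted effects (3.5 / 3.0 /
3.0 SD at stratum fractions 0.20 / 0.37 / 0.54) produce in-sample
responder AUROCs of roughly 0.86–0.95. Week-2 scores are a uniform
0.4–0.8 fraction of the week-4 change (a partial effect visible at the
interim visit); IGA response is 0.55 × the EASI percent change plus
N(0, 10) noise, rounded to a grade and bounded to changes in
{−2, …, +1}; EASI follow-ups are clipped to [0, 72]. Optional per-arm
dropout removes only the week-4 assessment; biomarker consent is drawn at
rate 0.875, giving a biomarker analysis set of ≈ 70.

What the generator does **not** emulate: correlation structure between
proteins (noise proteins are independent), heavy-tailed or skewed outcome
noise, site effects on outcomes, measurement batch effects, missingness
other than week-4 dropout, and adverse events. Consequently, passing
tests demonstrate that the *statistical machinery* behaves as specified
under a clean data-generating process — not that the scientific findings
of any one trial would replicate. The normal outcome model also puts
~15% of placebo patients past the EASI50 boundary (its left tail is
heavier than real placebo response), slightly inflating placebo responder
rates relative to the printed 11%.

## Validation experiments

`admarker.validation` packages two Monte-Carlo studies:

* **Recovery** — 25 placebo + 20 active patients (the biomarker-set arm
  sizes; an `allocation="exact"` mode exists because unequal totals cannot
  arise from 1:1:1 blocks), one planted marker with effect 2.5 SD at
  stratum fraction 0.3 (alternating hi/lo across replicates), responsive
  fraction aligned with the stratum. Over 200 seeded replicates the
  screen recovers the planted protein with its correct direction in
  well over 80% of trials.
* **Null calibration** — trials with no planted markers and identical
  response cells in every arm; the full single-marker path (in-sample
  cut-off, dual contrasts) is applied to a fixed protein, and the same
  computation runs after permuting arm labels on identical data. The two
  spurious-benefit rates agree within two standard errors, showing the
  pipeline adds no optimism beyond its stated in-sample design.

## Problem sizes used in the test suite

The default pytest run simulates full-size cohorts (80 patients) but
scales panel width and permutation counts where full size adds nothing to
the property under test: pipeline determinism and report plumbing run at
60 proteins and 50 GSEA permutations; the recovery experiment runs its
full 200 replicates at 469 proteins; exhaustive oracles (pairwise AUROC,
threshold scans, hypergeometric enumeration) run at n ≤ 30 instances and
all 2×2 tables with n ≤ 12. These sizes are the package's own choices for
tight, deterministic tests.

## Known limitations

* The entire cut-off/selection procedure is in-sample, by design: no
  cross-validation, no multiplicity correction over the 469-protein
  screen or the combination search. The generator makes the resulting
  optimism measurable (noise proteins pass the screen at the expected
  permutation-calibrated rate) but the package deliberately does not
  correct it.
* The ridge-stabilized logistic fit under separation yields finite but
  penalty-dependent coefficients; only the induced ranking (predicted
  probabilities and their threshold) should be interpreted.
* GSEA's membership-permutation null is the only null available for a
  preranked list; it calibrates set enrichment against random sets of the
  same size, not against phenotype relabeling.
* Fisher exact p-values are reported exactly; printed p-values in
  secondary sources for small zero-cell tables sometimes disagree with
  exact enumeration, and this package reports the enumerated value.
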