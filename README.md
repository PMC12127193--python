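# admarker

Predictive-biomarker stratification for small randomized trials with a
baseline targeted-proteomics panel.

Topical trials in mild-to-moderate atopic dermatitis often show weak
arm-level effects while subsets of patients respond strongly. `admarker`
implements the full post-hoc workflow for finding baseline plasma-protein
markers that predict who benefits from active treatment in a three-arm
(placebo / low-dose / high-dose) trial:

* **MRM-MS quantification QC** — transition-level filtering (SIS intensity
  ≥ 100 counts, co-elution, peak symmetry), absolute quantification
  (endogenous fmol = PAR × SIS spiked), spike-level linearity
  (0.1 < PAR < 1 over 50–400 fmol, R² ≥ 0.9), collision-energy calibration
  (CE = 0.031·m/z + 1 for 2+; 0.036·m/z − 4.8 for 3+).
* **Clinical endpoints** — percent change from baseline in EASI (0–72) and
  IGA (0–4), the EASI50 responder label (ΔEASI ≤ −50%), Shapiro–Wilk-gated
  within-arm tests (t vs Wilcoxon signed-rank), between-arm t contrasts with
  95% CIs, ANOVA baseline balance, analysis-set rules (SAS ⊇ FAS ⊇ PPS,
  BAS ⊆ FAS), and predefined subgroups (e.g. moderate disease,
  7 < EASI ≤ 21).
* **Single-marker engine** — per-protein AUROC (pairwise rank statistic),
  screening at AUROC > 0.7, direction-aware cut-offs maximizing Youden's
  J = sensitivity + specificity − 1 over between-value midpoints,
  favorable-stratum (marker^hi / marker^lo) contingency tables with
  PPV = a/(a+b) and NPV = d/(c+d), odds ratios with the Haldane–Anscombe
  correction (add 0.5 to every cell of a table containing a zero) and Wald
  CI exp(log OR ± z₀.₉₇₅·√Σ1/nᵢ) at the exact quantile 1.959964, two-sided
  Fisher exact p, and the benefit indicator B = I[Y(0) ≤ Y(1)],
  operationalized as both the stratified ΔEASI and ΔIGA active-vs-placebo
  contrasts having p < 0.05.
* **Marker combinations** — logistic models on 2–3 baseline markers (IRLS,
  separation detected and stabilized with a tiny ridge), Youden-optimal
  thresholds on the predicted probability, boolean union strata
  ("A^hi or B^lo"), and ranked combination reports.
* **Exploratory analytics** — z-scored hierarchical clustering
  (Canberra/complete), standardized PCA, volcano statistics (log2 fold
  change of group means, t-test p), and preranked GSEA (weighted
  running-sum ES, membership-permutation null, NES, FDR q, leading edge).
* **Synthetic trial generator** — seeded cohorts with stratified
  permuted-block randomization (blocks of 3 and 6 over 5 sites), baseline
  EASI ≈ 8.27 ± 4.36, a 469-protein log-normal panel spanning ≥ 5 orders of
  magnitude, and *planted markers* whose baseline abundance separates a
  latent drug-responsive stratum that benefits only under high-dose
  treatment — so every downstream claim can be tested against known truth.

## Worked example

`examples/04_single_marker_stratification.py` simulates a default trial
(planted markers `P0007^hi`, `P0042^lo`, `P0101^lo`), screens the active arm
and reports the top strata:

```
70 proteins pass the AUROC > 0.7 responder screen (6 responders / 26 active-arm patients)
 stratum  delta_easi  delta_easi_p  delta_iga_p  pct_bas   auc   ppv   npv      or  benefit
P0007^hi     -83.395         0.008        0.170   18.571 1.000 1.000 1.000 533.000    False
P0042^lo     -55.315         0.074        0.202   44.286 0.900 0.600 1.000  47.667    False
P0006^lo     -77.838         0.012        0.006   48.571 0.892 0.667 1.000  65.000     True
...
zero-cell 2x2 (4,0,1,15): OR 93.0 [3.2, 2699.7], Fisher p 0.00103 (0.5 added to all cells: corrected=True)
```

The planted high-direction marker tops the screen: its favorable stratum
(18.6% of the biomarker set) shows an 83-point greater EASI improvement
under active treatment than placebo (p = 0.008), with perfect in-sample
PPV/NPV. That 70 of 469 *noise-dominated* proteins also pass the screen —
and one (`P0006`) even reaches B = true — is the in-sample multiplicity
this screening design carries; the generator makes it measurable. The last
line shows the Haldane–Anscombe odds ratio on a reconstructed zero-cell
stratum table: OR 93.0, 95% CI [3.2, 2699.7].

The other scripts in `examples/` cover simulation, transition QC,
endpoints, combinations, and the exploratory stack, each printing the
numbers it computes with a line on what they mean. The command-line
entry point mirrors the pipeline stages:

```sh
admarker run-all --out-dir run1 --seed 7      # full synthetic run
admarker quant transitions.csv                # QC + quantify a Skyline-style report
```

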