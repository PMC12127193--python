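"""Monte-Carlo validation harnesses for the stratification pipeline.

These experiments run the full marker-discovery path on freshly generated
synthetic trials and measure operating characteristics against the
generator's latent truth:

* :func:`recovery_experiment` — how often a planted marker is recovered among
  the screened DEPs with the correct direction, at the biomarker-set sizes
  the analysis assumes (25 placebo + 20 active-arm patients);
* :func:`null_benefit_rates` — the rate of spurious benefit calls (B = true)
  on trials with no planted markers and no arm effect, next to an
  arm-label-permutation oracle estimating the same null rate on identical
  data.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import endpoints as ep
from . import stratify
from .synth import PlantedMarker, ResponseRates, TrialConfig, simulate_trial

__all__ = ["recovery_experiment", "null_benefit_rates", "recovery_config", "null_config"]


def recovery_config(
    seed: int,
    effect_size: float = 2.5,
    favorable_fraction: float = 0.3,
    direction: str = "hi",
    n_proteins: int = 469,
) -> TrialConfig:
    """Trial configuration for a planted-marker recovery replicate.

    Arm sizes follow the biomarker analysis set (25 placebo, 20 active); the
    latent responsive fraction equals the planted favorable fraction, so the
    marker's stratum is exactly the drug-responsive stratum.
    """
    marker = PlantedMarker(
        protein_id=7,
        direction=direction,
        favorable_fraction=favorable_fraction,
        effect_size=effect_size,
    )
    return TrialConfig(
        n_per_arm=(25, 3, 20),
        allocation="exact",
        planted_markers=(marker,),
        responsive_fraction=favorable_fraction,
        dropout_prob=(0.0, 0.0, 0.0),
        biomarker_consent_rate=1.0,
        n_proteins=n_proteins,
        seed=seed,
    )


def recovery_experiment(
    n_reps: int = 200,
    seed: int = 0,
    effect_size: float = 2.5,
    favorable_fraction: float = 0.3,
    auroc_min: float = 0.7,
    n_proteins: int = 469,
) -> float:
    """Fraction of replicates recovering the planted marker with its direction.

    Each replicate generates a fresh trial (alternating hi/lo planted
    directions), screens every protein in the active arm against EASI50
    responder labels, and counts success when the planted protein appears in
    the screened list with the correct direction.  Replicates whose active
    arm lacks a responder class are rare and count as failures.
    """
    hits = 0
    for r in range(n_reps):
        direction = "hi" if r % 2 == 0 else "lo"
        cfg = recovery_config(
            seed=seed * 100003 + r, effect_size=effect_size,
            favorable_fraction=favorable_fraction, direction=direction,
            n_proteins=n_proteins,
        )
        trial = simulate_trial(cfg)
        cohort = trial.cohort
        act = cohort["arm"] == "high_dose"
        endpoints = ep.compute_endpoints(cohort).set_index("patient_id")
        flags = endpoints.loc[cohort.loc[act, "patient_id"], "easi50_wk4"].astype(bool).to_numpy()
        if flags.all() or not flags.any():
            continue
        mat = trial.proteome.loc[cohort.loc[act, "patient_id"]]
        planted_id = "P0007"
        deps = stratify.select_deps(mat, flags, auroc_min=auroc_min)
        for c in deps:
            if c.protein_id == planted_id and c.direction == direction:
                hits += 1
                break
    return hits / n_reps


def null_config(seed: int, n_proteins: int = 20) -> TrialConfig:
    """A trial with no planted markers and identical response cells across
    arms: both the marker effect and the treatment effect are null."""
    cell = (-10.0, 45.0)
    return TrialConfig(
        n_per_arm=(25, 3, 20),
        allocation="exact",
        planted_markers=(),
        response_rates=ResponseRates(
            placebo=cell, low_dose=cell, high_dose_unmatched=cell, matched=cell
        ),
        dropout_prob=(0.0, 0.0, 0.0),
        biomarker_consent_rate=1.0,
        n_proteins=n_proteins,
        seed=seed,
    )


def _benefit_for(cohort, endpoints, levels) -> bool:
    """Fit the single-marker path end to end and return the benefit flag."""
    act = endpoints["arm"] == "high_dose"
    flags = endpoints.loc[act, "easi50_wk4"]
    flags = flags.astype(bool).to_numpy()
    if flags.all() or not flags.any():
        return False
    cut = stratify.youden_optimal_cutoff(
        levels.loc[endpoints.loc[act, "patient_id"]].to_numpy(), flags, protein_id=levels.name
    )
    if cut.direction is None:
        return False
    report = stratify.stratum_report(endpoints, levels, cut)
    return report.benefit


def null_benefit_rates(
    n_reps: int = 150, seed: int = 0
) -> dict[str, float]:
    """Spurious-benefit rate on null trials vs an arm-permutation oracle.

    For each replicate the full single-marker path (in-sample Youden cut-off,
    stratified ΔEASI and ΔIGA contrasts, dual p < 0.05) is applied to a fixed
    protein of a null trial; the oracle repeats the computation after
    permuting the arm labels of the same cohort.  Returns both rates and the
    two-SE band of their difference.
    """
    rng = np.random.default_rng(seed)
    pipeline_hits = oracle_hits = 0
    for r in range(n_reps):
        cfg = null_config(seed=seed * 99991 + r)
        trial = simulate_trial(cfg)
        cohort = trial.cohort
        endpoints = ep.compute_endpoints(cohort)
        levels = trial.proteome["P0000"]
        pipeline_hits += _benefit_for(cohort, endpoints, levels)

        perm = endpoints.copy()
        perm["arm"] = rng.permutation(perm["arm"].to_numpy())
        oracle_hits += _benefit_for(cohort, perm, levels)
    p1 = pipeline_hits / n_reps
    p2 = oracle_hits / n_reps
    se = float(np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n_reps))
    return {
        "pipeline_rate": p1,
        "oracle_rate": p2,
        "diff": p1 - p2,
        "two_se": 2 * se if se > 0 else 2 * np.sqrt(0.25 * 2 / n_reps),
    }
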