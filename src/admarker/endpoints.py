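"""Clinical endpoint computation and arm-level testing.

Endpoints are percent changes from baseline in EASI (0-72 composite severity)
and IGA (0-4 ordinal grade, treated as numeric for percent change).  The
EASI50 responder label is a percent change of -50 or better at week 4.
Within-arm change tests are gated on Shapiro-Wilk normality (t test if the
gate does not reject at alpha = 0.05, Wilcoxon signed-rank otherwise);
between-arm contrasts are two-sample t tests (Welch by default, pooled
variance available) with 95% confidence intervals on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArmContrast",
    "SubgroupSpec",
    "pct_change",
    "label_easi50",
    "compute_endpoints",
    "within_arm_change_test",
    "between_arm_contrast",
    "baseline_balance",
    "subgroup_filter",
    "arm_summary",
]

EASI50_THRESHOLD = -50.0


def pct_change(baseline, followup):
    """Percent change from baseline, 100*(followup - baseline)/baseline.

    Negative values are improvement.  Baseline must be positive.  Vectorized;
    missing follow-ups propagate as NaN.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline score must be positive to form a percent change")
    out = 100.0 * (followup - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def label_easi50(pct) -> np.ndarray | bool:
    """EASI50 responder flag: percent change <= -50 (boundary inclusive)."""
    pct = np.asarray(pct, dtype=float)
    out = pct <= EASI50_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def compute_endpoints(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient endpoint table from a clinical cohort table.

    Produces percent changes for EASI and IGA at weeks 2 and 4 and the week-4
    EASI50 flag.  Patients with a missing week-4 assessment keep NaN percent
    changes and a missing (pd.NA) responder flag; complete-case handling is
    left to the caller (mirrors full-analysis-set logic: no imputation).
    """
    ep = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "arm": cohort["arm"],
            "pct_easi_wk2": pct_change(cohort["easi_baseline"], cohort["easi_wk2"]),
            "pct_easi_wk4": pct_change(cohort["easi_baseline"], cohort["easi_wk4"]),
            "pct_iga_wk2": pct_change(cohort["iga_baseline"], cohort["iga_wk2"]),
            "pct_iga_wk4": pct_change(cohort["iga_baseline"], cohort["iga_wk4"]),
        }
    )
    flags = pd.array(label_easi50(ep["pct_easi_wk4"]), dtype="boolean")
    flags[ep["pct_easi_wk4"].isna().to_numpy()] = pd.NA
    ep["easi50_wk4"] = flags
    return ep


def within_arm_change_test(
    pct_changes, alpha_gate: float = 0.05
) -> tuple[float, str]:
    """Test whether a within-arm percent change differs from zero.

    Normality is assessed with Shapiro-Wilk at ``alpha_gate``; a non-rejecting
    sample is tested with a one-sample t test against zero, otherwise the
    Wilcoxon signed-rank test is used.  Returns ``(p_value, test_used)`` with
    ``test_used`` in {"t", "wilcoxon", "none"}; an all-zero change vector is
    the degenerate no-change case and reports p = 1 with no test.
    """
    x = np.asarray(pct_changes, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("within-arm test needs at least 3 observations")
    if np.all(x == 0):
        return 1.0, "none"
    if np.ptp(x) == 0:  # constant non-zero: Shapiro undefined, t is exact
        return 0.0, "t"
    if stats.shapiro(x).pvalue >= alpha_gate:
        return float(stats.ttest_1samp(x, 0.0).pvalue), "t"
    return float(stats.wilcoxon(x).pvalue), "wilcoxon"


@dataclass(frozen=True)
class ArmContrast:
    """Between-arm mean difference of percent changes with 95% CI."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    n_per_group: tuple[int, int]


def between_arm_contrast(
    active, placebo, equal_var: bool = True
) -> ArmContrast:
    """Two-sided two-sample t contrast of percent changes (active - placebo).

    The pooled-variance Student form is the default — stratified contrasts
    here routinely compare 3-8 patients per arm, where the pooled test is the
    reporting convention; ``equal_var=False`` selects Welch's form.  The 95%
    CI is on the difference in means.
    Degenerate two-point samples with zero spread yield an infinite-width CI
    rather than an error.
    """
    a = np.asarray(active, dtype=float)
    b = np.asarray(placebo, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    diff = float(a.mean() - b.mean())
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if diff == 0:
            return ArmContrast(diff, diff, diff, 1.0, "t", (a.size, b.size))
        return ArmContrast(diff, -np.inf, np.inf, 0.0, "t", (a.size, b.size))
    ci = res.confidence_interval(0.95)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return ArmContrast(
        diff, float(ci.low), float(ci.high), p,
        "t" if equal_var else "welch_t", (a.size, b.size),
    )


def baseline_balance(values_by_arm: dict[str, np.ndarray]) -> float:
    """One-way ANOVA p-value for a baseline variable across arms."""
    groups = [np.asarray(v, dtype=float) for v in values_by_arm.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 arms with >= 2 observations each")
    return float(stats.f_oneway(*groups).pvalue)


@dataclass(frozen=True)
class SubgroupSpec:
    """Predicate naming one of the trial's predefined subgroups.

    kind:
      * ``easi_range`` -- left-open, right-closed baseline EASI interval
        (e.g. the moderate-disease window 7 < EASI <= 21),
      * ``iga_level`` -- baseline IGA equals ``value``,
      * ``enrollment_window`` -- enrollment date within [start, end],
      * ``season`` -- enrollment season equals ``value``.
    """

    kind: str
    value: object = None
    low: float | None = None
    high: float | None = None
    start: str | None = None
    end: str | None = None


def subgroup_filter(cohort: pd.DataFrame, spec: SubgroupSpec) -> pd.DataFrame:
    """Rows of the cohort satisfying a subgroup predicate.

    An empty result is allowed (a warning is attached via DataFrame.attrs).
    """
    if spec.kind == "easi_range":
        e = cohort["easi_baseline"]
        mask = (e > spec.low) & (e <= spec.high)
    elif spec.kind == "iga_level":
        mask = cohort["iga_baseline"] == spec.value
    elif spec.kind == "enrollment_window":
        d = pd.to_datetime(cohort["enrollment_date"])
        mask = (d >= pd.Timestamp(spec.start)) & (d <= pd.Timestamp(spec.end))
    elif spec.kind == "season":
        mask = cohort["season"] == spec.value
    else:
        raise ValueError(f"unknown subgroup kind {spec.kind!r}")
    out = cohort.loc[mask].copy()
    out.attrs["empty_subgroup"] = bool(out.empty)
    return out


def arm_summary(endpoints: pd.DataFrame, column: str = "pct_easi_wk4") -> pd.DataFrame:
    """Per-arm mean change, 95% CI, within-arm p, and responder rate."""
    rows = []
    for arm, grp in endpoints.groupby("arm", sort=True):
        x = grp[column].dropna().to_numpy()
        p, used = within_arm_change_test(x)
        sem = x.std(ddof=1) / np.sqrt(x.size)
        half = stats.t.ppf(0.975, x.size - 1) * sem
        rows.append(
            {
                "arm": arm,
                "n": x.size,
                "mean_pct_change": x.mean(),
                "ci_low": x.mean() - half,
                "ci_high": x.mean() + half,
                "p_within": p,
                "test_used": used,
                "responder_rate": float(grp["easi50_wk4"].dropna().astype(bool).mean()),
            }
        )
    return pd.DataFrame(rows)
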