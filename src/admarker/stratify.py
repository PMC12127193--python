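"""Single-marker predictive-biomarker engine.

Given baseline biomarker levels and EASI50 responder labels in the active arm,
this module screens for differentially expressed proteins (AUROC > 0.7),
chooses a direction-aware Youden-optimal cut-off per marker, stratifies the
cohort into favorable/unfavorable strata, and summarizes the treatment benefit
of the active arm within the favorable stratum: between-arm contrasts of
percent changes, positive/negative predictive values, odds ratios with the
Haldane-Anscombe zero-cell correction, Fisher exact p-values, and the dual
p < 0.05 benefit indicator B = I[Y(0) <= Y(1)].

AUROC is the pairwise rank statistic (ties count one half), identical to the
trapezoidal area under the empirical ROC curve.  Cut-off candidates are the
midpoints between consecutive sorted unique levels; both directions
("hi": level >= cut-off predicts response; "lo": level <= cut-off) are scanned
and the direction maximizing J = sensitivity + specificity - 1 is kept, so the
reported J is always non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import ArmContrast, between_arm_contrast

__all__ = [
    "CutoffResult",
    "ContingencyTable",
    "AssociationResult",
    "StratumReport",
    "auroc",
    "auroc_matrix",
    "youden_optimal_cutoff",
    "select_deps",
    "favorable_mask",
    "stratify_and_confusion",
    "odds_ratio_ha",
    "fisher_exact",
    "benefit_indicator",
    "stratum_report",
    "table2_style",
]

#: Exact upper 0.975 normal quantile used for Wald intervals.  Using the
#: rounded 1.96 shifts the upper bound of wide intervals by several units.
Z_0975 = float(stats.norm.ppf(0.975))


def _as_xy(levels, responder_flags) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responder_flags).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and responder flags must be 1-D and aligned")
    return x, y


def auroc(levels, responder_flags) -> float:
    """Area under the empirical ROC curve (responders = positive class).

    Computed as the Mann-Whitney pairwise statistic: the fraction of
    (responder, non-responder) pairs where the responder has the higher
    level, ties counting one half.  Raises if only one class is present.
    """
    x, y = _as_xy(levels, responder_flags)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(x)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auroc_matrix(matrix: pd.DataFrame, responder_flags) -> pd.Series:
    """Column-wise AUROC for a patients x proteins matrix (vectorized)."""
    y = np.asarray(responder_flags).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(matrix.to_numpy(), axis=0)
    u = ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return pd.Series(u / (n1 * n0), index=matrix.columns)


@dataclass(frozen=True)
class CutoffResult:
    """Direction-aware Youden-optimal cut-off for one marker."""

    protein_id: str
    direction: str | None  # "hi", "lo", or None when levels are constant
    cutoff: float | None
    j: float
    sensitivity: float
    specificity: float
    auroc: float


def youden_optimal_cutoff(levels, responder_flags, protein_id: str = "") -> CutoffResult:
    """Scan midpoint thresholds in both directions and maximize Youden's J.

    Candidate thresholds are midpoints between consecutive sorted unique
    levels, so every non-degenerate split of the sample is evaluated exactly
    once and observed values are never themselves thresholds (which makes the
    boundary convention — values equal to the cut-off fall on the favorable
    side — vacuous for continuous data but well defined for ties).  For each
    candidate, direction "hi" calls level >= threshold favorable and "lo"
    calls level <= threshold favorable; since J flips sign between directions,
    the maximum over both is always >= 0.  Ties between candidates resolve to
    the lowest threshold, direction "hi" first (deterministic reporting).
    Constant levels yield J = 0 with an undefined direction.
    """
    x, y = _as_xy(levels, responder_flags)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("cut-off optimization needs both classes")
    area = auroc(x, y)
    uniq = np.unique(x)
    if uniq.size < 2:
        return CutoffResult(protein_id, None, None, 0.0, 0.0, 0.0, area)

    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = (-np.inf, None, None, 0.0, 0.0)
    for c in candidates:
        hi_pred = x >= c
        sens_hi = (hi_pred & y).sum() / n1
        spec_hi = (~hi_pred & ~y).sum() / n0
        j_hi = sens_hi + spec_hi - 1.0
        # direction "lo" on the same threshold mirrors the confusion table
        for direction, j, sens, spec in (
            ("hi", j_hi, sens_hi, spec_hi),
            ("lo", -j_hi, 1.0 - sens_hi, 1.0 - spec_hi),
        ):
            if j > best[0] + 1e-12:
                best = (j, direction, float(c), sens, spec)
    j, direction, cutoff, sens, spec = best
    return CutoffResult(protein_id, direction, cutoff, float(j), float(sens), float(spec), area)


def select_deps(
    matrix: pd.DataFrame, responder_flags, auroc_min: float = 0.7
) -> list[CutoffResult]:
    """Screen proteins whose direction-corrected AUROC strictly exceeds a bound.

    ``matrix`` must be restricted to the active arm.  Each protein's AUROC is
    reported as max(a, 1 - a) so markers predictive in either direction are
    retained; survivors get a full Youden cut-off and are sorted by AUROC
    descending with protein-id tie-break.
    """
    from dataclasses import replace

    y = np.asarray(responder_flags).astype(bool)
    raw = auroc_matrix(matrix, y)
    corrected = np.maximum(raw, 1.0 - raw)
    keep = corrected[corrected > auroc_min]
    results = []
    for pid in keep.index:
        r = youden_optimal_cutoff(matrix[pid].to_numpy(), y, protein_id=pid)
        results.append(replace(r, auroc=max(r.auroc, 1.0 - r.auroc)))
    results.sort(key=lambda r: (-r.auroc, r.protein_id))
    return results


def favorable_mask(levels, cutoff: CutoffResult) -> np.ndarray:
    """Favorable-stratum membership under a fitted cut-off.

    Values equal to the cut-off fall on the favorable side in both
    directions.
    """
    if cutoff.direction is None or cutoff.cutoff is None:
        raise ValueError("cut-off has no defined direction")
    x = np.asarray(levels, dtype=float)
    return x >= cutoff.cutoff if cutoff.direction == "hi" else x <= cutoff.cutoff


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 stratum x responder counts.

    a: favorable responders, b: favorable non-responders,
    c: unfavorable responders, d: unfavorable non-responders.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def ppv(self) -> float | None:
        """Responder fraction of the favorable stratum; None if empty."""
        return self.a / (self.a + self.b) if (self.a + self.b) else None

    @property
    def npv(self) -> float | None:
        """Non-responder fraction of the unfavorable stratum; None if empty."""
        return self.d / (self.c + self.d) if (self.c + self.d) else None


def stratify_and_confusion(
    levels, cutoff: CutoffResult, responder_flags
) -> tuple[ContingencyTable, float | None, float | None]:
    """Cross-tabulate stratum membership against responder status."""
    fav = favorable_mask(levels, cutoff)
    y = np.asarray(responder_flags).astype(bool)
    table = ContingencyTable(
        a=int((fav & y).sum()),
        b=int((fav & ~y).sum()),
        c=int((~fav & y).sum()),
        d=int((~fav & ~y).sum()),
    )
    return table, table.ppv, table.npv


@dataclass(frozen=True)
class AssociationResult:
    """Odds ratio with Wald CI and Fisher exact p for a 2x2 table."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed that of
    the observed table."""
    return float(
        stats.fisher_exact([[table.a, table.b], [table.c, table.d]])[1]
    )


def odds_ratio_ha(table: ContingencyTable) -> AssociationResult:
    """Odds ratio with Haldane-Anscombe correction and Wald 95% CI.

    If any cell is zero, 0.5 is added to all four cells before forming the
    cross-ratio OR = a'd'/(b'c') and its log-scale Wald interval with
    SE = sqrt(sum of reciprocal corrected cells) and the exact 0.975 normal
    quantile.  The Fisher exact p-value is always computed on the uncorrected
    table (the correction affects only the OR and CI).  A table with no
    responders or no non-responders has an undefined OR and raises.
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("odds ratio undefined: a responder margin is empty")
    corrected = 0 in (table.a, table.b, table.c, table.d)
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = np.log(or_)
    return AssociationResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - Z_0975 * se)),
        ci_high=float(np.exp(log_or + Z_0975 * se)),
        p_value=fisher_exact(table),
        corrected=corrected,
    )


def benefit_indicator(delta_easi_p: float, delta_iga_p: float) -> bool:
    """Treatment-benefit flag B = I[Y(0) <= Y(1)].

    Operationalized as both the EASI and the IGA between-arm contrasts
    (active - placebo within the favorable stratum) being significant at
    strictly p < 0.05.
    """
    for p in (delta_easi_p, delta_iga_p):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return delta_easi_p < 0.05 and delta_iga_p < 0.05


@dataclass(frozen=True)
class StratumReport:
    """Single-marker stratified benefit summary (one printed-table row)."""

    label: str
    delta_easi: ArmContrast | None
    delta_iga: ArmContrast | None
    pct_bas: float
    auroc: float
    auroc_p: float
    ppv: float | None
    npv: float | None
    association: AssociationResult | None
    benefit: bool


def _auroc_p(levels, flags) -> float:
    """Two-sided Mann-Whitney p for the AUROC differing from 1/2."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(flags).astype(bool)
    return float(stats.mannwhitneyu(x[y], x[~y], alternative="two-sided").pvalue)


def stratum_report(
    endpoints: pd.DataFrame,
    levels: pd.Series,
    cutoff: CutoffResult,
    active_arm: str = "high_dose",
    placebo_arm: str = "placebo",
    equal_var: bool = True,
    label: str | None = None,
) -> StratumReport:
    """Benefit evaluation of the active arm within one marker's favorable stratum.

    ``levels`` must be indexed by patient_id over the biomarker analysis set.
    The ΔEASI and ΔIGA contrasts compare active vs placebo week-4 percent
    changes inside the favorable stratum; %BAS is the stratum's share of the
    whole biomarker analysis set (all arms); the AUROC, its Mann-Whitney p,
    PPV and NPV are computed within the active arm.  A stratum lacking either
    arm yields missing contrasts and B = false.
    """
    ep = endpoints.set_index("patient_id").loc[levels.index]
    arm = ep["arm"]
    fav = pd.Series(favorable_mask(levels.to_numpy(), cutoff), index=levels.index)

    active = ep.loc[(arm == active_arm) & fav]
    placebo = ep.loc[(arm == placebo_arm) & fav]
    contrasts: dict[str, ArmContrast | None] = {}
    for key, col in (("easi", "pct_easi_wk4"), ("iga", "pct_iga_wk4")):
        a = active[col].dropna()
        b = placebo[col].dropna()
        if len(a) >= 2 and len(b) >= 2:
            contrasts[key] = between_arm_contrast(a, b, equal_var=equal_var)
        else:
            contrasts[key] = None

    act_all = ep.loc[arm == active_arm]
    act_levels = levels.loc[act_all.index].to_numpy()
    act_flags = act_all["easi50_wk4"].astype(bool).to_numpy()
    area = auroc(act_levels, act_flags)
    area = max(area, 1.0 - area)
    table, ppv, npv = stratify_and_confusion(act_levels, cutoff, act_flags)
    try:
        association = odds_ratio_ha(table)
    except ValueError:
        association = None

    de, di = contrasts["easi"], contrasts["iga"]
    benefit = bool(de and di and benefit_indicator(de.p_value, di.p_value))
    marker = label or cutoff.protein_id
    return StratumReport(
        label=f"{marker}^{cutoff.direction}",
        delta_easi=de,
        delta_iga=di,
        pct_bas=100.0 * float(fav.mean()),
        auroc=area,
        auroc_p=_auroc_p(act_levels, act_flags),
        ppv=ppv,
        npv=npv,
        association=association,
        benefit=benefit,
    )


def table2_style(reports: list[StratumReport]) -> pd.DataFrame:
    """Flatten stratum reports into a printed-table-style CSV frame."""
    rows = []
    for r in reports:
        row = {"stratum": r.label, "pct_bas": r.pct_bas, "auc": r.auroc,
               "auc_p": r.auroc_p, "ppv": r.ppv, "npv": r.npv, "benefit": r.benefit}
        for key, c in (("delta_easi", r.delta_easi), ("delta_iga", r.delta_iga)):
            row[key] = c.mean_diff if c else None
            row[f"{key}_ci_low"] = c.ci_low if c else None
            row[f"{key}_ci_high"] = c.ci_high if c else None
            row[f"{key}_p"] = c.p_value if c else None
        if r.association:
            row["or"] = r.association.odds_ratio
            row["or_ci_low"] = r.association.ci_low
            row["or_ci_high"] = r.association.ci_high
            row["or_p"] = r.association.p_value
        else:
            row["or"] = row["or_ci_low"] = row["or_ci_high"] = row["or_p"] = None
        rows.append(row)
    return pd.DataFrame(rows)
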