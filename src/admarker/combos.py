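"""Multi-marker combination search.

Two complementary stratification pathways are first-class:

* a logistic model on 2-3 baseline markers whose predicted probability (pp)
  is thresholded at its own Youden-optimal point, and
* a boolean union rule ("marker A^hi or marker B^lo") built from the
  single-marker Youden cut-offs.

The logistic fit is maximum likelihood by iteratively reweighted least
squares.  With ~20 active-arm patients and strong markers the likelihood
frequently separates; separation is detected and the model refit with a tiny
ridge penalty (lambda = 1e-4 on the slopes) so predicted probabilities remain
usable for ranking and thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .endpoints import between_arm_contrast
from .stratify import (
    CutoffResult,
    benefit_indicator,
    odds_ratio_ha,
    stratify_and_confusion,
    youden_optimal_cutoff,
)

__all__ = [
    "ComboModel",
    "UnionRule",
    "fit_combo_logistic",
    "pp_threshold",
    "union_stratify",
    "enumerate_and_report",
]

RIDGE_LAMBDA = 1e-4
MAX_ITER = 100
LL_TOL = 1e-8


@dataclass
class ComboModel:
    """Fitted logistic combination of baseline markers."""

    protein_ids: tuple[str, ...]
    log_transform_flags: tuple[bool, ...]
    intercept: float
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    separation_detected: bool
    pp_cutoff: float | None = None
    auc_of_pp: float | None = None

    def design(self, matrix: pd.DataFrame) -> np.ndarray:
        cols = []
        for pid, logt in zip(self.protein_ids, self.log_transform_flags):
            x = matrix[pid].to_numpy(dtype=float)
            cols.append(np.log(x) if logt else x)
        return np.column_stack(cols)

    def predict_pp(self, matrix: pd.DataFrame) -> np.ndarray:
        """Predicted response probability for each patient."""
        eta = self.intercept + self.design(matrix) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for logistic regression; returns (beta, se, converged).

    ``X`` includes the intercept column; the ridge penalty, when non-zero,
    applies to slopes only.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.zeros(k)
    pen[1:] = ridge
    ll_old = -np.inf
    converged = False
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))) - 0.5 * np.sum(pen * beta**2))
        info = X.T @ (w[:, None] * X) + np.diag(pen)
        score = X.T @ (y - p) - pen * beta
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if abs(ll - ll_old) < LL_TOL:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-10, None)
    info = X.T @ (w[:, None] * X) + np.diag(pen)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return beta, se, converged


def fit_combo_logistic(
    matrix: pd.DataFrame,
    responder_flags,
    protein_ids: tuple[str, ...] | list[str],
    log_transform_flags: tuple[bool, ...] | None = None,
) -> ComboModel:
    """Maximum-likelihood logistic fit of responder status on baseline markers.

    ``log_transform_flags`` marks covariates entered on the natural-log scale
    (the keratin-type marker is the one the printed models log-transform).
    Perfect or quasi-separation — fitted probabilities that perfectly split
    the classes, or divergence without convergence — triggers a refit with a
    tiny ridge on the slopes and sets ``separation_detected``.  A rank-
    deficient design (e.g. a constant covariate alongside the intercept)
    raises.
    """
    protein_ids = tuple(protein_ids)
    if log_transform_flags is None:
        log_transform_flags = (False,) * len(protein_ids)
    log_transform_flags = tuple(bool(f) for f in log_transform_flags)
    if len(log_transform_flags) != len(protein_ids):
        raise ValueError("one log flag per protein required")

    y = np.asarray(responder_flags).astype(float)
    if y.min() == y.max():
        raise ValueError("logistic fit needs both responder classes")
    if len(y) < len(protein_ids) + 2:
        raise ValueError("need n >= number of predictors + 2")

    model = ComboModel(
        protein_ids=protein_ids,
        log_transform_flags=log_transform_flags,
        intercept=0.0,
        coefficients=np.zeros(len(protein_ids)),
        standard_errors=np.zeros(len(protein_ids) + 1),
        converged=False,
        separation_detected=False,
    )
    Xraw = model.design(matrix)
    X = np.column_stack([np.ones(len(y)), Xraw])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear covariate)")

    beta, se, converged = _irls(X, y)
    pp = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -500, 500)))
    separated = (pp[y == 1].min() >= pp[y == 0].max() - 1e-9) or (
        not converged and np.abs(beta).max() > 1e2
    )
    if separated:
        beta, se, converged = _irls(X, y, ridge=RIDGE_LAMBDA)
    model.intercept = float(beta[0])
    model.coefficients = beta[1:]
    model.standard_errors = se
    model.converged = converged
    model.separation_detected = bool(separated)
    return model


def pp_threshold(
    model: ComboModel, matrix: pd.DataFrame, responder_flags
) -> ComboModel:
    """Youden-optimal threshold on the model's predicted probabilities.

    Uses the same candidate-midpoint rule as the single-marker cut-off scan;
    returns the model with ``pp_cutoff`` and ``auc_of_pp`` filled in.  All-
    equal predicted probabilities leave the threshold undefined (None).
    """
    pp = model.predict_pp(matrix)
    y = np.asarray(responder_flags).astype(bool)
    res = youden_optimal_cutoff(pp, y, protein_id="+".join(model.protein_ids))
    model.auc_of_pp = res.auroc
    model.pp_cutoff = res.cutoff if res.direction is not None else None
    if res.direction == "lo":
        # a fitted logistic pp is monotone in the response; a "lo" optimum can
        # only arise from noise-dominated fits — keep the threshold but warn
        warnings.warn("pp threshold selected with inverted direction")
    return model


@dataclass(frozen=True)
class UnionRule:
    """Boolean OR of single-marker clauses (protein, side, cut-off)."""

    clauses: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("union rule needs at least one clause")
        for _, side, _ in self.clauses:
            if side not in ("hi", "lo"):
                raise ValueError("clause side must be 'hi' or 'lo'")

    @property
    def label(self) -> str:
        return " or ".join(f"{pid}^{side}" for pid, side, _ in self.clauses)

    @classmethod
    def from_cutoffs(cls, cutoffs: list[CutoffResult]) -> "UnionRule":
        return cls(tuple((c.protein_id, c.direction, c.cutoff) for c in cutoffs))


def union_stratify(matrix: pd.DataFrame, rule: UnionRule) -> pd.Series:
    """Favorable membership: any clause holds (hi: >= cut-off; lo: <=)."""
    fav = np.zeros(len(matrix), dtype=bool)
    for pid, side, cutoff in rule.clauses:
        x = matrix[pid].to_numpy(dtype=float)
        fav |= (x >= cutoff) if side == "hi" else (x <= cutoff)
    return pd.Series(fav, index=matrix.index)


def _stratum_row(
    label: str,
    fav: pd.Series,
    endpoints: pd.DataFrame,
    active_arm: str,
    placebo_arm: str,
    equal_var: bool,
) -> dict:
    """Benefit metrics for an arbitrary favorable stratum (shared by pp and
    union pathways)."""
    ep = endpoints.set_index("patient_id").loc[fav.index]
    arm = ep["arm"]
    row: dict = {"stratum": label, "pct_bas": 100.0 * float(fav.mean())}
    for key, col in (("delta_easi", "pct_easi_wk4"), ("delta_iga", "pct_iga_wk4")):
        a = ep.loc[(arm == active_arm) & fav, col].dropna()
        b = ep.loc[(arm == placebo_arm) & fav, col].dropna()
        if len(a) >= 2 and len(b) >= 2:
            c = between_arm_contrast(a, b, equal_var=equal_var)
            row[key], row[f"{key}_p"] = c.mean_diff, c.p_value
            row[f"{key}_ci_low"], row[f"{key}_ci_high"] = c.ci_low, c.ci_high
        else:
            row[key] = row[f"{key}_p"] = None
            row[f"{key}_ci_low"] = row[f"{key}_ci_high"] = None

    act = ep.loc[arm == active_arm]
    y = act["easi50_wk4"].astype(bool).to_numpy()
    f = fav.loc[act.index].to_numpy()
    from .stratify import ContingencyTable  # local to avoid cycle at import

    table = ContingencyTable(
        a=int((f & y).sum()), b=int((f & ~y).sum()),
        c=int((~f & y).sum()), d=int((~f & ~y).sum()),
    )
    row["ppv"], row["npv"] = table.ppv, table.npv
    try:
        assoc = odds_ratio_ha(table)
        row["or"], row["or_p"] = assoc.odds_ratio, assoc.p_value
        row["or_ci_low"], row["or_ci_high"] = assoc.ci_low, assoc.ci_high
    except ValueError:
        row["or"] = row["or_p"] = row["or_ci_low"] = row["or_ci_high"] = None
    row["benefit"] = bool(
        row["delta_easi_p"] is not None
        and row["delta_iga_p"] is not None
        and benefit_indicator(row["delta_easi_p"], row["delta_iga_p"])
    )
    return row


def enumerate_and_report(
    matrix: pd.DataFrame,
    dep_list: list[CutoffResult],
    endpoints: pd.DataFrame,
    k: int = 2,
    log_transform: dict[str, bool] | None = None,
    active_arm: str = "high_dose",
    placebo_arm: str = "placebo",
    equal_var: bool = True,
    max_combos: int = 20000,
) -> pd.DataFrame:
    """Evaluate every k-subset of screened markers and rank the reports.

    For each subset, a logistic combination is fitted on the active arm and
    thresholded at the Youden-optimal predicted probability, and the boolean
    union of the single-marker cut-offs forms a second stratum; both strata
    get the full printed-table row (ΔEASI/ΔIGA contrasts, %BAS, AUC, PPV/NPV,
    OR with CI and Fisher p).  Rows are ordered by OR p-value then AUC
    descending (deterministic).  ``k = 1`` degenerates to the single-marker
    report.  Subset counts beyond ``max_combos`` are refused with guidance.
    """
    if k < 1 or k > 3:
        raise ValueError("k must be 1, 2 or 3")
    by_id = {c.protein_id: c for c in dep_list}
    ids = sorted(by_id)
    n_combos = len(list(combinations(range(len(ids)), k))) if len(ids) >= k else 0
    if n_combos > max_combos:
        raise ValueError(
            f"{n_combos} subsets exceed the configured budget ({max_combos}); "
            "shorten dep_list or raise max_combos"
        )
    log_transform = log_transform or {}

    ep = endpoints.set_index("patient_id").loc[matrix.index]
    act_mask = (ep["arm"] == active_arm).to_numpy()
    act_matrix = matrix.loc[act_mask]
    act_flags = ep.loc[act_mask, "easi50_wk4"].astype(bool).to_numpy()

    rows = []
    for subset in combinations(ids, k):
        cutoffs = [by_id[pid] for pid in subset]
        rule = UnionRule.from_cutoffs(cutoffs)
        fav_union = union_stratify(matrix, rule)
        row = _stratum_row(rule.label, fav_union, endpoints,
                           active_arm, placebo_arm, equal_var)
        row["pathway"] = "union"

        flags = tuple(log_transform.get(pid, False) for pid in subset)
        model = fit_combo_logistic(act_matrix, act_flags, subset, flags)
        model = pp_threshold(model, act_matrix, act_flags)
        row["pp_auc"] = model.auc_of_pp
        row["pp_cutoff"] = model.pp_cutoff
        row["separation"] = model.separation_detected
        if model.pp_cutoff is not None:
            pp_all = model.predict_pp(matrix)
            fav_pp = pd.Series(pp_all >= model.pp_cutoff, index=matrix.index)
            pp_row = _stratum_row(f"pp({'+'.join(subset)})", fav_pp, endpoints,
                                  active_arm, placebo_arm, equal_var)
            pp_row["pathway"] = "pp"
            pp_row["pp_auc"] = model.auc_of_pp
            pp_row["pp_cutoff"] = model.pp_cutoff
            pp_row["separation"] = model.separation_detected
            rows.append(pp_row)
        rows.append(row)

    report = pd.DataFrame(rows)
    report["_orp"] = report["or_p"].fillna(np.inf)
    report = (
        report.sort_values(["_orp", "pp_auc", "stratum"],
                           ascending=[True, False, True], kind="stable")
        .drop(columns="_orp")
        .reset_index(drop=True)
    )
    return report
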