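"""Exploratory analytics over the baseline quant matrix.

Hierarchical clustering (Canberra distance, complete linkage, on z-scored
biomarkers), standardized PCA, volcano statistics (log2 fold change of group
means with a two-sample t test), and preranked gene set enrichment analysis
with permutation significance.

GSEA here follows the weighted Kolmogorov-Smirnov-style running sum: proteins
are ranked by a score (log2 fold change, descending), hits advance the sum in
proportion to |score| (weight exponent p = 1), misses retreat it uniformly,
and the enrichment score ES is the extremum of the running sum.  Because the
input is a preranked list, the null is formed by permuting set membership:
each permutation draws a random same-size set from the ranked universe.  The
normalized score NES divides ES by the mean |null ES| of the same sign, the
permutation p-value is one-sided within sign, and FDR q follows the standard
NES-based pooled-null procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClusterResult",
    "VolcanoRow",
    "GseaResult",
    "zscore_matrix",
    "hcluster",
    "pca",
    "volcano",
    "enrichment_score",
    "gsea_preranked",
    "read_gmt",
]


def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each biomarker (column); zero-variance columns are dropped."""
    sd = matrix.std(axis=0, ddof=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance biomarker(s) excluded from z-scoring")
        matrix = matrix.loc[:, ~bad]
        sd = sd[~bad]
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy merge tree over rows
    row_order: list              # dendrogram leaf order (row labels)
    col_linkage: np.ndarray
    col_order: list


def hcluster(matrix: pd.DataFrame, metric: str = "canberra",
             method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of patients and biomarkers.

    Biomarkers are z-scored first so scale differences spanning orders of
    magnitude do not dominate the distance.  Rows (patients) and columns
    (biomarkers) are clustered with the same metric/linkage; distance ties
    merge the lowest-index pair (scipy's deterministic behaviour given the
    input order).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    z = zscore_matrix(matrix)
    zl = hierarchy.linkage(z.to_numpy(), method=method, metric=metric)
    cl = hierarchy.linkage(z.to_numpy().T, method=method, metric=metric)
    return ClusterResult(
        linkage=zl,
        row_order=[z.index[i] for i in hierarchy.leaves_list(zl)],
        col_linkage=cl,
        col_order=[z.columns[i] for i in hierarchy.leaves_list(cl)],
    )


def pca(matrix: pd.DataFrame, n_components: int | None = None):
    """Standardized principal component analysis.

    Columns are standardized to mean 0 / SD 1 (constant columns dropped with
    a warning); component signs follow the largest-|loading|-positive
    convention so results do not flip between runs.  Returns
    ``(scores, explained_variance_ratio, loadings)``.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    sd = matrix.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant column(s) dropped before PCA")
        matrix = matrix.loc[:, sd > 0]
    X = StandardScaler().fit_transform(matrix.to_numpy())
    model = PCA(n_components=n_components)
    scores = model.fit_transform(X)
    load = model.components_
    for i in range(load.shape[0]):
        j = np.argmax(np.abs(load[i]))
        if load[i, j] < 0:
            load[i] *= -1.0
            scores[:, i] *= -1.0
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=cols),
        pd.Series(model.explained_variance_ratio_, index=cols),
        pd.DataFrame(load, index=cols, columns=matrix.columns),
    )


@dataclass(frozen=True)
class VolcanoRow:
    protein_id: str
    log2_fc: float          # log2(mean responders / mean non-responders)
    p_value: float


def volcano(matrix: pd.DataFrame, responder_flags,
            equal_var: bool = True) -> pd.DataFrame:
    """Per-protein log2 fold change and two-sided t p-value.

    The fold change is the ratio of group means of responders over
    non-responders on the log2 scale, so it is invariant to rescaling a
    protein in both groups.  Proteins whose group mean is non-positive have
    an undefined fold change (NaN) but keep their p-value.
    """
    y = np.asarray(responder_flags).astype(bool)
    if y.all() or not y.any():
        raise ValueError("volcano needs both responder classes")
    X = matrix.to_numpy(dtype=float)
    m1 = X[y].mean(axis=0)
    m0 = X[~y].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((m1 > 0) & (m0 > 0), np.log2(m1 / m0), np.nan)
    p = stats.ttest_ind(X[y], X[~y], axis=0, equal_var=equal_var).pvalue
    return pd.DataFrame(
        {"protein_id": matrix.columns, "log2_fc": fc, "p_value": p}
    )


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked_ids: np.ndarray, scores: np.ndarray, members: set, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted running-sum enrichment score and the index of its extremum.

    ``ranked_ids``/``scores`` must already be sorted by score descending.
    Hits step up by |score|**weight (normalized), misses step down uniformly;
    ES is the running-sum value of largest magnitude.
    """
    is_hit = np.fromiter((g in members for g in ranked_ids), dtype=bool, count=len(ranked_ids))
    n_hits = int(is_hit.sum())
    if n_hits == 0 or n_hits == len(ranked_ids):
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all member scores are exactly zero: fall back to equal steps
        hit_w = is_hit.astype(float)
        denom = float(n_hits)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~is_hit) / (len(ranked_ids) - n_hits)
    running = p_hit - p_miss
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list = field(default_factory=list)
    size: int = 0


def gsea_preranked(
    ranked_scores: pd.Series,
    gene_sets: dict[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 2,
) -> list[GseaResult]:
    """Preranked GSEA with set-membership permutation.

    ``ranked_scores`` maps protein/gene id to its ranking score (log2 fold
    change); it is sorted descending internally.  Sets are intersected with
    the universe; sets emptier than ``min_size`` after intersection are
    skipped with a warning.  For each set, ``n_perm`` random same-size
    membership draws form the null; NES = ES / mean(|null ES| of the same
    sign), p is one-sided within sign, and q is the standard NES-based FDR
    over the collection.  The leading edge contains the members at or before
    the running-sum extremum (after, for negative ES).
    """
    ranked = ranked_scores.sort_values(ascending=False, kind="stable")
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    universe = set(ids)
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    null_nes: list[float] = []
    obs_nes: list[float] = []
    for name, members in gene_sets.items():
        inter = set(members) & universe
        if len(inter) < min_size or len(inter) >= len(ids):
            warnings.warn(f"gene set {name!r} skipped (size {len(inter)} after intersection)")
            continue
        es, idx = enrichment_score(ids, scores, inter, weight)
        m = len(inter)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = set(rng.choice(ids, size=m, replace=False))
            null[b], _ = enrichment_score(ids, scores, perm, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / np.abs(same_sign).mean()
            p = float((np.abs(same_sign) >= abs(es)).sum() + 1) / (same_sign.size + 1)
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            normed = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes.extend(normed[np.isfinite(normed)].tolist())
        obs_nes.append(float(nes))

        hit_positions = [i for i, g in enumerate(ids) if g in inter]
        if es >= 0:
            leading = [ids[i] for i in hit_positions if i <= idx]
        else:
            leading = [ids[i] for i in hit_positions if i >= idx]
        results.append(GseaResult(name, float(es), float(nes), p, 1.0, leading, m))

    # NES-based FDR: fraction of pooled null NES at least as extreme (same
    # sign) over fraction of observed NES at least as extreme, clipped to 1
    null_arr = np.asarray(null_nes)
    obs_arr = np.asarray(obs_nes)
    for r in results:
        if r.nes >= 0:
            null_tail = (null_arr >= r.nes).sum() / max((null_arr >= 0).sum(), 1)
            obs_tail = (obs_arr >= r.nes).sum() / max((obs_arr >= 0).sum(), 1)
        else:
            null_tail = (null_arr <= r.nes).sum() / max((null_arr < 0).sum(), 1)
            obs_tail = (obs_arr <= r.nes).sum() / max((obs_arr < 0).sum(), 1)
        r.fdr_q = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0
    results.sort(key=lambda r: (-r.nes, r.set_name))
    return results


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from GMT (name, description, members...; tab-separated)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
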