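"""Cluster-based permutation tests (CBPT) on source-wise complexity maps.

The test follows the standard seven-step scheme for spatial multiple-
comparison control:

1. a simple statistic per source (pooled-variance two-sample t between
   groups, or a Pearson correlation with a covariate);
2. sources whose two-sided p falls below the cluster-forming alpha are kept;
3. kept sources are partitioned into maximal spatially contiguous components
   of the same statistic sign, and each cluster's statistic is the sum of
   its members' statistics;
4. the design is randomly relabeled (group labels shuffled, or the covariate
   shuffled across subjects) many times;
5. steps 1-3 are repeated on each relabeling;
6. the maximum absolute cluster statistic per relabeling forms the null
   distribution (max-statistic correction, strong family-wise control);
7. each observed cluster's p-value is the fraction of null values at least
   as large as its absolute statistic, with the +1 correction so permutation
   p-values are never exactly zero.

Sources where the statistic is undefined (zero variance) are flagged and
treated as non-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sstats

from .grid import SourceGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterResult:
    """A contiguous cluster of sources with its permutation-corrected p-value."""

    sources: np.ndarray          # sorted source indices
    cluster_stat: float          # sum of member statistics
    p_value: float               # (1 + #{null >= |stat|}) / (1 + n_perm)
    sign: int                    # +1 or -1
    significant: bool
    effect_size: float | None = None  # Cohen's d (group) or mean rho (correlation)

    @property
    def n_sources(self) -> int:
        return self.sources.size


# ---------------------------------------------------------------------------
# per-source statistics (vectorized over permutations)
# ---------------------------------------------------------------------------

def _group_mask(groups: Sequence[str] | np.ndarray) -> np.ndarray:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two group levels, got {levels}")
    mask = groups == levels[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return mask  # True = first level alphabetically (F before M)


def _t_from_masks(X: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t and two-sided p for each mask row.

    X: (n_subj, n_src); masks: (n_rows, n_subj) boolean with constant row sum.
    Returns t, p of shape (n_rows, n_src); undefined t (zero pooled variance)
    comes back as NaN with p = 1.
    """
    n = X.shape[0]
    n1 = int(masks[0].sum())
    n2 = n - n1
    M = masks.astype(float)
    s1 = M @ X
    q1 = M @ (X * X)
    st = X.sum(axis=0)
    qt = (X * X).sum(axis=0)
    mean1 = s1 / n1
    mean2 = (st - s1) / n2
    ss1 = np.maximum(q1 - s1 ** 2 / n1, 0.0)
    ss2 = np.maximum((qt - q1) - (st - s1) ** 2 / n2, 0.0)
    sp2 = (ss1 + ss2) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / denom
    t = np.where(denom > 0, t, np.nan)
    p = np.full_like(t, 1.0)
    finite = np.isfinite(t)
    p[finite] = 2.0 * sstats.t.sf(np.abs(t[finite]), df=n - 2)
    return t, p


def _r_from_covariates(X: np.ndarray, covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of each covariate row against each source.

    X: (n_subj, n_src); covs: (n_rows, n_subj).  Constant sources give NaN r
    with p = 1; a constant covariate is rejected.
    """
    n = X.shape[0]
    if n < 4:
        raise ValueError("correlation statistics need at least 4 subjects")
    c_sd = covs.std(axis=1, ddof=1)
    if np.any(c_sd == 0):
        raise ValueError("covariate is constant")
    zc = (covs - covs.mean(axis=1, keepdims=True)) / c_sd[:, None]
    x_sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zx = (X - X.mean(axis=0, keepdims=True)) / x_sd[None, :]
    r = (zc @ np.where(x_sd > 0, zx, 0.0)) / (n - 1)
    r = np.where(x_sd[None, :] > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, 1.0)
    finite = np.isfinite(r)
    rr = r[finite]
    with np.errstate(divide="ignore"):
        tvals = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr ** 2, 1e-300))
    p[finite] = 2.0 * sstats.t.sf(np.abs(tvals), df=n - 2)
    return r, p


def source_ttest(values: np.ndarray, groups: Sequence[str] | np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Classic pooled-variance t (first group minus second) per source.

    Returns (t, p); sources where the pooled variance is zero are flagged
    with NaN t and p = 1 (logged, treated as non-significant).
    """
    X = np.asarray(values, dtype=float)
    mask = _group_mask(groups)
    t, p = _t_from_masks(X, mask[None, :])
    bad = ~np.isfinite(t[0])
    if bad.any():
        logger.warning("t undefined (zero variance) at %d source(s): %s",
                       bad.sum(), np.flatnonzero(bad).tolist())
    return t[0], p[0]


def source_correlation(values: np.ndarray, covariate: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson rho and two-sided p of a subject covariate against each source."""
    X = np.asarray(values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != X.shape[0]:
        raise ValueError("covariate length does not match subject count")
    r, p = _r_from_covariates(X, cov[None, :])
    bad = ~np.isfinite(r[0])
    if bad.any():
        logger.warning("rho undefined (constant source) at %d source(s)", bad.sum())
    return r[0], p[0]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _components(candidates: np.ndarray, adjacency: list[np.ndarray]) -> list[list[int]]:
    """Connected components of the candidate source set (BFS)."""
    member = set(int(i) for i in candidates)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in sorted(member):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in adjacency[node]:
                nb = int(nb)
                if nb in member and nb not in seen:
                    seen.add(nb)
                    comp.append(nb)
                    queue.append(nb)
        comps.append(sorted(comp))
    return comps


def form_clusters(stat_map: np.ndarray, p_map: np.ndarray, alpha: float,
                  grid: SourceGrid) -> list[tuple[np.ndarray, float, int]]:
    """Partition significant sources into same-sign contiguous clusters.

    Returns (sources, summed statistic, sign) triples; may be empty.
    NaN statistics never enter a cluster.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    p_map = np.asarray(p_map, dtype=float)
    if stat_map.shape != (grid.n_sources,) or p_map.shape != (grid.n_sources,):
        raise ValueError("statistic/p maps are not aligned with the grid")
    sig = (p_map < alpha) & np.isfinite(stat_map)
    out: list[tuple[np.ndarray, float, int]] = []
    adjacency = grid.adjacency()
    for sign in (1, -1):
        candidates = np.flatnonzero(sig & ((stat_map > 0) if sign > 0 else (stat_map < 0)))
        if candidates.size == 0:
            continue
        for comp in _components(candidates, adjacency):
            members = np.asarray(comp, dtype=np.int64)
            out.append((members, float(stat_map[members].sum()), sign))
    return out


def _max_cluster_stat(stat_map: np.ndarray, p_map: np.ndarray, alpha: float,
                      grid: SourceGrid) -> float:
    clusters = form_clusters(stat_map, p_map, alpha, grid)
    if not clusters:
        return 0.0
    return max(abs(stat) for _, stat, _ in clusters)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_d(values: np.ndarray, sources: np.ndarray,
             groups: Sequence[str] | np.ndarray) -> float:
    """Cohen's d (first group minus second) on per-subject cluster means."""
    sources = np.asarray(sources, dtype=np.int64)
    if sources.size == 0:
        raise ValueError("cluster is empty")
    X = np.asarray(values, dtype=float)[:, sources].mean(axis=1)
    mask = _group_mask(groups)
    a, b = X[mask], X[~mask]
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(X) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def cluster_mean_rho(values: np.ndarray, sources: np.ndarray,
                     covariate: np.ndarray) -> float:
    """Arithmetic mean of per-source Pearson rho over cluster members."""
    sources = np.asarray(sources, dtype=np.int64)
    if sources.size == 0:
        raise ValueError("cluster is empty")
    r, _ = source_correlation(np.asarray(values, dtype=float), covariate)
    rs = r[sources]
    good = np.isfinite(rs)
    if not good.all():
        logger.warning("excluding %d source(s) with undefined rho from cluster mean",
                       (~good).sum())
    if not good.any():
        raise ValueError("rho undefined at every cluster member")
    return float(rs[good].mean())


# ---------------------------------------------------------------------------
# the permutation test
# ---------------------------------------------------------------------------

def cbpt(
    values: np.ndarray,
    design: Sequence[str] | np.ndarray,
    grid: SourceGrid,
    *,
    mode: Literal["group", "correlation"] = "group",
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[ClusterResult]:
    """Cluster-based permutation test of a [subject, source] complexity map.

    ``design`` is the per-subject group label (mode "group") or scalar
    covariate (mode "correlation").  Returns every observed cluster, ordered
    by decreasing |cluster statistic|, with max-statistic permutation
    p-values; ``significant`` marks p < alpha.  Deterministic given seed.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a [subject, source] matrix")
    if not np.isfinite(X).all():
        raise ValueError("complexity map contains non-finite values")
    if X.shape[1] != grid.n_sources:
        raise ValueError("map source axis does not match the grid")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)

    if mode == "group":
        mask = _group_mask(design)
        obs_stat, obs_p = _t_from_masks(X, mask[None, :])
        perms = np.stack([rng.permutation(mask) for _ in range(n_perm)])
        perm_stat, perm_p = _t_from_masks(X, perms)
    elif mode == "correlation":
        cov = np.asarray(design, dtype=float)
        if cov.shape[0] != X.shape[0]:
            raise ValueError("covariate length does not match subject count")
        obs_stat, obs_p = _r_from_covariates(X, cov[None, :])
        perms = np.stack([rng.permutation(cov) for _ in range(n_perm)])
        perm_stat, perm_p = _r_from_covariates(X, perms)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    observed = form_clusters(obs_stat[0], obs_p[0], alpha, grid)
    if not observed:
        return []

    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _max_cluster_stat(perm_stat[i], perm_p[i], alpha, grid)

    results = []
    for members, stat, sign in observed:
        p_val = (1.0 + float((null >= abs(stat)).sum())) / (1.0 + n_perm)
        if mode == "group":
            effect = cohens_d(X, members, design)
        else:
            effect = cluster_mean_rho(X, members, np.asarray(design, dtype=float))
        results.append(ClusterResult(
            sources=members, cluster_stat=stat, p_value=p_val, sign=sign,
            significant=p_val < alpha, effect_size=effect))
    results.sort(key=lambda r: -abs(r.cluster_stat))
    return results
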