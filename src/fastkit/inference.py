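"""Permutation and rank-based tests, plus the serum-metabolite regression.

PERMANOVA follows Anderson's formulation: the pseudo-F is built from among-
and within-group sums of squared distances, and the p-value from random
relabelings (optionally restricted within strata, e.g. within-subject swaps
of aliquot labels).  Permuted statistics are computed in batch with one
matrix product per group, so null-calibration studies with hundreds of
replicates stay cheap.  Kruskal-Wallis and ordinary least squares are thin,
validated wrappers around scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "PermanovaResult",
    "RegressionResult",
    "permanova",
    "pairwise_permanova",
    "kruskal_wallis",
    "linear_regression",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    partial_r2: float

    def __str__(self) -> str:
        return (
            f"PERMANOVA: pseudo-F={self.pseudo_F:.4g}, "
            f"p={self.p_value:.4g} ({self.n_permutations} permutations), "
            f"R2={self.partial_r2:.4g}"
        )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def __str__(self) -> str:
        return (
            f"OLS: slope={self.slope:.4g}, intercept={self.intercept:.4g}, "
            f"R2={self.r_squared:.4g}, p={self.p_value:.4g}"
        )


def _resolve_dm(dm) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(dm, DistanceMatrix):
        return np.asarray(dm.data, dtype=float), list(dm.ids)
    arr = np.asarray(dm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr, None


def _resolve_labels(labels, ids: list[str] | None, n: int, what: str) -> np.ndarray:
    if isinstance(labels, Mapping):
        if ids is None:
            raise ValueError(f"{what} given as a mapping but matrix has no IDs")
        labels = [labels[i] for i in ids]
    out = np.asarray(list(labels))
    if len(out) != n:
        raise ValueError(f"{what} length {len(out)} != matrix size {n}")
    return out


def _ss_within_batch(D2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a batch of labelings.

    ``codes`` is (n, P) integer group codes; returns SS_W per column.
    """
    n, P = codes.shape
    ss_w = np.zeros(P)
    for c, n_c in enumerate(sizes):
        M = (codes == c).astype(float)
        ss_w += np.einsum("ij,ij->j", M, D2 @ M) / (2.0 * n_c)
    return ss_w


def permanova(
    dm,
    grouping,
    permutations: int = 999,
    seed: int | None = None,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    dm : skbio DistanceMatrix or square array
    grouping : sequence of labels aligned with the matrix, or id -> label map
    permutations : number of random relabelings (default 999)
    seed : RNG seed; fixed seed gives a reproducible p-value
    strata : optional labels; permutations shuffle only within each stratum
        (e.g. within-subject when comparing aliquot roles)

    The p-value uses the plus-one correction (1 + #{F* >= F}) / (1 + P), so
    it is never zero and has resolution 1/(permutations + 1).
    """
    D, ids = _resolve_dm(dm)
    n = D.shape[0]
    labels = _resolve_labels(grouping, ids, n, "grouping")
    uniq, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 1).any():
        raise ValueError("every group needs at least one member")
    D2 = D.astype(float) ** 2
    ss_total = D2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise ValueError("constant distance matrix: pseudo-F undefined")

    ss_w_obs = _ss_within_batch(D2, codes[:, None], sizes)[0]
    ss_a_obs = ss_total - ss_w_obs
    if n - k <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_w_obs <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_a_obs / (k - 1)) / (ss_w_obs / (n - k))

    rng = np.random.default_rng(seed)
    perm_codes = np.empty((n, permutations), dtype=np.int64)
    if strata is None:
        for p in range(permutations):
            perm_codes[:, p] = codes[rng.permutation(n)]
    else:
        strata_labels = _resolve_labels(strata, ids, n, "strata")
        groups_idx = [
            np.flatnonzero(strata_labels == s) for s in np.unique(strata_labels)
        ]
        for p in range(permutations):
            order = np.arange(n)
            for idx in groups_idx:
                order[idx] = idx[rng.permutation(len(idx))]
            perm_codes[:, p] = codes[order]
    ss_w_perm = _ss_within_batch(D2, perm_codes, sizes)
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ss_w_perm) / (k - 1)) / (ss_w_perm / (n - k))
    hits = int(np.sum(f_perm >= f_obs - 1e-12))
    p_value = (1 + hits) / (1 + permutations)
    return PermanovaResult(
        float(f_obs), float(p_value), permutations, float(ss_a_obs / ss_total)
    )


def pairwise_permanova(
    dm, grouping, permutations: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """PERMANOVA for every group pair with Bonferroni-adjusted p-values."""
    D, ids = _resolve_dm(dm)
    n = D.shape[0]
    labels = _resolve_labels(grouping, ids, n, "grouping")
    groups = list(dict.fromkeys(labels))
    if len(groups) < 3:
        raise ValueError("pairwise comparison needs at least 3 groups")
    pairs = list(combinations(groups, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in pairs:
        mask = np.isin(labels, [g1, g2])
        sub = D[np.ix_(mask, mask)]
        res = permanova(
            sub, labels[mask], permutations=permutations,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "p_adjusted": min(1.0, res.p_value * len(pairs)),
                "partial_r2": res.partial_r2,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p-value.

    All-identical values across groups return (0.0, 1.0) rather than an
    error: there is no evidence of any difference.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 values in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the F-test p-value on the slope."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(xv) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant: slope undefined")
    fit = stats.linregress(xv, yv)
    return RegressionResult(
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
    )
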