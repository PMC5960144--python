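"""Pairwise community distances: Bray-Curtis, Jaccard, and UniFrac.

The UniFrac metrics are computed from a branch-incidence matrix built in a
single postorder traversal: row b of the incidence matrix marks the features
descending from branch b.  Presence or proportion vectors are then lifted to
branches with one matrix product, which makes full distance matrices a few
dense linear-algebra operations.  Brute-force per-branch enumeration is kept
to the test suite as an independent oracle.

Jaccard is the binary (presence/absence) distance by default, the unweighted
counterpart to Bray-Curtis; the abundance-based Ruzicka variant is available
behind a flag.  Weighted UniFrac defaults to the normalized variant so values
are comparable across pairs; the raw branch-length sum is available with
``normalized=False``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .io import CountTable

__all__ = [
    "bray_curtis",
    "jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "distance_matrix",
    "branch_incidence",
]

METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


def _pair(x, y) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Align two count vectors; returns arrays plus feature IDs if available."""
    ids = None
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            y = y.reindex(x.index)
            if y.isna().any():
                raise ValueError("x and y must share a feature universe")
        ids = list(x.index)
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have the same length")
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("counts must be non-negative")
    return xv, yv, ids


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    xv, yv, _ = _pair(x, y)
    denom = (xv + yv).sum()
    if denom == 0:
        raise ValueError("both samples are empty")
    return float(np.abs(xv - yv).sum() / denom)


def jaccard(x, y, abundance: bool = False) -> float:
    """Jaccard distance 1 - |A&B|/|A|B| on presence/absence supports.

    ``abundance=True`` gives the quantitative Ruzicka variant
    1 - sum(min)/sum(max).
    """
    xv, yv, _ = _pair(x, y)
    if xv.sum() == 0 and yv.sum() == 0:
        raise ValueError("both samples are empty")
    if abundance:
        return float(1.0 - np.minimum(xv, yv).sum() / np.maximum(xv, yv).sum())
    a, b = xv > 0, yv > 0
    union = (a | b).sum()
    return float(1.0 - (a & b).sum() / union)


def branch_incidence(
    tree: TreeNode, feature_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch x feature incidence for the non-root nodes.

    Row b of the incidence matrix is True at the features that are leaves
    below branch b.  Tree tips outside ``feature_ids`` yield all-False
    columns' worth of nothing — they only matter if a sample claims them.
    """
    col = {f: i for i, f in enumerate(feature_ids)}
    n = len(feature_ids)
    rows: list[np.ndarray] = []
    lengths: list[float] = []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n, dtype=bool)
            if node.name in col:
                mask[col[node.name]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node is not tree:  # root carries no branch
            rows.append(mask)
            lengths.append(node.length or 0.0)
    return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)


def _check_in_tree(xv: np.ndarray, ids: Sequence[str], tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    present = [f for f, v in zip(ids, xv) if v > 0 and f not in tips]
    if present:
        raise ValueError(f"features with positive counts missing from tree: {present[:5]}")


def _unifrac_pair(x, y, tree: TreeNode):
    xv, yv, ids = _pair(x, y)
    if ids is None:
        raise ValueError("UniFrac needs feature-labeled vectors (pandas Series)")
    _check_in_tree(xv, ids, tree)
    _check_in_tree(yv, ids, tree)
    lengths, inc = branch_incidence(tree, ids)
    return xv, yv, lengths, inc


def unweighted_unifrac(x, y, tree: TreeNode) -> float:
    """Fraction of observed branch length unique to one of the two samples."""
    xv, yv, lengths, inc = _unifrac_pair(x, y, tree)
    px = inc @ (xv > 0) > 0
    py = inc @ (yv > 0) > 0
    observed = lengths[px | py].sum()
    if observed == 0:
        raise ValueError("no observed branch length (both samples empty?)")
    unique = lengths[px ^ py].sum()
    return float(unique / observed)


def weighted_unifrac(x, y, tree: TreeNode, normalized: bool = True) -> float:
    """Abundance-weighted UniFrac: sum_b l_b |p_b(x) - p_b(y)|.

    With ``normalized=True`` the sum is divided by sum_b l_b (p_b(x)+p_b(y)),
    bounding the distance by 1.
    """
    xv, yv, lengths, inc = _unifrac_pair(x, y, tree)
    if xv.sum() == 0 or yv.sum() == 0:
        raise ValueError("weighted UniFrac needs non-empty samples")
    pa = inc @ (xv / xv.sum())
    pb = inc @ (yv / yv.sum())
    raw = float((lengths * np.abs(pa - pb)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (pa + pb)).sum())
    return raw / denom


def distance_matrix(
    table: CountTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """All pairwise distances between the table's samples.

    ``metric`` is one of bray_curtis, jaccard, unweighted_unifrac,
    weighted_unifrac; the UniFrac metrics require ``tree``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {METRICS}")
    X = table.data.to_numpy(dtype=float)  # features x samples
    ids = table.sample_ids
    totals = X.sum(axis=0)
    if (totals == 0).any():
        empty = [s for s, t in zip(ids, totals) if t == 0]
        raise ValueError(f"samples with zero total: {empty}")

    if metric == "bray_curtis":
        condensed = pdist(X.T, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist((X > 0).T, metric="jaccard")
    else:
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        for j, s in enumerate(ids):
            _check_in_tree(X[:, j], table.feature_ids, tree)
        lengths, inc = branch_incidence(tree, table.feature_ids)
        if metric == "unweighted_unifrac":
            P = (inc.astype(float) @ (X > 0)) > 0  # branch x sample presence
            Pf = P.astype(float)
            shared = (lengths[:, None] * Pf).T @ Pf
            per = Pf.T @ lengths
            union = per[:, None] + per[None, :] - shared
            uniq = per[:, None] + per[None, :] - 2 * shared
            with np.errstate(invalid="ignore"):
                full = np.where(union > 0, uniq / np.maximum(union, 1e-300), 0.0)
            np.fill_diagonal(full, 0.0)
            return DistanceMatrix((full + full.T) / 2, ids=ids)
        else:
            Q = inc.astype(float) @ (X / totals)  # branch x sample proportions
            LQ = (lengths[:, None] * Q).T  # sample x branch
            raw = squareform(pdist(LQ, metric="cityblock"))
            if not normalized:
                return DistanceMatrix(raw, ids=ids)
            s = LQ.sum(axis=1)
            denom = s[:, None] + s[None, :]
            with np.errstate(invalid="ignore"):
                full = np.where(denom > 0, raw / np.maximum(denom, 1e-300), 0.0)
            np.fill_diagonal(full, 0.0)
            return DistanceMatrix((full + full.T) / 2, ids=ids)
    return DistanceMatrix(squareform(condensed), ids=ids)
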