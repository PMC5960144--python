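"""Independent brute-force oracles used to cross-check the implementations.

Everything here is deliberately naive — per-branch enumeration with explicit
leaf sets, plain-python sums, full permutation enumeration — and shares no
code with the fast paths it checks.
"""

from itertools import permutations

import numpy as np


def _branches(tree):
    """(length, leaf-name set) for every non-root node, via explicit tip walks."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            leaves = {node.name}
        else:
            leaves = {t.name for t in node.tips()}
        out.append((node.length or 0.0, leaves))
    return out


def unweighted_unifrac_brute(x: dict, y: dict, tree) -> float:
    """x, y: feature -> count mappings."""
    ax = {f for f, v in x.items() if v > 0}
    ay = {f for f, v in y.items() if v > 0}
    unique = observed = 0.0
    for length, leaves in _branches(tree):
        in_x = bool(leaves & ax)
        in_y = bool(leaves & ay)
        if in_x or in_y:
            observed += length
        if in_x != in_y:
            unique += length
    return unique / observed


def weighted_unifrac_brute(x: dict, y: dict, tree, normalized: bool = True) -> float:
    tx = sum(x.values())
    ty = sum(y.values())
    raw = denom = 0.0
    for length, leaves in _branches(tree):
        px = sum(v for f, v in x.items() if f in leaves) / tx
        py = sum(v for f, v in y.items() if f in leaves) / ty
        raw += length * abs(px - py)
        denom += length * (px + py)
    return raw / denom if normalized else raw


def bray_curtis_brute(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def jaccard_brute(x, y) -> float:
    a = {i for i, v in enumerate(x) if v > 0}
    b = {i for i, v in enumerate(y) if v > 0}
    return 1.0 - len(a & b) / len(a | b)


def pseudo_f_brute(D, labels) -> float:
    """Anderson's pseudo-F from explicit within-group double loops."""
    D = np.asarray(D, dtype=float)
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    k = len(groups)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += D[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += D[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova_exhaustive_p(D, labels) -> float:
    """Exact permutation p-value over all distinct relabelings."""
    f_obs = pseudo_f_brute(D, labels)
    seen = set()
    hits = total = 0
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if pseudo_f_brute(D, perm) >= f_obs - 1e-12:
            hits += 1
    return hits / total
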