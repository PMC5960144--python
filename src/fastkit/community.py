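"""Core count-table transformations and alpha-diversity statistics.

Relative abundance and taxonomic aggregation feed the recovery statistics
(computed on un-rarefied data); rarefaction feeds the diversity and distance
analyses.  Shannon diversity uses natural log, and rarefaction is a single
multivariate-hypergeometric draw per sample (mothur/vegan subsample
semantics), matching the upstream 16S pipeline conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OTU_RANK, RANKS, CountTable, TaxonomyMap

__all__ = [
    "AnalysisConfig",
    "relative_abundance",
    "aggregate_by_rank",
    "rarefy",
    "goods_coverage",
    "shannon",
]


@dataclass
class AnalysisConfig:
    """Knobs shared across the analysis stages.

    rarefaction_depth
        Reads per sample after rarefaction (default 4500).
    abundance_threshold
        Inclusion threshold tau as a proportion (default 0.001, i.e. 0.1%).
    alpha
        Significance level for hypothesis tests.
    """

    rarefaction_depth: int = 4500
    rng_seed: int = 0
    abundance_threshold: float = 0.001
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; all-zero samples stay all-zero (with a warning)."""
    totals = table.totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"all-zero samples left as zeros: {zero}", stacklevel=2)
    safe = totals.replace(0, 1)
    return table.data / safe


def aggregate_by_rank(table: CountTable, tax: TaxonomyMap, rank: str) -> CountTable:
    """Sum features sharing a label at ``rank``; rank ``"OTU"`` is the identity.

    Output feature IDs are the rank labels.  Per-sample totals are conserved.
    """
    if rank == OTU_RANK:
        return CountTable(table.data.copy())
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid: {RANKS + (OTU_RANK,)}")
    missing = [f for f in table.feature_ids if f not in tax]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing[:5]}")
    labels = [tax.label(f, rank) for f in table.feature_ids]
    grouped = table.data.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return CountTable(grouped)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each retained sample is one multivariate-hypergeometric draw; samples
    with fewer than ``depth`` reads are dropped with a warning.  Deterministic
    given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not keep:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    if dropped:
        warnings.warn(
            f"{len(dropped)} samples below depth {depth} dropped: {dropped[:5]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        counts = table.data[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(counts, depth)
    result = pd.DataFrame(out, index=table.data.index)
    return CountTable(result)


def _as_counts(sample) -> np.ndarray:
    counts = np.asarray(sample, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a 1-D counts vector")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("counts vector has zero total")
    return counts


def goods_coverage(sample) -> float:
    """Good's coverage, 1 - singletons/reads: estimated sampling completeness."""
    counts = _as_counts(sample)
    singletons = int((counts == 1).sum())
    return 1.0 - singletons / counts.sum()


def shannon(sample) -> float:
    """Shannon diversity H = -sum p ln p (nats)."""
    counts = _as_counts(sample)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())
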