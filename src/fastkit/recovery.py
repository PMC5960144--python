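"""Taxa-recovery statistics for paired aliquot and engraftment comparisons.

The central quantity: for a pair (reference, query group) of communities
from one subject, restrict to taxa reaching at least ``tau`` (default 0.1%)
relative abundance in at least one sample of the comparison group, and ask
what fraction of the reference's taxa are detected in the query.  Two
comparisons recur throughout: S1 vs S2 (two straw aliquots of the same
stool, a reproducibility check) and S2 vs mouse (the oral inoculum against
the recipient germ-free mice, an engraftment-fidelity check).  Abundance
capture — the summed reference relative abundance of recovered taxa — uses
all reference taxa, with no threshold.

All recovery statistics are computed from un-rarefied data; only the
distance-based analyses (see :mod:`fastkit.beta`) use rarefied counts.

The module exposes both the primitive operations and a statsmodels-style
model: build :class:`EngraftmentRecovery` from the study artifacts and call
``fit()`` for a :class:`RecoveryResults` with per-subject estimates,
per-rank mean +/- SE summaries and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .community import aggregate_by_rank, relative_abundance
from .io import OTU_RANK, RANKS, CountTable, SampleManifest, TaxonomyMap

__all__ = [
    "RecoveryConfig",
    "RecoveryResult",
    "inclusion_set",
    "taxa_recovery",
    "abundance_captured",
    "venn_partition",
    "summarize_recovery",
    "donor_matching_distances",
    "EngraftmentRecovery",
    "RecoveryResults",
]

POOLINGS = ("any_mouse", "per_mouse_mean")
DEFAULT_RANKS = ("phylum", "order", "family", "genus", OTU_RANK)


@dataclass
class RecoveryConfig:
    """Inclusion threshold, ranks, and mouse-pooling policy.

    tau
        Inclusion threshold as a proportion; a taxon enters a comparison if
        its relative abundance is >= tau in at least one sample of the
        comparison group ("at least 0.1%" is inclusive).
    pooling
        ``any_mouse``: a taxon counts as recovered if detected in any of the
        subject's mice.  ``per_mouse_mean``: the statistic is computed per
        mouse and averaged.
    """

    tau: float = 0.001
    ranks: tuple[str, ...] = DEFAULT_RANKS
    pooling: str = "any_mouse"

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        valid = RANKS + (OTU_RANK,)
        bad = [r for r in self.ranks if r not in valid]
        if bad:
            raise ValueError(f"unknown ranks {bad}; valid: {valid}")
        if self.pooling not in POOLINGS:
            raise ValueError(f"pooling must be one of {POOLINGS}")


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery statistics for one subject at one rank."""

    subject_id: str
    comparison: str
    pooling: str
    rank: str
    n_included: int
    n_reference: int
    n_recovered: float
    recovery_pct: float
    abundance_captured_pct: float
    venn: tuple[int, int, int]  # (reference_only, shared, query_only)

    @property
    def undefined(self) -> bool:
        """True when no reference taxon passed the inclusion rule."""
        return self.n_reference == 0


def _align(reference: pd.Series, queries: Sequence[pd.Series]) -> list[pd.Series]:
    out = []
    for q in queries:
        if not q.index.equals(reference.index):
            q = q.reindex(reference.index)
            if q.isna().any():
                raise ValueError("samples must share a feature universe")
        out.append(q)
    return out


def inclusion_set(samples: Sequence[pd.Series], tau: float) -> pd.Index:
    """Features reaching proportion >= tau in at least one provided sample.

    For mouse comparisons the comparison group is S2 plus all of the
    subject's mouse samples, so a taxon abundant only in mice still enters.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("inclusion_set needs at least one sample")
    stacked = pd.concat(_align(samples[0], samples), axis=1)
    mask = (stacked >= tau).any(axis=1)
    return stacked.index[mask]


def _detected(queries: Sequence[pd.Series]) -> pd.Series:
    """Union detection mask (proportion > 0 in any query)."""
    stacked = pd.concat(list(queries), axis=1)
    return (stacked > 0).any(axis=1)


def taxa_recovery(
    reference: pd.Series,
    query_group: Sequence[pd.Series],
    tau: float,
    pooling: str = "any_mouse",
) -> tuple[int, int, float, float]:
    """(n_included, n_reference, n_recovered, recovery_pct) for one comparison.

    n_reference counts inclusion-set taxa detected in the reference;
    n_recovered counts those also detected in the query group under the
    pooling policy.  recovery_pct is NaN when n_reference is zero.
    """
    queries = _align(reference, list(query_group))
    included = inclusion_set([reference, *queries], tau)
    ref_detected = included[reference.loc[included] > 0]
    n_reference = len(ref_detected)
    if n_reference == 0:
        return len(included), 0, 0.0, float("nan")
    if pooling == "any_mouse":
        n_recovered = float(_detected(queries).loc[ref_detected].sum())
    elif pooling == "per_mouse_mean":
        per_mouse = [(q.loc[ref_detected] > 0).sum() for q in queries]
        n_recovered = float(np.mean(per_mouse))
    else:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    return len(included), n_reference, n_recovered, 100.0 * n_recovered / n_reference


def abundance_captured(
    reference: pd.Series,
    query_group: Sequence[pd.Series],
    pooling: str = "any_mouse",
) -> float:
    """Percent of the reference community's abundance held by recovered taxa.

    Uses *all* taxa present in the reference (no inclusion threshold).
    """
    queries = _align(reference, list(query_group))
    present = reference > 0
    if not present.any():
        raise ValueError("reference sample is empty")
    if pooling == "any_mouse":
        detected = _detected(queries)
        return float(100.0 * reference[present & detected].sum())
    if pooling == "per_mouse_mean":
        vals = [100.0 * reference[present & (q > 0)].sum() for q in queries]
        return float(np.mean(vals))
    raise ValueError(f"pooling must be one of {POOLINGS}")


def venn_partition(
    reference: pd.Series,
    query_group: Sequence[pd.Series],
    tau: float,
) -> tuple[int, int, int]:
    """(reference_only, shared, query_only) partition of the inclusion set.

    Detection on the query side is the union over the query group (a taxon
    is on the query side of the diagram if any mouse carries it).
    """
    queries = _align(reference, list(query_group))
    included = inclusion_set([reference, *queries], tau)
    ref = reference.loc[included] > 0
    qry = _detected(queries).loc[included]
    shared = int((ref & qry).sum())
    return int((ref & ~qry).sum()), shared, int((~ref & qry).sum())


def summarize_recovery(results: Iterable[RecoveryResult]) -> pd.DataFrame:
    """Per (comparison, pooling, rank) mean +/- SE across subjects.

    SE is the sample SD over subjects divided by sqrt(n); with a single
    subject the SE is NaN.  Undefined results (empty reference sets) are
    excluded.
    """
    rows = [r for r in results if not r.undefined]
    if not rows:
        raise ValueError("no defined recovery results to summarize")
    frame = pd.DataFrame(
        {
            "comparison": [r.comparison for r in rows],
            "pooling": [r.pooling for r in rows],
            "rank": [r.rank for r in rows],
            "recovery_pct": [r.recovery_pct for r in rows],
            "abundance_captured_pct": [r.abundance_captured_pct for r in rows],
        }
    )

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        rec, ab = g["recovery_pct"], g["abundance_captured_pct"]
        return pd.Series(
            {
                "mean_recovery_pct": rec.mean(),
                "se_recovery_pct": rec.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "mean_abundance_pct": ab.mean(),
                "se_abundance_pct": ab.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_subjects": n,
            }
        )

    out = (
        frame.groupby(["comparison", "pooling", "rank"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_subjects"] = out["n_subjects"].astype(int)
    return out


def donor_matching_distances(
    dm: DistanceMatrix, manifest: SampleManifest
) -> dict[str, np.ndarray]:
    """Mouse-to-human distances split into DONOR and OTHER groups.

    DONOR: each mouse against its own subject's S1/S2 samples; OTHER: each
    mouse against every other subject's S1/S2 samples.  Mice whose subject
    has no human sample in the matrix are skipped with a warning.
    """
    ids = set(dm.ids)
    donor: list[float] = []
    other: list[float] = []
    skipped: list[str] = []
    humans_by_subject = {
        s: [h for h in manifest.human_samples(s) if h in ids]
        for s in manifest.subjects()
    }
    for sample in manifest.sample_ids:
        row = manifest.row(sample)
        if row.role != "mouse" or sample not in ids:
            continue
        own = humans_by_subject.get(row.subject_id, [])
        if not own:
            skipped.append(sample)
            continue
        donor.extend(dm[sample, h] for h in own)
        for subject, humans in humans_by_subject.items():
            if subject == row.subject_id:
                continue
            other.extend(dm[sample, h] for h in humans)
    if skipped:
        warnings.warn(
            f"mice without a human sample skipped: {skipped[:5]}", stacklevel=2
        )
    return {"DONOR": np.asarray(donor), "OTHER": np.asarray(other)}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

COMPARISONS = ("S1_vs_S2", "S2_vs_mouse")


class EngraftmentRecovery:
    """Model for aliquot-reproducibility and engraftment-fidelity recovery.

    Parameters
    ----------
    table : CountTable
        Un-rarefied OTU counts for every sample in the manifest.
    taxonomy : TaxonomyMap
        Lineages used to aggregate counts to higher ranks.
    manifest : SampleManifest
        Study design: per subject, the S1/S2 aliquots and recipient mice.
    config : RecoveryConfig, optional
        Threshold, rank list, and default pooling policy.

    ``fit()`` evaluates both study comparisons (S1 vs S2; S2 vs mouse) for
    every subject and rank and returns a :class:`RecoveryResults`.
    """

    def __init__(
        self,
        table: CountTable,
        taxonomy: TaxonomyMap,
        manifest: SampleManifest,
        config: RecoveryConfig | None = None,
    ):
        manifest.validate_against(table)
        self.table = table
        self.taxonomy = taxonomy
        self.manifest = manifest
        self.config = config or RecoveryConfig()

    @classmethod
    def from_files(
        cls,
        table_path,
        taxonomy_path,
        manifest_path,
        config: RecoveryConfig | None = None,
    ) -> "EngraftmentRecovery":
        from . import io

        table = io.read_count_table(table_path)
        tax = io.read_taxonomy(taxonomy_path, features=table.feature_ids)
        manifest = io.read_manifest(manifest_path)
        return cls(table, tax, manifest, config)

    def fit(self, comparisons: Sequence[str] = COMPARISONS) -> "RecoveryResults":
        cfg = self.config
        results: list[RecoveryResult] = []
        for rank in cfg.ranks:
            agg = aggregate_by_rank(self.table, self.taxonomy, rank)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                props = relative_abundance(agg)
            for subject in self.manifest.subjects():
                s1 = self.manifest.samples_for(subject, "S1")
                s2 = self.manifest.samples_for(subject, "S2")
                mice = sorted(
                    self.manifest.samples_for(subject, "mouse"),
                    key=lambda s: self.manifest.row(s).replicate,
                )
                if "S1_vs_S2" in comparisons and s1 and s2:
                    results.append(
                        self._one(
                            subject, "S1_vs_S2", "single", rank,
                            props[s1[0]], [props[s2[0]]],
                        )
                    )
                if "S2_vs_mouse" in comparisons and s2 and mice:
                    queries = [props[m] for m in mice]
                    for pooling in POOLINGS:
                        results.append(
                            self._one(
                                subject, "S2_vs_mouse", pooling, rank,
                                props[s2[0]], queries,
                            )
                        )
        return RecoveryResults(self, results)

    def _one(self, subject, comparison, pooling, rank, reference, queries):
        pol = pooling if pooling in POOLINGS else "any_mouse"
        n_inc, n_ref, n_rec, pct = taxa_recovery(
            reference, queries, self.config.tau, pol
        )
        if n_ref == 0:
            return RecoveryResult(
                subject, comparison, pooling, rank,
                n_inc, 0, 0.0, float("nan"), float("nan"), (0, 0, n_inc),
            )
        captured = abundance_captured(reference, queries, pol)
        venn = venn_partition(reference, queries, self.config.tau)
        return RecoveryResult(
            subject, comparison, pooling, rank,
            n_inc, n_ref, n_rec, pct, captured, venn,
        )


class RecoveryResults:
    """Per-subject recovery estimates with per-rank mean +/- SE summaries."""

    def __init__(self, model: EngraftmentRecovery, results: list[RecoveryResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        """Long-format per-subject results, one row per statistic cell."""
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.results],
                "comparison": [r.comparison for r in self.results],
                "pooling": [r.pooling for r in self.results],
                "rank": [r.rank for r in self.results],
                "n_included": [r.n_included for r in self.results],
                "n_reference": [r.n_reference for r in self.results],
                "n_recovered": [r.n_recovered for r in self.results],
                "recovery_pct": [r.recovery_pct for r in self.results],
                "abundance_captured_pct": [
                    r.abundance_captured_pct for r in self.results
                ],
                "venn_reference_only": [r.venn[0] for r in self.results],
                "venn_shared": [r.venn[1] for r in self.results],
                "venn_query_only": [r.venn[2] for r in self.results],
            }
        )

    @property
    def summary_frame(self) -> pd.DataFrame:
        return summarize_recovery(self.results)

    def mean_recovery(
        self, comparison: str, rank: str, pooling: str | None = None
    ) -> float:
        """Across-subject mean recovery %, for one comparison and rank."""
        if pooling is None:
            pooling = (
                "single" if comparison == "S1_vs_S2" else self.model.config.pooling
            )
        sf = self.summary_frame
        sel = sf[
            (sf["comparison"] == comparison)
            & (sf["rank"] == rank)
            & (sf["pooling"] == pooling)
        ]
        if sel.empty:
            raise KeyError(f"no summary for {comparison}/{rank}/{pooling}")
        return float(sel["mean_recovery_pct"].iloc[0])

    def donor_matching(self, dm: DistanceMatrix) -> dict[str, np.ndarray]:
        """DONOR/OTHER mouse-to-human distance groups for a distance matrix."""
        return donor_matching_distances(dm, self.model.manifest)

    def summary(self) -> str:
        """Human-readable per-rank summary table (mean +/- SE, % scale)."""
        sf = self.summary_frame
        lines = [
            "Taxa recovery under the 0.1% inclusion rule"
            if np.isclose(self.model.config.tau, 0.001)
            else f"Taxa recovery under tau={self.model.config.tau:g}",
            "=" * 74,
            f"{'comparison':<14}{'pooling':<16}{'rank':<8}"
            f"{'recovery %':>16}{'abundance %':>16}{'n':>4}",
            "-" * 74,
        ]
        for row in sf.itertuples():
            se = "" if np.isnan(row.se_recovery_pct) else f" ± {row.se_recovery_pct:.1f}"
            sea = (
                ""
                if np.isnan(row.se_abundance_pct)
                else f" ± {row.se_abundance_pct:.1f}"
            )
            lines.append(
                f"{row.comparison:<14}{row.pooling:<16}{row.rank:<8}"
                f"{f'{row.mean_recovery_pct:.1f}{se}':>16}"
                f"{f'{row.mean_abundance_pct:.1f}{sea}':>16}"
                f"{row.n_subjects:>4}"
            )
        lines.append("=" * 74)
        return "\n".join(lines)
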