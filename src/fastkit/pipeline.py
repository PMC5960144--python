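"""End-to-end orchestration: recover -> betadiv -> report, seeded and logged.

The pipeline enforces the study's data-handling split: recovery statistics
are computed on un-rarefied counts, while diversity and distance analyses
use counts rarefied to a common depth.  Outputs are long-format TSVs (one
statistic per row) plus a JSON run log echoing versions, seeds and the
configuration.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .beta import METRICS, distance_matrix
from .community import AnalysisConfig, rarefy, shannon
from .inference import kruskal_wallis, linear_regression, permanova
from .io import (
    CountTable,
    SampleManifest,
    TaxonomyMap,
    read_count_table,
    read_manifest,
    read_metabolites,
    read_taxonomy,
    read_tree,
    write_distance_matrix,
)
from .recovery import (
    EngraftmentRecovery,
    RecoveryConfig,
    donor_matching_distances,
)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_from_paths"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    table_path: str
    taxonomy_path: str
    tree_path: str | None = None
    manifest_path: str | None = None
    metabolites_path: str | None = None
    outdir: str = "fastkit_out"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    recovery: RecoveryConfig = field(default_factory=RecoveryConfig)
    n_permutations: int = 999
    metrics: tuple[str, ...] = METRICS


def run_pipeline_from_paths(config: PipelineConfig) -> dict:
    table = read_count_table(config.table_path)
    taxonomy = read_taxonomy(config.taxonomy_path, features=table.feature_ids)
    tree = read_tree(config.tree_path) if config.tree_path else None
    if config.manifest_path is None:
        raise ValueError("pipeline needs a sample manifest")
    manifest = read_manifest(config.manifest_path)
    metabolites = (
        read_metabolites(config.metabolites_path)
        if config.metabolites_path
        else None
    )
    return run_pipeline(config, table, taxonomy, manifest, tree, metabolites)


def run_pipeline(
    config: PipelineConfig,
    table: CountTable,
    taxonomy: TaxonomyMap,
    manifest: SampleManifest,
    tree=None,
    metabolites: pd.DataFrame | None = None,
) -> dict:
    """Run recovery, distance and inference stages; write the report bundle.

    Returns a dict with the fitted :class:`RecoveryResults`, the distance
    matrices, the statistics table and the output paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "fastkit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.analysis.rng_seed,
        "stages": [],
        "config": {
            "analysis": asdict(config.analysis),
            "recovery": {
                "tau": config.recovery.tau,
                "ranks": list(config.recovery.ranks),
                "pooling": config.recovery.pooling,
            },
            "n_permutations": config.n_permutations,
        },
    }

    # --- recovery stage: un-rarefied counts -------------------------------
    model = EngraftmentRecovery(table, taxonomy, manifest, config.recovery)
    results = model.fit()
    results.frame.to_csv(outdir / "recovery_per_subject.tsv", sep="\t", index=False)
    results.summary_frame.to_csv(outdir / "recovery_summary.tsv", sep="\t", index=False)
    log["stages"].append({"stage": "recovery", "input": "un-rarefied counts"})

    # --- distance stage: rarefied counts ----------------------------------
    depth = config.analysis.rarefaction_depth
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rare = rarefy(table, depth, config.analysis.rng_seed)
    dropped = sorted(set(table.sample_ids) - set(rare.sample_ids))
    log["stages"].append(
        {
            "stage": "distances",
            "input": f"counts rarefied to {depth}",
            "dropped_samples": dropped,
        }
    )
    matrices = {}
    for metric in config.metrics:
        if metric.endswith("unifrac") and tree is None:
            continue
        dm = distance_matrix(rare, metric, tree=tree)
        matrices[metric] = dm
        write_distance_matrix(dm, outdir / f"distance_{metric}.tsv")

    # --- inference stage ---------------------------------------------------
    stat_rows: list[dict] = []
    seed = config.analysis.rng_seed
    rare_ids = set(rare.sample_ids)
    human = [
        s for s in manifest.sample_ids
        if manifest.row(s).role in ("S1", "S2") and s in rare_ids
    ]
    mice = [
        s for s in manifest.sample_ids
        if manifest.row(s).role == "mouse" and s in rare_ids
    ]
    for metric, dm in matrices.items():
        # aliquot reproducibility: S1 vs S2, permuted within subject
        if len({manifest.row(s).role for s in human}) == 2:
            sub = dm.filter(human)
            res = permanova(
                sub,
                [manifest.row(s).role for s in sub.ids],
                permutations=config.n_permutations,
                seed=seed,
                strata=[manifest.row(s).subject_id for s in sub.ids],
            )
            stat_rows.append(
                {
                    "analysis": "permanova_S1_vs_S2",
                    "metric": metric,
                    "statistic": "pseudo_F",
                    "value": res.pseudo_F,
                    "p_value": res.p_value,
                }
            )
        # donor individuality: mouse samples grouped by subject
        if len({manifest.row(s).subject_id for s in mice}) >= 2:
            sub = dm.filter(mice)
            res = permanova(
                sub,
                [manifest.row(s).subject_id for s in sub.ids],
                permutations=config.n_permutations,
                seed=seed,
            )
            stat_rows.append(
                {
                    "analysis": "permanova_mouse_by_donor",
                    "metric": metric,
                    "statistic": "pseudo_F",
                    "value": res.pseudo_F,
                    "p_value": res.p_value,
                }
            )
        # donor matching: DONOR vs OTHER distances
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = donor_matching_distances(dm, manifest)
        if len(groups["DONOR"]) and len(groups["OTHER"]):
            h, p = kruskal_wallis([groups["DONOR"], groups["OTHER"]])
            stat_rows.append(
                {
                    "analysis": "kruskal_donor_vs_other",
                    "metric": metric,
                    "statistic": "H",
                    "value": h,
                    "p_value": p,
                    "donor_median": float(np.median(groups["DONOR"])),
                    "other_median": float(np.median(groups["OTHER"])),
                }
            )

    # paired Wilcoxon on S1/S2 Shannon diversity (rarefied), reported as a
    # nonparametric substitute for a subject-random-effect model
    s1v, s2v = [], []
    for subject in manifest.subjects():
        s1 = [s for s in manifest.samples_for(subject, "S1") if s in rare_ids]
        s2 = [s for s in manifest.samples_for(subject, "S2") if s in rare_ids]
        if s1 and s2:
            s1v.append(shannon(rare.sample(s1[0])))
            s2v.append(shannon(rare.sample(s2[0])))
    if len(s1v) >= 2 and np.ptp(np.asarray(s1v) - np.asarray(s2v)) > 0:
        w = sps.wilcoxon(s1v, s2v)
        stat_rows.append(
            {
                "analysis": "wilcoxon_shannon_S1_vs_S2",
                "metric": "shannon",
                "statistic": "W",
                "value": float(w.statistic),
                "p_value": float(w.pvalue),
            }
        )

    regression = None
    if metabolites is not None and len(metabolites) >= 3:
        regression = linear_regression(metabolites["tmao"], metabolites["choline"])
        stat_rows.append(
            {
                "analysis": "regression_choline_on_tmao",
                "metric": "serum",
                "statistic": "slope",
                "value": regression.slope,
                "p_value": regression.p_value,
                "r_squared": regression.r_squared,
            }
        )
    stats_frame = pd.DataFrame(stat_rows)
    stats_frame.to_csv(outdir / "stats.tsv", sep="\t", index=False)
    log["stages"].append({"stage": "inference", "n_statistics": len(stat_rows)})
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)

    return {
        "recovery": results,
        "distance_matrices": matrices,
        "stats": stats_frame,
        "regression": regression,
        "outdir": outdir,
        "log": log,
    }
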