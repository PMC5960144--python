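"""Readers, writers and validated containers for the pipeline's file formats.

Everything downstream operates on five artifacts: an OTU count table
(features x samples, TSV), a taxonomy map (GreenGenes-style lineage
strings), a rooted phylogenetic tree (newick), a sample manifest describing
the straw-aliquot / gnotobiotic-mouse study design, and an optional serum
metabolite table.  Parsers are strict: malformed input fails loudly with
coordinates rather than propagating silently.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "OTU_RANK",
    "ROLES",
    "FormatError",
    "CountTable",
    "TaxonomyMap",
    "SampleManifest",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_manifest",
    "write_manifest",
    "read_metabolites",
    "write_metabolites",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: Ordered taxonomic ranks above the OTU level (GreenGenes vocabulary).
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Pseudo-rank meaning "the features themselves".
OTU_RANK = "OTU"

#: Valid manifest roles: the two straw aliquots and the recipient mice.
ROLES = ("S1", "S2", "mouse")

_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


class CountTable:
    """Non-negative integer feature x sample matrix with unique IDs.

    Parameters
    ----------
    data : pandas.DataFrame
        Features in rows, samples in columns, non-negative integer counts.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise FormatError("count table needs at least 1 feature and 1 sample")
        dup_f = data.index[data.index.duplicated()].unique().tolist()
        if dup_f:
            raise FormatError(f"duplicate feature IDs: {dup_f}")
        dup_s = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample IDs: {dup_s}")
        values = data.to_numpy()
        if values.dtype.kind not in "iu":
            bad = np.argwhere(~np.isfinite(values.astype(float)))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-finite count at feature {data.index[i]!r}, "
                    f"sample {data.columns[j]!r}"
                )
            rounded = np.rint(values.astype(float))
            if not np.allclose(values.astype(float), rounded):
                bad = np.argwhere(values.astype(float) != rounded)
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at feature {data.index[i]!r}, "
                    f"sample {data.columns[j]!r}: {values[i, j]!r}"
                )
            values = rounded.astype(np.int64)
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at feature {data.index[i]!r}, "
                f"sample {data.columns[j]!r}: {values[i, j]}"
            )
        self.data = pd.DataFrame(
            values.astype(np.int64),
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Counts vector for one sample, indexed by feature ID."""
        return self.data[sample_id]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)])

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.data.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} features x {self.shape[1]} samples)"


def read_count_table(path: str | Path, transpose: bool = False) -> CountTable:
    """Read a TSV count table (feature rows, sample columns, header of sample IDs).

    ``transpose=True`` accepts the samples-in-rows dialect.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise FormatError(f"duplicate sample IDs in header of {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = sample_ids
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing/NaN count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if transpose:
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------

_CONFIDENCE = re.compile(r"\(\d+(\.\d+)?\)")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Normalize one GreenGenes lineage string to 6 rank labels.

    Rank prefixes (``k__`` ...) and per-rank confidences are stripped,
    whitespace around separators is ignored, and empty labels are filled as
    ``unclassified_<deepest named ancestor>``.  A trailing species field is
    dropped (the rank vocabulary stops at genus).
    """
    cleaned = _CONFIDENCE.sub("", lineage).strip().rstrip(";")
    if not cleaned:
        raise FormatError(f"empty lineage string: {lineage!r}")
    parts = [p.strip() for p in cleaned.split(";")]
    labels = []
    for part in parts:
        for pref in _GG_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        labels.append(part.strip().replace(" ", "_"))
    if len(labels) == len(RANKS) + 1:  # species present; out of vocabulary
        labels = labels[: len(RANKS)]
    if len(labels) > len(RANKS):
        raise FormatError(
            f"lineage has {len(labels)} ranks (max {len(RANKS)}): {lineage!r}"
        )
    # pad missing deep ranks, then backfill empties
    labels += [""] * (len(RANKS) - len(labels))
    if not labels[0]:
        raise FormatError(f"lineage has no kingdom label: {lineage!r}")
    out: list[str] = []
    deepest = labels[0]
    for lab in labels:
        if lab:
            deepest = lab
            out.append(lab)
        else:
            out.append(f"unclassified_{deepest}")
    return tuple(out)


class TaxonomyMap:
    """feature_id -> 6-rank lineage (kingdom..genus), unclassified-normalized."""

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for feature, lineage in lineages.items():
            lineage = tuple(lineage)
            if len(lineage) != len(RANKS):
                raise FormatError(
                    f"feature {feature!r}: lineage must have {len(RANKS)} ranks"
                )
            if any(not lab for lab in lineage):
                raise FormatError(f"feature {feature!r}: empty rank label")
            self._lineages[str(feature)] = lineage

    @classmethod
    def from_lineage_strings(cls, raw: Mapping[str, str]) -> "TaxonomyMap":
        return cls({f: parse_lineage(s) for f, s in raw.items()})

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        try:
            return self._lineages[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} missing from taxonomy") from None

    def label(self, feature_id: str, rank: str) -> str:
        """Rank label for a feature; rank ``"OTU"`` returns the feature ID."""
        if rank == OTU_RANK:
            return feature_id
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; valid: {RANKS + (OTU_RANK,)}")
        return self.lineage(feature_id)[RANKS.index(rank)]

    def features(self) -> list[str]:
        return list(self._lineages)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyMap) and self._lineages == other._lineages


def read_taxonomy(
    path: str | Path, features: Iterable[str] | None = None
) -> TaxonomyMap:
    """Read a 2-column TSV (feature_id, GreenGenes lineage string), no header.

    If ``features`` (e.g. a companion CountTable's IDs) is given, taxonomy
    entries absent from it are retained with a warning.
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated columns")
            feature, lineage = fields[0].strip(), fields[1]
            if feature in raw:
                raise FormatError(f"{path}:{ln}: duplicate feature {feature!r}")
            raw[feature] = lineage
    tax = TaxonomyMap.from_lineage_strings(raw)
    if features is not None:
        extra = sorted(set(raw) - set(features))
        if extra:
            warnings.warn(
                f"{len(extra)} taxonomy features absent from companion table "
                f"(e.g. {extra[:3]}); retained",
                stacklevel=2,
            )
    return tax


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    prefixes = ("k__", "p__", "c__", "o__", "f__", "g__")
    with open(path, "w") as fh:
        for feature in tax.features():
            lineage = ";".join(
                p + lab for p, lab in zip(prefixes, tax.lineage(feature))
            )
            fh.write(f"{feature}\t{lineage}\n")


# ---------------------------------------------------------------------------
# PhyloTree (skbio.TreeNode with validation)
# ---------------------------------------------------------------------------


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check leaf-label uniqueness and branch lengths; fill missing lengths with 0."""
    tips = [t.name for t in tree.tips()]
    dups = sorted({t for t in tips if tips.count(t) > 1})
    if dups:
        raise FormatError(f"duplicate leaf labels in tree: {dups}")
    if any(t is None for t in tips):
        raise FormatError("tree has unlabeled leaves")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise FormatError(
                f"invalid branch length {node.length!r} at node {node.name!r}"
            )
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branches without length set to 0", stacklevel=2
        )
    return tree


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"unparseable newick in {path}: {exc}") from exc
    return validate_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# SampleManifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestRow:
    sample_id: str
    subject_id: str
    role: str
    replicate: int


class SampleManifest:
    """sample_id -> (subject, role, replicate) describing the study design.

    Each subject may have at most one S1 aliquot, at most one S2 aliquot
    (the mouse inoculum), and any number of recipient mice numbered 1..n.
    """

    def __init__(self, rows: Sequence[ManifestRow]):
        seen: dict[str, ManifestRow] = {}
        per_subject_role: dict[tuple[str, str], int] = {}
        for row in rows:
            if row.role not in ROLES:
                raise FormatError(
                    f"sample {row.sample_id!r}: unknown role {row.role!r}; "
                    f"valid roles: {list(ROLES)}"
                )
            if row.sample_id in seen:
                raise FormatError(f"duplicate sample ID {row.sample_id!r}")
            if row.replicate < 1:
                raise FormatError(
                    f"sample {row.sample_id!r}: replicate must be >= 1"
                )
            key = (row.subject_id, row.role)
            per_subject_role[key] = per_subject_role.get(key, 0) + 1
            if row.role in ("S1", "S2") and per_subject_role[key] > 1:
                raise FormatError(
                    f"subject {row.subject_id!r} has more than one {row.role} sample"
                )
            seen[row.sample_id] = row
        for subject in {r.subject_id for r in rows}:
            reps = sorted(
                r.replicate for r in rows
                if r.subject_id == subject and r.role == "mouse"
            )
            if reps and reps != list(range(1, len(reps) + 1)):
                raise FormatError(
                    f"subject {subject!r}: mouse replicates must be numbered "
                    f"1..n, got {reps}"
                )
        self._rows = dict(seen)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._rows)

    def subjects(self) -> list[str]:
        out: list[str] = []
        for row in self._rows.values():
            if row.subject_id not in out:
                out.append(row.subject_id)
        return out

    def row(self, sample_id: str) -> ManifestRow:
        return self._rows[sample_id]

    def samples_for(self, subject_id: str, role: str | None = None) -> list[str]:
        return [
            s for s, r in self._rows.items()
            if r.subject_id == subject_id and (role is None or r.role == role)
        ]

    def human_samples(self, subject_id: str) -> list[str]:
        """The subject's straw-aliquot (S1/S2) samples."""
        return [
            s for s, r in self._rows.items()
            if r.subject_id == subject_id and r.role in ("S1", "S2")
        ]

    def validate_against(self, table: CountTable) -> None:
        missing = sorted(set(self._rows) - set(table.sample_ids))
        if missing:
            raise FormatError(
                f"manifest samples absent from count table: {missing}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.subject_id, r.role, r.replicate)
                for r in self._rows.values()
            ],
            columns=["sample_id", "subject_id", "role", "replicate"],
        )

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleManifest) and self._rows == other._rows


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a TSV manifest with header sample_id, subject_id, role, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject_id", "role", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    rows = [
        ManifestRow(r.sample_id, r.subject_id, r.role, int(r.replicate))
        for r in df.itertuples()
    ]
    return SampleManifest(rows)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MetaboliteTable and distance matrices
# ---------------------------------------------------------------------------


def read_metabolites(path: str | Path) -> pd.DataFrame:
    """Read a TSV of serum metabolites: sample_id, tmao, choline (arbitrary units)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "tmao", "choline"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metabolite table {path} missing columns: {missing}")
    df = df.set_index("sample_id")[["tmao", "choline"]].astype(float)
    values = df.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        bad = np.argwhere(~(np.isfinite(values) & (values >= 0)))[0]
        raise ValueError(
            f"invalid metabolite value at sample {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return df


def write_metabolites(metabolites: pd.DataFrame, path: str | Path) -> None:
    metabolites.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(dm, path: str | Path) -> None:
    """Write a skbio DistanceMatrix as a square labeled TSV."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path: str | Path):
    from skbio.stats.distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.columns))
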