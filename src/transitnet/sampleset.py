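"""Profile tables, metadata, and trees: the shared data model.

A community profile is a vector of relative abundances over a shared
feature space (typically OTUs from closed-reference 16S picking).  This
module reads the canonical tab-separated table plus a per-sample
metadata table, normalizes raw counts to fractions, applies the
standard sequencing-depth / mapping-rate quality filter, and exposes
the in-memory containers the rest of the package works on.

Feature identifiers are opaque strings; no taxonomy parsing happens
here — copy-number correction and OTU picking belong to upstream
tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "SampleProfile",
    "SampleSet",
    "QcReport",
    "read_sample_set",
    "read_biom_json",
    "write_sample_set",
    "read_tree",
    "qc_filter",
]

MOCK_LABEL = "mock"

#: Default quality-control thresholds: minimum number of mapped
#: sequences per sample and minimum fraction of reads mapped to the
#: 16S reference.  Both are inclusive lower bounds.
MIN_COUNT = 500
MIN_MAP_RATE = 0.80

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SampleProfile:
    """One community as a normalized abundance vector.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    abundances : dict
        Mapping of feature id to relative abundance.  Zero-abundance
        features may be omitted; the stored values sum to 1.
    total_count : int
        Raw number of mapped sequences the fractions were derived from.
    map_rate : float or None
        Fraction of reads mapped to the reference, in [0, 1].  ``None``
        when the metadata does not provide it (treated as passing QC).
    """

    sample_id: str
    abundances: dict[str, float]
    total_count: int
    map_rate: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError(f"sample {self.sample_id!r}: negative abundance")
        total = sum(self.abundances.values())
        if not math.isclose(total, 1.0, abs_tol=_NORM_TOL):
            raise ValueError(
                f"sample {self.sample_id!r}: abundances sum to {total!r}, not 1"
            )

    def vector(self, feature_space: list[str]) -> np.ndarray:
        """Dense abundance vector in the order of *feature_space*."""
        return np.array([self.abundances.get(f, 0.0) for f in feature_space])


@dataclass
class SampleSet:
    """A collection of profiles over one feature space, with habitat labels.

    Every profile's features are a subset of ``feature_space`` and every
    sample carries a habitat label; the label ``"mock"`` marks control
    communities that downstream habitat analyses exclude.
    """

    profiles: dict[str, SampleProfile]
    habitat: dict[str, str]
    feature_space: list[str]

    def __post_init__(self) -> None:
        if len(set(self.feature_space)) != len(self.feature_space):
            raise ValueError("duplicate feature ids in feature_space")
        space = set(self.feature_space)
        for sid, prof in self.profiles.items():
            if sid not in self.habitat:
                raise ValueError(f"sample {sid!r} has no habitat label")
            extra = set(prof.abundances) - space
            if extra:
                raise ValueError(
                    f"sample {sid!r} uses features outside the feature space: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.profiles)

    @property
    def mock_ids(self) -> list[str]:
        return sorted(s for s, h in self.habitat.items() if h == MOCK_LABEL)

    def to_frame(self) -> pd.DataFrame:
        """Dense samples x features table of relative abundances."""
        mat = np.zeros((len(self.profiles), len(self.feature_space)))
        ids = self.sample_ids
        col = {f: j for j, f in enumerate(self.feature_space)}
        for i, sid in enumerate(ids):
            for f, v in self.profiles[sid].abundances.items():
                mat[i, col[f]] = v
        return pd.DataFrame(mat, index=ids, columns=self.feature_space)

    def subset(self, sample_ids) -> "SampleSet":
        ids = set(sample_ids)
        missing = ids - set(self.profiles)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return SampleSet(
            profiles={s: self.profiles[s] for s in ids},
            habitat={s: self.habitat[s] for s in ids},
            feature_space=list(self.feature_space),
        )

    def merge(self, other: "SampleSet") -> "SampleSet":
        """Union of two sets; feature spaces are unioned, ids must not clash."""
        clash = set(self.profiles) & set(other.profiles)
        if clash:
            raise ValueError(f"duplicate sample ids in merge: {sorted(clash)[:5]}")
        space = list(self.feature_space)
        seen = set(space)
        for f in other.feature_space:
            if f not in seen:
                space.append(f)
                seen.add(f)
        return SampleSet(
            profiles={**self.profiles, **other.profiles},
            habitat={**self.habitat, **other.habitat},
            feature_space=space,
        )


@dataclass
class QcReport:
    """Bookkeeping from :func:`qc_filter`."""

    n_input: int
    n_kept: int
    removed_low_count: list[str] = field(default_factory=list)
    removed_low_map_rate: list[str] = field(default_factory=list)
    missing_map_rate: list[str] = field(default_factory=list)


def _normalize_counts(counts: pd.Series, sample_id: str) -> dict[str, float]:
    total = counts.sum()
    if total <= 0:
        raise ValueError(
            f"sample {sample_id!r} has zero total count; relative abundance undefined"
        )
    frac = counts / total
    return {f: float(v) for f, v in frac.items() if v > 0}


def _read_table(table_path) -> pd.DataFrame:
    """Read a profile TSV as a samples x features count frame.

    Orientation is auto-detected: a first header cell of ``#SampleID``
    means samples are rows, ``#FeatureID`` means features are rows.
    Without either marker the table is assumed samples x features.
    """
    df = pd.read_csv(table_path, sep="\t", index_col=0, comment=None)
    marker = str(df.index.name or "")
    if marker.lstrip("#").lower() in ("featureid", "feature_id", "otu id", "otuid"):
        df = df.T
    bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in profile table")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    return df


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    meta.columns = [c.lstrip("#").lower() for c in meta.columns]
    if "sample_id" not in meta.columns or "habitat" not in meta.columns:
        raise ValueError("metadata must have columns sample_id and habitat")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    return meta.set_index("sample_id")


def _assemble(counts: pd.DataFrame, meta: pd.DataFrame) -> SampleSet:
    missing = sorted(set(counts.index) - set(meta.index))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    profiles: dict[str, SampleProfile] = {}
    for sid, row in counts.iterrows():
        sid = str(sid)
        def _meta_val(col):
            if col not in meta.columns:
                return None
            raw = meta.loc[sid, col]
            if raw is None or raw != raw or str(raw) == "":
                return None
            return float(raw)

        rate = _meta_val("map_rate")
        # tables of relative abundances lose the sequencing depth; an
        # explicit total_count metadata column restores it
        total = _meta_val("total_count")
        profiles[sid] = SampleProfile(
            sample_id=sid,
            abundances=_normalize_counts(row, sid),
            total_count=int(total) if total is not None else int(round(row.sum())),
            map_rate=rate,
        )
    habitat = {str(s): str(meta.loc[s, "habitat"]) for s in counts.index}
    return SampleSet(
        profiles=profiles,
        habitat=habitat,
        feature_space=[str(c) for c in counts.columns],
    )


def read_sample_set(table_path, metadata_path) -> SampleSet:
    """Read a profile table plus metadata into a :class:`SampleSet`.

    The table may be samples x features or features x samples (detected
    from the first header cell); entries are raw counts, normalized to
    relative abundance per sample.  Every sample in the table must
    appear in the metadata; the converse is not required.
    """
    return _assemble(_read_table(table_path), _read_metadata(metadata_path))


def read_biom_json(biom_path, metadata_path) -> SampleSet:
    """Alternate reader for BIOM 1.0 (JSON) feature tables.

    Same contract as :func:`read_sample_set`; BIOM stores features as
    rows, so the matrix is transposed into the canonical orientation.
    Sparse and dense matrix types are both handled.
    """
    with open(biom_path) as fh:
        doc = json.load(fh)
    feats = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(feats), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    counts = pd.DataFrame(mat.T, index=samples, columns=feats)
    if counts.index.duplicated().any():
        raise ValueError("duplicate sample ids in BIOM table")
    return _assemble(counts, _read_metadata(metadata_path))


def write_sample_set(sset: SampleSet, table_path, metadata_path=None) -> None:
    """Write the canonical samples x features TSV (12 significant digits)."""
    frame = sset.to_frame()
    frame.index.name = "#SampleID"
    frame.to_csv(table_path, sep="\t", float_format="%.12g")
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            fh.write("sample_id\thabitat\n")
            for sid in sset.sample_ids:
                fh.write(f"{sid}\t{sset.habitat[sid]}\n")


def read_tree(tree_path) -> TreeNode:
    """Read a rooted newick tree whose leaves are feature ids."""
    tree = TreeNode.read(str(tree_path))
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def qc_filter(
    sset: SampleSet,
    min_count: int = MIN_COUNT,
    min_map_rate: float = MIN_MAP_RATE,
    return_report: bool = False,
):
    """Keep samples with enough mapped sequences and mapping rate.

    Both thresholds are inclusive lower bounds.  A missing map rate
    passes (recorded in the report).  An empty result is legal.
    """
    report = QcReport(n_input=len(sset), n_kept=0)
    keep = []
    for sid in sset.sample_ids:
        prof = sset.profiles[sid]
        ok = True
        if prof.total_count < min_count:
            report.removed_low_count.append(sid)
            ok = False
        if prof.map_rate is None:
            report.missing_map_rate.append(sid)
        elif prof.map_rate < min_map_rate:
            report.removed_low_map_rate.append(sid)
            ok = False
        if ok:
            keep.append(sid)
    report.n_kept = len(keep)
    out = sset.subset(keep)
    return (out, report) if return_report else out
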