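"""Canonical data types and readers/writers for the toolkit.

The on-disk formats are the plain-text ones common in amplicon work: a
TSV count matrix (samples x features, or transposed with a flag), a
rooted newick phylogeny, a TSV metadata table with a declared covariate
schema, a labeled square TSV distance matrix, and a one-ID-per-line
bloom list.  Feature IDs may be exact 16S fragment sequences; those are
uppercased but otherwise left untouched because bloom filtering matches
on exact string equality.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "GeoCoords",
    "FormatError",
    "MISSING_TOKENS",
    "read_feature_table",
    "write_feature_table",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_bloom_list",
    "write_bloom_list",
    "read_geo",
]

#: Metadata tokens unified to missing on read (configurable per call).
MISSING_TOKENS = frozenset({"", "Unspecified", "not provided", "NA"})

_NUCLEOTIDE = frozenset("ACGTUN")


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


def _looks_like_sequence(s: str) -> bool:
    return len(s) >= 5 and set(s.upper()) <= _NUCLEOTIDE


def _canonical_feature_id(fid: str) -> str:
    # exact-sequence IDs are uppercased; opaque IDs pass through
    return fid.upper() if _looks_like_sequence(fid) else fid


@dataclass
class FeatureTable:
    """Integer count matrix, samples x features.

    ``data`` is a pandas DataFrame indexed by sample ID with feature IDs
    as columns.  Counts are nonnegative integers; IDs are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate feature IDs")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.any(values < 0):
            raise FormatError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError("non-integer counts")
        self.data = self.data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = pd.Index(
            [_canonical_feature_id(str(c)) for c in self.data.columns]
        )
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate feature IDs after sequence uppercasing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def feature_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def filter_samples(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)].copy())

    def filter_features(self, ids) -> "FeatureTable":
        return FeatureTable(self.data[list(ids)].copy())

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero-sum sample; cannot form relative abundances")
        return self.data.div(totals, axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Typed covariate table.

    ``schema`` maps column name -> kind ("categorical" | "ordinal" |
    "continuous").  Ordinal columns must carry an explicit level order in
    ``ordinal_levels``.  Missing values are represented as NaN/None.
    """

    data: pd.DataFrame
    schema: dict[str, str]
    ordinal_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs in metadata")
        for col, kind in self.schema.items():
            if kind not in ("categorical", "ordinal", "continuous"):
                raise FormatError(f"unknown covariate kind {kind!r} for {col!r}")
            if col not in self.data.columns:
                raise FormatError(f"schema column {col!r} absent from metadata")
            if kind == "ordinal" and col not in self.ordinal_levels:
                raise FormatError(f"ordinal covariate {col!r} lacks a level order")
            if kind == "continuous":
                coerced = pd.to_numeric(self.data[col], errors="coerce")
                bad = coerced.isna() & self.data[col].notna()
                if bad.any():
                    raise FormatError(
                        f"continuous covariate {col!r} has non-numeric values"
                    )
                self.data[col] = coerced
                if np.isinf(coerced.dropna()).any():
                    raise FormatError(f"continuous covariate {col!r} has inf")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def kind(self, column: str) -> str:
        return self.schema[column]

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def ordinal_rank(self, column: str) -> pd.Series:
        """Map an ordinal column to numeric ranks by its declared order."""
        levels = self.ordinal_levels[column]
        mapping = {lvl: i for i, lvl in enumerate(levels)}
        return self.data[column].map(mapping)

    def filter_samples(self, ids) -> "SampleMetadata":
        return SampleMetadata(
            self.data.loc[list(ids)].copy(), dict(self.schema),
            {k: list(v) for k, v in self.ordinal_levels.items()},
        )


@dataclass
class GeoCoords:
    """Per-sample latitude/longitude in decimal degrees."""

    data: pd.DataFrame  # columns: latitude, longitude

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs in coordinates")
        for col in ("latitude", "longitude"):
            if col not in self.data.columns:
                raise FormatError(f"coordinate column {col!r} missing")
        lat = self.data["latitude"].to_numpy(float)
        lon = self.data["longitude"].to_numpy(float)
        if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
            raise FormatError("non-finite coordinates")
        if np.any((lat < -90) | (lat > 90)):
            raise FormatError("latitude out of [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise FormatError("longitude out of [-180, 180]")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def latitude(self) -> np.ndarray:
        return self.data["latitude"].to_numpy(float)

    @property
    def longitude(self) -> np.ndarray:
        return self.data["longitude"].to_numpy(float)


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path, orientation: str = "samples") -> FeatureTable:
    """Read a TSV count matrix.

    orientation: "samples" if rows are samples, "features" if rows are
    features (the file is transposed into the canonical samples x
    features layout).
    """
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("duplicate IDs in feature table file")
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in feature table: {exc}") from exc
    if orientation == "features":
        numeric = numeric.T
    return FeatureTable(numeric)


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="#SampleID")


def read_newick(path, allow_missing_lengths: bool = False) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    Missing branch lengths are rejected unless ``allow_missing_lengths``
    is set, in which case they are zero-filled.
    """
    tree = skbio.read(str(path), format="newick", into=TreeNode)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if allow_missing_lengths:
                node.length = 0.0
            else:
                raise FormatError("tree has a missing branch length")
        elif node.length < 0:
            raise FormatError("negative branch length")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def parse_newick(newick: str, **kwargs) -> TreeNode:
    """Parse a newick string (convenience wrapper around read_newick)."""
    buf = _io.StringIO(newick)
    tree = skbio.read(buf, format="newick", into=TreeNode)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if kwargs.get("allow_missing_lengths"):
                node.length = 0.0
            else:
                raise FormatError("tree has a missing branch length")
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_metadata(
    path,
    schema: dict[str, str],
    ordinal_levels: dict[str, list[str]] | None = None,
    missing_tokens=MISSING_TOKENS,
) -> SampleMetadata:
    """Read a TSV metadata table; unify missing tokens; type per schema."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.map(lambda v: np.nan if v in missing_tokens else v)
    return SampleMetadata(df, schema, ordinal_levels or {})


def write_metadata(md: SampleMetadata, path) -> None:
    md.data.to_csv(path, sep="\t", index_label="#SampleID")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = np.ascontiguousarray(df.to_numpy(float))
    if np.any(~np.isfinite(arr)):
        raise FormatError("non-finite distance entries")
    return skbio.DistanceMatrix(arr, ids=[str(i) for i in df.index])


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    arr = np.asarray(dm.data)
    if np.any(~np.isfinite(arr)):
        raise ValueError("distance matrix has non-finite entries")
    pd.DataFrame(arr, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="#SampleID", float_format="%.17g"
    )


def read_bloom_list(path) -> frozenset[str]:
    """One bloom feature ID or exact sequence per line; blanks ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh]
    return frozenset(_canonical_feature_id(i) for i in ids if i)


def write_bloom_list(blooms, path) -> None:
    with open(path, "w") as fh:
        for b in sorted(blooms):
            fh.write(f"{b}\n")


def read_geo(path) -> GeoCoords:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeoCoords(df[["latitude", "longitude"]].astype(float))
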