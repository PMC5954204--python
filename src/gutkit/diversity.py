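"""Alpha and beta diversity, ordination, and Procrustes fit.

Alpha metrics (Shannon in bits, observed features, Faith's phylogenetic
diversity) are reported as the mean over independent rarefactions of the
count table, which stabilises them against uneven sequencing depth.
Beta metrics are unweighted/weighted UniFrac and Bray-Curtis; ordination
is classical PCoA.  UniFrac and Faith's PD are delegated to scikit-bio;
the surrounding rarefaction averaging, the distance-matrix assembly, and
the Procrustes residual are handled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .bloom import rarefy
from .io import FeatureTable

__all__ = [
    "AlphaVector",
    "alpha_diversity",
    "shannon",
    "observed_features",
    "faith_pd",
    "unweighted_unifrac",
    "weighted_unifrac",
    "bray_curtis",
    "pcoa",
    "procrustes_m2",
]

ALPHA_METRICS = ("shannon", "observed", "faith_pd")


@dataclass
class AlphaVector:
    """Per-sample alpha-diversity values for one metric.

    Units: bits for Shannon (base 2), feature count for observed,
    branch-length units for Faith's PD.
    """

    metric: str
    values: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy in bits of one sample's count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def observed_features(counts: np.ndarray) -> int:
    return int(np.count_nonzero(counts))


def faith_pd(presence, tree: TreeNode) -> float:
    """Total branch length of the union of root-to-leaf paths.

    ``presence`` is an iterable of leaf names present in the sample.
    The root's own branch (if any) is included once any leaf is present.
    """
    present = list(presence)
    leaves = {t.name for t in tree.tips()}
    unknown = set(present) - leaves
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)[:5]}")
    if not present:
        return 0.0
    counts = np.ones(len(present))
    pd_val = float(_skbio_faith_pd(counts, present, tree))
    # skbio excludes the root's own stem; include it per our convention
    return pd_val + (tree.length or 0.0)


def _metric_value(metric, counts, feature_ids, tree):
    if metric == "shannon":
        return shannon(counts)
    if metric == "observed":
        return float(observed_features(counts))
    if metric == "faith_pd":
        present = [f for f, c in zip(feature_ids, counts) if c > 0]
        return faith_pd(present, tree)
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_diversity(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    depth: int | None = None,
    n_rarefactions: int = 10,
    seed: int | None = None,
) -> AlphaVector:
    """Alpha diversity, mean over ``n_rarefactions`` rarefactions.

    With ``depth=None`` no rarefaction is performed and the metric is
    computed once on the raw counts.  Faith's PD requires ``tree``.
    """
    if metric == "faith_pd" and tree is None:
        raise ValueError("faith_pd requires a phylogeny")
    if depth is None:
        vals = {
            s: _metric_value(metric, table.data.loc[s].to_numpy(),
                             table.feature_ids, tree)
            for s in table.sample_ids
        }
        return AlphaVector(metric, pd.Series(vals, name=metric))
    rng = np.random.default_rng(seed)
    acc: dict[str, list[float]] = {}
    for _ in range(n_rarefactions):
        sub, _report = rarefy(table, depth, seed=int(rng.integers(2**31)))
        for s in sub.sample_ids:
            acc.setdefault(s, []).append(
                _metric_value(metric, sub.data.loc[s].to_numpy(),
                              sub.feature_ids, tree)
            )
    means = {s: float(np.mean(v)) for s, v in acc.items()}
    return AlphaVector(metric, pd.Series(means, name=metric))


def _check_tree_coverage(table: FeatureTable, tree: TreeNode) -> None:
    leaves = {t.name for t in tree.tips()}
    nonzero = set(
        np.asarray(table.feature_ids)[np.asarray(table.counts).sum(axis=0) > 0]
    )
    missing = nonzero - leaves
    if missing:
        raise ValueError(f"features absent from tree: {sorted(missing)[:5]}")


def unweighted_unifrac(table: FeatureTable, tree: TreeNode) -> skbio.DistanceMatrix:
    """Unweighted UniFrac: unique branch length / union branch length."""
    _check_tree_coverage(table, tree)
    return _skbio_beta(
        "unweighted_unifrac", table.counts, ids=table.sample_ids,
        taxa=table.feature_ids, tree=tree,
    )


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = False
) -> skbio.DistanceMatrix:
    """Weighted UniFrac: sum of branch length x |proportion difference|.

    The normalized variant divides by the maximum attainable value so
    d is in [0, 1].
    """
    _check_tree_coverage(table, tree)
    if (table.sample_sums() == 0).any():
        raise ValueError("zero-sum sample; weighted UniFrac undefined")
    return _skbio_beta(
        "weighted_unifrac", table.counts, ids=table.sample_ids,
        taxa=table.feature_ids, tree=tree, normalized=normalized,
    )


def bray_curtis(table: FeatureTable) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min) / (sum_x + sum_y)."""
    if (table.sample_sums() == 0).any():
        raise ValueError("zero-sum sample; Bray-Curtis undefined")
    condensed = pdist(table.counts.astype(float), metric="braycurtis")
    return skbio.DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def pcoa(dm: skbio.DistanceMatrix) -> OrdinationResults:
    """Classical scaling (PCoA) on the double-centered -D^2/2 matrix.

    Negative eigenvalues are retained in the eigenvalue list; axes are
    sorted by eigenvalue.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*all dimensions will be computed.*"
        )
        return _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)


def procrustes_m2(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """Least-squares Procrustes residual M^2 between two configurations.

    Rows are matched samples; the smaller-dimensional configuration is
    zero-padded.  After optimal translation, scaling and
    rotation/reflection, M^2 = 1 - (fit sum of squares ratio), 0 for a
    perfect fit, near 1 for unrelated configurations.
    """
    a = np.asarray(config_a, dtype=float)
    b = np.asarray(config_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must have matching sample sets")
    d = max(a.shape[1], b.shape[1])
    if a.shape[1] < d:
        a = np.hstack([a, np.zeros((a.shape[0], d - a.shape[1]))])
    if b.shape[1] < d:
        b = np.hstack([b, np.zeros((b.shape[0], d - b.shape[1]))])
    _, _, m2 = _scipy_procrustes(a, b)
    return float(m2)
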