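"""Bloom removal and rarefaction.

A handful of taxa (notably an *E. coli* sequence variant) grow during
room-temperature transit of self-collected stool swabs, inflating their
read fractions.  The remedy is blunt and deliberate: drop the offending
exact sequence variants from every sample — including imported
meta-analysis samples — *before* rarefying, and carry the per-sample
bloom read fraction forward as a covariate so its residual influence can
be assessed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats import subsample_counts

from .io import FeatureTable

__all__ = ["bloom_fraction", "remove_blooms", "rarefy", "RarefactionReport"]

#: Default rarefaction depth (sequences per sample).
DEFAULT_DEPTH = 1250


def bloom_fraction(table: FeatureTable, blooms) -> pd.Series:
    """Per-sample fraction of reads recruiting to bloom features.

    Samples with zero total reads get NaN.  Bloom IDs absent from the
    table contribute nothing (exact string matching only).
    """
    if table.shape[0] == 0:
        raise ValueError("empty feature table")
    bloom_cols = [f for f in table.feature_ids if f in set(blooms)]
    totals = table.sample_sums().astype(float)
    bloom_reads = (
        table.data[bloom_cols].sum(axis=1).astype(float)
        if bloom_cols
        else pd.Series(0.0, index=table.data.index)
    )
    frac = bloom_reads / totals.replace(0, np.nan)
    frac.name = "bloom_fraction"
    return frac


def remove_blooms(table: FeatureTable, blooms) -> FeatureTable:
    """Drop bloom feature columns entirely; all other counts untouched.

    Idempotent; applied uniformly to every sample.
    """
    bset = set(blooms)
    keep = [f for f in table.feature_ids if f not in bset]
    return FeatureTable(table.data[keep].copy())


@dataclass
class RarefactionReport:
    """Samples dropped for falling below the rarefaction depth."""

    depth: int
    dropped: list[str]
    retained: list[str]


def rarefy(
    table: FeatureTable, depth: int = DEFAULT_DEPTH, seed: int | None = None
) -> tuple[FeatureTable, RarefactionReport]:
    """Subsample each sample to ``depth`` reads without replacement.

    Hypergeometric subsampling: every retained row sums to exactly
    ``depth`` and no count exceeds its original value.  Samples with
    fewer than ``depth`` total reads are dropped and listed in the
    report.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    retained = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    rows = []
    for s in retained:
        counts = table.data.loc[s].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(
                subsample_counts(counts, depth, replace=False,
                                 seed=rng.integers(2**31))
            )
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64) if rows else
        np.empty((0, table.shape[1]), dtype=np.int64),
        index=retained, columns=table.feature_ids,
    )
    return FeatureTable(data), RarefactionReport(depth, dropped, retained)
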