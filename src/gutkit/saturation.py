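"""Collector's (saturation) curves.

Three resampling curves describe how much of a cohort's diversity has
been captured: the count of rare sOTUs (within cumulative read-count
thresholds) over increasing numbers of sampled samples, the minimum
observed beta-diversity distance over increasing subset sizes, and the
within-individual divergence over month lags with a between-subject
baseline.  Subsampling is independent per subset size (not nested), 10
replicates per size by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .io import FeatureTable, SampleMetadata

__all__ = [
    "sotu_novelty_curve",
    "beta_added_curve",
    "within_individual_curve",
]

MONTH_DAYS = 30  # deterministic month bin width, days


def sotu_novelty_curve(
    table: FeatureTable,
    n_grid,
    reps: int = 10,
    max_threshold: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rare-feature counts over random sample subsets.

    For each subset size n (``reps`` independent draws without
    replacement) and each threshold t = 1..``max_threshold``, counts the
    features whose total reads in the subset are between 1 and t
    inclusive — t = 1 counts singletons, t = 2 singletons plus
    doubletons, and so on (cumulative).  Tidy frame with columns
    n, replicate, threshold, count.
    """
    n_samples = table.shape[0]
    counts = table.counts
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n > n_samples:
            raise ValueError(f"subset size {n} exceeds {n_samples} samples")
        for rep in range(reps):
            idx = rng.choice(n_samples, size=n, replace=False)
            totals = counts[idx].sum(axis=0)
            for t in range(1, max_threshold + 1):
                c = int(((totals >= 1) & (totals <= t)).sum())
                rows.append((n, rep, t, c))
    return pd.DataFrame(rows, columns=["n", "replicate", "threshold", "count"])


def beta_added_curve(
    dm: skbio.DistanceMatrix, n_grid, reps: int = 10, seed: int | None = None
) -> pd.DataFrame:
    """Minimum observed distance over random sample subsets.

    For each subset size n >= 2 and replicate, the minimum off-diagonal
    distance among the sampled subset.  Tidy frame with columns
    n, replicate, min_distance.
    """
    ids = list(dm.ids)
    arr = dm.data
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        if n < 2:
            raise ValueError("subset size must be >= 2")
        if n > len(ids):
            raise ValueError(f"subset size {n} exceeds {len(ids)} samples")
        for rep in range(reps):
            idx = rng.choice(len(ids), size=n, replace=False)
            sub = arr[np.ix_(idx, idx)]
            iu = np.triu_indices(n, k=1)
            rows.append((n, rep, float(sub[iu].min())))
    return pd.DataFrame(rows, columns=["n", "replicate", "min_distance"])


@dataclass
class WithinIndividualResult:
    """Month-lag-binned within-subject distances plus the baseline."""

    within: pd.DataFrame  # columns: subject, month_lag, distance
    between_subject: np.ndarray  # all cross-subject pairwise distances


def within_individual_curve(
    dm: skbio.DistanceMatrix,
    md: SampleMetadata,
    subject_col: str = "subject",
    date_col: str = "collection_day",
) -> WithinIndividualResult:
    """Within-subject divergence binned by 30-day month lag.

    Every within-subject sample pair is assigned to the bin
    floor(lag_days / 30); per (subject, bin) only one representative
    pair is kept — the one whose first sample is earliest, ties broken
    by sample ID — so longitudinally dense subjects do not dominate a
    bin.  The between-subject baseline (BSD) is the distribution of all
    cross-subject pairwise distances.
    """
    df = md.data[[subject_col, date_col]].dropna()
    df = df[df.index.isin(dm.ids)]
    subjects = df[subject_col]
    days = pd.to_numeric(df[date_col])

    chosen: dict[tuple, tuple] = {}
    for subj in subjects.unique():
        sids = sorted(
            subjects.index[subjects == subj],
            key=lambda s: (days[s], s),
        )
        for i, a in enumerate(sids):
            for b in sids[i + 1:]:
                lag = abs(days[b] - days[a])
                bin_ = int(lag // MONTH_DAYS)
                key = (subj, bin_)
                cand = (days[a], a, b)
                if key not in chosen or cand < chosen[key]:
                    chosen[key] = cand
    rows = [
        (subj, bin_, float(dm[a, b]))
        for (subj, bin_), (_, a, b) in sorted(chosen.items())
    ]
    within = pd.DataFrame(rows, columns=["subject", "month_lag", "distance"])

    sid_list = list(df.index)
    subj_arr = subjects.loc[sid_list].to_numpy()
    idx = [list(dm.ids).index(s) for s in sid_list]
    arr = dm.data[np.ix_(idx, idx)]
    iu = np.triu_indices(len(sid_list), k=1)
    cross = subj_arr[iu[0]] != subj_arr[iu[1]]
    between = arr[iu][cross]
    return WithinIndividualResult(within, between)
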