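"""Permutation group tests on distance matrices and count tables.

PERMANOVA is delegated to scikit-bio; PERMDISP is implemented here so
per-sample centroid distances and each group's maximum centroid
distance can be reported alongside the permutation p-value.  The
per-individual state-change resampling wrapper controls for repeated
measures by drawing one sample per (subject, condition) per trial.  The
matched-control selector and the permuted mean-difference test with
discrete FDR support case/control differential-abundance analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from skbio.stats.distance import permanova as _skbio_permanova

from .io import FeatureTable, SampleMetadata
from .diversity import pcoa

__all__ = [
    "PermutationResult",
    "permanova",
    "permdisp",
    "state_change_resampling",
    "match_controls",
    "permuted_mean_difference",
]


@dataclass
class PermutationResult:
    statistic_name: str
    statistic: float
    permutations: int
    p_value: float
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def permanova(
    dm: skbio.DistanceMatrix,
    labels,
    permutations: int = 999,
    seed: int | None = None,
) -> PermutationResult:
    """PERMANOVA pseudo-F with a label-permutation p (+1 correction)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    if not dm.data.flags.c_contiguous:
        dm = skbio.DistanceMatrix(np.ascontiguousarray(dm.data), ids=dm.ids)
    res = _skbio_permanova(dm, labels, permutations=permutations, seed=seed)
    return PermutationResult(
        "pseudo-F", float(res["test statistic"]), permutations,
        float(res["p-value"]), seed,
    )


def _geometric_median(pts: np.ndarray, max_iter: int = 200, tol: float = 1e-9):
    """Weiszfeld iteration for the spatial median of a point cloud."""
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        if np.any(d < 1e-12):
            return y
        w = 1.0 / d
        y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def permdisp(
    dm: skbio.DistanceMatrix,
    labels,
    permutations: int = 999,
    centroid: str = "median",
    seed: int | None = None,
) -> PermutationResult:
    """Homogeneity-of-dispersion test (PERMDISP).

    Samples are embedded by PCoA; each sample's distance to its group
    centroid (spatial median by default, mean optional) is computed
    once, then a one-way ANOVA F on those distances is compared against
    a label-permutation null.  Reported extras: per-sample centroid
    distances, per-group mean and max centroid distance.  Singleton
    groups are excluded from the F with a warning note in extras.
    """
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    ord_res = pcoa(dm)
    coords = ord_res.samples.to_numpy()
    # drop imaginary axes (negative eigenvalues give zero-filled columns)
    dists = pd.Series(0.0, index=labels.index)
    for lvl in labels.unique():
        idx = labels.index[labels == lvl]
        pts = coords[[list(dm.ids).index(i) for i in idx]]
        if centroid == "median":
            c = _geometric_median(pts)
        elif centroid == "mean":
            c = pts.mean(axis=0)
        else:
            raise ValueError("centroid must be 'median' or 'mean'")
        dists[idx] = np.linalg.norm(pts - c, axis=1)

    counts = labels.value_counts()
    usable = counts.index[counts >= 2]
    excluded = [str(g) for g in counts.index if g not in set(usable)]
    if len(usable) < 2:
        raise ValueError("PERMDISP needs >= 2 groups with >= 2 samples")
    mask = labels.isin(usable).to_numpy()
    d_use = dists.to_numpy()[mask]
    l_use = labels.to_numpy()[mask]

    def anova_f(lab):
        groups = [d_use[lab == g] for g in np.unique(lab)]
        return stats.f_oneway(*groups).statistic

    f_obs = float(anova_f(l_use))
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(permutations):
        f_perm = anova_f(rng.permutation(l_use))
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + permutations)
    per_group = {
        str(g): {
            "mean_centroid_distance": float(dists[labels == g].mean()),
            "max_centroid_distance": float(dists[labels == g].max()),
        }
        for g in labels.unique()
    }
    return PermutationResult(
        "dispersion F", f_obs, permutations, float(p), seed,
        extras={
            "centroid_distances": dists,
            "per_group": per_group,
            "excluded_singletons": excluded,
        },
    )


def state_change_resampling(
    dm: skbio.DistanceMatrix,
    md: SampleMetadata,
    subject_col: str = "subject",
    condition_col: str = "condition",
    trials: int = 100,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Repeated one-sample-per-subject-per-condition PERMANOVA.

    Each trial draws one sample per (subject, condition), runs PERMANOVA
    on the reduced matrix, and records the p-value; the summary is the
    fraction of trials with p < 0.05.  Subjects missing a condition are
    skipped for that condition (logged).
    """
    rng = np.random.default_rng(seed)
    df = md.data[[subject_col, condition_col]].dropna()
    df = df[df.index.isin(dm.ids)]
    conditions = df[condition_col].unique()
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    by_pair: dict[tuple, list[str]] = {}
    for sid, row in df.iterrows():
        by_pair.setdefault((row[subject_col], row[condition_col]), []).append(sid)
    skipped = sorted(
        {
            str(subj)
            for subj in df[subject_col].unique()
            for cond in conditions
            if (subj, cond) not in by_pair
        }
    )
    import zlib

    base = int(rng.integers(2**31))
    pvals = []
    for _ in range(trials):
        chosen, labels = [], []
        for (subj, cond), sids in sorted(by_pair.items()):
            pick = sids[rng.integers(len(sids))]
            chosen.append(pick)
            labels.append(cond)
        sub = dm.filter(chosen)
        # the permutation seed is a function of the drawn subset, so
        # identical draws (e.g. one sample per cell) give identical p
        trial_seed = (base ^ zlib.crc32("|".join(chosen).encode())) % 2**31
        res = permanova(
            sub, np.asarray(labels), permutations=permutations,
            seed=trial_seed,
        )
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    return {
        "p_values": pvals,
        "fraction_significant": float((pvals < 0.05).mean()),
        "trials": trials,
        "skipped_subject_conditions": skipped,
    }


def match_controls(
    md: SampleMetadata,
    cases,
    control_pool=None,
    exact: tuple[str, ...] = (),
    tolerance: dict[str, float] | None = None,
) -> dict[str, str | None]:
    """Greedy 1:1 matched-control selection without replacement.

    ``exact`` columns must match exactly (missing matches only missing);
    ``tolerance`` maps numeric columns to allowed absolute differences
    (e.g. age within 5 years).  Cases are processed in input order; each
    takes the nearest eligible control by summed normalised numeric
    distance.  Unmatched cases map to None.
    """
    tolerance = tolerance or {}
    cases = list(cases)
    if control_pool is None:
        control_pool = [s for s in md.sample_ids if s not in set(cases)]
    control_pool = list(control_pool)
    if set(cases) & set(control_pool):
        raise ValueError("control pool overlaps cases")
    if not control_pool:
        raise ValueError("empty control pool")
    df = md.data
    available = set(control_pool)
    matches: dict[str, str | None] = {}
    for case in cases:
        best, best_score = None, np.inf
        for ctrl in control_pool:
            if ctrl not in available:
                continue
            ok = True
            for col in exact:
                a, b = df.at[case, col], df.at[ctrl, col]
                if (pd.isna(a) != pd.isna(b)) or (
                    not pd.isna(a) and a != b
                ):
                    ok = False
                    break
            if not ok:
                continue
            score = 0.0
            for col, tol in tolerance.items():
                a = pd.to_numeric(pd.Series([df.at[case, col]]),
                                  errors="coerce").iloc[0]
                b = pd.to_numeric(pd.Series([df.at[ctrl, col]]),
                                  errors="coerce").iloc[0]
                if pd.isna(a) or pd.isna(b) or abs(a - b) > tol:
                    ok = False
                    break
                score += abs(a - b) / tol
            if ok and score < best_score:
                best, best_score = ctrl, score
        matches[case] = best
        if best is not None:
            available.discard(best)
    return matches


def permuted_mean_difference(
    table: FeatureTable,
    labels,
    permutations: int = 10000,
    alpha: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permuted mean-difference test with discrete FDR control.

    Per feature, the observed statistic is the difference of group mean
    relative abundances.  The two-sided p comes from a label-permutation
    null.  The rejection set is a discrete Benjamini-Hochberg step-up on
    the permutation p-values, where features whose attainable p-value
    support cannot reach the working threshold (constant features, whose
    only attainable p is 1) are excluded from the effective number of
    tests.  Constant features get p = 1 by convention.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(seed)
    X = table.relative_abundance().to_numpy()
    g1 = y == classes[1]
    n1, n0 = int(g1.sum()), int((~g1).sum())
    obs = X[g1].mean(axis=0) - X[~g1].mean(axis=0)

    n = len(y)
    null = np.empty((permutations, X.shape[1]))
    col_total = X.sum(axis=0)
    batch = max(1, int(2e7) // max(n * X.shape[1], 1))
    done = 0
    while done < permutations:
        b = min(batch, permutations - done)
        # indicator matrix of permuted group-1 memberships, BLAS-friendly
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        G = np.zeros((b, n))
        G[np.repeat(np.arange(b), n1), idx.ravel()] = 1.0
        s1 = G @ X
        null[done:done + b] = s1 / n1 - (col_total[None, :] - s1) / n0
        done += b

    abs_obs = np.abs(obs)
    abs_null = np.abs(null)
    p = (1 + (abs_null >= abs_obs[None, :]).sum(axis=0)) / (1 + permutations)
    constant = table.counts.std(axis=0) == 0
    p[constant] = 1.0

    # discrete step-up: constant features have a degenerate p-value
    # support ({1}) and are excluded from the effective test count
    testable = ~constant
    m_eff = int(testable.sum())
    reject = np.zeros(X.shape[1], dtype=bool)
    if m_eff:
        idx = np.where(testable)[0]
        order = idx[np.argsort(p[idx])]
        sorted_p = p[order]
        thresh = alpha * np.arange(1, m_eff + 1) / m_eff
        passing = np.where(sorted_p <= thresh)[0]
        if passing.size:
            reject[order[: passing[-1] + 1]] = True
    return pd.DataFrame(
        {
            "mean_difference": obs,
            "p_value": p,
            "reject": reject,
        },
        index=table.feature_ids,
    )
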