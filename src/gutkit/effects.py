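"""Covariate curation, cross-correlation, and the effect-size ledger.

Self-reported survey covariates need gating before any of them can be
trusted: implausible heights/weights are blanked, ages contradicted by
other answers are blanked, sparse ordinal extremes are merged, and
under-populated groups are dropped.  Redundant covariates are then
collapsed by clustering their pairwise associations.  Finally, for each
surviving covariate an effect-size record is computed on an alpha- or
beta-diversity response under mixed-directional FDR (mdFDR) control:
stage 1 selects covariates by Benjamini-Hochberg on their global test
p-values at level alpha; stage 2 runs all pairwise comparisons within
the selected covariates with BH at level (R/m) * alpha, taking the
direction from the sign of the mean difference; each significant pair
gets a Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import SampleMetadata
from .group_tests import permanova

__all__ = [
    "CurationRules",
    "curate_metadata",
    "collapse_and_gate_groups",
    "covariate_association",
    "association_matrix",
    "cluster_covariates",
    "quartile_bin",
    "cohens_d",
    "EffectSizeRecord",
    "pairwise_effect_sizes",
    "bh_adjust",
]


@dataclass
class CurationRules:
    """Plausibility gates for self-reported anthropometrics.

    Heights outside [48, 210] cm and weights outside [2.5, 200] kg are
    treated as misreported.  An age under ``child_age`` years is treated
    as misreported when contradicted by height over 105 cm, weight over
    20 kg, or any reported alcohol consumption, or when the birthdate
    postdates sample collection.
    """

    height_bounds_cm: tuple[float, float] = (48.0, 210.0)
    weight_bounds_kg: tuple[float, float] = (2.5, 200.0)
    child_age: float = 4.0
    child_height_cm: float = 105.0
    child_weight_kg: float = 20.0

    def __post_init__(self) -> None:
        for lo, hi in (self.height_bounds_cm, self.weight_bounds_kg):
            if lo >= hi:
                raise ValueError("lower bound must be below upper bound")


def curate_metadata(
    md: SampleMetadata, rules: CurationRules | None = None
) -> SampleMetadata:
    """Apply plausibility gates; invalidated values become missing.

    Recognised columns (all optional): ``height_cm``, ``weight_kg``,
    ``bmi``, ``age_years``, ``alcohol`` (categorical; any value other
    than "No"/missing counts as consumption), ``birth_year`` and
    ``collection_year``.  BMI is recomputed from in-bound height/weight
    pairs and blanked otherwise.  Nothing is imputed.
    """
    rules = rules or CurationRules()
    out = md.data.copy()
    h_lo, h_hi = rules.height_bounds_cm
    w_lo, w_hi = rules.weight_bounds_kg

    if "height_cm" in out:
        h = pd.to_numeric(out["height_cm"], errors="coerce")
        h[(h < h_lo) | (h > h_hi)] = np.nan
        out["height_cm"] = h
    if "weight_kg" in out:
        w = pd.to_numeric(out["weight_kg"], errors="coerce")
        w[(w < w_lo) | (w > w_hi)] = np.nan
        out["weight_kg"] = w
    if "bmi" in out and "height_cm" in out and "weight_kg" in out:
        h = out["height_cm"]
        w = out["weight_kg"]
        ok = h.notna() & w.notna()
        bmi = pd.Series(np.nan, index=out.index, dtype=float)
        bmi[ok] = w[ok] / (h[ok] / 100.0) ** 2
        out["bmi"] = bmi
    if "age_years" in out:
        age = pd.to_numeric(out["age_years"], errors="coerce")
        bad = pd.Series(False, index=out.index)
        if "birth_year" in out and "collection_year" in out:
            by = pd.to_numeric(out["birth_year"], errors="coerce")
            cy = pd.to_numeric(out["collection_year"], errors="coerce")
            bad |= (by > cy).fillna(False)
        child = age < rules.child_age
        if "height_cm" in md.data:
            raw_h = pd.to_numeric(md.data["height_cm"], errors="coerce")
            bad |= (child & (raw_h > rules.child_height_cm)).fillna(False)
        if "weight_kg" in md.data:
            raw_w = pd.to_numeric(md.data["weight_kg"], errors="coerce")
            bad |= (child & (raw_w > rules.child_weight_kg)).fillna(False)
        if "alcohol" in out:
            drinks = out["alcohol"].notna() & (out["alcohol"] != "No")
            bad |= (child & drinks).fillna(False)
        age[bad] = np.nan
        out["age_years"] = age
    return SampleMetadata(
        out, dict(md.schema),
        {k: list(v) for k, v in md.ordinal_levels.items()},
    )


def collapse_and_gate_groups(
    md: SampleMetadata,
    covariate: str,
    min_total: int = 25,
    min_group: int = 50,
    min_frac: float = 0.03,
) -> pd.Series | None:
    """Merge sparse ordinal extremes, then gate group sizes.

    Ordinal extremes with fewer than ``min_total`` observations are
    merged into their adjacent level (labels joined with "|").  Groups
    with fewer than ``min_group`` observations or holding less than
    ``min_frac`` of respondents are dropped (boundaries inclusive: a
    group at exactly the gate survives).  Returns the gated series or
    None when fewer than two groups survive.
    """
    if md.kind(covariate) not in ("categorical", "ordinal"):
        raise ValueError("group gating applies to categorical/ordinal covariates")
    col = md.column(covariate).copy()
    if md.kind(covariate) == "ordinal":
        levels = list(md.ordinal_levels[covariate])
        counts = col.value_counts()
        # merge sparse extremes inward until both ends pass min_total
        while len(levels) > 1:
            n_lo = counts.get(levels[0], 0)
            n_hi = counts.get(levels[-1], 0)
            if n_lo < min_total and n_lo <= n_hi:
                merged = f"{levels[0]}|{levels[1]}"
                col = col.replace({levels[0]: merged, levels[1]: merged})
                levels = [merged] + levels[2:]
            elif n_hi < min_total:
                merged = f"{levels[-2]}|{levels[-1]}"
                col = col.replace({levels[-2]: merged, levels[-1]: merged})
                levels = levels[:-2] + [merged]
            else:
                break
            counts = col.value_counts()
    counts = col.value_counts()
    n_total = int(col.notna().sum())
    keep_levels = [
        lvl for lvl, c in counts.items()
        if c >= min_group and (c / n_total) >= min_frac
    ]
    col[~col.isin(keep_levels)] = np.nan
    if col.dropna().nunique() < 2:
        return None
    return col


def _bias_corrected_cramers_v(a: pd.Series, b: pd.Series) -> float:
    """Bergsma bias-corrected Cramér's V on the complete-case overlap."""
    tab = pd.crosstab(a, b)
    n = tab.to_numpy().sum()
    if n == 0 or min(tab.shape) < 2:
        return np.nan
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    phi2 = chi2 / n
    r, k = tab.shape
    phi2_corr = max(0.0, phi2 - (k - 1) * (r - 1) / (n - 1))
    r_corr = r - (r - 1) ** 2 / (n - 1)
    k_corr = k - (k - 1) ** 2 / (n - 1)
    denom = min(r_corr - 1, k_corr - 1)
    if denom <= 0:
        return np.nan
    return float(np.sqrt(phi2_corr / denom))


def _welch_r(x: pd.Series, g: pd.Series) -> float:
    """Welch t between the two largest groups, converted to r."""
    groups = [x[g == lvl].dropna().to_numpy() for lvl in g.dropna().unique()]
    groups = sorted(groups, key=len, reverse=True)[:2]
    if len(groups) < 2 or min(len(v) for v in groups) < 2:
        return np.nan
    t, _ = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    n1, n2 = len(groups[0]), len(groups[1])
    v1, v2 = groups[0].var(ddof=1), groups[1].var(ddof=1)
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = num / den if den > 0 else n1 + n2 - 2
    return float(np.sqrt(t**2 / (t**2 + df)))


def covariate_association(md: SampleMetadata, cov_a: str, cov_b: str) -> float:
    """Pairwise association in [-1, 1]; |R| feeds the distance 1 - |R|.

    continuous/ordinal x continuous/ordinal -> Pearson r (ordinal via
    level ranks); categorical x categorical/ordinal -> bias-corrected
    Cramér's V; continuous x categorical -> Welch t converted to r.
    Complete-case overlap; empty overlap -> NaN.
    """
    ka, kb = md.kind(cov_a), md.kind(cov_b)

    def numeric(c, k):
        return (
            md.ordinal_rank(c) if k == "ordinal"
            else pd.to_numeric(md.column(c), errors="coerce")
        )

    if {ka, kb} <= {"continuous", "ordinal"}:
        x, y = numeric(cov_a, ka), numeric(cov_b, kb)
        ok = x.notna() & y.notna()
        if ok.sum() < 2 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            return np.nan
        return float(stats.pearsonr(x[ok], y[ok])[0])
    if ka == "categorical" and kb == "categorical" or (
        "categorical" in (ka, kb) and "ordinal" in (ka, kb)
    ):
        a, b = md.column(cov_a), md.column(cov_b)
        ok = a.notna() & b.notna()
        return _bias_corrected_cramers_v(a[ok], b[ok])
    # continuous vs categorical
    cont, cat = (cov_a, cov_b) if ka == "continuous" else (cov_b, cov_a)
    x = pd.to_numeric(md.column(cont), errors="coerce")
    g = md.column(cat)
    ok = x.notna() & g.notna()
    return _welch_r(x[ok], g[ok])


def association_matrix(md: SampleMetadata, covariates=None) -> pd.DataFrame:
    covs = list(covariates) if covariates is not None else list(md.schema)
    R = pd.DataFrame(np.eye(len(covs)), index=covs, columns=covs)
    for i, a in enumerate(covs):
        for b in covs[i + 1:]:
            r = covariate_association(md, a, b)
            R.loc[a, b] = R.loc[b, a] = 0.0 if np.isnan(r) else r
    return R


def cluster_covariates(
    R: pd.DataFrame,
    md: SampleMetadata | None = None,
    cut_branch_length: float = 0.29,
) -> tuple[dict[str, int], dict[int, str]]:
    """Average-linkage clustering of covariates on distance 1 - |R|.

    Tips whose subtree is entered within cumulative branch length
    ``cut_branch_length`` of the tip level share a cluster.  One
    representative per cluster: the covariate with the fewest missing
    values in ``md`` (ties by name), else the first name alphabetically.
    Returns (covariate -> cluster id, cluster id -> representative).
    """
    covs = list(R.index)
    if len(covs) == 1:
        return {covs[0]: 0}, {0: covs[0]}
    dist = 1.0 - np.abs(R.to_numpy(float))
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    # average-linkage dendrogram with tips at height 0: the cumulative
    # branch length from a tip into its containing subtree equals the
    # subtree's merge height, so the bottom-up grouping is a height cut
    labels = hierarchy.fcluster(Z, t=cut_branch_length, criterion="distance")
    assignment = {c: int(l) for c, l in zip(covs, labels)}
    reps: dict[int, str] = {}
    for cid in sorted(set(labels)):
        members = sorted(c for c, l in assignment.items() if l == cid)
        if md is not None:
            members.sort(key=lambda c: (int(md.column(c).isna().sum()), c))
        reps[cid] = members[0]
    return assignment, reps


def quartile_bin(md: SampleMetadata, covariate: str) -> pd.Series:
    """Bin a continuous covariate at its empirical quartiles.

    Left-closed bins; values tied with a quartile edge go to the lower
    bin.  Labels are Q1..Q4.  Requires >= 4 distinct observed values.
    """
    if md.kind(covariate) != "continuous":
        raise ValueError("quartile binning applies to continuous covariates")
    x = md.column(covariate)
    obs = x.dropna()
    if obs.nunique() < 4:
        raise ValueError("need at least 4 distinct values to form quartiles")
    edges = np.quantile(obs.to_numpy(float), [0.25, 0.5, 0.75])
    binned = pd.Series(np.nan, index=x.index, dtype=object)
    idx = np.searchsorted(edges, obs.to_numpy(float), side="left")
    binned[obs.index] = np.array([f"Q{i + 1}" for i in idx], dtype=object)
    binned.name = f"{covariate}_quartile"
    return binned


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute mean difference over the pooled standard deviation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return np.nan
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        return 0.0
    return float(abs(x.mean() - y.mean()) / pooled)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@dataclass
class EffectSizeRecord:
    """One row of the effect-size ledger."""

    covariate: str
    group_a: str
    group_b: str
    response: str
    cohens_d: float
    raw_p: float
    reject: bool
    direction: str  # "a>b" | "b>a" | ""


@dataclass
class EffectSizeLedger:
    records: list[EffectSizeRecord] = field(default_factory=list)
    global_pvalues: dict[str, float] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _within_between(dm: skbio.DistanceMatrix, ids_a, ids_b):
    sub = dm.filter(list(ids_a) + list(ids_b))
    n_a = len(ids_a)
    arr = sub.data
    iu = np.triu_indices(len(arr), k=1)
    within = [
        arr[i, j] for i, j in zip(*iu)
        if (i < n_a) == (j < n_a)
    ]
    between = [arr[i, j] for i, j in zip(*iu) if (i < n_a) != (j < n_a)]
    return np.asarray(within), np.asarray(between)


def pairwise_effect_sizes(
    response,
    groupings: dict[str, pd.Series],
    alpha: float = 0.05,
    global_test: str = "anova",
    permutations: int = 999,
    seed: int | None = None,
) -> EffectSizeLedger:
    """mdFDR-controlled pairwise effect sizes over many covariates.

    ``response`` is an alpha-diversity Series (sample -> value) or a
    skbio DistanceMatrix.  ``groupings`` maps covariate name to a gated
    group Series (NaN = excluded).  Stage 1: global test per covariate
    (alpha response: one-way ANOVA or Kruskal-Wallis; beta response:
    PERMANOVA), BH selection at ``alpha`` giving R of m.  Stage 2: all
    pairwise comparisons within selected covariates (Welch t for alpha,
    pairwise PERMANOVA for beta), BH within covariate at (R/m) * alpha,
    direction from the sign of the mean difference.  Cohen's d is on the
    response values for alpha, and on within- vs between-group distance
    distributions for beta.
    """
    rng = np.random.default_rng(seed)
    is_beta = isinstance(response, skbio.DistanceMatrix)
    ledger = EffectSizeLedger()

    group_values: dict[str, dict[str, np.ndarray]] = {}
    for cov, series in groupings.items():
        series = series.dropna()
        if is_beta:
            series = series[series.index.isin(response.ids)]
        else:
            series = series[series.index.isin(response.index)]
        levels = series.unique()
        if len(levels) < 2 or series.value_counts().min() < 2:
            ledger.skipped[cov] = "fewer than 2 usable groups"
            continue
        if is_beta:
            sub = response.filter(series.index)
            res = permanova(
                sub, series.loc[list(sub.ids)].to_numpy(),
                permutations=permutations, seed=int(rng.integers(2**31)),
            )
            ledger.global_pvalues[cov] = res.p_value
            group_values[cov] = {
                lvl: series.index[series == lvl].to_numpy() for lvl in levels
            }
        else:
            vals = {
                str(lvl): response.loc[series.index[series == lvl]].to_numpy()
                for lvl in levels
            }
            if global_test == "kruskal":
                _, p = stats.kruskal(*vals.values())
            else:
                _, p = stats.f_oneway(*vals.values())
            ledger.global_pvalues[cov] = float(p)
            group_values[cov] = vals

    m = len(ledger.global_pvalues)
    if m == 0:
        return ledger
    covs = list(ledger.global_pvalues)
    adj = bh_adjust(np.array([ledger.global_pvalues[c] for c in covs]))
    ledger.selected = [c for c, a in zip(covs, adj) if a <= alpha]
    R = len(ledger.selected)
    if R == 0:
        return ledger
    stage2_alpha = (R / m) * alpha

    resp_name = "beta" if is_beta else getattr(response, "name", "alpha") or "alpha"
    for cov in ledger.selected:
        vals = group_values[cov]
        levels = sorted(vals)
        pairs, pvals, diffs, ds = [], [], [], []
        for i, la in enumerate(levels):
            for lb in levels[i + 1:]:
                if is_beta:
                    ids_a, ids_b = vals[la], vals[lb]
                    sub = response.filter(list(ids_a) + list(ids_b))
                    lab = np.array(
                        ["a"] * len(ids_a) + ["b"] * len(ids_b)
                    )
                    res = permanova(
                        sub, lab, permutations=permutations,
                        seed=int(rng.integers(2**31)),
                    )
                    p = res.p_value
                    within, between = _within_between(response, ids_a, ids_b)
                    d = cohens_d(between, within)
                    diff = between.mean() - within.mean()
                else:
                    a, b = vals[la], vals[lb]
                    _, p = stats.ttest_ind(a, b, equal_var=False)
                    d = cohens_d(a, b)
                    diff = a.mean() - b.mean()
                pairs.append((la, lb))
                pvals.append(float(p))
                diffs.append(diff)
                ds.append(d)
        adj2 = bh_adjust(np.asarray(pvals))
        for (la, lb), p, a2, diff, d in zip(pairs, pvals, adj2, diffs, ds):
            reject = bool(a2 <= stage2_alpha)
            direction = "" if not reject else ("a>b" if diff > 0 else "b>a")
            ledger.records.append(
                EffectSizeRecord(cov, str(la), str(lb), resp_name, d, p,
                                 reject, direction)
            )
    return ledger
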