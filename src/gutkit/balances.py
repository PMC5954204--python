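"""Two-way balance classifier for compositional count data.

The pipeline identifies the features most strongly associated with each
side of a binary covariate while respecting compositionality:

1. the count table is CLR-transformed with a pseudocount of 1;
2. a single-component PLS (NIPALS) regresses the binary response on the
   CLR matrix, giving each feature a score;
3. a 3-component univariate Gaussian mixture is fitted to the scores,
   modelling a negative-associated, a null, and a positive-associated
   population of features;
4. the density intersections between adjacent components give two
   thresholds; features strictly below the lower threshold form
   ``x_neg``, strictly above the upper form ``x_pos``;
5. the per-sample balance
   b = sqrt(r s / (r + s)) * log(g(x_pos) / g(x_neg)),
   with r = |x_pos|, s = |x_neg| and g the geometric mean over
   pseudocounted counts, is a signed log-ratio contrast;
6. the balance is evaluated against the labels with ROC/AUC and a
   one-way ANOVA.

Dimensionality is shrunk first by an abundance/prevalence/variance
filter so that samples outnumber features.

The whole pipeline is wrapped statsmodels-style in
:class:`BalanceClassifier` (model) / :class:`BalanceResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

__all__ = [
    "filter_features",
    "clr_transform",
    "pls_component",
    "GaussianMixture1D",
    "fit_gmm_1d",
    "gaussian_intersection",
    "gmm_thresholds",
    "classify_features",
    "balance_values",
    "evaluate_balance",
    "BalanceEvaluation",
    "BalanceClassifier",
    "BalanceResults",
]


def filter_features(
    table: FeatureTable,
    min_reads: int = 50,
    min_samples: int = 20,
    min_variance: float = 10.0,
) -> FeatureTable:
    """Abundance/prevalence/variance feature filter.

    A feature is kept iff it has at least ``min_reads`` total reads,
    occurs in at least ``min_samples`` samples, and its count variance
    exceeds ``min_variance``.  ``min_samples=5`` is the variant used
    when group sizes are small.
    """
    counts = table.counts
    total = counts.sum(axis=0)
    prevalence = (counts > 0).sum(axis=0)
    variance = counts.var(axis=0, ddof=0)
    keep = (total >= min_reads) & (prevalence >= min_samples) & (
        variance > min_variance
    )
    if not keep.any():
        raise ValueError(
            "feature filter removed everything "
            f"(min_reads={min_reads}, min_samples={min_samples}, "
            f"min_variance={min_variance})"
        )
    out = table.filter_features(np.asarray(table.feature_ids)[keep])
    if out.shape[0] <= out.shape[1]:
        warnings.warn(
            "fewer samples than features after filtering; "
            "PLS may overfit", stacklevel=2,
        )
    return out


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform with a pseudocount.

    Per sample: log(x_i + pc) - mean_j log(x_j + pc).  Rows of the
    result sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logx = np.log(table.counts.astype(float) + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.feature_ids)


def pls_component(X: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """First PLS weight vector (NIPALS, one component).

    ``X`` is column-centered (not scaled — CLR already normalises
    scale), ``y`` centered.  For a single component the NIPALS weight is
    w = X'y / ||X'y||.  The sign is fixed so the class coded 1 has a
    positive mean projection.
    """
    yv = np.asarray(y, dtype=float)
    classes = np.unique(yv)
    if classes.size < 2:
        raise ValueError("need both classes present")
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0, keepdims=True)
    yc = yv - yv.mean()
    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate PLS: X'y is zero")
    w = w / norm
    if (Xc @ w)[yv == yv.max()].mean() < 0:
        w = -w
    return pd.Series(w, index=X.columns, name="pls_score")


@dataclass
class GaussianMixture1D:
    """Univariate 3-component Gaussian mixture, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool = True
    log_likelihood: float = np.nan

    def component_density(self, k: int, x) -> np.ndarray:
        return self.weights[k] * stats.norm.pdf(x, self.means[k], self.sds[k])

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(self.component_density(k, x) for k in range(len(self.means)))


def _kmeans_pp_init(x: np.ndarray, k: int, rng) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        if d2.sum() == 0:
            centers.append(x[rng.integers(len(x))])
        else:
            centers.append(rng.choice(x, p=d2 / d2.sum()))
    return np.sort(np.asarray(centers))


def fit_gmm_1d(
    x: np.ndarray,
    n_components: int = 3,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> GaussianMixture1D:
    """EM fit of a univariate Gaussian mixture, k-means++ initialised.

    Best of ``n_restarts`` seeded restarts; components relabeled by
    sorted mean.  Raises if no restart converges.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < n_components:
        raise ValueError("need at least n_components distinct values")
    rng = np.random.default_rng(seed)
    span = x.std() if x.std() > 0 else 1.0
    min_sd = 1e-4 * span
    best = None
    for _ in range(n_restarts):
        mu = _kmeans_pp_init(x, n_components, rng)
        sd = np.full(n_components, span / n_components + min_sd)
        w = np.full(n_components, 1.0 / n_components)
        ll_prev = -np.inf
        converged = False
        for _it in range(max_iter):
            dens = w[None, :] * stats.norm.pdf(
                x[:, None], mu[None, :], sd[None, :]
            )
            total = dens.sum(axis=1)
            total = np.maximum(total, 1e-300)
            resp = dens / total[:, None]
            ll = float(np.log(total).sum())
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-10)
            w = nk / len(x)
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, min_sd**2))
            if abs(ll - ll_prev) < tol * (1 + abs(ll)):
                converged = True
                break
            ll_prev = ll
        if converged and (best is None or ll > best.log_likelihood):
            order = np.argsort(mu)
            best = GaussianMixture1D(
                mu[order], sd[order], w[order], True, ll
            )
    if best is None:
        raise RuntimeError("EM failed to converge in all restarts")
    return best


def gaussian_intersection(
    m1: float, s1: float, w1: float, m2: float, s2: float, w2: float
) -> tuple[float, bool]:
    """Crossing of two weighted Gaussian densities between their means.

    Solves w1 N(x; m1, s1) = w2 N(x; m2, s2) in closed form (quadratic
    in x) and returns the root inside (min(m1,m2), max(m1,m2)).  When no
    real root lies between the means the midpoint is returned with a
    ``fallback`` flag.
    """
    lo, hi = sorted((m1, m2))
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log((w1 * s2) / (w2 * s1))
    )
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            return (lo + hi) / 2, True
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            return (lo + hi) / 2, True
        sq = np.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size == 0:
        return (lo + hi) / 2, True
    # if both roots fall between the means take the one where the
    # densities genuinely cross sides (nearest to midpoint is robust)
    mid = (lo + hi) / 2
    return float(inside[np.argmin(np.abs(inside - mid))]), False


def gmm_thresholds(
    scores, seed: int | None = None, n_restarts: int = 10
) -> tuple[GaussianMixture1D, float, float, dict]:
    """Fit the 3-Gaussian mixture and derive the two thresholds.

    theta_lo = crossing of the (negative, null) component densities
    between their means; theta_hi = crossing of (null, positive).
    Returns (mixture, theta_lo, theta_hi, flags) where flags marks
    midpoint fallbacks.
    """
    x = np.asarray(scores, dtype=float)
    gmm = fit_gmm_1d(x, 3, seed=seed, n_restarts=n_restarts)
    m, s, w = gmm.means, gmm.sds, gmm.weights
    theta_lo, fb_lo = gaussian_intersection(m[0], s[0], w[0], m[1], s[1], w[1])
    theta_hi, fb_hi = gaussian_intersection(m[1], s[1], w[1], m[2], s[2], w[2])
    if theta_lo > theta_hi:  # pathological overlap; fall back to midpoints
        theta_lo = (m[0] + m[1]) / 2
        theta_hi = (m[1] + m[2]) / 2
        fb_lo = fb_hi = True
    return gmm, theta_lo, theta_hi, {"lo_fallback": fb_lo, "hi_fallback": fb_hi}


def classify_features(
    scores: pd.Series, theta_lo: float, theta_hi: float
) -> tuple[list[str], list[str]]:
    """Assign features by strict threshold comparison.

    score < theta_lo -> x_neg; score > theta_hi -> x_pos; scores equal
    to a threshold remain unassigned (null).
    """
    x_neg = list(scores.index[scores < theta_lo])
    x_pos = list(scores.index[scores > theta_hi])
    return x_pos, x_neg


def balance_values(
    table: FeatureTable, x_pos, x_neg, pseudocount: float = 1.0
) -> pd.Series:
    """Per-sample balance b = sqrt(rs/(r+s)) log(g(x_pos)/g(x_neg)).

    Geometric means are over pseudocounted raw counts, making b
    invariant to per-sample scaling.
    """
    x_pos, x_neg = list(x_pos), list(x_neg)
    if not x_pos or not x_neg:
        raise ValueError("both feature sets must be nonempty")
    if set(x_pos) & set(x_neg):
        raise ValueError("x_pos and x_neg overlap")
    r, s = len(x_pos), len(x_neg)
    coef = np.sqrt(r * s / (r + s))
    logc = np.log(table.data[x_pos + x_neg].to_numpy(float) + pseudocount)
    log_g_pos = logc[:, :r].mean(axis=1)
    log_g_neg = logc[:, r:].mean(axis=1)
    return pd.Series(
        coef * (log_g_pos - log_g_neg), index=table.sample_ids, name="balance"
    )


@dataclass
class BalanceEvaluation:
    """ROC/AUC and one-way ANOVA of the balance against the labels."""

    auc: float
    f_statistic: float
    p_value: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray


def evaluate_balance(b: pd.Series, labels) -> BalanceEvaluation:
    """AUC via the Mann-Whitney rank statistic plus ANOVA F and p."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    pos = b.to_numpy()[y == classes[1]]
    neg = b.to_numpy()[y == classes[0]]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u / (len(pos) * len(neg)))
    f, p = stats.f_oneway(pos, neg)
    # ROC curve by threshold sweep over observed values
    order = np.argsort(-b.to_numpy())
    yy = (y == classes[1]).astype(int)[order]
    tpr = np.concatenate([[0], np.cumsum(yy) / max(yy.sum(), 1)])
    fpr = np.concatenate(
        [[0], np.cumsum(1 - yy) / max((1 - yy).sum(), 1)]
    )
    return BalanceEvaluation(auc, float(f), float(p), fpr, tpr)


class BalanceClassifier:
    """Model object for the CLR -> PLS -> mixture -> balance pipeline.

    Parameters
    ----------
    table : FeatureTable
        Raw (unfiltered) count table.
    labels : array-like or pd.Series
        Binary covariate aligned to the table's samples.  The lexically
        larger class is coded as the positive category.
    min_reads, min_samples, min_variance :
        Feature filter thresholds.
    pseudocount :
        CLR and geometric-mean pseudocount.
    """

    def __init__(
        self,
        table: FeatureTable,
        labels,
        min_reads: int = 50,
        min_samples: int = 20,
        min_variance: float = 10.0,
        pseudocount: float = 1.0,
    ):
        if isinstance(labels, pd.Series):
            labels = labels.loc[table.sample_ids]
        self.table = table
        self.labels = np.asarray(labels)
        if np.unique(self.labels).size != 2:
            raise ValueError("labels must be binary")
        self.min_reads = min_reads
        self.min_samples = min_samples
        self.min_variance = min_variance
        self.pseudocount = pseudocount

    @classmethod
    def from_metadata(cls, table, metadata, covariate, **kwargs):
        labels = metadata.column(covariate).loc[table.sample_ids]
        keep = labels.notna()
        return cls(
            table.filter_samples(labels.index[keep]), labels[keep], **kwargs
        )

    def fit(self, seed: int | None = None) -> "BalanceResults":
        filtered = filter_features(
            self.table, self.min_reads, self.min_samples, self.min_variance
        )
        clr = clr_transform(filtered, self.pseudocount)
        y = (self.labels == np.unique(self.labels)[1]).astype(float)
        scores = pls_component(clr, y)
        gmm, th_lo, th_hi, flags = gmm_thresholds(scores.to_numpy(), seed=seed)
        x_pos, x_neg = classify_features(scores, th_lo, th_hi)
        if x_pos and x_neg:
            b = balance_values(filtered, x_pos, x_neg, self.pseudocount)
            evaluation = evaluate_balance(b, self.labels)
        else:
            b = pd.Series(np.nan, index=filtered.sample_ids, name="balance")
            evaluation = None
        return BalanceResults(
            self, filtered, scores, gmm, th_lo, th_hi, flags,
            x_pos, x_neg, b, evaluation,
        )


class BalanceResults:
    """Fitted balance classifier: estimates, thresholds, diagnostics."""

    def __init__(
        self, model, filtered_table, scores, gmm, theta_lo, theta_hi,
        threshold_flags, x_pos, x_neg, balances, evaluation,
    ):
        self.model = model
        self.filtered_table = filtered_table
        self.scores = scores
        self.mixture = gmm
        self.theta_lo = theta_lo
        self.theta_hi = theta_hi
        self.threshold_flags = threshold_flags
        self.x_pos = x_pos
        self.x_neg = x_neg
        self.balances = balances
        self.evaluation = evaluation

    @property
    def auc(self) -> float:
        return self.evaluation.auc if self.evaluation else np.nan

    def evaluate_on(self, table: FeatureTable, labels) -> BalanceEvaluation:
        """Score held-out samples with the fitted feature sets.

        The in-sample AUC is optimistic because the feature sets were
        selected on the same labels; evaluating balances computed on
        samples unseen during fitting gives the honest estimate.
        """
        if not self.x_pos or not self.x_neg:
            raise ValueError("balance undefined: an assigned set is empty")
        b = balance_values(table, self.x_pos, self.x_neg,
                           self.model.pseudocount)
        return evaluate_balance(b, labels)

    def summary(self) -> str:
        g = self.mixture
        lines = [
            "Balance classifier results",
            "==========================",
            f"samples: {self.filtered_table.shape[0]}"
            f"   features after filter: {self.filtered_table.shape[1]}",
            f"mixture means: {g.means[0]:+.4f} {g.means[1]:+.4f} {g.means[2]:+.4f}",
            f"mixture sds:   {g.sds[0]: .4f} {g.sds[1]: .4f} {g.sds[2]: .4f}",
            f"mixture weights: {g.weights[0]:.3f} {g.weights[1]:.3f} "
            f"{g.weights[2]:.3f}",
            f"thresholds: theta_lo={self.theta_lo:+.4f} "
            f"theta_hi={self.theta_hi:+.4f}"
            + ("  [midpoint fallback]" if any(self.threshold_flags.values())
               else ""),
            f"|x_pos|={len(self.x_pos)}   |x_neg|={len(self.x_neg)}",
        ]
        if self.evaluation:
            lines += [
                f"AUC: {self.evaluation.auc:.4f}",
                f"ANOVA: F={self.evaluation.f_statistic:.3f} "
                f"p={self.evaluation.p_value:.3g}",
            ]
        else:
            lines.append("balance undefined (an assigned set is empty)")
        return "\n".join(lines)
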