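import itertools

import numpy as np
import pandas as pd
import pytest
import skbio

from conftest import brute_pseudo_f
from gutkit import group_tests as gt
from gutkit.io import FeatureTable, SampleMetadata


def cluster_dm(rng, n_per=4, sep=0.0, dim=3, groups=2):
    pts, labels = [], []
    for g in range(groups):
        pts.append(rng.normal(size=(n_per, dim)) + g * sep)
        labels += [f"g{g}"] * n_per
    pts = np.vstack(pts)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(len(labels))]
    return skbio.DistanceMatrix(d, ids=ids), np.array(labels)


def test_permanova_statistic_matches_bruteforce():
    rng = np.random.default_rng(0)
    for _ in range(5):
        dm, labels = cluster_dm(rng, n_per=4, sep=1.0)
        res = gt.permanova(dm, labels, permutations=99, seed=1)
        assert res.statistic == pytest.approx(
            brute_pseudo_f(dm.data**2, labels), rel=1e-10)


def test_permanova_exhaustive_permutation_oracle():
    """Exhaustive enumeration of all label permutations on n = 8 gives the
    exact permutation p; the sampled p agrees within Monte-Carlo error."""
    rng = np.random.default_rng(1)
    dm, labels = cluster_dm(rng, n_per=4, sep=4.0)
    d2 = dm.data**2
    f_obs = brute_pseudo_f(d2, labels)
    f_null = np.array([
        brute_pseudo_f(d2, np.array(perm))
        for perm in itertools.permutations(labels)
    ])
    p_exact = (f_null >= f_obs - 1e-12).mean()
    res = gt.permanova(dm, labels, permutations=999, seed=2)
    se = np.sqrt(p_exact * (1 - p_exact) / 999)
    assert abs(res.p_value - p_exact) <= 3 * se + 1 / 999


def test_permanova_separated_and_null():
    rng = np.random.default_rng(2)
    dm, labels = cluster_dm(rng, n_per=12, sep=4.0)
    assert gt.permanova(dm, labels, seed=0).p_value <= 0.01

    dm0, labels0 = cluster_dm(rng, n_per=12, sep=0.0)
    p = gt.permanova(dm0, labels0, seed=0).p_value
    assert p > 0.01  # overwhelmingly likely under the null

    with pytest.raises(ValueError):
        gt.permanova(dm, np.array(["x"] * 24))
    # determinism
    assert gt.permanova(dm, labels, seed=7).p_value == \
        gt.permanova(dm, labels, seed=7).p_value


def test_permdisp_detects_scale_difference():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(size=(15, 3)), 3 * rng.normal(size=(15, 3))])
    labels = np.array(["tight"] * 15 + ["spread"] * 15)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(30)])
    res = gt.permdisp(dm, labels, permutations=199, seed=1)
    assert res.p_value <= 0.01
    pg = res.extras["per_group"]
    assert pg["spread"]["mean_centroid_distance"] > \
        pg["tight"]["mean_centroid_distance"]
    assert pg["spread"]["max_centroid_distance"] > \
        pg["tight"]["max_centroid_distance"]


def test_permdisp_equal_dispersion_null():
    rng = np.random.default_rng(4)
    dm, labels = cluster_dm(rng, n_per=15, sep=0.0)
    res = gt.permdisp(dm, labels, permutations=199, seed=2)
    assert res.p_value > 0.01


def test_permdisp_agrees_with_skbio():
    from skbio.stats.distance import permdisp as skbio_permdisp

    rng = np.random.default_rng(5)
    dm, labels = cluster_dm(rng, n_per=10, sep=1.0)
    ours = gt.permdisp(dm, labels, permutations=999, seed=3)
    ref = skbio_permdisp(dm, labels, test="median", permutations=999, seed=3)
    assert ours.statistic == pytest.approx(float(ref["test statistic"]),
                                           rel=0.05)
    assert abs(ours.p_value - float(ref["p-value"])) < 0.1


def test_permdisp_singleton_group_excluded():
    rng = np.random.default_rng(6)
    dm, labels = cluster_dm(rng, n_per=8, sep=0.0)
    labels = labels.astype(object)
    labels[0] = "single"
    labels[1:] = ["a"] * 8 + ["b"] * 7
    res = gt.permdisp(dm, labels, permutations=49, seed=0)
    assert res.extras["excluded_singletons"] == ["single"]


# ------------------------------------------------------ state-change resampling


def _longitudinal_dm(rng, n_subj=10, shift=0.0):
    sids, subjects, conditions, pts = [], [], [], []
    for s in range(n_subj):
        base = rng.normal(size=3)
        for cond in ("pre", "post"):
            for rep in range(2):
                sid = f"s{s}.{cond}.{rep}"
                sids.append(sid)
                subjects.append(f"subj{s}")
                conditions.append(cond)
                delta = shift if cond == "post" else 0.0
                pts.append(base + rng.normal(scale=0.5, size=3)
                           + np.array([delta, 0, 0]))
    pts = np.vstack(pts)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    dm = skbio.DistanceMatrix(d, ids=sids)
    md = SampleMetadata(
        pd.DataFrame({"subject": subjects, "condition": conditions},
                     index=sids),
        {"subject": "categorical", "condition": "categorical"},
    )
    return dm, md


def test_state_change_null_and_planted():
    rng = np.random.default_rng(7)
    dm, md = _longitudinal_dm(rng, shift=0.0)
    out = gt.state_change_resampling(dm, md, trials=30, permutations=199,
                                    seed=0)
    assert out["fraction_significant"] <= 0.2

    dm2, md2 = _longitudinal_dm(rng, shift=4.0)
    out2 = gt.state_change_resampling(dm2, md2, trials=30, permutations=199,
                                     seed=0)
    assert out2["fraction_significant"] >= 0.9


def test_state_change_single_sample_per_cell_degenerate():
    rng = np.random.default_rng(8)
    sids, subjects, conditions, pts = [], [], [], []
    for s in range(6):
        for cond in ("pre", "post"):
            sids.append(f"s{s}.{cond}")
            subjects.append(f"subj{s}")
            conditions.append(cond)
            pts.append(rng.normal(size=3))
    d = np.sqrt((((p := np.vstack(pts))[:, None] - p[None]) ** 2).sum(-1))
    dm = skbio.DistanceMatrix(d, ids=sids)
    md = SampleMetadata(
        pd.DataFrame({"subject": subjects, "condition": conditions},
                     index=sids),
        {"subject": "categorical", "condition": "categorical"},
    )
    out = gt.state_change_resampling(dm, md, trials=10, permutations=99,
                                    seed=1)
    # every trial draws the same samples: p variance is exactly 0
    assert np.var(out["p_values"]) == 0.0


# ----------------------------------------------------------------- matching


def test_match_controls_exact_twins_and_tolerances():
    df = pd.DataFrame({
        "age": [30.0, 50.0, 31.0, 49.0, 80.0],
        "country": ["US", "UK", "US", "UK", "US"],
    }, index=["case1", "case2", "ctrlA", "ctrlB", "ctrlC"])
    md = SampleMetadata(df, {"age": "continuous", "country": "categorical"})
    m = gt.match_controls(md, ["case1", "case2"],
                          exact=("country",), tolerance={"age": 5.0})
    assert m == {"case1": "ctrlA", "case2": "ctrlB"}

    # no control within age +-5 -> unmatched
    m2 = gt.match_controls(md, ["case1"], control_pool=["ctrlC"],
                           exact=("country",), tolerance={"age": 5.0})
    assert m2 == {"case1": None}

    with pytest.raises(ValueError):
        gt.match_controls(md, ["case1"], control_pool=["case1"])


def test_match_controls_without_replacement_deterministic():
    df = pd.DataFrame({"age": [30.0, 30.0, 30.0, 30.0]},
                      index=["c1", "c2", "p1", "p2"])
    md = SampleMetadata(df, {"age": "continuous"})
    m = gt.match_controls(md, ["c1", "c2"], control_pool=["p1", "p2"],
                          tolerance={"age": 5.0})
    assert m == {"c1": "p1", "c2": "p2"}
    assert m == gt.match_controls(md, ["c1", "c2"],
                                  control_pool=["p1", "p2"],
                                  tolerance={"age": 5.0})


# ----------------------------------------------- permuted mean difference


def _shifted_table(rng, n=100, p=40, k=8, fold=3.0):
    base = np.exp(rng.normal(size=p))
    labels = np.array(["x"] * (n // 2) + ["y"] * (n // 2))
    counts = np.empty((n, p), dtype=np.int64)
    shifted = rng.choice(p, size=k, replace=False)
    for i in range(n):
        mu = base.copy()
        if labels[i] == "y":
            mu[shifted] *= fold
        prob = mu / mu.sum()
        counts[i] = rng.multinomial(5000, prob)
    table = FeatureTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)]))
    return table, labels, {f"f{j}" for j in shifted}


def test_permuted_mean_difference_recovers_planted():
    rng = np.random.default_rng(9)
    table, labels, truth = _shifted_table(rng)
    res = gt.permuted_mean_difference(table, labels, permutations=2000,
                                      seed=0)
    hits = set(res.index[res.reject]) & truth
    assert len(hits) / len(truth) >= 0.8


def test_permuted_mean_difference_antisymmetry_and_constant():
    rng = np.random.default_rng(10)
    table, labels, _ = _shifted_table(rng, n=30, p=10, k=2)
    res_a = gt.permuted_mean_difference(table, labels, permutations=200,
                                        seed=1)
    swapped = np.where(labels == "x", "y", "x")
    res_b = gt.permuted_mean_difference(table, swapped, permutations=200,
                                        seed=1)
    np.testing.assert_allclose(res_a["mean_difference"],
                               -res_b["mean_difference"], atol=1e-12)

    const = FeatureTable(pd.DataFrame(
        {"c": [5] * 10, "v": list(range(1, 11))},
        index=[f"s{i}" for i in range(10)]))
    res_c = gt.permuted_mean_difference(
        const, np.array(["x"] * 5 + ["y"] * 5), permutations=100, seed=2)
    assert res_c.loc["c", "p_value"] == 1.0
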