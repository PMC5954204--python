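import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutkit import effects
from gutkit.io import SampleMetadata


def make_md(df, schema, ordinal_levels=None):
    return SampleMetadata(df, schema, ordinal_levels or {})


# --------------------------------------------------------------------- curation


def test_curation_height_weight_bounds():
    df = pd.DataFrame({
        "height_cm": [211.0, 170.0, 47.0],
        "weight_kg": [70.0, 250.0, 60.0],
        "bmi": [1.0, 1.0, 1.0],
    }, index=["a", "b", "c"])
    md = make_md(df, {c: "continuous" for c in df})
    out = effects.curate_metadata(md)
    assert pd.isna(out.column("height_cm")["a"])
    assert pd.isna(out.column("weight_kg")["b"])
    assert pd.isna(out.column("height_cm")["c"])
    # BMI recomputed only from in-bound pairs
    assert pd.isna(out.column("bmi")["a"])
    assert out.column("bmi")["b"] != out.column("bmi")["b"] or True
    assert pd.isna(out.column("bmi")["b"])


def test_curation_child_inconsistency_blanks_age():
    df = pd.DataFrame({
        "age_years": [3.0, 3.0, 30.0, 3.0],
        "height_cm": [120.0, 90.0, 180.0, 90.0],
        "weight_kg": [15.0, 15.0, 80.0, 15.0],
        "alcohol": [np.nan, np.nan, "Daily", "Rarely"],
    }, index=["kid_tall", "kid_ok", "adult", "kid_drinks"])
    md = make_md(df, {
        "age_years": "continuous", "height_cm": "continuous",
        "weight_kg": "continuous", "alcohol": "categorical",
    })
    out = effects.curate_metadata(md)
    assert pd.isna(out.column("age_years")["kid_tall"])
    assert out.column("age_years")["kid_ok"] == 3.0
    assert out.column("age_years")["adult"] == 30.0
    assert pd.isna(out.column("age_years")["kid_drinks"])


def test_curation_identity_on_valid_record():
    df = pd.DataFrame({
        "height_cm": [170.0], "weight_kg": [70.0], "age_years": [40.0],
    }, index=["ok"])
    md = make_md(df, {c: "continuous" for c in df})
    out = effects.curate_metadata(md)
    pd.testing.assert_frame_equal(out.data, df)


# ----------------------------------------------------------------- group gating


def test_gate_merges_sparse_ordinal_extremes():
    levels = ["less than 5", "6 to 10", "more than 10"]
    col = (["less than 5"] * 10 + ["6 to 10"] * 300 + ["more than 10"] * 300)
    df = pd.DataFrame({"plants": col},
                      index=[f"s{i}" for i in range(len(col))])
    md = make_md(df, {"plants": "ordinal"}, {"plants": levels})
    out = effects.collapse_and_gate_groups(md, "plants")
    assert set(out.dropna().unique()) == {"less than 5|6 to 10", "more than 10"}


def test_gate_drops_underpowered_covariate():
    df = pd.DataFrame({"c": ["x"] * 30 + ["y"] * 20},
                      index=[f"s{i}" for i in range(50)])
    md = make_md(df, {"c": "categorical"})
    assert effects.collapse_and_gate_groups(md, "c") is None


def test_gate_boundaries_inclusive():
    # a group at exactly 3% of respondents and exactly 50 observations stays
    col = ["big"] * 1649 + ["edge"] * 51
    df = pd.DataFrame({"c": col}, index=[f"s{i}" for i in range(len(col))])
    md = make_md(df, {"c": "categorical"})
    out = effects.collapse_and_gate_groups(md, "c")
    assert set(out.dropna().unique()) == {"big", "edge"}
    assert (51 / len(col)) >= 0.03


# ------------------------------------------------------------------ association


def test_association_self_and_null():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "x": rng.normal(size=2000), "y": rng.normal(size=2000),
    }, index=[f"s{i}" for i in range(2000)])
    md = make_md(df, {"x": "continuous", "y": "continuous"})
    assert effects.covariate_association(md, "x", "x") == pytest.approx(1.0)
    hits = 0
    for rep in range(50):
        rng2 = np.random.default_rng(100 + rep)
        df2 = pd.DataFrame({
            "x": rng2.normal(size=2000), "y": rng2.normal(size=2000),
        }, index=df.index)
        md2 = make_md(df2, {"x": "continuous", "y": "continuous"})
        if abs(effects.covariate_association(md2, "x", "y")) < 0.1:
            hits += 1
    assert hits >= 48  # ~95% of null reps


def test_cramers_v_deterministic_mapping():
    rng = np.random.default_rng(1)
    a = rng.choice(list("pqr"), size=500)
    mapping = {"p": "u", "q": "v", "r": "w"}
    df = pd.DataFrame({"a": a, "b": [mapping[x] for x in a]},
                      index=[f"s{i}" for i in range(500)])
    md = make_md(df, {"a": "categorical", "b": "categorical"})
    v = effects.covariate_association(md, "a", "b")
    assert v >= 0.95
    # oracle: chi2 by hand from the contingency table
    tab = pd.crosstab(df["a"], df["b"]).to_numpy()
    n = tab.sum()
    expected = np.outer(tab.sum(1), tab.sum(0)) / n
    chi2 = ((tab - expected) ** 2 / expected).sum()
    assert chi2 == pytest.approx(stats.chi2_contingency(tab, correction=False)[0])


def test_welch_association_continuous_vs_categorical():
    rng = np.random.default_rng(2)
    g = rng.choice(["m", "f"], size=400)
    x = np.where(g == "m", 2.0, 0.0) + rng.normal(size=400)
    df = pd.DataFrame({"g": g, "x": x}, index=[f"s{i}" for i in range(400)])
    md = make_md(df, {"g": "categorical", "x": "continuous"})
    r = effects.covariate_association(md, "x", "g")
    assert 0.5 < r <= 1.0


# -------------------------------------------------------------------- clustering


def test_cluster_covariates_rules():
    covs = ["a", "b", "c"]
    R = pd.DataFrame(np.eye(3), index=covs, columns=covs)
    R.loc["a", "b"] = R.loc["b", "a"] = 0.95
    assign, reps = effects.cluster_covariates(R)
    assert assign["a"] == assign["b"] != assign["c"]

    # all independent -> every covariate its own cluster
    R0 = pd.DataFrame(np.eye(3), index=covs, columns=covs)
    assign0, _ = effects.cluster_covariates(R0)
    assert len(set(assign0.values())) == 3

    # duplicated covariates share a cluster; representative = fewest missing
    df = pd.DataFrame({
        "a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0], "c": [0, 1, 0],
    }, index=["s1", "s2", "s3"])
    md = make_md(df, {c: "continuous" for c in df})
    R2 = pd.DataFrame(np.eye(3), index=covs, columns=covs)
    R2.loc["a", "b"] = R2.loc["b", "a"] = 1.0
    assign2, reps2 = effects.cluster_covariates(R2, md)
    cid = assign2["a"]
    assert assign2["b"] == cid and reps2[cid] == "b"


# ------------------------------------------------------------------- quartiles


def test_quartile_bin_even_and_ties():
    df = pd.DataFrame({"v": np.arange(1, 101, dtype=float)},
                      index=[f"s{i}" for i in range(100)])
    md = make_md(df, {"v": "continuous"})
    q = effects.quartile_bin(md, "v")
    assert q.value_counts().to_dict() == {f"Q{i}": 25 for i in range(1, 5)}

    # monotone in the original value
    order = df["v"].sort_values().index
    ranks = q.loc[order].map({f"Q{i}": i for i in range(1, 5)})
    assert (ranks.diff().dropna() >= 0).all()

    # heavy ties at the median all land deterministically in the lower bin
    df2 = pd.DataFrame({"v": [1.0, 2.0, 5.0, 5.0, 5.0, 5.0, 9.0, 10.0]},
                       index=[f"s{i}" for i in range(8)])
    md2 = make_md(df2, {"v": "continuous"})
    q2 = effects.quartile_bin(md2, "v")
    tied = q2[df2["v"] == 5.0]
    assert tied.nunique() == 1

    with pytest.raises(ValueError):
        effects.quartile_bin(
            make_md(pd.DataFrame({"v": [1.0, 1.0, 2.0]}, index=list("abc")),
                    {"v": "continuous"}), "v")


# -------------------------------------------------------------------- Cohen's d


def test_cohens_d_hand_value_and_invariances():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 200)
    y = rng.normal(1, 1, 200)
    # hand evaluation of the formula
    pooled = np.sqrt(((199) * x.var(ddof=1) + (199) * y.var(ddof=1)) / 398)
    assert effects.cohens_d(x, y) == pytest.approx(
        abs(x.mean() - y.mean()) / pooled)
    # shift invariance and scale equivariance (d is scale-free)
    assert effects.cohens_d(x + 5, y + 5) == pytest.approx(
        effects.cohens_d(x, y))
    assert effects.cohens_d(3 * x, 3 * y) == pytest.approx(
        effects.cohens_d(x, y))
    assert effects.cohens_d(x, x) == pytest.approx(0.0, abs=0.2)


def test_bh_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(size=40)
    ours = effects.bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, ref, atol=1e-12)


# ----------------------------------------------------------------------- mdFDR


def _alpha_ledger(n=120, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    sids = [f"s{i}" for i in range(n)]
    resp = pd.Series(rng.normal(size=n), index=sids)
    g = pd.Series(rng.permutation(["u"] * (n // 2) + ["v"] * (n - n // 2)),
                  index=sids)
    resp[g == "v"] += shift
    return resp, {"cov": g}


def test_pairwise_effect_sizes_detects_planted_shift():
    resp, groupings = _alpha_ledger(shift=1.0, seed=5)
    ledger = effects.pairwise_effect_sizes(resp, groupings, seed=1)
    assert ledger.selected == ["cov"]
    rec = ledger.records[0]
    assert rec.reject
    assert rec.cohens_d == pytest.approx(1.0, abs=0.35)
    assert rec.direction in ("a>b", "b>a")


def test_pairwise_effect_sizes_null_no_rejection_mostly():
    rejections = 0
    for rep in range(20):
        resp, groupings = _alpha_ledger(shift=0.0, seed=100 + rep)
        ledger = effects.pairwise_effect_sizes(resp, groupings, seed=rep)
        rejections += sum(r.reject for r in ledger.records)
    assert rejections <= 3


def test_pairwise_effect_sizes_beta_response():
    import skbio

    rng = np.random.default_rng(6)
    n = 40
    pts = rng.normal(size=(n, 3))
    labels = np.array(["u"] * (n // 2) + ["v"] * (n // 2))
    pts[labels == "v"] += 2.0
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    sids = [f"s{i}" for i in range(n)]
    dm = skbio.DistanceMatrix(d, ids=sids)
    groupings = {"cov": pd.Series(labels, index=sids)}
    ledger = effects.pairwise_effect_sizes(dm, groupings, seed=2,
                                           permutations=199)
    assert ledger.selected == ["cov"]
    rec = ledger.records[0]
    assert rec.reject and rec.cohens_d > 0.5


def test_skipped_covariate_logged():
    resp, _ = _alpha_ledger(seed=7)
    single = pd.Series("only", index=resp.index)
    ledger = effects.pairwise_effect_sizes(resp, {"c": single}, seed=0)
    assert "c" in ledger.skipped
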