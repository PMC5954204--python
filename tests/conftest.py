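import numpy as np
import pandas as pd
import pytest

from gutkit import synth
from gutkit.io import FeatureTable, SampleMetadata, parse_newick


@pytest.fixture
def tiny_tree():
    """Three-leaf tree used in the hand-computed diversity examples."""
    return parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def tiny_table():
    return FeatureTable(
        pd.DataFrame(
            [[5, 3, 0], [0, 2, 7], [1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture(scope="session")
def calibration_cohort():
    """The calibration study conditions: 400 samples x 150 features,
    20 discriminating features with a 2-fold planted shift."""
    cfg = synth.SimConfig(seed=11)
    tree = synth.simulate_tree(cfg.n_features, cfg.seed)
    table, truth = synth.simulate_counts(cfg, tree)
    md = synth.simulate_metadata(cfg, truth)
    return cfg, tree, table, truth, md


def random_tree(rng, n_leaves):
    """Random binary tree with uniform branch lengths for oracle tests."""
    return synth.simulate_tree(n_leaves, int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# independent brute-force oracles shared by unit and acceptance tests


def branch_leaf_sets(tree):
    """[(branch_length, frozenset(descendant leaves))] for every branch,
    including the root's own stem."""
    out = []
    for node in tree.traverse(include_self=True):
        length = node.length or 0.0
        leaves = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        out.append((length, leaves))
    return out


def brute_faith_pd(present, tree):
    present = set(present)
    return sum(
        b for b, leaves in branch_leaf_sets(tree) if leaves & present
    )


def brute_unweighted_unifrac(set_a, set_b, tree):
    unique = union = 0.0
    for b, leaves in branch_leaf_sets(tree):
        in_a = bool(leaves & set_a)
        in_b = bool(leaves & set_b)
        if in_a or in_b:
            union += b
            if in_a != in_b:
                unique += b
    return unique / union if union else 0.0


def brute_weighted_unifrac(abund_a, abund_b, tree, normalized=False):
    """abund_* map leaf name -> relative abundance."""
    num = den = 0.0
    for b, leaves in branch_leaf_sets(tree):
        pa = sum(abund_a.get(x, 0.0) for x in leaves)
        pb = sum(abund_b.get(x, 0.0) for x in leaves)
        num += b * abs(pa - pb)
        den += b * (pa + pb)
    if not normalized:
        return num
    return num / den if den else 0.0


def brute_auc(pos, neg):
    """Concordant-pair count / (n1 n2), ties counted half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_pseudo_f(d2, labels):
    """PERMANOVA pseudo-F from squared distances, by the textbook
    sum-of-squares decomposition."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))
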