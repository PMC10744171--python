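"""Compositional transforms, diversity indices, distances, PERMANOVA and ICC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.special import comb

from viromix.stats import (bray_curtis, chao1, clr_transform, icc, jaccard,
                           observed_richness, permanova, rarefy, shannon)


# ----------------------------------------------------------------------- CLR

def test_clr_of_equal_counts_is_zero():
    t = pd.DataFrame({"s": [5, 5, 5, 5]})
    assert np.allclose(clr_transform(t, pseudocount=0)["s"], 0)


def test_clr_hand_value_1_3_9():
    t = pd.DataFrame({"s": [1, 3, 9]})
    out = clr_transform(t, pseudocount=0)["s"].to_numpy()
    assert np.allclose(out, [-math.log(3), 0.0, math.log(3)])


def test_clr_columns_sum_to_zero_on_random_tables():
    rng = np.random.default_rng(0)
    t = pd.DataFrame(rng.integers(0, 50, size=(30, 8)).astype(float))
    out = clr_transform(t)  # pseudocount 1 handles the zeros
    assert np.abs(out.sum(axis=0)).max() < 1e-9


def test_clr_zero_counts_need_pseudocount():
    with pytest.raises(ValueError):
        clr_transform(pd.DataFrame({"s": [0, 1]}), pseudocount=0)


# ----------------------------------------------------------- alpha diversity

def test_shannon_uniform_single_and_hand_value():
    assert shannon([3, 3, 3, 3]) == pytest.approx(math.log(4))
    assert shannon([7]) == pytest.approx(0.0)
    p = np.array([5, 1, 1, 2]) / 9
    assert shannon([5, 1, 1, 2]) == pytest.approx(float(-(p * np.log(p)).sum()))
    with pytest.raises(ValueError):
        shannon([0, 0])


def test_shannon_scale_invariant_and_maximal_at_uniform():
    rng = np.random.default_rng(1)
    c = rng.integers(1, 100, size=12)
    assert shannon(c) == pytest.approx(shannon(10 * c))
    assert shannon(c) <= math.log(12) + 1e-12


def test_shannon_agrees_with_skbio():
    c = [5, 1, 1, 2, 0, 9]
    assert shannon(c) == pytest.approx(
        float(skbio.diversity.alpha.shannon(np.array(c), base=math.e)))


def test_chao1_bias_corrected_hand_value():
    # S_obs=4, f1=2, f2=1 -> 4 + 2*1/(2*2) = 4.5
    assert chao1([5, 1, 1, 2]) == pytest.approx(4.5)
    assert chao1([5, 3, 4]) == pytest.approx(3)   # no singletons
    assert chao1([]) == 0
    with pytest.raises(ValueError):
        chao1([1.5, 2])


def test_chao1_at_least_observed_richness_and_matches_skbio():
    rng = np.random.default_rng(2)
    for _ in range(20):
        c = rng.integers(0, 5, size=30)
        assert chao1(c) >= observed_richness(c)
        assert chao1(c) == pytest.approx(
            float(skbio.diversity.alpha.chao1(c, bias_corrected=True)))


# ---------------------------------------------------------------- rarefaction

def test_rarefy_identity_and_depth_one():
    t = pd.DataFrame({"s1": [3, 2, 0], "s2": [1, 1, 3]})
    same = rarefy(t, depth=5, seed=0)
    assert same["s1"].tolist() == [3, 2, 0]
    one = rarefy(t, depth=1, seed=0)
    assert one.sum(axis=0).tolist() == [1, 1]
    with pytest.raises(ValueError):
        rarefy(t, depth=6)
    with pytest.raises(ValueError):
        rarefy(pd.DataFrame({"s": [1.5]}))


def test_rarefied_richness_matches_hypergeometric_closed_form():
    """E[S_rarefied] = sum_i (1 - C(N - N_i, d) / C(N, d))."""
    counts = np.array([40, 25, 10, 4, 1])
    depth = 20
    N = counts.sum()
    expected = float(sum(1 - comb(N - c, depth) / comb(N, depth) for c in counts))
    t = pd.DataFrame({"s": counts})
    sims = [observed_richness(rarefy(t, depth=depth, seed=s)["s"])
            for s in range(1000)]
    mc_se = np.std(sims, ddof=1) / math.sqrt(len(sims))
    assert np.mean(sims) == pytest.approx(expected, abs=4 * mc_se + 1e-9)


# ------------------------------------------------------------------ distances

def test_distance_hand_values_and_bounds():
    t = pd.DataFrame({"u": [2, 2, 0], "v": [0, 2, 2]})
    bc = bray_curtis(t)
    jc = jaccard(t)
    assert bc.loc["u", "v"] == pytest.approx(0.5)
    assert jc.loc["u", "v"] == pytest.approx(1 - 1 / 3)
    for dm in (bc, jc):
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
        assert ((dm.to_numpy() >= 0) & (dm.to_numpy() <= 1)).all()


def test_distance_identical_and_disjoint_and_empty():
    t = pd.DataFrame({"a": [1, 2, 0], "b": [1, 2, 0], "c": [0, 0, 7],
                      "z1": [0, 0, 0], "z2": [0, 0, 0]})
    bc, jc = bray_curtis(t), jaccard(t)
    for dm in (bc, jc):
        assert dm.loc["a", "b"] == 0
        assert dm.loc["a", "c"] == 1
        assert dm.loc["z1", "z2"] == 0   # both empty: defined as identical
        assert dm.loc["a", "z1"] == 1    # empty vs non-empty: maximal


# ------------------------------------------------------------------ PERMANOVA

def _toy_distance(rng, n):
    x = rng.normal(size=(n, 3))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=range(n), columns=range(n))


def _brute_force_f(d2, labels):
    n = len(labels)
    ss_t = d2.sum() / (2 * n)
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def test_permanova_exact_p_matches_enumeration_on_2_plus_2():
    rng = np.random.default_rng(3)
    dm = _toy_distance(rng, 4)
    groups = ["x", "x", "y", "y"]
    res = permanova(dm, groups, n_perm="exact")
    # independent enumeration of all 4!/(2!2!) = 6 distinct labelings
    d2 = dm.to_numpy() ** 2
    f_obs = _brute_force_f(d2, groups)
    fs = []
    seen = set()
    for p in itertools.permutations(groups):
        if p in seen:
            continue
        seen.add(p)
        fs.append(_brute_force_f(d2, list(p)))
    expected_p = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
    assert res["p_value"] == pytest.approx(expected_p)
    assert res["n_permutations"] == 6
    assert res["pseudo_F"] == pytest.approx(f_obs)


def test_permanova_f_matches_skbio():
    rng = np.random.default_rng(4)
    dm = _toy_distance(rng, 10)
    groups = ["x"] * 5 + ["y"] * 5
    res = permanova(dm, groups, n_perm=99)
    sk = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(dm.to_numpy(), ids=[str(i) for i in range(10)]),
        grouping=groups, permutations=99)
    assert res["pseudo_F"] == pytest.approx(float(sk["test statistic"]))


def test_permanova_p_bounds_and_small_group_error():
    rng = np.random.default_rng(5)
    dm = _toy_distance(rng, 8)
    res = permanova(dm, ["x"] * 4 + ["y"] * 4, n_perm=99, seed=1)
    assert 1 / 100 <= res["p_value"] <= 1
    with pytest.raises(ValueError, match="fewer than 2"):
        permanova(dm, ["x"] * 7 + ["y"], n_perm=9)


def test_restricted_permutations_stay_within_households():
    """With one case and one control per household, the restricted scheme
    only swaps labels within pairs: enumeration over 2^3 arrangements."""
    rng = np.random.default_rng(6)
    dm = _toy_distance(rng, 6)
    groups = ["case", "control"] * 3
    households = ["H1", "H1", "H2", "H2", "H3", "H3"]
    res = permanova(dm, groups, n_perm="exact", restriction="within_household",
                    households=households)
    assert res["n_permutations"] == 8
    with pytest.raises(ValueError, match="household"):
        permanova(dm, groups, n_perm=9, restriction="within_household")


def test_permanova_detects_planted_group_separation():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(12, 3))
    x[6:] += 4.0  # strong separation
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    dm = pd.DataFrame(d)
    res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
    assert res["p_value"] <= 0.01


# ------------------------------------------------------------------------ ICC

def test_icc_perfect_household_clustering_is_one():
    values = [1, 1, 5, 5, 9, 9]
    households = ["a", "a", "b", "b", "c", "c"]
    assert icc(values, households) == pytest.approx(1.0)


def test_icc_null_is_near_zero_on_average():
    rng = np.random.default_rng(8)
    households = np.repeat([f"h{i}" for i in range(200)], 2)
    estimates = [icc(rng.normal(size=400), households) for _ in range(400)]
    # truncation at 0 biases single estimates up; the mean must stay small
    assert abs(np.mean(estimates)) < 0.05
    assert np.median(estimates) < 0.02


def test_icc_recovers_variance_ratio():
    """sigma_h=0.8, sigma_e=0.3 -> ICC = 0.64/(0.64+0.09) ~ 0.877."""
    rng = np.random.default_rng(9)
    n_h = 10000
    b = np.repeat(rng.normal(0, 0.8, n_h), 2)
    v = b + rng.normal(0, 0.3, 2 * n_h)
    households = np.repeat([f"h{i}" for i in range(n_h)], 2)
    assert icc(v, households) == pytest.approx(0.64 / 0.73, abs=0.01)


def test_icc_matches_pingouin():
    rng = np.random.default_rng(10)
    n_h = 12
    b = np.repeat(rng.normal(0, 1.0, n_h), 2)
    v = b + rng.normal(0, 0.5, 2 * n_h)
    households = np.repeat([f"h{i:02d}" for i in range(n_h)], 2)
    import pingouin as pg
    df = pd.DataFrame({"target": households, "rater": ["r1", "r2"] * n_h, "y": v})
    ref = pg.intraclass_corr(df, targets="target", raters="rater", ratings="y")
    icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
    assert icc(v, households) == pytest.approx(icc1, abs=1e-6)


def test_icc_requires_multi_member_households():
    with pytest.raises(ValueError):
        icc([1, 2, 3], ["a", "b", "c"])


# ------------------------------------------------------- property-based checks

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=20)
       .filter(lambda c: sum(c) > 0))
def test_clr_rows_sum_to_zero_property(counts):
    out = clr_transform(pd.DataFrame({"s": counts}))
    assert abs(float(out["s"].sum())) < 1e-9


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=30))
def test_chao1_never_below_observed_richness_property(counts):
    assert chao1(counts) >= observed_richness(counts)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=15),
       st.integers(min_value=2, max_value=20))
def test_shannon_scale_invariance_property(counts, factor):
    scaled = [factor * c for c in counts]
    assert shannon(scaled) == pytest.approx(shannon(counts))
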