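"""Quality filtering, pairwise ANI and greedy dereplication."""

import numpy as np
import pytest

from viromix.derep import (Votu, assign_quality_tier, filter_votus,
                           greedy_cluster, pairwise_ani)

from conftest import dp_global_identity, mutate, random_seq


# ---------------------------------------------------------------- quality gate

@pytest.mark.parametrize("completeness,tier", [
    (100, "complete"),
    (95, "high"),
    (90.001, "high"),
    (90, "medium"),      # inclusive upper bound of the 50-90 bracket
    (50, "medium"),
    (49.9, "low"),
    (0, "low"),
    (None, "undetermined"),
])
def test_quality_tier_brackets(completeness, tier):
    assert assign_quality_tier(completeness) == tier


def test_quality_tier_rejects_out_of_range():
    with pytest.raises(ValueError):
        assign_quality_tier(101)
    with pytest.raises(ValueError):
        assign_quality_tier(-1)


def test_filter_retains_only_kilobase_determined_half_complete():
    votus = [
        Votu(id="short", length_bp=900, completeness_pct=95.0),
        Votu(id="undet", length_bp=5000, completeness_pct=None),
        Votu(id="lowq", length_bp=5000, completeness_pct=30.0),
        Votu(id="edge_len", length_bp=1000, completeness_pct=50.0),
        Votu(id="good", length_bp=40000, completeness_pct=100.0),
    ]
    kept = {v.id for v in filter_votus(votus)}
    assert kept == {"edge_len", "good"}
    assert filter_votus([]) == []


def test_negative_length_rejected():
    with pytest.raises(ValueError, match="negative length"):
        Votu(id="bad", length_bp=-5)


# ---------------------------------------------------------------- pairwise ANI

def test_identical_sequences_are_100_100():
    rng = np.random.default_rng(0)
    s = random_seq(rng, 5000)
    r = pairwise_ani(Votu(id="a", sequence=s), Votu(id="b", sequence=s))
    assert r.ani_pct == pytest.approx(100.0)
    assert r.af_pct == pytest.approx(100.0)


def test_exact_prefix_containment_full_af_of_shorter():
    rng = np.random.default_rng(1)
    parent = random_seq(rng, 10000)
    r = pairwise_ani(Votu(id="p", sequence=parent),
                     Votu(id="c", sequence=parent[:9000]))
    assert r.ani_pct == pytest.approx(100.0)
    assert r.af_pct == pytest.approx(100.0)


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_mutated_copy_ani_matches_dp_oracle(seed):
    """2 % substituted copy: ANI ~ 98, agreeing with the exhaustive-DP oracle."""
    rng = np.random.default_rng(seed)
    parent = random_seq(rng, 1500)
    copy = mutate(rng, parent, 0.02)
    r = pairwise_ani(Votu(id="p", sequence=parent), Votu(id="c", sequence=copy))
    oracle_ani, oracle_af = dp_global_identity(parent, copy)
    assert r.ani_pct == pytest.approx(oracle_ani, abs=0.5)
    assert r.af_pct == pytest.approx(oracle_af, abs=1.0)
    assert r.ani_pct == pytest.approx(98.0, abs=1.5)


def test_unrelated_sequences_fail_both_thresholds():
    rng = np.random.default_rng(5)
    a, b = random_seq(rng, 5000), random_seq(rng, 5000)
    r = pairwise_ani(Votu(id="a", sequence=a), Votu(id="b", sequence=b))
    assert r.ani_pct < 95 or r.af_pct < 85
    assert r.af_pct < 85  # random pairs share no long block


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        pairwise_ani(Votu(id="a", sequence=""), Votu(id="b", sequence="ACGT"))


def test_reflexivity_over_random_sequences():
    rng = np.random.default_rng(6)
    for length in (50, 500, 3000):
        s = random_seq(rng, length)
        r = pairwise_ani(Votu(id="x", sequence=s), Votu(id="x", sequence=s))
        assert (r.ani_pct, r.af_pct) == (100.0, 100.0)


# ------------------------------------------------------------ greedy clustering

def _votus_from(seqs: dict[str, str]) -> list[Votu]:
    return [Votu(id=k, sequence=v, completeness_pct=95.0) for k, v in seqs.items()]


def test_single_input_single_cluster():
    cs = greedy_cluster(_votus_from({"only": "ACGT" * 300}))
    assert cs.members == {"only": ["only"]}
    assert cs.representatives == {"only": "only"}


def test_parent_copy_decoy_partition():
    rng = np.random.default_rng(7)
    parent = random_seq(rng, 10000)
    contained = mutate(rng, parent[:9000], 0.02)
    decoy = random_seq(rng, 5000)
    cs = greedy_cluster(_votus_from({"A": parent, "B": contained, "C": decoy}))
    assert cs.as_frozensets() == {frozenset({"A", "B"}), frozenset({"C"})}
    assert cs.representatives["A"] == "A"  # longest member leads


def test_thresholds_must_be_percentages():
    with pytest.raises(ValueError):
        greedy_cluster(_votus_from({"a": "ACGT" * 300}), min_ani=101)


def test_partition_and_representative_maximality():
    rng = np.random.default_rng(8)
    seqs = {}
    for i in range(4):
        p = random_seq(rng, int(rng.integers(1500, 3000)))
        seqs[f"p{i}"] = p
        seqs[f"c{i}"] = mutate(rng, p, 0.02)
    votus = _votus_from(seqs)
    cs = greedy_cluster(votus)
    lengths = {v.id: v.length_bp for v in votus}
    assert sorted(m for ms in cs.members.values() for m in ms) == sorted(seqs)
    for cid, ms in cs.members.items():
        rep = cs.representatives[cid]
        assert rep in ms
        assert all(lengths[m] <= lengths[rep] for m in ms)


def test_raising_thresholds_never_merges_clusters():
    rng = np.random.default_rng(9)
    seqs = {}
    for i in range(3):
        p = random_seq(rng, 2000)
        seqs[f"p{i}"] = p
        seqs[f"c{i}"] = mutate(rng, p, 0.04)  # near the ANI boundary
    votus = _votus_from(seqs)
    n_prev = 0
    for ani in (90, 95, 97, 99):
        n = len(greedy_cluster(votus, min_ani=ani).members)
        assert n >= n_prev
        n_prev = n


def test_greedy_agrees_with_all_pairs_oracle():
    """Exhaustive agglomeration against every representative, re-derived
    independently of the clustering routine's bookkeeping."""
    rng = np.random.default_rng(10)
    seqs = {}
    for i in range(3):
        p = random_seq(rng, int(rng.integers(1500, 2500)))
        seqs[f"p{i}"] = p
        seqs[f"c{i}"] = mutate(rng, p, 0.02)
    for i in range(4):
        seqs[f"d{i}"] = random_seq(rng, int(rng.integers(1500, 2500)))
    votus = _votus_from(seqs)
    cs = greedy_cluster(votus)

    order = sorted(votus, key=lambda v: (-v.length_bp, v.id))
    clusters: list[list[Votu]] = []
    for v in order:
        for cl in clusters:
            r = pairwise_ani(v, cl[0])
            if r.ani_pct >= 95 and r.af_pct >= 85:
                cl.append(v)
                break
        else:
            clusters.append([v])
    oracle = {frozenset(v.id for v in cl) for cl in clusters}
    assert cs.as_frozensets() == oracle
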