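"""Synthetic-data generators: determinism, planted truth, guaranteed margins."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from viromix.config import ConfigError, SimConfig
from viromix.simulate import (build_metadata, gen_abundance, gen_contigs,
                              gen_coverage, gen_host_predictions,
                              gen_vc_membership, write_simulated_inputs)


def _dir_hashes(d):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir())}


def test_identical_seed_gives_byte_identical_files(tmp_path):
    cfg = SimConfig(seed=5)
    write_simulated_inputs(cfg, tmp_path / "a")
    write_simulated_inputs(cfg, tmp_path / "b")
    assert _dir_hashes(tmp_path / "a") == _dir_hashes(tmp_path / "b")


def test_different_seeds_differ(tmp_path):
    write_simulated_inputs(SimConfig(seed=5), tmp_path / "a")
    write_simulated_inputs(SimConfig(seed=6), tmp_path / "b")
    assert _dir_hashes(tmp_path / "a") != _dir_hashes(tmp_path / "b")


def test_metadata_household_pairing():
    md = build_metadata(SimConfig(seed=0))
    assert md["sample_id"].is_unique
    for (_, _), hh in md.groupby(["dataset", "household"]):
        assert (hh["group"] == "case").sum() <= 1
        assert (hh["group"] == "control").sum() <= 1


def test_contig_truth_completeness():
    seqs, ann, truth = gen_contigs(SimConfig(seed=1))
    clustered = set(truth.true_clusters)
    filtered = set(truth.filtered_contigs)
    assert clustered | filtered == set(seqs)
    assert not clustered & filtered
    assert set(ann["contig_id"]) == set(seqs)


def test_identity_copy_at_zero_mutation_rate():
    cfg = SimConfig(seed=2, mutation_rate=0.0)
    seqs, _, truth = gen_contigs(cfg)
    assert seqs["genome_00_mut"] == seqs["genome_00"]
    assert truth.true_clusters["genome_00_mut"] == truth.true_clusters["genome_00"]


def test_high_mutation_rate_separates_clusters():
    cfg = SimConfig(seed=2, mutation_rate=0.12)
    _, _, truth = gen_contigs(cfg)
    assert truth.true_clusters["genome_00_mut"] != truth.true_clusters["genome_00"]


def test_containment_fraction_respected():
    cfg = SimConfig(seed=3, containment_fraction=0.8)
    seqs, _, _ = gen_contigs(cfg)
    assert len(seqs["genome_00_frag"]) == pytest.approx(0.8 * len(seqs["genome_00"]), abs=1)


def test_degenerate_length_range_rejected():
    with pytest.raises(ConfigError, match="contig_length_range"):
        gen_contigs(SimConfig(seed=0, contig_length_range=(3000, 1500)))
    with pytest.raises(ConfigError):
        SimConfig(mutation_rate=0.6).validate()
    with pytest.raises(ConfigError):
        SimConfig(containment_fraction=0.0).validate()
    with pytest.raises(ConfigError):
        SimConfig(n_genera=0).validate()


def test_coverage_margins_and_boundary_probe():
    cfg = SimConfig(seed=4)
    cov, md, truth = gen_coverage(cfg)
    arr = cov.to_numpy()
    # every cell is either safely above or safely below the 10-fold rule,
    # except the single planted boundary probe at exactly 10.0
    at_boundary = (arr == 10.0).sum()
    assert at_boundary == 1
    off = arr[(arr != 10.0)]
    assert ((off > 12.0) | (off < 9.5)).all()
    # planted class structure per dataset
    for ds in ("VLP", "WMS"):
        sub = md[md["dataset"] == ds]
        case = sub.loc[sub["group"] == "case", "sample_id"]
        ctrl = sub.loc[sub["group"] == "control", "sample_id"]
        for votu, cls in truth.true_presence[ds].items():
            pc = (cov.loc[votu, case] > 10).any()
            pk = (cov.loc[votu, ctrl] > 10).any()
            assert {"case_unique": (True, False), "control_unique": (False, True),
                    "communal": (True, True), "absent": (False, False)}[cls] == (pc, pk)


def test_coverage_high_mean_must_exceed_threshold():
    with pytest.raises(ValueError, match="coverage_high_mean"):
        gen_coverage(SimConfig(seed=0, coverage_high_mean=9.0))


def test_host_predictions_plant_one_exclusive_host():
    cfg = SimConfig(seed=5)
    _, _, truth = gen_coverage(cfg)
    preds = gen_host_predictions(cfg, truth)
    assert truth.true_host_class[cfg.planted_exclusive_host] == "exclusively_case"
    exclusive = [h for h, c in truth.true_host_class.items()
                 if c == "exclusively_case"]
    assert exclusive == [cfg.planted_exclusive_host]
    mine = preds[preds["host"] == cfg.planted_exclusive_host]
    assert (mine["confidence"] >= 90).all()
    assert set(mine["votu_id"]) <= {
        v for v, c in truth.true_presence["VLP"].items() if c == "case_unique"}
    # sub-cutoff rows exist so the filter is actually exercised
    assert (preds["confidence"] < 90).any()


def test_host_predictions_require_case_unique_votus():
    cfg = SimConfig(seed=6, planted_case_unique=0)
    _, _, truth = gen_coverage(cfg)
    with pytest.raises(ValueError, match="case-unique"):
        gen_host_predictions(cfg, truth)


def test_vc_membership_partitions_votus():
    cfg = SimConfig(seed=7)
    _, _, truth = gen_coverage(cfg)
    vcs = gen_vc_membership(cfg, truth)
    assert not vcs["votu_id"].duplicated().any()
    assert set(vcs["votu_id"]) == set(truth.true_presence["VLP"])


def test_null_fold_changes_give_zero_paired_difference():
    cfg = SimConfig(seed=8, n_genera=5, fold_changes=(1.0,) * 5,
                    n_households=200, n_case_samples=200, n_control_samples=200)
    counts, md, _ = gen_abundance(cfg)
    diffs = _paired_log_diffs(counts, md)
    assert abs(diffs.mean().mean()) < 0.05


def test_tenfold_genus_shifts_paired_difference_by_one():
    cfg = SimConfig(seed=9, n_genera=3, fold_changes=(10.0, 1.0, 1.0),
                    n_households=400, n_case_samples=400, n_control_samples=400)
    counts, md, truth = gen_abundance(cfg)
    assert truth.true_genus_effects["genus_000"] == 10.0
    diffs = _paired_log_diffs(counts, md)
    assert diffs.loc["genus_000"].mean() == pytest.approx(1.0, abs=0.12)
    assert abs(diffs.loc["genus_001"].mean()) < 0.12


def _paired_log_diffs(counts, md):
    log = np.log10(counts + 1)
    out = {}
    for h, hh in md.groupby("household"):
        case = hh.loc[hh["group"] == "case", "sample_id"]
        ctrl = hh.loc[hh["group"] == "control", "sample_id"]
        if len(case) == 1 and len(ctrl) == 1:
            out[h] = log[case.iloc[0]] - log[ctrl.iloc[0]]
    return pd.DataFrame(out)


def test_abundance_household_icc_matches_variance_ratio():
    """ICC of per-genus log abundance across household members approaches
    sigma_h^2 / (sigma_h^2 + sigma_e^2)."""
    from viromix.stats import icc
    cfg = SimConfig(seed=10, n_genera=40, fold_changes=(1.0,) * 40,
                    n_households=60, n_case_samples=60, n_control_samples=60,
                    sigma_household=0.8, sigma_resid=0.3)
    counts, md, _ = gen_abundance(cfg)
    log = np.log10(counts + 1)
    households = md.set_index("sample_id").loc[list(log.columns), "household"]
    vals = [icc(log.loc[g], households) for g in log.index]
    assert np.mean(vals) == pytest.approx(0.64 / 0.73, abs=0.06)
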