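"""End-to-end pipeline: simulate -> derep -> presence -> match -> hosts -> stats -> power.

``run_all`` executes the stages in dependency order on synthetic inputs,
writing each stage's outputs before the next begins, and consolidates the
headline results — the per-dataset unique/communal Venn partitions (vOTU-
and VC-level), the cross-dataset matches, the host Venn and the
exclusively-case host list, diversity and PERMANOVA/ICC summaries, and the
power curve — into ``report.json``.  A ``manifest.json`` records the master
seed, a config hash and a SHA-256 digest of every emitted file, so a rerun
with the same config is byte-identical and verifiably so.

A stage failure writes a ``FAILED`` marker naming the stage and re-raises;
outputs of completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._io import digest_files, read_fasta, read_tsv, write_json, write_tsv
from .config import PipelineConfig
from .derep import Votu, cluster_table, filter_votus, greedy_cluster
from .hosts import classify_hosts, filter_predictions, top_n_cross_reference, venn_hosts
from .matching import align_votus, hits_from_frame, match_datasets
from .power import PowerSpec, simulate_power
from .presence import classify_by_dataset, classify_vcs
from .simulate import write_simulated_inputs
from .stats import alpha_diversity_table, bray_curtis, icc, jaccard, permanova

__all__ = ["run_all", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_votus(seq_path, ann_path) -> list[Votu]:
    seqs = read_fasta(seq_path)
    ann = read_tsv(ann_path)
    votus = []
    for r in ann.itertuples():
        comp = None if pd.isna(r.completeness) else float(r.completeness)
        votus.append(Votu(id=r.contig_id, dataset_origin=r.dataset,
                          sequence=seqs[r.contig_id], completeness_pct=comp))
    return votus


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a fresh synthetic dataset; return the report dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.sim.seed}
    emitted: list[Path] = []
    stage = "simulate"
    try:
        # ------------------------------------------------------------ simulate
        paths = write_simulated_inputs(config.sim, outdir / "inputs")
        emitted += list(paths.values())
        truth = json.loads(Path(paths["truth"]).read_text())

        # --------------------------------------------------------------- derep
        stage = "derep"
        votus = _load_votus(paths["contigs"], paths["annotations"])
        kept = filter_votus(votus, config.min_length, config.min_completeness)
        by_ds = {"VLP": [v for v in kept if v.dataset_origin == "VLP"],
                 "WMS": [v for v in kept if v.dataset_origin == "WMS"]}
        clusters = {}
        derep_rows = []
        for ds, vs in by_ds.items():
            cs = greedy_cluster(vs, config.min_ani, config.min_af)
            clusters[ds] = cs
            for row in cluster_table(cs):
                derep_rows.append({"dataset": ds, **row})
        derep_path = outdir / "derep_clusters.tsv"
        write_tsv(pd.DataFrame(derep_rows), derep_path)
        emitted.append(derep_path)
        report["derep"] = {
            "n_input_contigs": len(votus),
            "n_after_quality_filter": len(kept),
            "n_clusters": {ds: len(cs.members) for ds, cs in clusters.items()},
        }

        # ------------------------------------------------------------ presence
        stage = "presence"
        coverage = read_tsv(paths["coverage"], index_col=0)
        metadata = read_tsv(paths["metadata"])
        pcs = classify_by_dataset(coverage, metadata, config.coverage_threshold)
        class_rows = [{"dataset": ds, "votu_id": v, "presence_class": c}
                      for ds, pc in sorted(pcs.items())
                      for v, c in sorted(pc.votu_class.items())]
        pres_path = outdir / "presence_classes.tsv"
        write_tsv(pd.DataFrame(class_rows), pres_path)
        emitted.append(pres_path)
        vc_df = read_tsv(paths["vc_membership"])
        vc_class, vc_venn = classify_vcs(pcs["VLP"], vc_df)
        report["presence"] = {
            "votu_venn": {ds: pc.venn() for ds, pc in sorted(pcs.items())},
            "vc_venn": vc_venn,
        }

        # --------------------------------------------------------------- match
        stage = "match"
        seqs = read_fasta(paths["contigs"])
        reps = {ds: {r: seqs[r] for r in clusters[ds].representatives}
                for ds in ("VLP", "WMS")}
        hit_df = align_votus(reps["WMS"], reps["VLP"])
        hits_path = outdir / "cross_dataset_hits.tsv"
        hit_df.to_csv(hits_path, sep="\t", header=False, index=False)
        emitted.append(hits_path)
        pairs, match_summary = match_datasets(
            list(reps["WMS"]), list(reps["VLP"]), hits_from_frame(hit_df),
            max_evalue=config.max_evalue, min_bitscore=config.min_bitscore,
            min_pident=config.min_pident, min_qcovs=config.min_qcovs)
        pairs_path = outdir / "matched_pairs.tsv"
        write_tsv(pd.DataFrame(pairs, columns=["wms_id", "vlp_id"]), pairs_path)
        emitted.append(pairs_path)
        report["match"] = {**match_summary, "pairs": [list(p) for p in pairs]}

        # --------------------------------------------------------------- hosts
        stage = "hosts"
        preds = read_tsv(paths["host_predictions"])
        preds_kept = filter_predictions(preds, config.min_confidence)
        host_classes = classify_hosts(preds_kept, pcs)
        hc_rows = [{"host": hc.host_taxon, "dataset": hc.dataset, "label": hc.label,
                    "linked_classes": ",".join(hc.linked_classes)}
                   for hc in host_classes]
        hosts_path = outdir / "host_classes.tsv"
        write_tsv(pd.DataFrame(hc_rows), hosts_path)
        emitted.append(hosts_path)
        _, host_venn = venn_hosts(
            {hc.host_taxon for hc in host_classes if hc.dataset == "VLP"},
            {hc.host_taxon for hc in host_classes if hc.dataset == "WMS"})
        abundance = read_tsv(paths["abundance"], index_col=0)
        top_tbl = top_n_cross_reference(host_classes, abundance, metadata,
                                        n=min(config.top_n_genera, len(abundance)))
        top_path = outdir / "top_genera_host_classes.tsv"
        write_tsv(top_tbl, top_path)
        emitted.append(top_path)
        report["hosts"] = {
            "host_venn": host_venn,
            "exclusively_case": sorted({hc.host_taxon for hc in host_classes
                                        if hc.label == "exclusively_case"}),
        }

        # --------------------------------------------------------------- stats
        stage = "stats"
        wms_md = metadata[metadata["dataset"] == "WMS"].reset_index(drop=True)
        alpha = alpha_diversity_table(abundance, seed=config.sim.seed)
        alpha_path = outdir / "alpha_diversity.tsv"
        write_tsv(alpha, alpha_path)
        emitted.append(alpha_path)
        bc = bray_curtis(abundance)
        jc = jaccard(abundance)
        for name, dm in (("bray_curtis", bc), ("jaccard", jc)):
            p = outdir / f"distance_{name}.tsv"
            write_tsv(dm, p, index=True)
            emitted.append(p)
        md_idx = wms_md.set_index("sample_id").loc[list(bc.columns)]
        perm = permanova(bc, md_idx["group"], n_perm=config.n_permutations,
                         restriction=config.permutation_restriction,
                         households=md_idx["household"], seed=config.sim.seed)
        alpha_by_sample = alpha.set_index("sample_id").loc[list(bc.columns)]
        icc_rich = icc(alpha_by_sample["observed_richness_rarefied"], md_idx["household"])
        icc_chao = icc(alpha_by_sample["chao1"], md_idx["household"])
        # per-genus abundance ICC across household members, averaged
        logab = np.log10(abundance[list(bc.columns)] + 1)
        genus_iccs = [icc(logab.loc[g], md_idx["household"])
                      for g in logab.index if logab.loc[g].std() > 0]
        report["stats"] = {
            "permanova_group": perm,
            "icc_observed_richness": icc_rich,
            "icc_chao1": icc_chao,
            "mean_genus_abundance_icc": float(np.mean(genus_iccs)),
            "mean_shannon": float(alpha["shannon"].mean()),
        }

        # --------------------------------------------------------------- power
        stage = "power"
        spec = PowerSpec(fold_change=config.power_fold_change, alpha=config.alpha,
                         target_power=config.target_power,
                         n_pairs_grid=tuple(config.power_grid),
                         sigma_household=config.sim.sigma_household,
                         sigma_resid=config.sim.sigma_resid,
                         n_sims=config.power_sims, seed=config.sim.seed)
        pr = simulate_power(spec)
        power_path = outdir / "power_curve.tsv"
        write_tsv(pd.DataFrame(pr.as_rows()), power_path)
        emitted.append(power_path)
        report["power"] = {
            "fold_change": spec.fold_change,
            "alpha": spec.alpha,
            "curve": {str(n): pr.power[n] for n in sorted(pr.power)},
            "minimal_n_on_grid": pr.minimal_n,
        }

        # -------------------------------------------------------------- report
        stage = "report"
        report_path = outdir / "report.json"
        write_json(report, report_path)
        emitted.append(report_path)
        manifest = {
            "tool": f"viromix {__version__}",
            "master_seed": config.sim.seed,
            "config_sha256": _config_hash(config),
            "files": digest_files(emitted),
        }
        write_json(manifest, outdir / "manifest.json")
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        raise StageError(stage, e) from e
    return report
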