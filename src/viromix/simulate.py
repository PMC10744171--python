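"""Synthetic-data generator with planted ground truth.

Every input the pipeline consumes can be generated here under a single
master seed: contig sets with planted redundancy (mutated and contained
copies of parent genomes among random decoys), household-structured sample
metadata for two sequencing routes (virus-particle-enriched VLP metagenomes
and bulk WMS whole metagenomes), coverage matrices with planted
case-unique / control-unique / communal viruses, host-prediction tables
with one planted exclusively-case-associated host, and log-normal genus
abundance tables with explicit between/within-household variance components
and per-genus fold-change effects.

Ground truth for every planted feature is recorded in :class:`TruthTables`,
so each downstream stage can be checked for exact recovery.

Randomness: each generator operation draws from its own stream, derived
from the master seed by a fixed offset — adding or re-running one generator
never perturbs another's output, and a fixed seed gives byte-identical
files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._io import write_fasta, write_json, write_tsv
from .config import SimConfig

__all__ = [
    "TruthTables", "build_metadata", "gen_contigs", "gen_coverage",
    "gen_host_predictions", "gen_abundance", "gen_vc_membership",
    "write_simulated_inputs",
]

_BASES = np.array(list("ACGT"))
# fixed per-operation stream offsets (see module docstring)
_STREAMS = {"contigs": 1, "coverage": 2, "hosts": 3, "abundance": 4, "vc": 5}

PRESENCE_CLASSES = ("case_unique", "control_unique", "communal", "absent")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


@dataclass
class TruthTables:
    """Planted ground truth for everything the generators emit."""

    true_clusters: dict[str, str] = field(default_factory=dict)        # contig -> cluster id
    filtered_contigs: list[str] = field(default_factory=list)          # removed by QC gate
    contig_dataset: dict[str, str] = field(default_factory=dict)       # contig -> VLP|WMS
    true_cross_matches: list[tuple[str, str]] = field(default_factory=list)  # (wms, vlp)
    true_presence: dict[str, dict[str, str]] = field(default_factory=dict)   # dataset -> votu -> class
    true_host_class: dict[str, str] = field(default_factory=dict)      # host -> label
    true_genus_effects: dict[str, float] = field(default_factory=dict)  # genus -> fold change

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_cross_matches"] = [list(p) for p in self.true_cross_matches]
        return d


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

def build_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Sample sheet: one case and one control member per household, per dataset.

    Columns: sample_id, group, household, dataset.  Case sample i and control
    sample i of the same dataset share household H<i mod n_households>, which
    is what makes the design household-matched.
    """
    rows = []
    for ds in ("VLP", "WMS"):
        for grp, n, tag in (("case", cfg.n_case_samples, "M"),
                            ("control", cfg.n_control_samples, "C")):
            for i in range(n):
                rows.append({
                    "sample_id": f"{ds}_{tag}{i + 1:02d}",
                    "group": grp,
                    "household": f"H{(i % cfg.n_households) + 1:02d}",
                    "dataset": ds,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contigs with planted redundancy
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])

def _mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point substitutions at the given per-site rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    base_idx = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    for i in hit:
        shift = rng.integers(1, 4)
        arr[i] = _BASES[(base_idx[bytes(arr[i])] + shift) % 4].encode()
    return arr.tobytes().decode()


def gen_contigs(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame, TruthTables]:
    """Contig set with planted redundancy for the dereplication stage.

    Emits, per parent genome: the parent, a point-mutated full-length copy,
    and a contained fragment (``containment_fraction`` of the parent, then
    mutated); remaining contigs are i.i.d. random decoys.  The first
    ``planted_cross_matches`` parents additionally get a verbatim copy
    assigned to the opposite dataset, which is what the cross-dataset
    matching stage must recover.  ``n_filter_decoys`` extra contigs violate
    the quality gate (sub-kilobase, undetermined or low completeness) and
    must be removed by filtering.

    At ``mutation_rate`` <= 0.03 derived copies are guaranteed to co-cluster
    with their parent at the 95 % ANI / 85 % AF thresholds; at >= 0.10 they
    are guaranteed to separate.  Truth records co-clustering for rates
    <= 0.03 and separation otherwise.  Contig ids are chosen so that under
    length-then-id ordering the parent founds its cluster and serves as the
    representative (derived copies carry an id suffix): every derived contig
    is then compared against the parent itself, keeping its divergence from
    the representative at the single mutation rate rather than the doubled
    copy-to-copy divergence, which is what makes the margin a guarantee.

    Returns (sequences, annotation table, truth).  Annotation columns:
    contig_id, dataset, completeness (empty = undetermined).
    """
    cfg.validate()
    rng = _rng(cfg, "contigs")
    lo, hi = cfg.contig_length_range

    n = cfg.n_contigs
    n_parents = max(1, (n + 3) // 4)
    n_copies = min(n_parents, max(0, n - n_parents))
    n_frags = min(n_parents, max(0, n - n_parents - n_copies))
    n_decoys = max(0, n - n_parents - n_copies - n_frags)

    seqs: dict[str, str] = {}
    ann_rows = []
    truth = TruthTables()
    co_cluster = cfg.mutation_rate <= 0.03

    def add(cid: str, seq: str, ds: str, completeness, cluster: str | None):
        seqs[cid] = seq
        ann_rows.append({"contig_id": cid, "dataset": ds,
                         "completeness": completeness})
        truth.contig_dataset[cid] = ds
        if cluster is not None:
            truth.true_clusters[cid] = cluster

    parents = []
    for i in range(n_parents):
        ds = "VLP" if i % 2 == 0 else "WMS"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        pid = f"genome_{i:02d}"
        add(pid, seq, ds, round(float(rng.uniform(55, 100)), 1), pid)
        parents.append((pid, seq, ds))

    for i in range(n_copies):
        pid, pseq, ds = parents[i]
        cid = f"genome_{i:02d}_mut"
        seq = _mutate_seq(rng, pseq, cfg.mutation_rate)
        add(cid, seq, ds, round(float(rng.uniform(55, 100)), 1),
            pid if co_cluster else cid)

    for i in range(n_frags):
        pid, pseq, ds = parents[i]
        cid = f"genome_{i:02d}_frag"
        cut = int(round(cfg.containment_fraction * len(pseq)))
        start = int(rng.integers(0, len(pseq) - cut + 1))
        seq = _mutate_seq(rng, pseq[start:start + cut], cfg.mutation_rate)
        add(cid, seq, ds, round(float(rng.uniform(55, 100)), 1),
            pid if co_cluster else cid)

    for i in range(n_decoys):
        ds = "VLP" if i % 2 == 0 else "WMS"
        cid = f"decoy_{i:02d}"
        add(cid, _random_seq(rng, int(rng.integers(lo, hi + 1))), ds,
            round(float(rng.uniform(55, 100)), 1), cid)

    # verbatim cross-dataset copies of the first parents
    for i in range(min(cfg.planted_cross_matches, n_parents)):
        pid, pseq, ds = parents[i]
        other = "WMS" if ds == "VLP" else "VLP"
        cid = f"genome_{i:02d}_x"
        add(cid, pseq, other, round(float(rng.uniform(55, 100)), 1), pid)
        pair = (cid, pid) if other == "WMS" else (pid, cid)
        truth.true_cross_matches.append(pair)

    # quality-gate decoys: short / undetermined / low completeness, cycled
    for i in range(cfg.n_filter_decoys):
        cid = f"qcdecoy_{i:02d}"
        kind = i % 3
        if kind == 0:
            add(cid, _random_seq(rng, int(rng.integers(200, 999))), "VLP", 95.0, None)
        elif kind == 1:
            add(cid, _random_seq(rng, int(rng.integers(lo, hi + 1))), "WMS", None, None)
        else:
            add(cid, _random_seq(rng, int(rng.integers(lo, hi + 1))), "VLP", 30.0, None)
        truth.filtered_contigs.append(cid)

    ann = pd.DataFrame(ann_rows)
    return seqs, ann, truth


# ---------------------------------------------------------------------------
# coverage matrices with planted presence classes
# ---------------------------------------------------------------------------

def gen_coverage(cfg: SimConfig, metadata: pd.DataFrame | None = None,
                 truth: TruthTables | None = None, threshold: float = 10.0,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """vOTU x sample average fold-coverage matrix with planted classes.

    The first ``planted_case_unique`` vOTUs exceed the presence threshold in
    at least one case sample and in no control sample (per dataset);
    control-unique vOTUs are symmetric; communal vOTUs exceed it in at least
    one sample of each group; all remaining vOTUs stay below threshold
    everywhere.  Planted-present cells are drawn from a log-normal truncated
    strictly above ``threshold + 2`` and background cells strictly below
    ``threshold - 0.5``, so recovery under the strict 'over threshold' rule
    is guaranteed.  One background cell of the first absent vOTU is set to
    exactly ``threshold`` as a boundary probe: under the strict rule it must
    not count as present.
    """
    cfg.validate()
    if cfg.coverage_high_mean <= threshold:
        raise ValueError(
            f"coverage_high_mean {cfg.coverage_high_mean} must exceed the presence "
            f"threshold {threshold} to guarantee planted presence")
    rng = _rng(cfg, "coverage")
    if metadata is None:
        metadata = build_metadata(cfg)
    truth = truth or TruthTables()

    votus = [f"votu_{i:04d}" for i in range(cfg.n_votus)]
    classes = (["case_unique"] * cfg.planted_case_unique
               + ["control_unique"] * cfg.planted_control_unique
               + ["communal"] * cfg.planted_communal)
    classes += ["absent"] * (cfg.n_votus - len(classes))

    samples = metadata["sample_id"].tolist()
    cov = pd.DataFrame(0.0, index=votus, columns=samples)

    def draw_high() -> float:
        while True:
            x = float(rng.lognormal(np.log(cfg.coverage_high_mean), 0.5))
            if x > threshold + 2:
                return round(x, 3)

    def draw_low() -> float:
        while True:
            x = float(rng.lognormal(np.log(cfg.coverage_low_mean), 0.5))
            if x < threshold - 0.5:
                return round(x, 3)

    for ds in ("VLP", "WMS"):
        md = metadata[metadata["dataset"] == ds]
        case_samples = md.loc[md["group"] == "case", "sample_id"].tolist()
        ctrl_samples = md.loc[md["group"] == "control", "sample_id"].tolist()
        truth.true_presence.setdefault(ds, {})
        for votu, cls in zip(votus, classes):
            truth.true_presence[ds][votu] = cls
            high_in: list[str] = []
            if cls in ("case_unique", "communal"):
                k = int(rng.integers(1, len(case_samples) + 1))
                high_in += list(rng.choice(case_samples, size=k, replace=False))
            if cls in ("control_unique", "communal"):
                k = int(rng.integers(1, len(ctrl_samples) + 1))
                high_in += list(rng.choice(ctrl_samples, size=k, replace=False))
            for s in md["sample_id"]:
                cov.loc[votu, s] = draw_high() if s in high_in else (
                    draw_low() if rng.random() < 0.5 else 0.0)

    # boundary probe: exactly-threshold coverage must read as NOT present
    absent = [v for v, c in zip(votus, classes) if c == "absent"]
    if absent:
        cov.loc[absent[0], samples[0]] = float(threshold)

    cov.index.name = "votu_id"
    return cov, metadata, truth


# ---------------------------------------------------------------------------
# host predictions with one planted exclusively-case host
# ---------------------------------------------------------------------------

_DECOY_PATTERNS = (
    "communal_only", "case_associated", "control_associated",
    "mixed", "exclusively_control", "near_miss",
)


def gen_host_predictions(cfg: SimConfig, truth: TruthTables,
                         min_confidence: float = 90.0) -> pd.DataFrame:
    """Host-prediction table exercising the confidence filter and host classes.

    The planted exclusive host links only to case-unique vOTUs, at high
    confidence, in the VLP dataset — the pattern of a bacterium associated
    solely with disease-unique viruses.  Decoy hosts cycle through the other
    association patterns in both datasets, including a 'near miss' whose only
    case-unique link sits just below the confidence cutoff (so the filter,
    not luck, determines the outcome).  Columns: votu_id, host, confidence,
    dataset.
    """
    if not truth.true_presence:
        raise ValueError("generate coverage truth before host predictions")
    rng = _rng(cfg, "hosts")

    def pool(ds: str, cls: str) -> list[str]:
        return sorted(v for v, c in truth.true_presence[ds].items() if c == cls)

    if not pool("VLP", "case_unique"):
        raise ValueError("planted exclusive host requires case-unique vOTUs; none planted")

    rows = []

    def link(host: str, ds: str, cls: str, conf: float, k: int = 1):
        vs = pool(ds, cls)
        pick = rng.choice(vs, size=min(k, len(vs)), replace=False)
        for v in pick:
            rows.append({"votu_id": v, "host": host,
                         "confidence": round(float(conf), 1), "dataset": ds})

    # the planted pattern: case-unique links only, high confidence, VLP
    link(cfg.planted_exclusive_host, "VLP", "case_unique",
         rng.uniform(min_confidence + 2, 99), k=3)
    truth.true_host_class[cfg.planted_exclusive_host] = "exclusively_case"

    hi = lambda: rng.uniform(min_confidence + 1, 99)
    lo_conf = lambda: rng.uniform(50, min_confidence - 1)
    for i in range(max(0, cfg.n_hosts - 1)):
        host = f"host_{i:02d}"
        pattern = _DECOY_PATTERNS[i % len(_DECOY_PATTERNS)]
        # every third decoy is predicted in both datasets (a 'shared' host)
        datasets = ("VLP", "WMS") if i % 3 == 0 else (("VLP", "WMS")[i % 2],)
        for ds in datasets:
            if pattern == "communal_only":
                link(host, ds, "communal", hi(), k=2)
            elif pattern == "case_associated":
                link(host, ds, "case_unique", hi())
                link(host, ds, "communal", hi())
            elif pattern == "control_associated":
                link(host, ds, "control_unique", hi())
                link(host, ds, "communal", hi())
            elif pattern == "mixed":
                link(host, ds, "case_unique", hi())
                link(host, ds, "control_unique", hi())
            elif pattern == "exclusively_control":
                link(host, ds, "control_unique", hi(), k=2)
            else:  # near_miss: case link below cutoff + communal link above
                link(host, ds, "case_unique", lo_conf())
                link(host, ds, "communal", hi())
        truth.true_host_class[host] = (
            "communal_only" if pattern == "near_miss" else pattern)
        # sub-cutoff noise links that the filter must drop
        if i % 3 == 1:
            link(host, datasets[0], "communal", lo_conf())

    df = pd.DataFrame(rows, columns=["votu_id", "host", "confidence", "dataset"])
    return df.sort_values(["host", "dataset", "votu_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# household-structured genus abundances
# ---------------------------------------------------------------------------

def gen_abundance(cfg: SimConfig, metadata: pd.DataFrame | None = None,
                  truth: TruthTables | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """Genus count table with household random intercepts and fold-change effects.

    For genus g in sample s of household h:

        log10 count = mu_g + b_{g,h} + delta_g * I(s is case) + eps,
        b_{g,h} ~ N(0, sigma_household^2),  eps ~ N(0, sigma_resid^2),
        delta_g = log10(fold_change_g)

    The household intercept is drawn per (genus, household), so each genus
    carries its own household signature and its log abundance has intraclass
    correlation sigma_household^2 / (sigma_household^2 + sigma_resid^2)
    across household members.  Counts are obtained by exponentiation and
    half-up rounding; genus baselines mu_g span low to high abundance, so
    rare genera drop to zero counts in some samples and observed richness
    varies.  Samples are the WMS arm of the cohort (the bacteriome is
    profiled from the whole metagenome).  Truth records the fold change per
    genus.
    """
    cfg.validate()
    rng = _rng(cfg, "abundance")
    if metadata is None:
        metadata = build_metadata(cfg)
    truth = truth or TruthTables()
    md = metadata[metadata["dataset"] == "WMS"].reset_index(drop=True)

    genera = [f"genus_{i:03d}" for i in range(cfg.n_genera)]
    fold = cfg.genus_fold_changes()
    delta = np.log10(fold)
    mu = rng.uniform(0.0, 3.5, size=cfg.n_genera)
    households = sorted(md["household"].unique())
    b = pd.DataFrame(
        rng.normal(0, cfg.sigma_household, (cfg.n_genera, len(households))),
        index=genera, columns=households)

    counts = pd.DataFrame(0, index=genera, columns=md["sample_id"].tolist(), dtype=int)
    for _, row in md.iterrows():
        is_case = row["group"] == "case"
        eps = rng.normal(0, cfg.sigma_resid, cfg.n_genera)
        logx = mu + b[row["household"]].to_numpy() + delta * is_case + eps
        counts[row["sample_id"]] = np.floor(10.0 ** logx + 0.5).astype(np.int64)

    truth.true_genus_effects = dict(zip(genera, map(float, fold)))
    counts.index.name = "genus"
    return counts, md, truth


# ---------------------------------------------------------------------------
# viral-cluster membership (consumed, not computed, by the pipeline)
# ---------------------------------------------------------------------------

def gen_vc_membership(cfg: SimConfig, truth: TruthTables,
                      dataset: str = "VLP") -> pd.DataFrame:
    """Group vOTUs into viral clusters (VCs) of up to three same-class members.

    Gene-sharing-network clustering is upstream of this pipeline; membership
    is simulated instead.  Same-class vOTUs are chunked into VCs, then the
    last case-unique VC and the last communal VC are merged into one mixed VC
    so that the 'any non-case member breaks uniqueness' rule is exercised.
    """
    pres = truth.true_presence[dataset]
    rows = []
    vc_n = 0
    chunks_by_class: dict[str, list[list[str]]] = {}
    for cls in PRESENCE_CLASSES:
        members = sorted(v for v, c in pres.items() if c == cls)
        chunks = [members[i:i + 3] for i in range(0, len(members), 3)]
        chunks_by_class[cls] = chunks
    # merge one case-unique chunk with one communal chunk -> a 'shared' VC
    if chunks_by_class["case_unique"] and chunks_by_class["communal"]:
        mixed = chunks_by_class["case_unique"].pop() + chunks_by_class["communal"].pop()
        chunks_by_class.setdefault("mixed", []).append(mixed)
    for cls in list(PRESENCE_CLASSES) + ["mixed"]:
        for chunk in chunks_by_class.get(cls, []):
            vc_n += 1
            for v in chunk:
                rows.append({"votu_id": v, "vc_id": f"VC_{vc_n:04d}"})
    return pd.DataFrame(rows).sort_values("votu_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulated_inputs(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir`` and return the paths.

    Files: contigs.fasta, contig_annotations.tsv, metadata.tsv, coverage.tsv,
    host_predictions.tsv, abundance.tsv, vc_membership.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, ann, truth = gen_contigs(cfg)
    cov, metadata, truth = gen_coverage(cfg, truth=truth)
    preds = gen_host_predictions(cfg, truth)
    counts, _, truth = gen_abundance(cfg, metadata, truth)
    vcs = gen_vc_membership(cfg, truth)

    paths = {
        "contigs": outdir / "contigs.fasta",
        "annotations": outdir / "contig_annotations.tsv",
        "metadata": outdir / "metadata.tsv",
        "coverage": outdir / "coverage.tsv",
        "host_predictions": outdir / "host_predictions.tsv",
        "abundance": outdir / "abundance.tsv",
        "vc_membership": outdir / "vc_membership.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(seqs, paths["contigs"])
    write_tsv(ann, paths["annotations"])
    write_tsv(metadata, paths["metadata"])
    write_tsv(cov, paths["coverage"], index=True)
    write_tsv(preds, paths["host_predictions"])
    write_tsv(counts, paths["abundance"], index=True)
    write_tsv(vcs, paths["vc_membership"])
    write_json(truth.to_json(), paths["truth"])
    return paths
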