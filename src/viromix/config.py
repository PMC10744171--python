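"""Configuration objects for the synthetic-data generator and the pipeline.

Two dataclasses carry all tunables:

* :class:`SimConfig` — the synthetic study conditions (cohort layout, planted
  effects, noise levels).  Its defaults define the conditions every
  downstream stage is exercised under.
* :class:`PipelineConfig` — the analysis thresholds.  Defaults are the
  published values of the study the pipeline re-implements (95 % ANI over
  85 % aligned fraction, 1 kbp / 50 % completeness quality gate, 10-fold
  coverage presence rule, the 1e-5 / 1000 / 95 / 85 identity cascade, host
  confidence >= 90, alpha = 0.001 and 90 % target power), so a zero-argument
  run reproduces the published analysis settings.

Configs load from YAML or JSON; unknown keys are rejected and every invalid
field is reported, not just the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised with the exhaustive list of configuration problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    The cohort emulates a small household-matched case/control design with
    two sequencing routes per sample (a virus-particle-enriched 'VLP'
    metagenome and a bulk 'WMS' whole metagenome).
    """

    seed: int = 0

    # -- contig generator (dereplication stage) -----------------------------
    n_contigs: int = 16
    contig_length_range: tuple[int, int] = (1500, 3000)
    mutation_rate: float = 0.02
    containment_fraction: float = 0.9
    n_filter_decoys: int = 2          # short / undetermined contigs removed by QC
    planted_cross_matches: int = 3    # parents copied verbatim into both datasets

    # -- cohort layout ------------------------------------------------------
    n_households: int = 6
    n_case_samples: int = 6           # per dataset
    n_control_samples: int = 6        # per dataset

    # -- coverage matrix (presence stage) -----------------------------------
    n_votus: int = 200
    planted_case_unique: int = 30
    planted_control_unique: int = 30
    planted_communal: int = 60
    coverage_high_mean: float = 50.0  # fold-coverage of planted-present cells
    coverage_low_mean: float = 2.0    # fold-coverage of background cells

    # -- host predictions ---------------------------------------------------
    n_hosts: int = 10
    planted_exclusive_host: str = "Anaerotruncus"

    # -- genus abundances (stats / power stages) ----------------------------
    n_genera: int = 30
    sigma_household: float = 0.8      # between-household SD, log10 scale
    sigma_resid: float = 0.5          # within-household residual SD, log10 scale
    fold_changes: tuple[float, ...] | None = None  # None -> one 10-fold genus, rest null

    def validate(self) -> "SimConfig":
        p: list[str] = []
        lo, hi = self.contig_length_range
        if lo > hi:
            p.append(f"contig_length_range min {lo} > max {hi}")
        if lo < 1:
            p.append("contig lengths must be positive")
        if not 0 <= self.mutation_rate < 0.5:
            p.append(f"mutation_rate {self.mutation_rate} outside [0, 0.5)")
        if not 0 < self.containment_fraction <= 1:
            p.append(f"containment_fraction {self.containment_fraction} outside (0, 1]")
        planted = self.planted_case_unique + self.planted_control_unique + self.planted_communal
        if planted > self.n_votus:
            p.append(f"planted classes ({planted}) exceed n_votus ({self.n_votus})")
        if min(self.planted_case_unique, self.planted_control_unique, self.planted_communal) < 0:
            p.append("planted counts must be non-negative")
        if self.n_households < 2:
            p.append("n_households must be >= 2")
        if self.n_case_samples < 1 or self.n_control_samples < 1:
            p.append("need at least one case and one control sample per dataset")
        if self.sigma_household < 0 or self.sigma_resid < 0:
            p.append("variance components must be >= 0")
        if self.n_genera <= 0:
            p.append("n_genera must be positive")
        if self.n_contigs < 1:
            p.append("n_contigs must be >= 1")
        if self.fold_changes is not None and len(self.fold_changes) != self.n_genera:
            p.append("fold_changes length must equal n_genera")
        if p:
            raise ConfigError(p)
        return self

    def genus_fold_changes(self) -> tuple[float, ...]:
        """Resolved per-genus fold changes (default: genus 0 at 10-fold, rest null)."""
        if self.fold_changes is not None:
            return tuple(self.fold_changes)
        return (10.0,) + (1.0,) * (self.n_genera - 1)


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the published analysis settings."""

    # dereplication / quality gate
    min_ani: float = 95.0
    min_af: float = 85.0
    min_length: int = 1000
    min_completeness: float = 50.0
    # presence calling
    coverage_threshold: float = 10.0
    # cross-dataset identity cascade
    max_evalue: float = 1e-5
    min_bitscore: float = 1000.0
    min_pident: float = 95.0
    min_qcovs: float = 85.0
    # host association
    min_confidence: float = 90.0
    top_n_genera: int = 20
    # statistics
    n_permutations: int = 199
    permutation_restriction: str = "within_household"  # or "none"
    # power simulation
    alpha: float = 0.001
    target_power: float = 0.90
    power_fold_change: float = 10.0
    power_grid: tuple[int, ...] = (5, 10, 15, 20, 30)
    power_sims: int = 400

    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> "PipelineConfig":
        p: list[str] = []
        for name in ("min_ani", "min_af", "min_pident", "min_qcovs", "min_completeness",
                     "min_confidence"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                p.append(f"{name} {v} outside [0, 100]")
        if self.coverage_threshold < 0:
            p.append(f"coverage_threshold {self.coverage_threshold} must be >= 0")
        if self.min_length < 0:
            p.append("min_length must be >= 0")
        if self.max_evalue < 0 or self.min_bitscore < 0:
            p.append("evalue/bitscore cutoffs must be >= 0")
        if not 0 < self.alpha < 1:
            p.append(f"alpha {self.alpha} outside (0, 1)")
        if not 0 < self.target_power < 1:
            p.append(f"target_power {self.target_power} outside (0, 1)")
        if self.permutation_restriction not in ("none", "within_household"):
            p.append(f"unknown permutation_restriction {self.permutation_restriction!r}")
        if list(self.power_grid) != sorted(set(self.power_grid)) or (
                self.power_grid and self.power_grid[0] < 2):
            p.append("power_grid must be strictly increasing with minimum >= 2")
        if p:
            raise ConfigError(p)
        try:
            self.sim.validate()
        except ConfigError as e:
            raise ConfigError([f"sim.{q}" for q in e.problems]) from None
        return self


def _from_mapping(cls, data: dict, prefix: str = ""):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ConfigError([f"unknown key {prefix}{k!r}" for k in sorted(unknown)])
    kwargs = {}
    for k, v in data.items():
        if k == "sim" and isinstance(v, dict):
            v = _from_mapping(SimConfig, v, prefix="sim.")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config from YAML/JSON.

    An absent or empty file yields the fully defaulted (published-settings)
    configuration. ``overrides`` is merged on top of the file contents.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw) if raw.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"config root must be a mapping, got {type(loaded).__name__}"])
        data = loaded
    if overrides:
        overrides = dict(overrides)
        if isinstance(overrides.get("sim"), dict):
            overrides["sim"] = {**data.get("sim", {}), **overrides["sim"]}
        data = {**data, **overrides}
    cfg = _from_mapping(PipelineConfig, data)
    return cfg.validate()
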