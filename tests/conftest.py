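"""Shared fixtures and independent oracles.

The DP-alignment oracle here is deliberately independent of the package's
edlib-based aligner: it uses Biopython's exhaustive global dynamic
programming alignment, so ANI values can be cross-checked through a second
route.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from viromix.config import SimConfig


@pytest.fixture
def small_sim() -> SimConfig:
    return SimConfig(seed=11)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[("ACGT".index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def dp_global_identity(a: str, b: str) -> tuple[float, float]:
    """Exhaustive-DP oracle: (percent identity over aligned columns,
    aligned fraction of the shorter sequence), from a single optimal global
    alignment under match +1 / mismatch -1 / gap open -5 / extend -1 with
    free end gaps on the longer sequence."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # end gaps free so containment is not penalised
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = next(iter(aligner.align(a, b)))
    ta, tb = aln[0], aln[1]
    matches = cols = short_cols = 0
    shorter_is_a = len(a) <= len(b)
    for x, y in zip(ta, tb):
        if x == "-" and y == "-":
            continue
        # skip terminal free end gaps: columns where the shorter seq is absent
        inner = (x != "-") if shorter_is_a else (y != "-")
        if not inner:
            continue
        cols += 1
        if x == y:
            matches += 1
        short_cols += 1
    ani = 100.0 * matches / cols if cols else 0.0
    af = 100.0 * short_cols / min(len(a), len(b))
    return ani, af
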