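"""Quality filtering and ANI-based dereplication of uncultivated viral genomes.

Contigs annotated with an estimated genome completeness are first gated on
length (>= 1 kbp) and completeness (determined and >= 50 %), then clustered
into species-level viral OTUs (vOTUs) by greedy centroid clustering at
>= 95 % average nucleotide identity (ANI) over >= 85 % aligned fraction (AF)
of the shorter sequence, each cluster represented by its longest member.

ANI/AF are computed from a local alignment block between the two sequences:
the shorter sequence is aligned into the longer with an infix edit-distance
alignment (edlib), and the maximal-scoring contiguous stretch of that
alignment under a match +1 / mismatch -1 / gap open -5 / gap extend -1
scoring is taken as the block.  ANI is the percent identity over the block's
columns; AF is the block's span on the shorter sequence as a percentage of
its length.  For collinear genomes (the dereplication use case) this equals
the classical merged-block ANI; it does not chain rearranged blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

__all__ = [
    "Votu", "AniResult", "ClusterSet", "AlignScoring",
    "assign_quality_tier", "filter_votus", "pairwise_ani", "greedy_cluster",
]

UNDETERMINED = None  # completeness sentinel


@dataclass(frozen=True)
class Votu:
    """One (candidate) viral genome with its quality annotations."""

    id: str
    dataset_origin: str = "VLP"            # "VLP" | "WMS"
    sequence: str | None = None
    length_bp: int = 0
    completeness_pct: float | None = None  # None = undetermined
    is_provirus: bool = False

    def __post_init__(self):
        if self.sequence is not None:
            object.__setattr__(self, "length_bp", len(self.sequence))
        if self.length_bp < 0:
            raise ValueError(f"vOTU {self.id!r}: negative length {self.length_bp}")

    @property
    def quality_tier(self) -> str:
        return assign_quality_tier(self.completeness_pct)


@dataclass(frozen=True)
class AniResult:
    query_id: str
    subject_id: str
    ani_pct: float
    af_pct: float


@dataclass
class ClusterSet:
    """A partition of vOTU ids into clusters, each led by its longest member."""

    members: dict[str, list[str]] = field(default_factory=dict)       # cluster_id -> ids
    representatives: dict[str, str] = field(default_factory=dict)     # cluster_id -> rep id

    def partition(self) -> dict[str, str]:
        """Mapping member id -> cluster id."""
        return {m: c for c, ms in self.members.items() for m in ms}

    def as_frozensets(self) -> set[frozenset[str]]:
        """Order-free view of the partition, for comparisons."""
        return {frozenset(ms) for ms in self.members.values()}


def assign_quality_tier(completeness_pct: float | None) -> str:
    """Map estimated completeness to a quality tier.

    100 -> complete, (90, 100) -> high, [50, 90] -> medium, [0, 50) -> low,
    undetermined (None) -> undetermined.  The 50-90 bracket is inclusive at
    both ends, so exactly 90 is medium.
    """
    if completeness_pct is None:
        return "undetermined"
    if not 0 <= completeness_pct <= 100:
        raise ValueError(f"completeness {completeness_pct} outside [0, 100]")
    if completeness_pct == 100:
        return "complete"
    if completeness_pct > 90:
        return "high"
    if completeness_pct >= 50:
        return "medium"
    return "low"


def filter_votus(votus: Iterable[Votu], min_length: int = 1000,
                 min_completeness: float = 50.0) -> list[Votu]:
    """Retain genomes >= min_length bp with determined completeness >= min_completeness.

    This is the HQ-vOTU gate: sub-kilobase contigs and low-quality or
    completeness-undetermined genomes are removed before clustering.
    """
    kept = []
    for v in votus:
        if v.length_bp >= min_length and v.completeness_pct is not None \
                and v.completeness_pct >= min_completeness:
            kept.append(v)
    return kept


@dataclass(frozen=True)
class AlignScoring:
    """Scoring used to trim the infix alignment to its best local block."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1


def _cigar_ops(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def pairwise_ani(a: Votu, b: Votu, scoring: AlignScoring = AlignScoring()) -> AniResult:
    """ANI and aligned fraction between two genomes.

    Returns ``ani_pct`` (percent identity over the local alignment block) and
    ``af_pct`` (block span as a percent of the shorter genome's length).  An
    unalignable pair yields (0, 0).
    """
    for v in (a, b):
        if not v.sequence:
            raise ValueError(f"vOTU {v.id!r} has no sequence")
    # infix alignment: shorter sequence (query) placed inside the longer
    if len(a.sequence) <= len(b.sequence):
        query, target = a.sequence, b.sequence
    else:
        query, target = b.sequence, a.sequence
    res = edlib.align(query, target, mode="HW", task="path")
    cigar = res["cigar"]
    if not cigar:
        return AniResult(a.id, b.id, 0.0, 0.0)

    # per-column scores along the alignment path; query-consuming ops are =,X,I
    cols: list[tuple[int, bool, bool]] = []  # (score, is_match, consumes_query)
    for n, op in _cigar_ops(cigar):
        if op == "=":
            cols.extend([(scoring.match, True, True)] * n)
        elif op == "X":
            cols.extend([(scoring.mismatch, False, True)] * n)
        elif op in "ID":
            consumes_q = op == "I"
            for i in range(n):
                s = scoring.gap_open if i == 0 else scoring.gap_extend
                cols.append((s, False, consumes_q))
        else:  # pragma: no cover - edlib emits only =,X,I,D with task="path"
            raise ValueError(f"unexpected CIGAR op {op!r}")

    # Kadane: maximal-scoring contiguous block of the alignment path
    best, best_span = 0, (0, 0)
    cur, start = 0, 0
    for i, (s, _, _) in enumerate(cols):
        if cur <= 0:
            cur, start = s, i
        else:
            cur += s
        if cur > best:
            best, best_span = cur, (start, i + 1)
    if best <= 0:
        return AniResult(a.id, b.id, 0.0, 0.0)

    lo, hi = best_span
    block = cols[lo:hi]
    n_cols = hi - lo
    n_match = sum(1 for _, m, _ in block if m)
    q_span = sum(1 for _, _, cq in block if cq)
    ani = 100.0 * n_match / n_cols
    af = 100.0 * q_span / len(query)
    return AniResult(a.id, b.id, ani, af)


def greedy_cluster(votus: Sequence[Votu], min_ani: float = 95.0, min_af: float = 85.0,
                   scoring: AlignScoring = AlignScoring()) -> ClusterSet:
    """Greedy centroid clustering at the given ANI/AF thresholds (inclusive).

    Genomes are visited in order of decreasing length (ties broken by
    ascending id).  Each genome joins the first existing cluster whose
    representative it matches at ani >= min_ani and af >= min_af, otherwise it
    founds a new cluster; the founder (the longest member) is the
    representative.
    """
    for name, v in (("min_ani", min_ani), ("min_af", min_af)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} {v} outside [0, 100]")
    order = sorted(votus, key=lambda v: (-v.length_bp, v.id))
    cs = ClusterSet()
    reps: list[Votu] = []  # in founding order
    for v in order:
        for rep in reps:
            r = pairwise_ani(v, rep, scoring=scoring)
            if r.ani_pct >= min_ani and r.af_pct >= min_af:
                cs.members[rep.id].append(v.id)
                break
        else:
            cs.members[v.id] = [v.id]
            cs.representatives[v.id] = v.id
            reps.append(v)
    return cs


def cluster_table(cs: ClusterSet, votus: Mapping[str, Votu] | None = None):
    """Rows (cluster_id, representative, member) for TSV output."""
    rows = []
    for cid in sorted(cs.members):
        for m in sorted(cs.members[cid]):
            rows.append({"cluster_id": cid, "representative": cs.representatives[cid],
                         "member": m})
    return rows
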