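"""Cross-dataset vOTU matching via a best-hit alignment filter cascade.

Whole-metagenome (WMS) vOTUs are aligned as queries against virus-particle
(VLP) vOTUs as subjects.  Per query, the single best hit (maximal bitscore;
ties broken by minimal e-value, then ascending subject id) is kept and then
passed through four thresholds — e-value <= 1e-5, bitscore >= 1000, percent
identity >= 95 and query coverage per subject >= 85 — to retain alignments
highly likely to represent the same virus recovered by both routes.

The cascade operates on the common 12-column tabular alignment format with
an appended query-coverage column ("outfmt 6 std qcovs").  For synthetic
tests an internal aligner produces the same dialect with blastn-style
Karlin-Altschul bitscores/e-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .derep import AlignScoring, Votu, pairwise_ani

__all__ = [
    "AlignmentHit", "best_hit", "identity_filter", "match_datasets",
    "align_votus", "read_hit_table", "OUTFMT6_QCOVS_COLUMNS",
]

OUTFMT6_QCOVS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs",
]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    evalue: float
    bitscore: float
    qcovs: float

    def __post_init__(self):
        for name in ("pident", "qcovs"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} {v} outside [0, 100]")
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("evalue and bitscore must be >= 0")


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a headerless 'outfmt 6 std qcovs' table into hits."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_QCOVS_COLUMNS)
    return hits_from_frame(df)


def hits_from_frame(df: pd.DataFrame) -> list[AlignmentHit]:
    return [
        AlignmentHit(query_id=str(r.qseqid), subject_id=str(r.sseqid),
                     pident=float(r.pident), aln_len=int(r.length),
                     evalue=float(r.evalue), bitscore=float(r.bitscore),
                     qcovs=float(r.qcovs))
        for r in df.itertuples()
    ]


def best_hit(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Per query, the hit with maximal bitscore.

    Ties go to the minimal e-value, remaining ties to the ascending
    lexicographic subject id, so the result is independent of row order.
    Duplicate (query, subject) rows collapse to their max-bitscore row by the
    same rule.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def _hit_rank(h: AlignmentHit) -> tuple:
    return (-h.bitscore, h.evalue, h.subject_id)


def identity_filter(hit: AlignmentHit, max_evalue: float = 1e-5,
                    min_bitscore: float = 1000.0, min_pident: float = 95.0,
                    min_qcovs: float = 85.0) -> bool:
    """All four thresholds must pass for a hit to count as 'likely identical'."""
    return (hit.evalue <= max_evalue and hit.bitscore >= min_bitscore
            and hit.pident >= min_pident and hit.qcovs >= min_qcovs)


def match_datasets(wms_ids: Sequence[str], vlp_ids: Sequence[str],
                   hits: Iterable[AlignmentHit], **thresholds,
                   ) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Best hits passing the identity cascade, as (wms_id, vlp_id) pairs.

    Returns the sorted pair list and summary counts
    (n_queries, n_queries_with_hits, n_passing).
    """
    wms, vlp = set(wms_ids), set(vlp_ids)
    hits = [h for h in hits]
    stray_q = sorted({h.query_id for h in hits} - wms)
    stray_s = sorted({h.subject_id for h in hits} - vlp)
    if stray_q or stray_s:
        raise ValueError(f"hit table ids outside the datasets: "
                         f"queries {stray_q}, subjects {stray_s}")
    best = best_hit(hits)
    pairs = sorted((q, h.subject_id) for q, h in best.items()
                   if identity_filter(h, **thresholds))
    summary = {"n_queries": len(wms), "n_queries_with_hits": len(best),
               "n_passing": len(pairs)}
    return pairs, summary


# ---------------------------------------------------------------------------
# internal aligner producing the same tabular dialect
# ---------------------------------------------------------------------------

# blastn-like Karlin-Altschul parameters for match +1 / mismatch -2 (ungapped
# approximation): bits = (lambda*S - ln K) / ln 2
_KA_LAMBDA = 1.28
_KA_K = 0.46


def _blastn_like_stats(n_match: int, n_mismatch: int, n_gapcols: int,
                       qlen: int, slen: int) -> tuple[float, float]:
    score = n_match - 2 * n_mismatch - 2 * n_gapcols
    bits = max(0.0, (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2))
    evalue = qlen * slen * 2.0 ** (-bits)
    return bits, evalue


def align_votus(queries: Mapping[str, str], subjects: Mapping[str, str],
                scoring: AlignScoring = AlignScoring(),
                min_block_bp: int = 100) -> pd.DataFrame:
    """All-vs-all local alignment emitting an 'outfmt 6 std qcovs' frame.

    A convenience for synthetic data at desk scale; a dedicated sequence
    search tool fills the same role on real datasets.  Alignments whose best
    local block is shorter than ``min_block_bp`` are omitted (no hit).
    """
    rows = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            r = pairwise_ani(Votu(id=qid, sequence=qseq),
                             Votu(id=sid, sequence=sseq), scoring=scoring)
            if r.ani_pct <= 0:
                continue
            # block statistics back out of ANI/AF definitions
            shorter = min(len(qseq), len(sseq))
            q_span = int(round(r.af_pct / 100 * shorter))
            if q_span < min_block_bp:
                continue
            n_cols = q_span  # substitution-dominated blocks: columns ~ query span
            n_match = int(round(r.ani_pct / 100 * n_cols))
            n_mismatch = n_cols - n_match
            bits, evalue = _blastn_like_stats(n_match, n_mismatch, 0,
                                              len(qseq), len(sseq))
            qcovs = 100.0 * q_span / len(qseq)
            rows.append({
                "qseqid": qid, "sseqid": sid, "pident": round(r.ani_pct, 3),
                "length": n_cols, "mismatch": n_mismatch, "gapopen": 0,
                "qstart": 1, "qend": q_span, "sstart": 1, "send": q_span,
                "evalue": evalue, "bitscore": round(bits, 1),
                "qcovs": round(qcovs, 2),
            })
    return pd.DataFrame(rows, columns=OUTFMT6_QCOVS_COLUMNS)
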