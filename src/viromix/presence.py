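"""Coverage-based presence calling and unique/communal partitioning.

A vOTU counts as truly present in a sample when its average read coverage
(read count x mean read length / vOTU length) is strictly over a 10-fold
threshold.  Presence sets are then reduced, per dataset, to one of four
classes: present only in case samples (case_unique), only in controls
(control_unique), in at least one of each (communal), or nowhere (absent).
The same partition lifts to viral clusters (VCs): a VC is case-unique only
if every present member is case-unique.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "average_coverage", "call_presence", "classify_votus", "classify_vcs",
    "classify_by_dataset", "PresenceClassification",
]

CLASSES = ("case_unique", "control_unique", "communal", "absent")


def average_coverage(read_count: int, mean_read_length: float, votu_length: int) -> float:
    """Average fold-coverage of a vOTU: read_count x mean read length / vOTU length."""
    if votu_length <= 0:
        raise ValueError(f"votu_length must be positive, got {votu_length}")
    if read_count < 0:
        raise ValueError(f"read_count must be >= 0, got {read_count}")
    return read_count * mean_read_length / votu_length


def call_presence(coverage: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Boolean vOTU x sample presence: present iff coverage strictly over threshold.

    Coverage exactly at the threshold (e.g. 10.0 under the 10-fold rule) is
    NOT presence.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if (coverage.to_numpy() < 0).any():
        raise ValueError("coverage matrix contains negative values")
    return coverage.gt(threshold)


@dataclass
class PresenceClassification:
    """Per-vOTU class plus the supporting presence sets."""

    votu_class: dict[str, str]
    present_in: dict[str, set[str]]
    dataset: str | None = None

    def class_counts(self) -> dict[str, int]:
        c = Counter(self.votu_class.values())
        return {k: c.get(k, 0) for k in CLASSES}

    def venn(self) -> dict[str, int]:
        """Unique/communal Venn counts over non-absent vOTUs."""
        c = self.class_counts()
        return {"case_unique": c["case_unique"], "communal": c["communal"],
                "control_unique": c["control_unique"]}


def classify_votus(presence: pd.DataFrame, metadata: pd.DataFrame) -> PresenceClassification:
    """Partition vOTUs into case_unique / control_unique / communal / absent.

    ``presence`` is the boolean matrix from :func:`call_presence` restricted
    to the samples of one dataset; ``metadata`` must cover all its columns.
    Process-control samples are excluded before classification.  Presence in
    a single sample of a group suffices for group presence.
    """
    md = metadata.set_index("sample_id")
    unknown = [s for s in presence.columns if s not in md.index]
    if unknown:
        raise ValueError(f"samples without metadata: {unknown}")
    groups = md.loc[list(presence.columns), "group"]
    case_cols = [s for s in presence.columns if groups[s] == "case"]
    ctrl_cols = [s for s in presence.columns if groups[s] == "control"]

    in_case = presence[case_cols].any(axis=1)
    in_ctrl = presence[ctrl_cols].any(axis=1)
    votu_class, present_in = {}, {}
    for votu in presence.index:
        if in_case[votu] and in_ctrl[votu]:
            cls = "communal"
        elif in_case[votu]:
            cls = "case_unique"
        elif in_ctrl[votu]:
            cls = "control_unique"
        else:
            cls = "absent"
        votu_class[votu] = cls
        row = presence.loc[votu, case_cols + ctrl_cols]
        present_in[votu] = set(row.index[row])
    return PresenceClassification(votu_class, present_in)


def classify_by_dataset(coverage: pd.DataFrame, metadata: pd.DataFrame,
                        threshold: float = 10.0) -> dict[str, PresenceClassification]:
    """Call presence and classify each dataset (VLP, WMS) independently.

    Datasets are never pooled before classification; each gets its own
    unique/communal partition.
    """
    md = metadata[metadata["group"].isin(["case", "control"])]
    out = {}
    for ds, sub in md.groupby("dataset"):
        cols = [s for s in sub["sample_id"] if s in coverage.columns]
        pres = call_presence(coverage[cols], threshold)
        pc = classify_votus(pres, sub)
        pc.dataset = ds
        out[ds] = pc
    return out


def classify_vcs(votu_classes: PresenceClassification,
                 vc_membership: Mapping[str, str] | pd.DataFrame,
                 ) -> tuple[dict[str, str], dict[str, int]]:
    """Lift vOTU classes to viral clusters and count the VC-level Venn.

    A VC is case_unique iff it has at least one present member and every
    present member is case_unique (any communal or control member breaks
    uniqueness); control_unique symmetric; otherwise shared.  VCs whose
    members are all absent are excluded from the Venn counts.
    """
    if isinstance(vc_membership, pd.DataFrame):
        dup = vc_membership["votu_id"].duplicated()
        if dup.any():
            bad = sorted(vc_membership.loc[dup, "votu_id"].unique())
            raise ValueError(f"vOTUs mapped to multiple VCs: {bad}")
        vc_membership = dict(zip(vc_membership["votu_id"], vc_membership["vc_id"]))

    members: dict[str, list[str]] = {}
    for votu, vc in vc_membership.items():
        members.setdefault(vc, []).append(votu)

    vc_class = {}
    for vc, votus in members.items():
        present = [votu_classes.votu_class[v] for v in votus
                   if v in votu_classes.votu_class
                   and votu_classes.votu_class[v] != "absent"]
        if not present:
            vc_class[vc] = "absent"
        elif all(c == "case_unique" for c in present):
            vc_class[vc] = "case_unique"
        elif all(c == "control_unique" for c in present):
            vc_class[vc] = "control_unique"
        else:
            vc_class[vc] = "shared"
    counts = Counter(v for v in vc_class.values() if v != "absent")
    venn = {"case_unique": counts.get("case_unique", 0),
            "shared": counts.get("shared", 0),
            "control_unique": counts.get("control_unique", 0)}
    return vc_class, venn
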