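"""Disease association of predicted phage hosts.

Host-prediction tables (virus id, host genus, confidence score) are filtered
at a confidence cutoff (>= 90, i.e. medium or high confidence), joined with
the per-dataset presence classes of their viruses, and each host genus is
labelled by the pattern of viruses it interacts with:

* ``exclusively_case``    — every linked present virus is case-unique (the
  signature of a host associated solely with disease-unique viruses)
* ``case_associated``     — at least one case-unique link plus communal ones
* ``exclusively_control`` / ``control_associated`` — symmetric
* ``communal_only``       — only communal links
* ``mixed``               — both case- and control-unique links

Host genus labels are compared verbatim: GTDB-style suffixed genera (e.g.
Clostridium_J) count as distinct taxa.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .presence import PresenceClassification

__all__ = [
    "HostClass", "filter_predictions", "classify_hosts", "venn_hosts",
    "top_n_cross_reference",
]


@dataclass(frozen=True)
class HostClass:
    host_taxon: str
    dataset: str
    label: str
    linked_classes: tuple[str, ...]  # sorted multiset of presence classes


def filter_predictions(preds: pd.DataFrame, min_confidence: float = 90.0) -> pd.DataFrame:
    """Keep predictions at or above the confidence cutoff (inclusive)."""
    return preds[preds["confidence"] >= min_confidence].reset_index(drop=True)


def _label(classes: Counter) -> str:
    has_case = classes.get("case_unique", 0) > 0
    has_ctrl = classes.get("control_unique", 0) > 0
    has_comm = classes.get("communal", 0) > 0
    if has_case and has_ctrl:
        return "mixed"
    if has_case:
        return "exclusively_case" if not has_comm else "case_associated"
    if has_ctrl:
        return "exclusively_control" if not has_comm else "control_associated"
    return "communal_only"


def classify_hosts(preds: pd.DataFrame,
                   votu_classes: dict[str, PresenceClassification],
                   ) -> list[HostClass]:
    """Label each (host, dataset) by the presence classes of its linked viruses.

    ``preds`` must already be confidence-filtered and carry a ``dataset``
    column; ``votu_classes`` maps dataset -> per-vOTU classification.  Links
    to absent viruses carry no evidence and are dropped; hosts left with no
    present links are omitted from the result.
    """
    missing = sorted(
        set(zip(preds["votu_id"], preds["dataset"]))
        - {(v, ds) for ds, pc in votu_classes.items() for v in pc.votu_class})
    if missing:
        raise ValueError(f"predictions reference unclassified vOTUs: {missing}")

    out = []
    for (host, ds), sub in preds.groupby(["host", "dataset"], sort=True):
        linked = [votu_classes[ds].votu_class[v] for v in sub["votu_id"]]
        linked = [c for c in linked if c != "absent"]
        if not linked:
            continue
        out.append(HostClass(host_taxon=host, dataset=ds,
                             label=_label(Counter(linked)),
                             linked_classes=tuple(sorted(linked))))
    return out


def venn_hosts(hosts_vlp: set[str], hosts_wms: set[str],
               ) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Partition predicted hosts into shared / VLP-only / WMS-only."""
    sets = {"shared": hosts_vlp & hosts_wms,
            "vlp_only": hosts_vlp - hosts_wms,
            "wms_only": hosts_wms - hosts_vlp}
    return sets, {k: len(v) for k, v in sets.items()}


def top_n_cross_reference(host_classes: list[HostClass],
                          abundance: pd.DataFrame, metadata: pd.DataFrame,
                          n: int = 20) -> pd.DataFrame:
    """Cross-reference the n most abundant case-sample genera with host classes.

    Genera are ranked by mean relative abundance across case samples; each of
    the top n rows is annotated with the host's association label per dataset,
    or 'no prediction' where the genus never appears in a prediction output.
    """
    case_samples = metadata.loc[metadata["group"] == "case", "sample_id"]
    case_samples = [s for s in case_samples if s in abundance.columns]
    if not case_samples:
        raise ValueError("no case samples in the abundance table")
    rel = abundance[case_samples].div(abundance[case_samples].sum(axis=0), axis=1)
    mean_rel = rel.mean(axis=1).sort_values(ascending=False, kind="stable")
    if n > len(mean_rel):
        warnings.warn(f"requested top {n} of {len(mean_rel)} genera; using all")
        n = len(mean_rel)

    by_host: dict[tuple[str, str], str] = {
        (hc.host_taxon, hc.dataset): hc.label for hc in host_classes}
    datasets = sorted({hc.dataset for hc in host_classes}) or ["VLP", "WMS"]
    rows = []
    for rank, (genus, ab) in enumerate(mean_rel.head(n).items(), start=1):
        row = {"rank": rank, "genus": genus, "mean_relative_abundance": float(ab)}
        for ds in datasets:
            row[f"host_class_{ds}"] = by_host.get((genus, ds), "no prediction")
        rows.append(row)
    return pd.DataFrame(rows)
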