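"""Compositional and diversity statistics for household-matched microbiome designs.

Implements the statistical toolbox the pipeline's comparisons rest on:
centred log-ratio (CLR) transformation, Shannon and bias-corrected Chao1
alpha diversity, rarefaction to a common depth, Bray-Curtis and Jaccard
distances, PERMANOVA with optionally household-restricted permutations, and
the one-way intraclass correlation coefficient (ICC).

Conventions: abundance tables are taxa x samples DataFrames; Shannon and CLR
use natural logarithms; CLR adds a pseudocount of 1 to every cell before
closure; Chao1 uses the bias-corrected form so samples without doubletons
are defined.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "clr_transform", "shannon", "chao1", "rarefy", "observed_richness",
    "bray_curtis", "jaccard", "permanova", "icc", "alpha_diversity_table",
]


# ---------------------------------------------------------------------------
# compositional transform and alpha diversity
# ---------------------------------------------------------------------------

def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio per sample: log(x_i / geometric mean of the sample).

    ``pseudocount`` is added to every cell first, so zeros are handled and
    each sample's transformed values sum to zero exactly.  A pseudocount of
    0 is allowed only when every cell is already positive.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if (table.to_numpy() < 0).any():
        raise ValueError("abundance table contains negative values")
    x = table.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    logx = np.log(x)
    out = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity index in nats: -sum p_i ln p_i over non-zero taxa."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1)).

    f1/f2 are singleton/doubleton counts, so inputs must be integers; round
    coverage-valued tables first.
    """
    c = np.asarray(counts)
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("Chao1 requires integer counts; round the table first")
    c = c.astype(np.int64)
    if (c < 0).any():
        raise ValueError("negative counts")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def observed_richness(counts: Sequence[float]) -> int:
    return int((np.asarray(counts) > 0).sum())


def rarefy(table: pd.DataFrame, depth: int | None = None,
           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample sum; larger depths than a
    sample's total are an error.  Deterministic for a fixed seed.
    """
    c = table.to_numpy()
    if not np.all(np.equal(np.mod(c, 1), 0)):
        raise ValueError("rarefaction requires integer counts; round the table first")
    c = c.astype(np.int64)
    sums = c.sum(axis=0)
    if depth is None:
        depth = int(sums.min())
    shallow = [s for s, tot in zip(table.columns, sums) if tot < depth]
    if shallow:
        raise ValueError(f"depth {depth} exceeds sample totals of: {shallow}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty_like(c)
    for j in range(c.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(c[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def alpha_diversity_table(table: pd.DataFrame, rarefy_depth: int | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Per-sample Shannon (unrarefied), Chao1 and rarefied observed richness."""
    rare = rarefy(table, depth=rarefy_depth, seed=seed)
    rows = []
    for s in table.columns:
        rows.append({
            "sample_id": s,
            "shannon": shannon(table[s]),
            "chao1": chao1(table[s]),
            "observed_richness_rarefied": observed_richness(rare[s]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def _distance_frame(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    x = table.to_numpy(dtype=float).T  # samples x taxa
    d = squareform(pdist(x, metric=metric))
    empty = x.sum(axis=1) == 0
    if empty.any():
        # convention: two empty samples are identical, empty vs non-empty maximal
        for i in np.flatnonzero(empty):
            d[i, :] = d[:, i] = 1.0
            for j in np.flatnonzero(empty):
                d[i, j] = d[j, i] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples: sum|u-v| / sum(u+v)."""
    return _distance_frame(table, "braycurtis")


def jaccard(table: pd.DataFrame) -> pd.DataFrame:
    """Jaccard distance on presence/absence: 1 - |intersection| / |union|."""
    return _distance_frame(table.gt(0), "jaccard")


# ---------------------------------------------------------------------------
# PERMANOVA with restricted permutations
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group labels."""
    n = len(labels)
    ss_total = d2.sum() / (2 * n)  # d2 is the full symmetric matrix
    ss_within = 0.0
    n_groups = 0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_groups += 1
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(dist: pd.DataFrame, groups: Sequence[str], n_perm: int | str = 999,
              restriction: str = "none", households: Sequence[str] | None = None,
              seed: int | np.random.Generator = 0) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    ``groups`` labels each sample (matrix order).  With
    ``restriction='within_household'`` labels are permuted only within each
    household block, which is the exchangeability structure of a
    household-matched design.  ``n_perm='exact'`` enumerates every distinct
    label permutation instead of sampling (feasible for small designs only).
    The p-value uses the (1 + more-extreme) / (1 + n_perm) convention.
    """
    labels, uniques = pd.factorize(np.asarray(groups))
    if len(labels) != len(dist):
        raise ValueError("groups must label every sample of the distance matrix")
    counts = np.bincount(labels)
    if (counts < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if restriction not in ("none", "within_household"):
        raise ValueError(f"unknown restriction {restriction!r}")
    if restriction == "within_household":
        if households is None:
            raise ValueError("within_household restriction requires household labels")
        households = np.asarray(households)

    d2 = dist.to_numpy(dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)

    if n_perm == "exact":
        perms = _exact_permutations(labels, restriction, households)
        f_perm = np.array([_pseudo_f(d2, p) for p in perms])
        # the identity arrangement is part of the enumeration
        p = float((f_perm >= f_obs - 1e-12).sum()) / len(f_perm)
        n_used = len(f_perm)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        more = 0
        for _ in range(int(n_perm)):
            perm = _one_permutation(labels, restriction, households, rng)
            if _pseudo_f(d2, perm) >= f_obs - 1e-12:
                more += 1
        p = (1 + more) / (1 + int(n_perm))
        n_used = int(n_perm)
    return {"pseudo_F": float(f_obs), "p_value": float(p), "n_permutations": n_used}


def _one_permutation(labels, restriction, households, rng):
    perm = labels.copy()
    if restriction == "none":
        rng.shuffle(perm)
    else:
        for h in np.unique(households):
            idx = np.flatnonzero(households == h)
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
    return perm


def _exact_permutations(labels, restriction, households):
    n = len(labels)
    if restriction == "none":
        seen = set()
        out = []
        for p in itertools.permutations(range(n)):
            arrangement = tuple(labels[list(p)])
            if arrangement not in seen:
                seen.add(arrangement)
                out.append(np.array(arrangement))
        return out
    blocks = [np.flatnonzero(households == h) for h in np.unique(households)]
    per_block = []
    for idx in blocks:
        seen = set()
        opts = []
        for p in itertools.permutations(labels[idx]):
            if p not in seen:
                seen.add(p)
                opts.append(p)
        per_block.append(opts)
    out = []
    for combo in itertools.product(*per_block):
        arr = labels.copy()
        for idx, vals in zip(blocks, combo):
            arr[idx] = vals
        out.append(arr)
    return out


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc(values: Sequence[float], households: Sequence[str]) -> float:
    """One-way intraclass correlation by the ANOVA method of moments.

    ICC = sigma_between^2 / (sigma_between^2 + sigma_within^2) from the
    between/within household mean squares, truncated at 0.  Households with a
    single member carry no within-household information and are dropped;
    unequal household sizes use the standard k0 average-size correction.
    """
    v = np.asarray(values, dtype=float)
    h = np.asarray(households)
    keep_h = [g for g in np.unique(h) if (h == g).sum() >= 2]
    if len(keep_h) < 2:
        raise ValueError("ICC needs at least 2 households with >= 2 members")
    mask = np.isin(h, keep_h)
    v, h = v[mask], h[mask]

    grand = v.mean()
    n = len(v)
    groups = [v[h == g] for g in keep_h]
    a = len(groups)
    sizes = np.array([len(g) for g in groups])
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n - a)
    k0 = (n - (sizes ** 2).sum() / n) / (a - 1)
    sigma_b = max(0.0, (ms_between - ms_within) / k0)
    denom = sigma_b + ms_within
    if denom == 0:
        return 0.0
    return float(sigma_b / denom)
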