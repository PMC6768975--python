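"""Which taxa drive between-group differences: SIMPER decomposition of
Bray-Curtis, indicator species analysis (IndVal), and shared-OTU overlap
fractions between named sample sets.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .core import OtuTable

__all__ = ["simper", "indval", "shared_otu_fractions"]

#: the conventional indicator thresholds: sqrt(A*B) > 0.3 at p < 0.05
INDVAL_STAT_THRESHOLD = 0.3
INDVAL_P_THRESHOLD = 0.05


def simper(table: OtuTable, groups, group_pair) -> pd.DataFrame:
    """Similarity-percentage decomposition for one pair of groups.

    For every between-group sample pair (x, y), taxon k contributes
    ``|x_k - y_k| / sum(x + y)`` to their Bray-Curtis dissimilarity; the
    per-taxon average over all between-group pairs is reported together
    with its percent of the total (the percents sum to 100 and the
    averages sum to the mean between-group Bray-Curtis).
    """
    groups = np.asarray(list(groups))
    g1, g2 = group_pair
    idx1 = np.flatnonzero(groups == g1)
    idx2 = np.flatnonzero(groups == g2)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError(f"empty group in pair {group_pair!r}")
    counts = table.counts.astype(float)
    contrib = np.zeros(table.n_otus)
    n_pairs = 0
    for i in idx1:
        for j in idx2:
            x, y = counts[i], counts[j]
            contrib += np.abs(x - y) / (x + y).sum()
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    out = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "average_contribution": contrib,
            "percent": 100.0 * contrib / total,
        }
    ).sort_values("percent", ascending=False, kind="mergesort")
    out["cumulative_percent"] = out["percent"].cumsum()
    return out.reset_index(drop=True)


def _indval_stats(relabund: np.ndarray, codes: np.ndarray, n_groups: int):
    """Specificity A, fidelity B and sqrt(A*B), (n_groups x n_otus)."""
    means = np.zeros((n_groups, relabund.shape[1]))
    occ = np.zeros_like(means)
    for g in range(n_groups):
        rows = relabund[codes == g]
        means[g] = rows.mean(axis=0)
        occ[g] = (rows > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    return a, occ, np.sqrt(a * occ)


def indval(
    table: OtuTable, groups, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Indicator value of every OTU for its best group.

    A (specificity) is the group's mean relative abundance over the sum of
    all groups' means; B (fidelity) is the occurrence fraction within the
    group; the statistic is sqrt(A*B) with the OTU assigned to its
    argmax group.  p is the (+1-corrected) fraction of label permutations
    whose best-group statistic reaches the observed one.  ``indicator`` is
    True when stat > 0.3 and p < 0.05.
    """
    groups = np.asarray(list(groups))
    if len(groups) != table.n_samples:
        raise ValueError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    relabund = table.relative_abundance().to_numpy()
    a, b, stat = _indval_stats(relabund, codes, len(labels))
    best = stat.argmax(axis=0)
    cols = np.arange(table.n_otus)
    obs = stat[best, cols]

    rng = np.random.default_rng(seed)
    count = np.zeros(table.n_otus)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, s = _indval_stats(relabund, perm, len(labels))
        count += s.max(axis=0) >= obs
    p = (count + 1) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "group": labels[best],
            "A": a[best, cols],
            "B": b[best, cols],
            "stat": obs,
            "stat_squared": obs**2,
            "p_value": p,
        }
    )
    out["indicator"] = (out["stat"] > INDVAL_STAT_THRESHOLD) & (
        out["p_value"] < INDVAL_P_THRESHOLD
    )
    return out.sort_values("stat", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def shared_otu_fractions(named_sets: dict) -> dict:
    """Overlap structure of named OTU sets, as fractions of the union.

    ``named_sets`` maps a name to an iterable of OTU ids (or an
    :class:`OtuTable`, whose observed OTUs are used).  Returns the union
    size, the fraction of the union unique to each set, and the raw
    intersection fraction for every combination of two or more sets.
    """
    sets = {}
    for name, val in named_sets.items():
        if isinstance(val, OtuTable):
            present = val.data.sum(axis=0) > 0
            sets[name] = set(val.data.columns[present])
        else:
            sets[name] = set(val)
    if len(sets) < 2:
        raise ValueError("need at least 2 named sets")
    union = set().union(*sets.values())
    if not union:
        raise ValueError("empty union")
    n_union = len(union)
    out = {"union_size": n_union, "unique": {}, "intersections": {}}
    names = list(sets)
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name))
        out["unique"][name] = len(sets[name] - others) / n_union
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(sets[c] for c in combo))
            out["intersections"][combo] = len(inter) / n_union
    return out
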