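"""Phylogenetic and taxonomic null models for community assembly.

The inference runs in two stages per sample pair:

1. Phylogenetic turnover.  The abundance-weighted beta mean nearest taxon
   distance (betaMNTD) is compared against a null distribution obtained by
   shuffling taxon labels across the tips of the phylogeny (999
   randomizations by default).  The standardized deviate is the beta
   nearest taxon index (betaNTI): betaNTI > +2 indicates heterogeneous
   (variable) selection, betaNTI < -2 homogeneous selection.

2. Taxonomic turnover.  For pairs not dominated by selection
   (|betaNTI| < 2), the Bray-Curtis dissimilarity is compared against a
   Raup-Crick null in which each community is reassembled at its observed
   richness and read depth from the metacommunity: membership drawn with
   probability proportional to occupancy, individuals then assigned with
   probability proportional to metacommunity relative abundance.  The
   resulting RCbray lies in [-1, 1]: RC > +0.95 indicates dispersal
   limitation, RC < -0.95 homogenizing dispersal, and |RC| < 0.95 leaves
   the pair "undominated" (ecological drift plus weak selection/dispersal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import OtuTable

__all__ = [
    "PROCESSES",
    "cophenetic_distances",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "rc_from_counts",
    "classify_pair",
    "quantify_processes",
    "assembly_analysis",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated_drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

#: ties in null-vs-observed Bray-Curtis comparisons within this tolerance
_TIE_TOL = 1e-10


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic (tip-to-tip path length) distances between all tips."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("missing branch length")
    return tree.tip_tip_distances()


def beta_mntd(x, y, taxon_distances: DistanceMatrix) -> float:
    """Abundance-weighted beta mean nearest taxon distance of two samples.

    ``x`` and ``y`` are count (or relative-abundance) vectors aligned to
    ``taxon_distances.ids``.  Each taxon present in one community is
    matched to its phylogenetically nearest taxon in the other community
    (a shared taxon matches itself at distance 0), and the two directed
    abundance-weighted means are averaged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("empty community")
    d = taxon_distances.data
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    fx = x[ix] / x.sum()
    fy = y[iy] / y.sum()
    sub = d[np.ix_(ix, iy)]
    return float(0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0)))


def _sample_profiles(table: OtuTable, tip_index: dict[str, int]):
    """Per sample: (tip positions of present OTUs, their rel. abundances)."""
    profiles = []
    rel = table.relative_abundance().to_numpy()
    otu_pos = np.array([tip_index[o] for o in table.otu_ids])
    for i in range(table.n_samples):
        present = np.flatnonzero(rel[i] > 0)
        profiles.append((otu_pos[present], rel[i][present]))
    return profiles


def beta_nti(
    table: OtuTable,
    tree: TreeNode,
    reps: int = 999,
    seed: int | None = None,
    pool: str = "tree",
) -> pd.DataFrame:
    """betaMNTD, its null distribution, and betaNTI for every sample pair.

    The null shuffles taxon labels; with ``pool="tree"`` (default) the
    shuffle spans every tip of the phylogeny (regional-pool
    randomization), with ``pool="pair"`` only the taxa present in the two
    samples exchange labels.  betaNTI = (observed - null mean) / null SD
    (SD with one delta degree of freedom over the ``reps`` null values).
    Pairs with zero null SD are flagged ``degenerate`` and get NaN betaNTI.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if pool not in ("tree", "pair"):
        raise ValueError("pool must be 'tree' or 'pair'")
    tips = [t.name for t in tree.tips()]
    missing = set(table.otu_ids) - set(tips)
    if missing:
        raise ValueError(f"{len(missing)} table OTU(s) missing from tree")
    dm = cophenetic_distances(tree)
    tip_index = {name: i for i, name in enumerate(dm.ids)}
    d = dm.data
    n_tips = len(tips)
    profiles = _sample_profiles(table, tip_index)
    pairs = list(combinations(range(table.n_samples), 2))

    obs = np.array(
        [
            0.5
            * (
                profiles[i][1] @ d[np.ix_(profiles[i][0], profiles[j][0])].min(1)
                + profiles[j][1] @ d[np.ix_(profiles[i][0], profiles[j][0])].min(0)
            )
            for i, j in pairs
        ]
    )

    rng = np.random.default_rng(seed)
    nulls = np.empty((reps, len(pairs)))
    if pool == "tree":
        for r in range(reps):
            perm = rng.permutation(n_tips)
            for q, (i, j) in enumerate(pairs):
                pi = perm[profiles[i][0]]
                pj = perm[profiles[j][0]]
                sub = d[np.ix_(pi, pj)]
                nulls[r, q] = 0.5 * (
                    profiles[i][1] @ sub.min(axis=1)
                    + profiles[j][1] @ sub.min(axis=0)
                )
    else:  # pool == "pair": relabel only within the union of the pair's taxa
        for q, (i, j) in enumerate(pairs):
            union = np.union1d(profiles[i][0], profiles[j][0])
            for r in range(reps):
                relab = union[rng.permutation(len(union))]
                mapping = np.empty(n_tips, dtype=int)
                mapping[union] = relab
                pi = mapping[profiles[i][0]]
                pj = mapping[profiles[j][0]]
                sub = d[np.ix_(pi, pj)]
                nulls[r, q] = 0.5 * (
                    profiles[i][1] @ sub.min(axis=1)
                    + profiles[j][1] @ sub.min(axis=0)
                )

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    degenerate = null_sd <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = np.where(degenerate, np.nan, (obs - null_mean) / null_sd)
    ids = table.sample_ids
    return pd.DataFrame(
        {
            "sample_i": [ids[i] for i, _ in pairs],
            "sample_j": [ids[j] for _, j in pairs],
            "beta_mntd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "beta_nti": bnti,
            "degenerate": degenerate,
        }
    )


def rc_from_counts(n_lt: int, n_eq: int, reps: int) -> float:
    """Raup-Crick deviation from null-count tallies, scaled to [-1, 1]."""
    return ((n_lt + 0.5 * n_eq) / reps - 0.5) * 2.0


def _null_communities(
    rng: np.random.Generator,
    reps: int,
    richness: int,
    depth: int,
    occupancy_p: np.ndarray,
    abundance_p: np.ndarray,
) -> np.ndarray:
    """``reps`` null communities (rows) at fixed richness and read depth.

    Membership: ``richness`` taxa without replacement, probability
    proportional to metacommunity occupancy.  Abundance: each member gets
    one read, the remaining reads are multinomial with probability
    proportional to metacommunity relative abundance within the members.
    """
    n_taxa = len(occupancy_p)
    out = np.zeros((reps, n_taxa), dtype=np.int64)
    for r in range(reps):
        members = rng.choice(n_taxa, size=richness, replace=False, p=occupancy_p)
        counts = np.ones(richness, dtype=np.int64)
        extra = depth - richness
        if extra > 0:
            w = abundance_p[members]
            counts += rng.multinomial(extra, w / w.sum())
        out[r, members] = counts
    return out


def raup_crick_bray(
    table: OtuTable, reps: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """RCbray for every sample pair against the metacommunity null.

    The metacommunity is the whole input table: occupancy weights are each
    taxon's occurrence frequency across samples, abundance weights its
    pooled relative abundance.  One set of ``reps`` null communities is
    drawn per sample and shared across that sample's pairs, so null
    Bray-Curtis values are paired per randomization index.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if table.n_samples < 2:
        raise ValueError("metacommunity needs at least 2 samples")
    counts = table.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    occupancy_p = occupancy / occupancy.sum()
    abundance = counts.sum(axis=0).astype(float)
    abundance_p = abundance / abundance.sum()

    rng = np.random.default_rng(seed)
    nulls = [
        _null_communities(
            rng,
            reps,
            int((counts[i] > 0).sum()),
            int(counts[i].sum()),
            occupancy_p,
            abundance_p,
        ).astype(float)
        for i in range(table.n_samples)
    ]

    ids = table.sample_ids
    rows = []
    for i, j in combinations(range(table.n_samples), 2):
        x, y = counts[i].astype(float), counts[j].astype(float)
        obs = np.abs(x - y).sum() / (x + y).sum()
        null_bray = np.abs(nulls[i] - nulls[j]).sum(axis=1) / (
            nulls[i] + nulls[j]
        ).sum(axis=1)
        n_lt = int((null_bray < obs - _TIE_TOL).sum())
        n_eq = int((np.abs(null_bray - obs) <= _TIE_TOL).sum())
        rows.append(
            {
                "sample_i": ids[i],
                "sample_j": ids[j],
                "bray_obs": obs,
                "rc_bray": rc_from_counts(n_lt, n_eq, reps),
            }
        )
    return pd.DataFrame(rows)


def classify_pair(
    beta_nti_value: float,
    rc_bray_value: float,
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
) -> str:
    """Five-way assembly-process call for one sample pair.

    Strict inequalities throughout: betaNTI > +2 heterogeneous selection,
    betaNTI < -2 homogeneous selection; otherwise RC > +0.95 dispersal
    limitation, RC < -0.95 homogenizing dispersal; otherwise undominated
    (drift).  Exactly |betaNTI| = 2 therefore falls through to the RC step.
    """
    if np.isnan(beta_nti_value):
        raise ValueError("undefined betaNTI (degenerate null)")
    if beta_nti_value > bnti_threshold:
        return "heterogeneous_selection"
    if beta_nti_value < -bnti_threshold:
        return "homogeneous_selection"
    if rc_bray_value > rc_threshold:
        return "dispersal_limitation"
    if rc_bray_value < -rc_threshold:
        return "homogenizing_dispersal"
    return "undominated_drift"


def quantify_processes(pairs: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Per-group fractions of sample pairs attributed to each process.

    ``pairs`` needs columns sample_i/sample_j/process (and optionally
    ``degenerate``; degenerate pairs are excluded from the denominator and
    counted separately).  ``groups`` maps sample id -> group label; only
    pairs whose two samples share a group count toward that group.  A
    ``total`` row covers all pairs.
    """
    pairs = pairs.copy()
    degen = (
        pairs["degenerate"].to_numpy()
        if "degenerate" in pairs.columns
        else np.zeros(len(pairs), dtype=bool)
    )

    def summarize(mask, name):
        sub = pairs[mask & ~degen]
        n = len(sub)
        if n == 0:
            raise ValueError(f"group {name!r} has no classifiable pairs")
        row = {"group": name, "n_pairs": n, "n_degenerate": int((mask & degen).sum())}
        fracs = sub["process"].value_counts(normalize=True)
        for proc in PROCESSES:
            row[proc] = float(fracs.get(proc, 0.0))
        return row

    rows = [summarize(np.ones(len(pairs), dtype=bool), "total")]
    if groups is not None:
        groups = pd.Series(groups)
        gi = pairs["sample_i"].map(groups)
        gj = pairs["sample_j"].map(groups)
        for g in pd.unique(groups):
            mask = ((gi == g) & (gj == g)).to_numpy()
            if mask.sum() == 0:
                continue
            rows.append(summarize(mask, g))
    return pd.DataFrame(rows).set_index("group")


def assembly_analysis(
    table: OtuTable,
    tree: TreeNode,
    groups=None,
    reps: int = 999,
    seed: int | None = None,
    pool: str = "tree",
):
    """Full two-stage inference: per-pair statistics plus process summary.

    Returns ``(pairs, summary)``: ``pairs`` holds betaMNTD, null moments,
    betaNTI, observed Bray-Curtis, RCbray and the process label per sample
    pair; ``summary`` the per-group process fractions.  The two null
    models draw from independent streams spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_bnti, seed_rc = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    bnti = beta_nti(table, tree, reps=reps, seed=seed_bnti, pool=pool)
    rc = raup_crick_bray(table, reps=reps, seed=seed_rc)
    pairs = bnti.merge(rc, on=["sample_i", "sample_j"], validate="1:1")
    pairs["process"] = [
        None
        if deg
        else classify_pair(b, r)
        for b, r, deg in zip(
            pairs["beta_nti"], pairs["rc_bray"], pairs["degenerate"]
        )
    ]
    summary = quantify_processes(pairs, groups)
    return pairs, summary
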