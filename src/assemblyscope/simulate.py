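"""Synthetic communities assembled under known ecological processes.

The generator produces the post-clustering state the analysis consumes: a
fixed-depth OTU table, an ultrametric phylogeny, and site metadata over an
environmental/spatial gradient.  Niche optima evolve by Brownian motion
along a Yule tree, so nearest-taxon phylogenetic metrics have power
against selection scenarios; read counts are multinomial at fixed depth,
matching rarefied tables.

Scenarios
---------
heterogeneous_selection
    Sites spread across the environmental gradient; taxon k's expected
    abundance at site s is a Gaussian niche kernel
    exp(-(opt_k - env_s)^2 / (2 sigma^2)).
homogeneous_selection
    Every site filtered to one shared environmental value.  Because
    nearest-taxon metrics only register selection when the filtered pool
    is phylogenetically compact, the generator implements the filter at
    clade level: the clade whose mean niche optimum best matches the
    shared environment becomes the suitable pool, and each site hosts a
    random half of it (selection fixes the candidate pool, local drift
    decides who establishes).
dispersal_limitation
    Neutral draws from disjoint random sub-pools of taxa, one per site
    cluster; no environmental filtering.
homogenizing_dispersal
    Every site drawn from one shared, well-mixed realized pool (high
    exchange, turnover at read-noise level).
drift
    Each site independently resamples the shared pool through a small
    effective population, producing mid-range turnover with no
    phylogenetic or spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import AnalysisBundle, OtuTable, align_bundle, tree_from_newick

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "simulate_tree",
    "evolve_niche_optima",
    "simulate_scenario",
    "make_fixture",
    "FIXTURE_NEWICK",
    "FIXTURE_BRAY_S1_S2",
]

SCENARIOS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def simulate_tree(n_taxa: int, seed: int | None = None) -> TreeNode:
    """Pure-birth (Yule) tree, ultrametric and scaled to unit height.

    The process starts from the root split (two lineages at time 0); a
    random lineage splits after each exponential waiting time, and a final
    exponential hold places all tips at the present before rescaling.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    first = [TreeNode(), TreeNode()]
    root.extend(first)
    birth = {id(node): 0.0 for node in first}
    active = list(first)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.length = t - birth.pop(id(node))
        kids = [TreeNode(), TreeNode()]
        node.extend(kids)
        for kid in kids:
            birth[id(kid)] = t
        active.extend(kids)
    t += rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length = t - birth[id(node)]
    width = len(str(n_taxa))
    for k, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU{k:0{width}d}"
    for node in root.traverse(include_self=False):
        node.length /= t
    return root


def evolve_niche_optima(
    tree: TreeNode,
    rate: float,
    seed: int | None = None,
    conservatism: float = 0.0,
) -> pd.Series:
    """Brownian-motion niche optima along the tree (root value 0).

    Each branch adds a Normal(0, rate * length) increment, so tip variance
    is proportional to root-to-tip path length times ``rate`` and close
    relatives share similar optima (phylogenetic niche conservatism).

    ``conservatism`` > 0 switches to an early-burst (ACDC) diffusion whose
    instantaneous rate decays as ``exp(-conservatism * t)`` with time from
    the root: trait variance then accrues mostly on deep branches, making
    niches effectively clade-heritable.  0 (default) is pure Brownian
    motion.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    depth = {id(tree): 0.0}
    g = conservatism
    out = {}
    for node in tree.preorder(include_self=False):
        t0 = depth[id(node.parent)]
        t1 = t0 + (node.length or 0.0)
        depth[id(node)] = t1
        if g > 0:
            var = rate * (np.exp(-g * t0) - np.exp(-g * t1)) / g
        else:
            var = rate * (t1 - t0)
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, np.sqrt(var))
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="niche_optimum")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic assembly scenario.

    Defaults give the selection mechanisms strong contrast: niche breadth
    sigma = 0.25 environmental units against trait tip scatter of SD ~1
    over a gradient spanning [-2, 2], early-burst trait evolution
    (``trait_conservatism``) so niches are clade-heritable, and three
    disjoint taxon pools for dispersal limitation; see docs/methods.md
    for the reasoning behind each value.
    """

    scenario: str
    n_taxa: int = 128
    n_sites: int = 12
    reads_per_site: int = 2000
    niche_sigma: float = 0.25
    brownian_rate: float = 5.0
    trait_conservatism: float = 5.0
    env_range: tuple = (-2.0, 2.0)
    homogeneous_env: float = 1.0
    clade_frac: tuple = (0.2, 0.45)
    clade_occupancy: float = 0.5
    local_abundance_logsd: float = 0.5
    n_pools: int = 3
    pool_overlap: float = 0.0
    metacommunity_logsd: float = 1.5
    mixing_pool_size: int = 100_000
    drift_effective_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_taxa, self.n_sites, self.reads_per_site) < 1:
            raise ValueError("counts must be >= 1")
        if self.niche_sigma <= 0:
            raise ValueError("niche breadth sigma must be positive")


def _selection_counts(rng, optima, env_values, sigma, reads):
    rows = []
    for env in env_values:
        w = np.exp(-((optima - env) ** 2) / (2.0 * sigma**2))
        total = w.sum()
        if total <= 0:
            raise ValueError("no taxon has support at this environment")
        rows.append(rng.multinomial(reads, w / total))
    return np.array(rows)


def _lognormal_metacommunity(rng, n_taxa, logsd):
    p = rng.lognormal(0.0, logsd, size=n_taxa)
    return p / p.sum()


def _best_matching_clade(tree, optima: pd.Series, env: float, frac: tuple):
    """Tip names of the clade whose mean optimum best matches ``env``.

    Candidates are subtrees holding between ``frac[0]`` and ``frac[1]`` of
    all tips; among them the one minimizing |mean optimum - env| wins.
    """
    n_tips = optima.size
    best = None
    for node in tree.non_tips(include_self=False):
        names = [t.name for t in node.tips()]
        if frac[0] * n_tips <= len(names) <= frac[1] * n_tips:
            gap = abs(optima.loc[names].mean() - env)
            if best is None or gap < best[0]:
                best = (gap, names)
    if best is None:
        raise ValueError("no clade in the requested size range")
    return best[1]


def simulate_scenario(
    spec: ScenarioSpec,
    tree: TreeNode | None = None,
    optima: pd.Series | None = None,
    return_tree: bool = False,
):
    """Generate ``(OtuTable, metadata)`` under the scenario's process.

    ``tree``/``optima`` may be passed in (e.g. to share one phylogeny
    across scenarios); otherwise they are simulated from seeds spawned
    from ``spec.seed``.  With ``return_tree=True`` the result is
    ``(table, metadata, tree)``.  Metadata records the environmental
    value, a synthetic transect position, depths spanning the sampled
    water column, and alternating seasons.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_tree, s_opt, s_table = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    if tree is None:
        tree = simulate_tree(spec.n_taxa, seed=s_tree)
    tips = [t.name for t in tree.tips()]
    if optima is None:
        optima = evolve_niche_optima(
            tree,
            spec.brownian_rate,
            seed=s_opt,
            conservatism=spec.trait_conservatism,
        )
    optima = optima.loc[tips]
    rng = np.random.default_rng(s_table)
    n, reads = spec.n_sites, spec.reads_per_site
    lo, hi = spec.env_range

    if spec.scenario == "heterogeneous_selection":
        env = np.linspace(lo, hi, n)
        counts = _selection_counts(
            rng, optima.to_numpy(), env, spec.niche_sigma, reads
        )
    elif spec.scenario == "homogeneous_selection":
        env = np.full(n, spec.homogeneous_env)
        pool_names = _best_matching_clade(
            tree, optima, spec.homogeneous_env, spec.clade_frac
        )
        pool = np.array([tips.index(name) for name in pool_names])
        m = max(2, int(round(spec.clade_occupancy * len(pool))))
        counts = np.zeros((n, len(tips)), dtype=np.int64)
        for s in range(n):
            members = rng.choice(pool, size=m, replace=False)
            ab = np.zeros(len(tips))
            ab[members] = rng.lognormal(0.0, spec.local_abundance_logsd, m)
            counts[s] = rng.multinomial(reads, ab / ab.sum())
    elif spec.scenario == "dispersal_limitation":
        env = np.full(n, (lo + hi) / 2.0)
        order = rng.permutation(len(tips))
        pools = np.array_split(order, spec.n_pools)
        extra = int(round(spec.pool_overlap * len(tips) / spec.n_pools))
        weights = []
        for pool in pools:
            members = set(pool.tolist())
            if extra:
                members |= set(
                    rng.choice(len(tips), size=extra, replace=False).tolist()
                )
            if not members:
                raise ValueError("empty taxon sub-pool")
            w = np.zeros(len(tips))
            idx = np.fromiter(members, dtype=int)
            w[idx] = rng.lognormal(0.0, spec.metacommunity_logsd, size=len(idx))
            weights.append(w / w.sum())
        counts = np.array(
            [
                rng.multinomial(reads, weights[s * spec.n_pools // n])
                for s in range(n)
            ]
        )
    elif spec.scenario == "homogenizing_dispersal":
        env = np.full(n, (lo + hi) / 2.0)
        p = _lognormal_metacommunity(rng, len(tips), spec.metacommunity_logsd)
        pool = rng.multinomial(spec.mixing_pool_size, p).astype(float)
        q = pool / pool.sum()
        counts = np.array([rng.multinomial(reads, q) for _ in range(n)])
    else:  # drift
        env = np.full(n, (lo + hi) / 2.0)
        p = _lognormal_metacommunity(rng, len(tips), spec.metacommunity_logsd)
        counts = np.empty((n, len(tips)), dtype=np.int64)
        for s in range(n):
            local = rng.multinomial(spec.drift_effective_size, p).astype(float)
            counts[s] = rng.multinomial(reads, local / local.sum())

    sample_ids = [f"site{str(s + 1).zfill(2)}" for s in range(n)]
    table = OtuTable(pd.DataFrame(counts, index=sample_ids, columns=tips))
    meta = pd.DataFrame(
        {
            "depth_m": np.linspace(3.0, 1000.0, n),
            "latitude": 18.0 + 0.25 * np.arange(n),
            "longitude": 112.0 + 0.35 * np.arange(n),
            "season": ["spring", "summer"] * (n // 2) + ["spring"] * (n % 2),
            "env": env,
            "water_depth_m": 1300.0,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if return_tree:
        return table, meta, tree
    return table, meta


# -- small deterministic fixture ------------------------------------------

FIXTURE_NEWICK = (
    "((((OTU01:0.2,OTU02:0.2):0.3,(OTU03:0.1,OTU04:0.4):0.4):0.5,"
    "((OTU05:0.3,OTU06:0.3):0.2,OTU07:0.6):0.4):0.2,"
    "((OTU08:0.5,OTU09:0.5):0.3,OTU10:0.9):0.4);"
)

_FIXTURE_COUNTS = [
    [40, 30, 15, 10, 0, 0, 5, 0, 0, 0],
    [35, 35, 10, 15, 5, 0, 0, 0, 0, 0],
    [5, 0, 10, 30, 25, 20, 10, 0, 0, 0],
    [0, 5, 5, 25, 30, 20, 10, 5, 0, 0],
    [0, 0, 0, 5, 5, 10, 20, 25, 20, 15],
    [0, 0, 0, 0, 10, 5, 15, 30, 20, 20],
]

#: Bray-Curtis between fixture samples S1 and S2, by hand:
#: sum|x-y| = 5+5+5+5+5+0+5+0+0+0 = 30, sum(x+y) = 200 -> 0.15
FIXTURE_BRAY_S1_S2 = 0.15


def make_fixture(seed: int = 7) -> AnalysisBundle:
    """Six samples x ten taxa on a fixed toy tree, fully deterministic.

    The counts are literal (two samples per layer sliding along the tree,
    so surface/euphotic/mesopelagic groups occupy different clades) and
    hand-checkable: Bray-Curtis of the first two samples is exactly
    :data:`FIXTURE_BRAY_S1_S2`.  ``seed`` is recorded in provenance only.
    """
    otus = [f"OTU{k:02d}" for k in range(1, 11)]
    samples = [f"S{k}" for k in range(1, 7)]
    table = OtuTable(pd.DataFrame(_FIXTURE_COUNTS, index=samples, columns=otus))
    meta = pd.DataFrame(
        {
            "depth_m": [3.0, 3.0, 75.0, 75.0, 500.0, 500.0],
            "latitude": [18.0, 18.2, 18.4, 18.6, 18.8, 19.0],
            "longitude": [112.0, 112.3, 112.6, 112.9, 113.2, 113.5],
            "season": ["spring", "summer"] * 3,
            "water_depth_m": [30.0, 30.0, 1300.0, 1300.0, 1300.0, 1300.0],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    tree = tree_from_newick(FIXTURE_NEWICK)
    return align_bundle(table, tree, meta, provenance={"seed": seed, "source": "make_fixture"})
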