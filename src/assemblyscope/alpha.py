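"""Per-sample alpha diversity: observed richness, Shannon H' (nats),
effective number of species exp(H'), Faith's phylogenetic diversity, and
the Chao1 richness estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .core import AnalysisBundle, OtuTable

__all__ = [
    "richness",
    "shannon",
    "effective_species",
    "faith_pd",
    "chao1",
    "alpha_table",
]


def richness(counts) -> int:
    """Number of OTUs observed (count > 0)."""
    counts = np.asarray(counts)
    return int(np.count_nonzero(counts > 0))


def shannon(counts) -> float:
    """Shannon entropy H' in nats, over OTUs with positive counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def effective_species(shannon_h: float) -> float:
    """True diversity of order 1: exp(H')."""
    if shannon_h < 0:
        raise ValueError("Shannon entropy cannot be negative")
    return float(np.exp(shannon_h))


def faith_pd(counts, otu_ids, tree: TreeNode) -> float:
    """Faith's PD: branch length of the subtree spanning the observed OTUs.

    The path to the root is included, so a single-tip sample has PD equal
    to that tip's root distance.  An empty sample has PD 0.
    """
    counts = np.asarray(counts)
    if richness(counts) == 0:
        return 0.0
    return float(_skbio_faith_pd(counts, taxa=list(otu_ids), tree=tree))


def chao1(counts) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    ``S_obs + F1^2 / (2 F2)``, falling back to the bias-corrected
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when there are no doubletons.
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires integer counts")
    s_obs = richness(counts)
    f1 = int(np.count_nonzero(counts == 1))
    f2 = int(np.count_nonzero(counts == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def alpha_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """All alpha metrics per sample, joined with layer/region/season."""
    table: OtuTable = bundle.table
    rows = []
    for sid in table.sample_ids:
        counts = table.data.loc[sid].to_numpy()
        h = shannon(counts)
        rows.append(
            {
                "sample_id": sid,
                "richness": richness(counts),
                "shannon": h,
                "effective_species": effective_species(h),
                "faith_pd": faith_pd(counts, table.otu_ids, bundle.tree),
                "chao1": chao1(counts),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    for col in ("layer", "region", "season"):
        if col in bundle.metadata.columns:
            out[col] = bundle.metadata[col]
    return out
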