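#!/usr/bin/env python
"""Alpha diversity along the simulated environmental transect.

Reads the heterogeneous-selection dataset from 01, computes per-site
richness, Shannon H', exp(H'), Faith's PD and Chao1, and summarizes them
by depth band with rank tests and compact letters.

Writes results/alpha.tsv and results/alpha_by_band.tsv.
"""

import os

import pandas as pd

from assemblyscope import (
    align_bundle,
    alpha_table,
    read_metadata,
    read_otu_table,
    read_tree,
    summarize_groups,
)

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SRC = os.path.join(BASE, "scenarios", "heterogeneous_selection")


def main() -> None:
    table = read_otu_table(os.path.join(SRC, "otu.tsv"))
    tree = read_tree(os.path.join(SRC, "tree.nwk"))
    meta = read_metadata(os.path.join(SRC, "meta.tsv"))
    bundle = align_bundle(table, tree, meta)

    alpha = alpha_table(bundle)
    alpha["depth_band"] = pd.qcut(
        bundle.metadata["depth_m"], 3, labels=["upper", "mid", "deep"]
    )
    alpha.to_csv(os.path.join(BASE, "alpha.tsv"), sep="\t")

    summary = summarize_groups(alpha, "depth_band")
    summary.to_csv(os.path.join(BASE, "alpha_by_band.tsv"), sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        "\nUnder environmental filtering the niche pool shifts along the "
        "gradient; shared letters mark bands whose diversity does not "
        "differ at adjusted p = 0.05."
    )


if __name__ == "__main__":
    main()
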