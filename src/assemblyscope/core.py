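"""Core data model: OTU tables, phylogenies, sample metadata, and the
operations that prepare them for analysis (rarefaction, depth-layer and
region assignment, alignment of table/tree/metadata into one bundle).

Conventions
-----------
* An OTU table is held as a :class:`pandas.DataFrame` of non-negative
  integers with samples as rows and OTUs as columns.
* Trees are :class:`skbio.TreeNode` objects read from newick; they must be
  rooted (bifurcating root) and carry branch lengths on every non-root edge.
* Depth layers follow the mesopelagic-transect convention: 3 m casts are
  "surface", 50-100 m "euphotic", 100-200 m "transitional", 200-1000 m
  "mesopelagic".  Intervals are closed on the left and open on the right,
  with 1000 m included in the mesopelagic stratum.
"""

from __future__ import annotations

import io
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "AnalysisBundle",
    "read_otu_table",
    "read_tree",
    "read_metadata",
    "rarefy",
    "assign_layer",
    "assign_region",
    "align_bundle",
    "write_bundle",
    "read_bundle",
]

LAYERS = ("surface", "euphotic", "transitional", "mesopelagic")

#: metadata columns that must be present
REQUIRED_META = ("depth_m",)


@dataclass
class OtuTable:
    """Sample x OTU matrix of read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are OTUs, cells are non-negative integer
        read counts.  Validated on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty table")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric cell")
        if np.any(values < 0):
            raise ValueError("negative count")
        if not np.allclose(values, np.round(values)):
            raise ValueError("non-integer cell")
        self.data = df.astype(np.int64)
        if np.any(self.data.sum(axis=1).to_numpy() <= 0):
            raise ValueError("sample with zero total reads")

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; each row sums to 1."""
        return self.data.div(self.data.sum(axis=1), axis=0)

    def select_samples(self, ids) -> "OtuTable":
        sub = self.data.loc[list(ids)]
        keep = sub.columns[sub.sum(axis=0) > 0]
        return OtuTable(sub[keep])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.data.equals(other.data)


@dataclass
class AnalysisBundle:
    """An OTU table, a phylogeny, and sample metadata sharing sample ids."""

    table: OtuTable
    tree: TreeNode
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids


def read_otu_table(path, orientation: str = "auto") -> OtuTable:
    """Read a TSV OTU table, normalizing orientation to samples x OTUs.

    ``orientation`` is one of ``"samples"`` (rows are samples), ``"otus"``
    (rows are OTUs, as in classic ``#OTU_ID`` tables), or ``"auto"`` which
    keys off the first header cell: ``#OTU_ID`` means rows are OTUs,
    ``sample_id`` means rows are samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    first_cell = df.index.name or ""
    if orientation == "auto":
        if first_cell.lstrip("#").lower() in ("otu_id", "otuid", "otu id"):
            orientation = "otus"
        elif first_cell.lower() in ("sample_id", "sampleid", "sample id", ""):
            orientation = "samples"
        else:
            raise ValueError(
                f"cannot infer orientation from header cell {first_cell!r}; "
                "pass orientation='samples' or 'otus'"
            )
    if orientation == "otus":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df)


def read_tree(path, root_policy: str | None = None) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    A trifurcating (or higher) root is treated as unrooted and rejected
    unless ``root_policy="midpoint"`` is given, in which case the tree is
    midpoint-rooted.  Every non-root edge must have a non-negative length.
    """
    tree = TreeNode.read(path if hasattr(path, "read") else str(path))
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")
    if len(tree.children) > 2:
        if root_policy == "midpoint":
            tree = tree.root_at_midpoint()
        else:
            raise ValueError(
                "unrooted tree (multifurcating root); pass "
                "root_policy='midpoint' to root it"
            )
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at {node.name!r}")
        if node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def total_branch_length(tree: TreeNode) -> float:
    return float(
        sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    )


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (required: sample_id, depth_m)."""
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    for col in REQUIRED_META:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if (meta["depth_m"] < 0).any():
        raise ValueError("negative depth_m")
    if "latitude" in meta.columns and not meta["latitude"].dropna().between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if "longitude" in meta.columns and not meta["longitude"].dropna().between(-180, 180).all():
        raise ValueError("longitude outside [-180, 180]")
    return meta


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int,
    n_draws: int = 1,
) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    With ``n_draws > 1`` the element-wise mean of repeated draws is
    rounded to the nearest integer (row sums then only approximate
    ``depth``); the default single draw matches standard practice of one
    seeded resampling.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums[sums >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: "
            + ", ".join(map(str, dropped))
        )
    if len(keep) == 0:
        raise ValueError("all samples below depth")
    rows = []
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        draws = np.stack(
            [
                rng.multivariate_hypergeometric(counts, depth)
                for _ in range(n_draws)
            ]
        )
        rows.append(np.round(draws.mean(axis=0)).astype(np.int64))
    sub = pd.DataFrame(rows, index=list(keep), columns=table.data.columns)
    keep_otus = sub.columns[sub.sum(axis=0) > 0]
    return OtuTable(sub[keep_otus])


def assign_layer(depth_m: float) -> str:
    """Map a sampling depth (m) to its ecological layer.

    [0, 50) surface, [50, 100) euphotic, [100, 200) transitional,
    [200, 1000] mesopelagic; depths beyond 1000 m are outside the sampled
    range and raise.
    """
    if depth_m < 0:
        raise ValueError("negative depth")
    if depth_m < 50:
        return "surface"
    if depth_m < 100:
        return "euphotic"
    if depth_m < 200:
        return "transitional"
    if depth_m <= 1000:
        return "mesopelagic"
    raise ValueError("depth beyond 1000 m is outside the layer scheme")


def assign_region(station_water_depth_m: float) -> str:
    """Nearshore iff the station's water-column depth is < 50 m."""
    if station_water_depth_m <= 0:
        raise ValueError("water depth must be positive")
    return "nearshore" if station_water_depth_m < 50 else "offshore"


def annotate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Add derived layer/region columns where the inputs are present."""
    out = meta.copy()
    out["layer"] = out["depth_m"].map(assign_layer)
    if "water_depth_m" in out.columns:
        out["region"] = out["water_depth_m"].map(assign_region)
    return out


def align_bundle(
    table: OtuTable,
    tree: TreeNode,
    metadata: pd.DataFrame,
    provenance: dict | None = None,
) -> AnalysisBundle:
    """Restrict table/tree/metadata to shared samples and tree-covered OTUs.

    Samples are intersected between table and metadata (order follows the
    table); OTUs absent from the tree are pruned from the table with a
    warning; the tree is sheared to the table's OTUs.
    """
    common = [s for s in table.sample_ids if s in metadata.index]
    if not common:
        raise ValueError("no samples shared between table and metadata")
    n_drop_samples = table.n_samples - len(common)
    if n_drop_samples:
        warnings.warn(f"dropping {n_drop_samples} sample(s) absent from metadata")
    table = table.select_samples(common)

    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        warnings.warn(f"pruning {len(missing)} OTU(s) absent from the tree")
        kept = [o for o in table.otu_ids if o in tips]
        if not kept:
            raise ValueError("no OTUs shared between table and tree")
        table = OtuTable(table.data[kept])
    tree = tree.shear(table.otu_ids)
    tree.prune()

    prov = dict(provenance or {})
    prov.update(
        dropped_samples=n_drop_samples, pruned_otus=len(missing)
    )
    meta = annotate_metadata(metadata.loc[table.sample_ids])
    return AnalysisBundle(table, tree, meta, prov)


# -- on-disk bundle (TSV + newick + JSON), used by the CLI -----------------

def write_bundle(bundle: AnalysisBundle, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle.table.to_tsv(os.path.join(out_dir, "otu_table.tsv"))
    bundle.tree.write(os.path.join(out_dir, "tree.nwk"))
    meta = bundle.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t")
    with open(os.path.join(out_dir, "bundle.json"), "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, default=str)


def read_bundle(in_dir) -> AnalysisBundle:
    table = read_otu_table(os.path.join(in_dir, "otu_table.tsv"))
    tree = read_tree(os.path.join(in_dir, "tree.nwk"))
    meta = read_metadata(os.path.join(in_dir, "metadata.tsv"))
    prov_path = os.path.join(in_dir, "bundle.json")
    prov = {}
    if os.path.exists(prov_path):
        with open(prov_path) as fh:
            prov = json.load(fh)
    return align_bundle(table, tree, meta, prov)


def tree_from_newick(newick: str) -> TreeNode:
    """Parse a newick string through the same validation as :func:`read_tree`."""
    return read_tree(io.StringIO(newick))
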