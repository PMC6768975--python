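"""End-to-end orchestration: ingest -> rarefy -> alpha -> beta/ordination
-> group tests -> composition drivers -> assembly processes, with every
stage's table written as TSV plus one ``run.json`` manifest.
"""

from __future__ import annotations

import json
import os
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu, false_discovery_control

from . import __version__
from .alpha import alpha_table
from .assembly import assembly_analysis
from .beta import bray_curtis, depth_distance, env_distance, geo_distance, pcoa
from .core import AnalysisBundle, align_bundle, rarefy
from .drivers import indval, simper
from .group_tests import anosim, mantel, mrpp, partial_mantel, permanova

__all__ = ["RunConfig", "run_pipeline", "summarize_groups", "compact_letters"]

ALPHA_METRICS = ("richness", "shannon", "effective_species", "faith_pd", "chao1")


@dataclass
class RunConfig:
    """Knobs of a full pipeline run (defaults match the study design)."""

    rarefaction_depth: int = 7597
    permutations: int = 999
    seed: int = 42
    group_var: str = "layer"
    env_vars: list = field(default_factory=list)
    out_dir: str = "run_out"
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    null_pool: str = "tree"

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if self.permutations < 99:
            raise ValueError("need at least 99 permutations")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: RunConfig, bundle: AnalysisBundle) -> dict:
    """Run every analysis stage on a bundle and write the report files.

    Outputs under ``config.out_dir``: alpha.tsv, bray_curtis.tsv,
    pcoa.tsv, tests.tsv, simper.tsv, indicators.tsv, assembly_pairs.tsv,
    assembly_summary.tsv and run.json.  Partial outputs are removed if a
    stage fails.  Returns the stage results as DataFrames.
    """
    out = config.out_dir
    created = not os.path.exists(out)
    os.makedirs(out, exist_ok=True)
    try:
        return _run_stages(config, bundle)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for name in _OUTPUT_FILES:
                path = os.path.join(out, name)
                if os.path.exists(path):
                    os.remove(path)
        raise


_OUTPUT_FILES = (
    "alpha.tsv",
    "bray_curtis.tsv",
    "pcoa.tsv",
    "tests.tsv",
    "simper.tsv",
    "indicators.tsv",
    "assembly_pairs.tsv",
    "assembly_summary.tsv",
    "run.json",
)


def _run_stages(config: RunConfig, bundle: AnalysisBundle) -> dict:
    out = config.out_dir
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("rarefy", "tests", "indval", "assembly"), ss.spawn(4)
        )
    }
    log: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rare = rarefy(bundle.table, config.rarefaction_depth, seeds["rarefy"])
        log.extend(str(w.message) for w in caught)
    bundle = align_bundle(rare, bundle.tree, bundle.metadata, bundle.provenance)
    meta = bundle.metadata
    if config.group_var not in meta.columns:
        raise ValueError(f"grouping variable {config.group_var!r} not in metadata")
    groups = meta[config.group_var]

    alpha = alpha_table(bundle)
    alpha.to_csv(os.path.join(out, "alpha.tsv"), sep="\t")

    dm = bray_curtis(bundle.table)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        os.path.join(out, "bray_curtis.tsv"), sep="\t"
    )
    ordination = pcoa(dm)
    coords = ordination.coordinates.copy()
    coords.to_csv(os.path.join(out, "pcoa.tsv"), sep="\t")

    n_perm = config.permutations
    tests = []
    usable = groups.value_counts()
    usable = usable[usable >= 2]
    if len(usable) >= 2:
        keep = groups.isin(usable.index)
        sub_dm = dm.filter(list(groups.index[keep]))
        sub_groups = groups[keep]
        for fn in (anosim, permanova, mrpp):
            res = fn(sub_dm, sub_groups, n_perm=n_perm, seed=seeds["tests"])
            tests.append(
                {
                    "test": res.test,
                    "factor": config.group_var,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    **res.extras,
                }
            )
    d_depth = depth_distance(meta)
    distance_factors = {"depth": d_depth}
    if {"latitude", "longitude"}.issubset(meta.columns):
        distance_factors["geo_distance"] = geo_distance(meta)
    if config.env_vars:
        distance_factors["environment"] = env_distance(meta, config.env_vars)
    for name, dist in distance_factors.items():
        res = mantel(dm, dist, n_perm=n_perm, seed=seeds["tests"])
        tests.append(
            {
                "test": "mantel",
                "factor": name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
        controls = {c: d for c, d in distance_factors.items() if c != name}
        for cname, cdist in controls.items():
            res = partial_mantel(
                dm, dist, cdist, n_perm=n_perm, seed=seeds["tests"]
            )
            tests.append(
                {
                    "test": "partial_mantel",
                    "factor": f"{name}|{cname}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    tests_df = pd.DataFrame(tests)
    tests_df.to_csv(os.path.join(out, "tests.tsv"), sep="\t", index=False)

    simper_frames = []
    for g1, g2 in combinations(sorted(usable.index), 2):
        rec = simper(bundle.table, groups, (g1, g2))
        rec.insert(0, "group_pair", f"{g1}~{g2}")
        simper_frames.append(rec)
    simper_df = (
        pd.concat(simper_frames, ignore_index=True)
        if simper_frames
        else pd.DataFrame()
    )
    simper_df.to_csv(os.path.join(out, "simper.tsv"), sep="\t", index=False)

    if groups.nunique() >= 2:
        ind_df = indval(bundle.table, groups, n_perm=n_perm, seed=seeds["indval"])
    else:
        ind_df = pd.DataFrame()
    ind_df.to_csv(os.path.join(out, "indicators.tsv"), sep="\t", index=False)

    pairs, summary = assembly_analysis(
        bundle.table,
        bundle.tree,
        groups=groups,
        reps=n_perm,
        seed=seeds["assembly"],
        pool=config.null_pool,
    )
    pairs.to_csv(os.path.join(out, "assembly_pairs.tsv"), sep="\t", index=False)
    summary.to_csv(os.path.join(out, "assembly_summary.tsv"), sep="\t")

    manifest = {
        "config": asdict(config),
        "stage_seeds": seeds,
        "version": __version__,
        "n_samples": bundle.table.n_samples,
        "n_otus": bundle.table.n_otus,
        "log": log,
        "provenance": bundle.provenance,
    }
    with open(os.path.join(out, "run.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "alpha": alpha,
        "bray_curtis": dm,
        "pcoa": ordination,
        "tests": tests_df,
        "simper": simper_df,
        "indicators": ind_df,
        "assembly_pairs": pairs,
        "assembly_summary": summary,
        "manifest": manifest,
    }


def compact_letters(groups: list, significant: set) -> dict:
    """Compact letter display from a set of significantly-different pairs.

    Insert-and-absorb: start with one letter covering all groups; for each
    significant pair split every letter containing both; absorb letter
    sets contained in another.  Groups share a letter iff they are not
    significantly different (for transitive significance patterns).
    """
    letters: list[set] = [set(groups)]
    for a, b in significant:
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            letters.extend([s - {a}, s - {b}])
        letters = [
            s
            for s in letters
            if s and not any(s < t for t in letters if t is not s)
        ]
    # deduplicate while keeping order stable by first group
    uniq = []
    for s in letters:
        if s not in uniq:
            uniq.append(s)
    uniq.sort(key=lambda s: [groups.index(g) for g in sorted(s, key=groups.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, uniq):
        for g in s:
            out[g] += letter
    return out


def summarize_groups(
    alpha: pd.DataFrame, group_col: str, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Group means/SDs of alpha metrics with rank-test letter displays.

    Pairwise two-sided Mann-Whitney tests per metric, Benjamini-Hochberg
    adjusted across the pairs of that metric; groups that differ at the
    adjusted threshold get disjoint letters.  Groups with fewer than 2
    samples are excluded with a warning.
    """
    if group_col not in alpha.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    sizes = alpha[group_col].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding group(s) with < 2 samples: {small}")
    data = alpha[alpha[group_col].isin(sizes[sizes >= 2].index)]
    groups = sorted(data[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")
    rows = []
    for metric in ALPHA_METRICS:
        if metric not in data.columns:
            continue
        pairs = list(combinations(groups, 2))
        pvals = []
        for g1, g2 in pairs:
            x = data.loc[data[group_col] == g1, metric]
            y = data.loc[data[group_col] == g2, metric]
            if x.nunique() == 1 and y.nunique() == 1 and x.iat[0] == y.iat[0]:
                pvals.append(1.0)
            else:
                pvals.append(float(mannwhitneyu(x, y, method="exact").pvalue))
        adj = false_discovery_control(pvals, method="bh") if pvals else []
        significant = {
            pair for pair, p in zip(pairs, adj) if p < p_threshold
        }
        letters = compact_letters(groups, significant)
        for g in groups:
            vals = data.loc[data[group_col] == g, metric]
            rows.append(
                {
                    "metric": metric,
                    "group": g,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "letters": letters[g],
                }
            )
    return pd.DataFrame(rows)
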