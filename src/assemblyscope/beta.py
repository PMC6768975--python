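"""Pairwise dissimilarity and ordination: Bray-Curtis, principal
coordinate analysis, geographic/environmental/depth distance matrices, and
the distance-decay regression of community dissimilarity on space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from skbio import DistanceMatrix

from .core import OtuTable

__all__ = [
    "bray_curtis",
    "pcoa",
    "Ordination",
    "geo_distance",
    "env_distance",
    "depth_distance",
    "distance_decay",
]

EARTH_RADIUS_KM = 6371.0


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(x, y) = sum_k |x_k - y_k| / sum_k (x_k + y_k), computed on counts;
    on equal-depth (rarefied) tables this equals the relative-abundance
    version.
    """
    counts = table.counts.astype(float)
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("sample with zero total reads")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on positive-eigenvalue axes.

    ``eigenvalues`` keeps the full spectrum, negatives included;
    ``proportion_explained`` is per positive axis, relative to the sum of
    positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers ``-0.5 * D**2``, eigendecomposes, and scales the
    eigenvectors of positive eigenvalues by ``sqrt(eigenvalue)``.  Negative
    eigenvalues are reported untransformed and excluded from coordinates
    and from the proportion-explained denominator.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # clip numerically-zero eigenvalues so degenerate inputs give 0 axes
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def geo_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distance between sample sites, in km."""
    for col in ("latitude", "longitude"):
        if col not in metadata.columns or metadata[col].isna().any():
            raise ValueError("metadata must have complete latitude/longitude")
    lat = np.radians(metadata["latitude"].to_numpy(float))
    lon = np.radians(metadata["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=list(metadata.index))


def env_distance(metadata: pd.DataFrame, variables) -> DistanceMatrix:
    """Euclidean distance on z-standardized environmental variables.

    Zero-variance variables are dropped with a warning (they cannot be
    standardized and carry no contrast).
    """
    sub = metadata[list(variables)].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing environmental values")
    sd = sub.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance variable(s): {dead}")
        sub = sub.drop(columns=dead)
        sd = sd.drop(index=dead)
    if sub.shape[1] == 0:
        raise ValueError("no environmental variables with variance")
    z = (sub - sub.mean(axis=0)) / sd
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=list(metadata.index))


def depth_distance(metadata: pd.DataFrame) -> DistanceMatrix:
    """|depth_i - depth_j| in metres."""
    depth = metadata["depth_m"].to_numpy(float)
    d = np.abs(depth[:, None] - depth[None, :])
    return DistanceMatrix(d, ids=list(metadata.index))


def distance_decay(d_comm: DistanceMatrix, d_space: DistanceMatrix):
    """OLS of community dissimilarity on spatial distance (upper triangles).

    Returns ``(slope, intercept, r)``.  A positive slope means
    dissimilarity grows — equivalently similarity decays — with distance.
    """
    if list(d_comm.ids) != list(d_space.ids):
        raise ValueError("distance matrices must share ids in order")
    iu = np.triu_indices(d_comm.shape[0], k=1)
    y = d_comm.data[iu]
    x = d_space.data[iu]
    if np.allclose(x, x[0]):
        raise ValueError("constant spatial predictor")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
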