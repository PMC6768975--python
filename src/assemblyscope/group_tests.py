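"""Permutation tests on distance matrices: ANOSIM, one-way PERMANOVA
(Adonis), MRPP, Mantel, and partial Mantel.

All tests share the permutation p-value estimator
``p = (count + 1) / (n_perm + 1)`` (so the smallest attainable p at 999
permutations is 0.001) and are bit-reproducible for a fixed seed.  For
ANOSIM/PERMANOVA/Mantel the count is of permuted statistics >= observed;
for MRPP it is of permuted deltas <= observed (small delta = tight groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = [
    "GroupTestResult",
    "anosim",
    "permanova",
    "mrpp",
    "mantel",
    "partial_mantel",
]


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    extras: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, table-friendly
        extras = "".join(f", {k}={v:.4g}" for k, v in self.extras.items())
        return (
            f"{self.test}(stat={self.statistic:.4f}, p={self.p_value:.4g}"
            f"{extras}, n_perm={self.n_permutations})"
        )


def _as_groups(groups, ids):
    groups = np.asarray(list(groups))
    if len(groups) != len(ids):
        raise ValueError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = labels[sizes < 2].tolist()
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    return labels, codes


def _perm_pvalue(count: int, n_perm: int) -> float:
    return (count + 1) / (n_perm + 1)


def anosim(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Analysis of similarities on ranked dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2; ties get average ranks.  p by random relabeling.
    """
    labels, codes = _as_groups(groups, dm.ids)
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    m = n * (n - 1) / 2

    def stat(c):
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = stat(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += stat(rng.permutation(codes)) >= r_obs
    return GroupTestResult(
        "anosim", float(r_obs), _perm_pvalue(count, n_perm), n_perm, seed
    )


def _permanova_ss(d2_cond, iu, codes, sizes, n):
    """(SS_total, SS_within) from squared condensed distances."""
    ss_total = d2_cond.sum() / n
    within = codes[iu[0]] == codes[iu[1]]
    ss_within = np.bincount(
        codes[iu[0]][within], weights=d2_cond[within], minlength=len(sizes)
    )
    return ss_total, float((ss_within / sizes).sum())


def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    pseudo-F = (SS_between / (a-1)) / (SS_within / (n-a));
    R^2 = SS_between / SS_total.  Statistic reported is pseudo-F, with
    R^2 in ``extras``; p by label permutation of pseudo-F.
    """
    labels, codes = _as_groups(groups, dm.ids)
    n, a = len(codes), len(labels)
    iu = np.triu_indices(n, k=1)
    d2 = dm.data[iu] ** 2

    def stats(c):
        sizes = np.bincount(c, minlength=a)
        ss_t, ss_w = _permanova_ss(d2, iu, c, sizes, n)
        ss_b = ss_t - ss_w
        if ss_w <= 0:
            f = np.inf
        else:
            f = (ss_b / (a - 1)) / (ss_w / (n - a))
        return f, ss_b / ss_t if ss_t > 0 else 0.0

    f_obs, r2 = stats(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += stats(rng.permutation(codes))[0] >= f_obs
    return GroupTestResult(
        "permanova",
        float(f_obs),
        _perm_pvalue(count, n_perm),
        n_perm,
        seed,
        extras={"R2": float(r2)},
    )


def mrpp(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Multiple response permutation procedure.

    delta = sum_g (n_g / n) * mean within-group distance; chance-corrected
    agreement A = 1 - delta_obs / mean(delta_perm); p is the fraction of
    permuted deltas <= observed (+1-corrected).
    """
    labels, codes = _as_groups(groups, dm.ids)
    n, a = len(codes), len(labels)
    iu = np.triu_indices(n, k=1)
    d = dm.data[iu]

    def delta(c):
        sizes = np.bincount(c, minlength=a)
        within = c[iu[0]] == c[iu[1]]
        sums = np.bincount(c[iu[0]][within], weights=d[within], minlength=a)
        n_pairs = sizes * (sizes - 1) / 2
        return float(((sums / n_pairs) * (sizes / n)).sum())

    delta_obs = delta(codes)
    rng = np.random.default_rng(seed)
    perm = np.array([delta(rng.permutation(codes)) for _ in range(n_perm)])
    a_stat = 1.0 - delta_obs / perm.mean()
    count = int((perm <= delta_obs).sum())
    return GroupTestResult(
        "mrpp",
        float(a_stat),
        _perm_pvalue(count, n_perm),
        n_perm,
        seed,
        extras={"delta": delta_obs},
    )


def _triu_vec(dm: DistanceMatrix) -> np.ndarray:
    iu = np.triu_indices(dm.shape[0], k=1)
    return dm.data[iu]


def _pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dx: DistanceMatrix, dy: DistanceMatrix, n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the unfolded upper triangles; p is
    one-sided (r_perm >= r_obs) under simultaneous row/column permutation
    of the first matrix.
    """
    if list(dx.ids) != list(dy.ids):
        raise ValueError("distance matrices must share ids in order")
    n = dx.shape[0]
    if n < 4:
        raise ValueError("mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    y = dy.data[iu]
    r_obs = _pearson(dx.data[iu], y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        count += _pearson(dx.data[np.ix_(p, p)][iu], y) >= r_obs
    return GroupTestResult(
        "mantel", r_obs, _perm_pvalue(count, n_perm), n_perm, seed
    )


def _partial_r(rxy, rxz, ryz) -> float:
    denom = (1 - rxz**2) * (1 - ryz**2)
    if denom <= 0:
        raise ValueError("degenerate control matrix (|r| = 1)")
    return (rxy - rxz * ryz) / np.sqrt(denom)


def partial_mantel(
    dx: DistanceMatrix, dy: DistanceMatrix, dz: DistanceMatrix,
    n_perm: int = 999, seed: int | None = None,
) -> GroupTestResult:
    """Partial Mantel correlation of dx with dy controlling for dz.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); p by
    permuting rows/columns of dx while dy and dz stay fixed.
    """
    for other in (dy, dz):
        if list(dx.ids) != list(other.ids):
            raise ValueError("distance matrices must share ids in order")
    n = dx.shape[0]
    if n < 4:
        raise ValueError("partial mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    x, y, z = dx.data[iu], dy.data[iu], dz.data[iu]
    ryz = _pearson(y, z)
    r_obs = _partial_r(_pearson(x, y), _pearson(x, z), ryz)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        xp = dx.data[np.ix_(p, p)][iu]
        count += _partial_r(_pearson(xp, y), _pearson(xp, z), ryz) >= r_obs
    return GroupTestResult(
        "partial_mantel", float(r_obs), _perm_pvalue(count, n_perm), n_perm, seed
    )
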