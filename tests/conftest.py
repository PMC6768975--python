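import numpy as np
import pandas as pd
import pytest

from assemblyscope import OtuTable, make_fixture, tree_from_newick

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def toy_tree():
    """Four-tip balanced tree with unit branch lengths (total length 6)."""
    return tree_from_newick(TOY_NEWICK)


@pytest.fixture
def fixture_bundle():
    """The deterministic 6-sample x 10-OTU bundle."""
    return make_fixture()


@pytest.fixture
def random_table():
    """A 12-sample x 30-OTU table of seeded random counts."""
    rng = np.random.default_rng(1234)
    counts = rng.integers(0, 50, size=(12, 30))
    counts[:, 0] += 1  # keep every row nonzero
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i:02d}" for i in range(12)],
            columns=[f"o{i:02d}" for i in range(30)],
        )
    )


def beta_mntd_brute(x, y, dist, ids):
    """Brute-force nearest-taxon double loop; oracle for beta_mntd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fx, fy = x / x.sum(), y / y.sum()
    total = 0.0
    for i in np.flatnonzero(x > 0):
        best = min(dist[ids[i]][ids[j]] for j in np.flatnonzero(y > 0))
        total += 0.5 * fx[i] * best
    for j in np.flatnonzero(y > 0):
        best = min(dist[ids[j]][ids[i]] for i in np.flatnonzero(x > 0))
        total += 0.5 * fy[j] * best
    return total
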