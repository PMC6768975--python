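import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscope import (
    OtuTable,
    assembly_analysis,
    beta_mntd,
    beta_nti,
    classify_pair,
    cophenetic_distances,
    quantify_processes,
    raup_crick_bray,
    rc_from_counts,
)
from conftest import beta_mntd_brute


class TestCopheneticDistances:
    def test_hand_values_on_toy_tree(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["C", "D"] == pytest.approx(2.0)

    def test_star_tree_equidistant(self):
        tree = TreeNode.read(["(A:1.5,B:1.5,C:1.5,D:1.5);"])
        dm = cophenetic_distances(tree)
        off = dm.data[np.triu_indices(4, k=1)]
        np.testing.assert_allclose(off, 3.0)

    def test_zero_diagonal(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        np.testing.assert_allclose(np.diag(dm.data), 0.0)


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        x = pd.Series([1, 2, 0, 0], index=list(dm.ids))
        assert beta_mntd(x, x, dm) == 0.0

    def test_single_taxon_pair(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        ids = list(dm.ids)
        x = pd.Series(0, index=ids)
        y = pd.Series(0, index=ids)
        x["A"], y["C"] = 1, 1
        assert beta_mntd(x.to_numpy(), y.to_numpy(), dm) == pytest.approx(4.0)

    def test_weighted_pair_by_hand(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        ids = list(dm.ids)
        x = pd.Series(0.0, index=ids)
        y = pd.Series(0.0, index=ids)
        x["A"], x["B"] = 0.5, 0.5
        y["C"] = 1.0
        # each side's nearest-taxon distance is 4 on this tree
        assert beta_mntd(x.to_numpy(), y.to_numpy(), dm) == pytest.approx(4.0)

    def test_symmetry(self, fixture_bundle):
        dm = cophenetic_distances(fixture_bundle.tree)
        table = fixture_bundle.table.data[list(dm.ids)]
        a = beta_mntd(table.iloc[0], table.iloc[3], dm)
        b = beta_mntd(table.iloc[3], table.iloc[0], dm)
        assert a == pytest.approx(b, abs=1e-15)

    def test_matches_brute_force_on_fixture(self, fixture_bundle):
        dm = cophenetic_distances(fixture_bundle.tree)
        ids = list(dm.ids)
        table = fixture_bundle.table.data[ids]
        dist = {
            i: {j: dm[i, j] for j in ids} for i in ids
        }
        for i in range(6):
            for j in range(i + 1, 6):
                fast = beta_mntd(table.iloc[i], table.iloc[j], dm)
                brute = beta_mntd_brute(
                    table.iloc[i].to_numpy(), table.iloc[j].to_numpy(), dist, ids
                )
                assert fast == pytest.approx(brute, abs=1e-12)

    def test_empty_community_rejected(self, toy_tree):
        dm = cophenetic_distances(toy_tree)
        with pytest.raises(ValueError, match="empty"):
            beta_mntd([0, 0, 0, 0], [1, 0, 0, 0], dm)


class TestBetaNti:
    def test_observed_equal_to_null_mean_gives_zero(self, fixture_bundle):
        out = beta_nti(
            fixture_bundle.table, fixture_bundle.tree, reps=199, seed=0
        )
        recomputed = (out.beta_mntd_obs - out.null_mean) / out.null_sd
        np.testing.assert_allclose(out.beta_nti, recomputed)

    def test_star_tree_null_is_degenerate(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        table = OtuTable(
            pd.DataFrame(
                [[5, 5, 0, 0], [0, 0, 5, 5]],
                index=["s1", "s2"],
                columns=["A", "B", "C", "D"],
            )
        )
        out = beta_nti(table, tree, reps=99, seed=0)
        assert bool(out["degenerate"].iloc[0])
        assert np.isnan(out["beta_nti"].iloc[0])

    def test_seed_reproducibility(self, fixture_bundle):
        a = beta_nti(fixture_bundle.table, fixture_bundle.tree, reps=99, seed=3)
        b = beta_nti(fixture_bundle.table, fixture_bundle.tree, reps=99, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_pair_pool_randomization_runs(self, fixture_bundle):
        out = beta_nti(
            fixture_bundle.table, fixture_bundle.tree, reps=99, seed=3, pool="pair"
        )
        assert len(out) == 15
        assert out["null_sd"].notna().all()


class TestRaupCrick:
    def test_tie_formula_is_exact(self):
        assert rc_from_counts(499, 1, 999) == 0.0
        assert rc_from_counts(999, 0, 999) == 1.0
        assert rc_from_counts(0, 0, 999) == -1.0

    def test_bounds_on_random_pairs(self, random_table):
        out = raup_crick_bray(random_table, reps=199, seed=0)
        assert out["rc_bray"].between(-1, 1).all()

    def test_seed_reproducibility(self, random_table):
        a = raup_crick_bray(random_table, reps=99, seed=5)
        b = raup_crick_bray(random_table, reps=99, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_null_drawn_pairs_are_rarely_extreme(self):
        """Communities produced by the RC null generator itself should
        rarely reach |RC| >= 0.95."""
        from assemblyscope.assembly import _null_communities

        rng = np.random.default_rng(8)
        counts = rng.multinomial(500, rng.dirichlet(np.ones(40)), size=10)
        counts[:, 0] += 1
        occ = (counts > 0).sum(axis=0).astype(float)
        ab = counts.sum(axis=0).astype(float)
        redrawn = np.vstack(
            [
                _null_communities(
                    rng, 1, int((row > 0).sum()), int(row.sum()),
                    occ / occ.sum(), ab / ab.sum(),
                )
                for row in counts
            ]
        )
        base = OtuTable(
            pd.DataFrame(
                redrawn,
                index=[f"s{i}" for i in range(10)],
                columns=[f"o{i}" for i in range(40)],
            )
        )
        out = raup_crick_bray(base, reps=199, seed=9)
        assert (out["rc_bray"].abs() >= 0.95).mean() <= 0.15

    def test_single_sample_metacommunity_rejected(self):
        t = OtuTable(pd.DataFrame([[1, 2]], index=["s1"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            raup_crick_bray(t, reps=99, seed=0)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti,rc,label",
        [
            (2.5, 0.1, "heterogeneous_selection"),
            (2.01, -0.99, "heterogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (1.99, 0.951, "dispersal_limitation"),
            (0.5, -0.97, "homogenizing_dispersal"),
            (-0.3, 0.2, "undominated_drift"),
            (0.0, 0.0, "undominated_drift"),
            # boundaries fall through (strict inequalities)
            (2.0, 0.0, "undominated_drift"),
            (-2.0, 0.0, "undominated_drift"),
            (0.0, 0.95, "undominated_drift"),
            (0.0, -0.95, "undominated_drift"),
        ],
    )
    def test_truth_table(self, bnti, rc, label):
        assert classify_pair(bnti, rc) == label

    def test_undefined_beta_nti_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.5)


class TestQuantifyProcesses:
    def _pairs(self, labels, samples=None):
        n = len(labels)
        rows = []
        k = 0
        m = int((1 + np.sqrt(1 + 8 * n)) / 2)
        samples = samples or [f"s{i}" for i in range(m)]
        for i in range(m):
            for j in range(i + 1, m):
                rows.append(
                    {"sample_i": samples[i], "sample_j": samples[j], "process": labels[k]}
                )
                k += 1
        return pd.DataFrame(rows)

    def test_mesopelagic_arithmetic(self):
        # 7 samples -> 21 pairs split 12/7/2
        labels = (
            ["dispersal_limitation"] * 12
            + ["heterogeneous_selection"] * 7
            + ["undominated_drift"] * 2
        )
        out = quantify_processes(self._pairs(labels))
        row = out.loc["total"]
        assert row["n_pairs"] == 21
        assert 100 * row["dispersal_limitation"] == pytest.approx(57.1, abs=0.05)
        assert 100 * row["heterogeneous_selection"] == pytest.approx(33.3, abs=0.05)
        assert 100 * row["undominated_drift"] == pytest.approx(9.5, abs=0.05)

    def test_single_label_degenerate(self):
        out = quantify_processes(self._pairs(["homogenizing_dispersal"] * 3))
        assert out.loc["total", "homogenizing_dispersal"] == 1.0

    def test_fractions_partition_to_one(self, fixture_bundle):
        pairs, summary = assembly_analysis(
            fixture_bundle.table,
            fixture_bundle.tree,
            groups=fixture_bundle.metadata["layer"],
            reps=99,
            seed=0,
        )
        from assemblyscope import PROCESSES

        sums = summary[list(PROCESSES)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        # three layers of 2 samples -> one pair each
        for layer in ("surface", "euphotic", "mesopelagic"):
            assert summary.loc[layer, "n_pairs"] + summary.loc[layer, "n_degenerate"] == 1
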