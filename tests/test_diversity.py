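import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from guildscope import diversity, tabio


class TestShannon:
    @pytest.mark.parametrize(
        "comp, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1, 0, 0), 0.0),
            ((0.5, 0.25, 0.25), 1.5),
        ],
    )
    def test_known_values_base2(self, comp, expected):
        assert diversity.shannon(comp) == pytest.approx(expected)

    def test_base_parameter(self):
        assert diversity.shannon([1, 1, 1], base=3) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity.shannon([0, 0])


def test_observed_features_counts_nonzero():
    assert diversity.observed_features([5, 0, 3]) == 2
    assert diversity.observed_features([0, 0]) == 0


class TestRarefy:
    def test_columns_sum_to_depth(self, small_cohort):
        counts, _, _ = small_cohort
        rare = diversity.rarefy(counts, 2000, seed=1)
        assert (rare.sum(axis=0) == 2000).all()

    def test_depth_equal_to_total_is_identity(self):
        t = pd.DataFrame({"s": [4, 6, 0]}, index=list("abc"))
        rare = diversity.rarefy(t, 10, seed=0)
        assert rare["s"].tolist() == [4, 6, 0]

    def test_single_taxon_forced(self):
        t = pd.DataFrame({"s": [100]}, index=["only"])
        assert diversity.rarefy(t, 40, seed=0)["s"].tolist() == [40]

    def test_depth_one_observes_exactly_one_taxon(self):
        t = pd.DataFrame({"s": [5, 3, 2]}, index=list("abc"))
        rare = diversity.rarefy(t, 1, seed=3)
        assert diversity.observed_features(rare["s"]) == 1

    def test_shallow_samples_dropped(self):
        t = pd.DataFrame({"deep": [50, 50], "shallow": [2, 1]}, index=["a", "b"])
        rare = diversity.rarefy(t, 10, seed=0)
        assert list(rare.columns) == ["deep"]
        with pytest.raises(ValueError):
            diversity.rarefy(t, 1000, seed=0)

    def test_expected_relative_abundance_preserved(self):
        # mean over 200 seeded rarefactions stays within 2 SE of the truth
        col = np.array([500, 300, 150, 50])
        t = pd.DataFrame({"s": col}, index=list("abcd"))
        depth = 200
        draws = np.stack([diversity.rarefy(t, depth, seed=s)["s"].to_numpy() for s in range(200)])
        props = draws.mean(axis=0) / depth
        true_p = col / col.sum()
        se = np.sqrt(true_p * (1 - true_p) / depth / 200)
        assert (np.abs(props - true_p) <= 2 * se + 1e-12).all()


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]})
        assert diversity.bray_curtis(t).loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]})
        assert diversity.bray_curtis(t).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_formula(self):
        t = pd.DataFrame({"x": [0.5, 0.5, 0.0], "y": [0.25, 0.25, 0.5]})
        assert diversity.bray_curtis(t).loc["x", "y"] == pytest.approx(0.5)


class TestUnifrac:
    @pytest.fixture()
    def paired_tree(self, tmp_path):
        (tmp_path / "t.nwk").write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        return tabio.read_tree(tmp_path / "t.nwk")

    def test_identical_profiles_zero(self, paired_tree):
        t = pd.DataFrame({"s1": [1, 1, 0, 0], "s2": [1, 1, 0, 0]}, index=list("ABCD"))
        d = diversity.unifrac(t, paired_tree, weighted=False)
        assert d.loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_clades_distance_one(self, paired_tree):
        # sample1={A}, sample2={C}: no shared branch out of 4 covered units
        t = pd.DataFrame({"s1": [1, 0, 0, 0], "s2": [0, 0, 1, 0]}, index=list("ABCD"))
        d = diversity.unifrac(t, paired_tree, weighted=False)
        assert d.loc["s1", "s2"] == pytest.approx(1.0)

    def test_star_tree_equals_jaccard(self, tmp_path, rng):
        # on a star tree with unit branches, unweighted UniFrac is Jaccard distance
        # effectively a star: unit pendant branches, zero-length internal
        # branch so the root is bifurcating (required by the UniFrac driver)
        taxa = [f"L{i}" for i in range(8)]
        inner = ",".join(f"{t}:1" for t in taxa[1:])
        (tmp_path / "star.nwk").write_text(f"({taxa[0]}:1,({inner}):0);\n")
        tree = tabio.read_tree(tmp_path / "star.nwk")
        for _ in range(5):
            presence = rng.integers(0, 2, size=(8, 4))
            presence[0, :] = 1  # avoid empty samples
            t = pd.DataFrame(presence, index=taxa, columns=[f"s{j}" for j in range(4)])
            d = diversity.unifrac(t, tree, weighted=False)
            jac = squareform(pdist(presence.T.astype(bool), metric="jaccard"))
            np.testing.assert_allclose(d.to_numpy(), jac, atol=1e-12)

    def test_missing_taxon_rejected(self, paired_tree):
        t = pd.DataFrame({"s1": [1], "s2": [1]}, index=["Zebra"])
        with pytest.raises(ValueError, match="Zebra"):
            diversity.unifrac(t, paired_tree)

    def test_weighted_normalized_in_unit_interval(self, paired_tree, rng):
        t = pd.DataFrame(rng.integers(0, 50, size=(4, 5)), index=list("ABCD"))
        t.iloc[0] += 1
        d = diversity.unifrac(t, paired_tree, weighted=True)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()


class TestPcoa:
    def test_recovers_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]), index=list("wxyz"), columns=list("wxyz"))
        res = diversity.pcoa(d)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        recon = np.abs(res.coordinates["PC1"].to_numpy()[:, None] - res.coordinates["PC1"].to_numpy()[None, :])
        np.testing.assert_allclose(recon, d.to_numpy(), atol=1e-9)

    def test_equilateral_three_points_have_equal_eigenvalues(self):
        d = pd.DataFrame(1 - np.eye(3))
        res = diversity.pcoa(d)
        positive = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_duplicate_sample_zero_separation(self):
        pts = np.array([0.0, 0.0, 5.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]))
        res = diversity.pcoa(d)
        delta = res.coordinates.iloc[0] - res.coordinates.iloc[1]
        assert np.abs(delta.to_numpy()).max() < 1e-9

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            diversity.pcoa(d)


def _exhaustive_permanova_p(d, labels):
    """Exact permutation p-value by enumerating every relabeling."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    d2 = d**2
    groups = np.unique(labels)
    from guildscope.diversity import _permanova_stats

    gid = np.arange(len(groups))
    _, inv = np.unique(labels, return_inverse=True)
    f_obs, _ = _permanova_stats(d2, inv, gid)
    count = total = 0
    for perm in itertools.permutations(inv):
        f, _ = _permanova_stats(d2, np.array(perm), gid)
        total += 1
        count += f >= f_obs
    return count / total


class TestPermanova:
    def test_sampled_p_close_to_exhaustive_at_n6(self, rng):
        pts = rng.standard_normal((6, 2))
        pts[3:] += 1.5
        d = pd.DataFrame(squareform(pdist(pts)))
        labels = ["a", "a", "a", "b", "b", "b"]
        exact = _exhaustive_permanova_p(d, labels)
        res = diversity.permanova(d, labels, n_permutations=9999, seed=0)
        assert abs(res.p_value - exact) < 0.02

    def test_single_group_rejected(self):
        d = pd.DataFrame(1 - np.eye(4))
        with pytest.raises(ValueError, match="two groups"):
            diversity.permanova(d, ["g"] * 4)

    def test_group_of_one_rejected(self):
        d = pd.DataFrame(1 - np.eye(4))
        with pytest.raises(ValueError, match="needs >="):
            diversity.permanova(d, ["a", "b", "b", "b"])

    def test_label_independent_distances_give_p_one(self):
        d = pd.DataFrame(1 - np.eye(6))
        res = diversity.permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1.0)

    def test_agrees_with_skbio(self, rng):
        # independent published implementation as oracle on one random dataset
        import skbio

        pts = rng.standard_normal((12, 3))
        pts[6:] += 1.0
        m = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        res = diversity.permanova(pd.DataFrame(m), labels, n_permutations=999, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(m), grouping=labels, permutations=999
        )
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)
        assert abs(res.p_value - sk["p-value"]) < 0.05


class TestWilcoxonRankSum:
    def test_identical_groups_p_one(self):
        _, p = diversity.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        # fully separated n=3/3: one-sided tail 1/20, two-sided 0.1
        _, p = diversity.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_shift_significant(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50) + 2
        _, p = diversity.wilcoxon_rank_sum(a, b)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            diversity.wilcoxon_rank_sum([], [1.0])
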