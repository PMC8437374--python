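import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from guildscope import cag, synthio, tabio


class TestSelectTopTaxa:
    def test_exact_size_identity(self, small_relative):
        rel, _, _ = small_relative
        assert set(cag.select_top_taxa(rel, n=rel.shape[0])) == set(rel.index)

    def test_top_two_of_three(self):
        t = pd.DataFrame({"s1": [0.5, 0.3, 0.2], "s2": [0.5, 0.3, 0.2]}, index=["big", "mid", "small"])
        assert cag.select_top_taxa(t, n=2) == ["big", "mid"]

    def test_tie_broken_lexicographically(self):
        t = pd.DataFrame({"s": [0.4, 0.3, 0.3]}, index=["top", "zeta", "alpha"])
        assert cag.select_top_taxa(t, n=2) == ["top", "alpha"]

    def test_fewer_taxa_than_requested_uses_all(self, toy_counts):
        rel = tabio.to_relative(toy_counts)
        assert len(cag.select_top_taxa(rel, n=99)) == 2


def _kendall_oracle(x, y):
    """Brute-force tau-b from concordant/discordant pair counts."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else 0.0


class TestKendallMatrix:
    def test_self_correlation_one(self, small_relative):
        rel, _, _ = small_relative
        tau = cag.kendall_matrix(rel.iloc[:5])
        np.testing.assert_allclose(np.diag(tau.to_numpy()), 1.0)

    def test_full_discordance(self):
        t = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["up", "down"])
        tau = cag.kendall_matrix(t)
        assert tau.loc["up", "down"] == pytest.approx(-1.0)

    def test_known_pair_count_value(self):
        t = pd.DataFrame([[1, 2, 3, 4], [1, 3, 2, 4]], index=["x", "y"])
        tau = cag.kendall_matrix(t)
        assert tau.loc["x", "y"] == pytest.approx((5 - 1) / 6)

    def test_matches_brute_force_oracle_on_random_toys(self, rng):
        # ties included: small integer draws, up to 8 samples
        for _ in range(25):
            n = rng.integers(3, 9)
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            t = pd.DataFrame([x, y], index=["x", "y"])
            tau = cag.kendall_matrix(t).loc["x", "y"]
            assert tau == pytest.approx(_kendall_oracle(x, y), abs=1e-12)

    def test_constant_taxon_zeroed(self):
        t = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "x"])
        tau = cag.kendall_matrix(t)
        assert tau.loc["flat", "x"] == 0.0
        assert tau.loc["flat", "flat"] == 1.0


class TestClusterCags:
    def test_two_anticorrelated_blocks_recovered(self, rng):
        # 4+4 taxa, near-perfect within-block correlation, blocks anti-correlated
        base = rng.standard_normal(60)
        rows = [base + 0.01 * rng.standard_normal(60) for _ in range(4)]
        rows += [-base + 0.01 * rng.standard_normal(60) for _ in range(4)]
        t = pd.DataFrame(rows, index=[f"t{i}" for i in range(8)])
        res = cag.cluster_cags(t, k_range=range(2, 5), n_permutations=199, seed=0)
        assert res.k == 2
        truth = [0] * 4 + [1] * 4
        pred = [res.labels[f"t{i}"] for i in range(8)]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_planted_four_blocks_high_ari(self):
        cfg = synthio.SynthConfig(n_case=150, n_control=150, n_taxa=40, n_blocks=4,
                                  within_block_corr=0.8, depth_mean=20000, timepoints=("T2",), seed=21)
        counts, _, truth = synthio.generate_community(cfg)
        rel = tabio.to_relative(counts)
        res = cag.cluster_cags(rel, k_range=range(2, 7), n_permutations=199, seed=1)
        true_labels = [truth.block_assignment[t] for t in rel.index]
        pred = [res.labels[t] for t in rel.index]
        assert adjusted_rand_score(true_labels, pred) >= 0.9

    def test_structureless_taxa_trigger_fallback(self, rng):
        # one indistinguishable guild: every pairwise distance is 0, so no
        # candidate k can show significant separation and the fallback fires
        base = rng.standard_normal(30)
        t = pd.DataFrame([base] * 12, index=[f"t{i}" for i in range(12)])
        res = cag.cluster_cags(t, k_range=range(2, 5), n_permutations=99, seed=0)
        assert res.fallback_used

    def test_invariant_to_taxon_order(self, small_relative):
        rel, _, _ = small_relative
        sub = rel.iloc[:20]
        res1 = cag.cluster_cags(sub, k_range=range(2, 5), n_permutations=99, seed=3)
        shuffled = sub.sample(frac=1.0, random_state=1)
        res2 = cag.cluster_cags(shuffled, k_range=range(2, 5), n_permutations=99, seed=3)
        taxa = list(sub.index)
        l1 = [res1.labels[t] for t in taxa]
        l2 = [res2.labels[t] for t in taxa]
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_too_few_taxa_rejected(self, small_relative):
        rel, _, _ = small_relative
        with pytest.raises(ValueError, match="more taxa"):
            cag.cluster_cags(rel.iloc[:4], k_range=range(2, 6))


class TestCagAbundance:
    def _assignment(self, labels):
        return cag.CAGAssignment(labels=labels, k=len(set(labels.values())),
                                 diagnostics=pd.DataFrame(), linkage_method="ward")

    def test_single_cag_sums_to_one(self, small_relative):
        rel, _, _ = small_relative
        assignment = self._assignment({t: 1 for t in rel.index})
        ab = cag.cag_abundance(rel, assignment, include_remainder=False)
        np.testing.assert_allclose(ab.loc["CAG1"].to_numpy(), 1.0)

    def test_two_cag_split(self):
        rel = pd.DataFrame({"s": [0.2, 0.3, 0.5]}, index=["a", "b", "c"])
        assignment = self._assignment({"a": 1, "b": 1, "c": 2})
        ab = cag.cag_abundance(rel, assignment, include_remainder=False)
        assert ab["s"].tolist() == [0.5, 0.5]

    def test_sums_plus_remainder_conserve_total(self, small_relative):
        rel, _, _ = small_relative
        members = {t: 1 + (i % 3) for i, t in enumerate(rel.index[:30])}
        assignment = self._assignment(members)
        ab = cag.cag_abundance(rel, assignment, include_remainder=True)
        np.testing.assert_allclose(ab.sum(axis=0).to_numpy(), 1.0, atol=1e-9)

    def test_missing_taxon_rejected(self, small_relative):
        rel, _, _ = small_relative
        assignment = self._assignment({"ghost": 1})
        with pytest.raises(ValueError, match="ghost"):
            cag.cag_abundance(rel, assignment)


class TestSparsePartialNetwork:
    def test_independent_variables_near_empty(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = pd.DataFrame(rng.standard_normal((1000, 20)).T,
                             index=[f"v{i}" for i in range(20)])
            counts.append(len(cag.sparse_partial_network(d).edges))
        assert sum(c <= 2 for c in counts) >= 9

    def test_chain_drops_marginal_edge(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        z = y + rng.standard_normal(2000)
        assert abs(np.corrcoef(x, z)[0, 1]) > 0.4
        net = cag.sparse_partial_network(pd.DataFrame({"X": x, "Y": y, "Z": z}).T)
        pairs = {frozenset((a, b)) for a, b, _ in net.edges}
        assert frozenset(("X", "Y")) in pairs
        assert frozenset(("Y", "Z")) in pairs
        assert frozenset(("X", "Z")) not in pairs

    def test_two_variable_edge_sign_and_shrinkage(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(500)
        b = 0.7 * a + 0.5 * rng.standard_normal(500)
        net = cag.sparse_partial_network(pd.DataFrame({"A": a, "B": b}).T)
        assert len(net.edges) == 1
        _, _, w = net.edges[0]
        r = np.corrcoef(a, b)[0, 1]
        assert np.sign(w) == np.sign(r)
        assert abs(w) <= abs(r) + 1e-9

    def test_gamma_monotone_sparsity(self, rng):
        cov = 0.3 * np.ones((8, 8)) + 0.7 * np.eye(8)
        x = rng.standard_normal((300, 8)) @ np.linalg.cholesky(cov).T
        d = pd.DataFrame(x.T, index=[f"v{i}" for i in range(8)])
        counts = [len(cag.sparse_partial_network(d, ebic_gamma=g).edges) for g in (0.0, 0.25, 0.5)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_unpenalized_precision_matches_direct_inversion(self, rng):
        x = rng.standard_normal((2000, 5))
        s = np.corrcoef(x, rowvar=False)
        from sklearn.covariance import graphical_lasso

        _, prec = graphical_lasso(s, alpha=1e-10, max_iter=500)
        pc_glasso = cag.partial_correlations(prec)
        pc_direct = cag.partial_correlations(np.linalg.inv(s))
        np.testing.assert_allclose(pc_glasso, pc_direct, atol=1e-6)

    def test_constant_variable_rejected(self):
        d = pd.DataFrame({"s%d" % i: [1.0, float(i)] for i in range(10)}, index=["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            cag.sparse_partial_network(d)
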