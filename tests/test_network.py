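"""Co-expression network construction, module detection and stability."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from dosagenet.network import (
    GREY,
    CoexpressionNetwork,
    NetworkParams,
    StabilityParams,
    average_linkage_dendrogram,
    choose_soft_power,
    cut_modules,
    gene_correlation_matrix,
    merge_close_modules,
    module_eigengenes,
    module_stability,
    scale_free_fit_index,
    soft_adjacency,
    tom_matrix,
)

from _oracles import pearson_sum_formula, tom_bruteforce, upgma_cophenetic_bruteforce


def _frame(a, prefix="g"):
    a = np.asarray(a, dtype=float)
    idx = [f"{prefix}{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=idx, columns=idx)


def _expr(a, rng=None):
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(
        a,
        index=[f"g{i}" for i in range(a.shape[0])],
        columns=[f"s{j}" for j in range(a.shape[1])],
    )


class TestCorrelation:
    def test_duplicated_gene_and_negation(self, rng):
        x = rng.normal(size=6)
        expr = _expr(np.vstack([x, x, -x]))
        cor = gene_correlation_matrix(expr)
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cor), 1.0)

    def test_matches_sum_formula_oracle(self, rng):
        expr = _expr(rng.normal(size=(4, 6)))
        cor = gene_correlation_matrix(expr)
        for i in range(4):
            for j in range(4):
                expect = pearson_sum_formula(
                    expr.iloc[i].to_numpy(), expr.iloc[j].to_numpy()
                )
                assert cor.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = _expr(np.vstack([np.ones(5), rng.normal(size=5)]))
        with pytest.warns(UserWarning, match="constant"):
            cor = gene_correlation_matrix(expr)
        assert list(cor.index) == ["g1"]

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError):
            gene_correlation_matrix(_expr(rng.normal(size=(4, 2))))


class TestAdjacency:
    def test_unsigned_arithmetic(self):
        cor = _frame([[1.0, 0.5], [0.5, 1.0]])
        adj = soft_adjacency(cor, NetworkParams(soft_power=12))
        assert adj.iloc[0, 1] == pytest.approx(0.5**12)
        assert adj.iloc[0, 0] == 1.0

    def test_perfect_correlation_stays_one(self):
        cor = _frame([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 5, 20):
            adj = soft_adjacency(cor, NetworkParams(soft_power=beta))
            assert adj.iloc[0, 1] == 1.0

    def test_signed_arithmetic(self):
        cor = _frame([[1.0, -0.5], [-0.5, 1.0]])
        adj = soft_adjacency(cor, NetworkParams(soft_power=2, signed=True))
        assert adj.iloc[0, 1] == pytest.approx(0.0625)

    def test_increasing_power_weakly_decreases_offdiagonal(self, rng):
        r = rng.uniform(-0.99, 0.99, size=(5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cor = _frame(r)
        prev = soft_adjacency(cor, NetworkParams(soft_power=2)).to_numpy()
        for beta in (4, 8, 16):
            cur = soft_adjacency(cor, NetworkParams(soft_power=beta)).to_numpy()
            off = ~np.eye(5, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-15).all()
            prev = cur


def _adjacency_with_connectivities(spec):
    """Adjacency whose off-diagonal row sums realize the given (k, count)
    histogram exactly, by pairing equal-connectivity genes on single edges.

    Counts must be even so each gene pairs with an equal-k partner.
    """
    ks = []
    for k, count in spec:
        assert count % 2 == 0
        ks.extend([float(k)] * count)
    n = len(ks)
    a = np.zeros((n, n))
    for i in range(0, n, 2):
        a[i, i + 1] = a[i + 1, i] = ks[i]
    np.fill_diagonal(a, 1.0)
    return _frame(a)


class TestScaleFreeFit:
    def test_exact_power_law_scores_one(self):
        # frequency ~ k^-2 exactly: counts fall 4x per doubling of k
        adj = _adjacency_with_connectivities([(1.0, 64), (2.0, 16), (4.0, 4)])
        fit = scale_free_fit_index(adj, NetworkParams(n_bins=3))
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)

    def test_increasing_power_law_scores_minus_one(self):
        adj = _adjacency_with_connectivities([(1.0, 4), (2.0, 16), (4.0, 64)])
        fit = scale_free_fit_index(adj, NetworkParams(n_bins=3))
        assert fit.fit_r2 == pytest.approx(-1.0, abs=1e-9)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)

    def test_fit_index_bounded(self, rng):
        r = np.clip(rng.normal(0.3, 0.3, size=(40, 40)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        adj = soft_adjacency(_frame(r), NetworkParams(soft_power=6))
        fit = scale_free_fit_index(adj)
        assert -1.0 <= fit.fit_r2 <= 1.0
        assert (fit.connectivity >= 0).all()

    def test_degenerate_connectivity_raises(self):
        a = np.full((5, 5), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit_index(_frame(a))


class TestChooseSoftPower:
    def _modular_cor(self, rng, n=60):
        x = np.repeat(rng.normal(size=(3, 12)), n // 3, axis=0)
        x = x + rng.normal(scale=0.6, size=(n, 12))
        return gene_correlation_matrix(_expr(x))

    def test_selection_rule_smallest_passing(self, rng):
        cor = self._modular_cor(rng)
        fits = {
            beta: scale_free_fit_index(
                soft_adjacency(cor, NetworkParams(soft_power=beta))
            ).fit_r2
            for beta in (1, 2, 4, 6, 8, 12)
        }
        passing = [b for b, f in sorted(fits.items()) if f >= 0.5]
        if passing:
            beta, diag = choose_soft_power(
                cor, [1, 2, 4, 6, 8, 12], NetworkParams(scale_free_target=0.5)
            )
            assert beta == passing[0]
        else:
            with pytest.warns(UserWarning, match="argmax"):
                beta, diag = choose_soft_power(
                    cor, [1, 2, 4, 6, 8, 12], NetworkParams(scale_free_target=0.5)
                )
        assert set(diag["power"]).issubset({1, 2, 4, 6, 8, 12})

    def test_no_candidate_passing_returns_argmax_with_warning(self, rng):
        cor = self._modular_cor(rng)
        with pytest.warns(UserWarning, match="argmax"):
            beta, diag = choose_soft_power(
                cor, [1, 2], NetworkParams(scale_free_target=0.999999)
            )
        assert beta == int(diag.loc[diag["fit_r2"].idxmax(), "power"])

    def test_empty_candidates_raise(self, rng):
        with pytest.raises(ValueError):
            choose_soft_power(self._modular_cor(rng), [])


class TestTOM:
    def test_complete_graph_is_all_ones(self):
        a = np.ones((6, 6))
        tom = tom_matrix(_frame(a))
        assert np.allclose(tom, 1.0)

    def test_three_gene_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(_frame(a))
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_empty_graph_offdiagonal_zero(self):
        a = np.eye(5)
        tom = tom_matrix(_frame(a))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(tom.to_numpy()[off], 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        """TOM equals a brute-force triple loop on random <=12-gene graphs."""
        for n in (5, 8, 12):
            r = np.clip(rng.uniform(-1, 1, size=(n, n)), -1, 1)
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            a = np.abs(r) ** 6
            np.fill_diagonal(a, 1.0)
            tom = tom_matrix(_frame(a)).to_numpy()
            oracle = tom_bruteforce(a)
            assert np.allclose(tom, oracle, atol=1e-12)
            assert (tom >= 0).all() and (tom <= 1).all()
            assert np.allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_matrix(_frame(a))


class TestDendrogram:
    def test_matches_cubic_oracle_on_random_instances(self, rng):
        """Cophenetic distances equal a greedy O(n^3) UPGMA oracle."""
        for n in (5, 6, 8):
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            Z = average_linkage_dendrogram(_frame(d))
            coph = squareform(cophenet(Z))
            oracle = upgma_cophenetic_bruteforce(d)
            assert np.allclose(coph, oracle, atol=1e-10)

    def test_identical_points_merge_at_zero(self):
        d = np.array([[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]])
        Z = average_linkage_dendrogram(_frame(d))
        assert Z[0, 2] == pytest.approx(0.0)

    def test_leaf_permutation_invariance(self, rng):
        n = 7
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(n)
        coph_a = squareform(cophenet(average_linkage_dendrogram(_frame(d))))
        coph_b = squareform(
            cophenet(average_linkage_dendrogram(_frame(d[np.ix_(perm, perm)])))
        )
        assert np.allclose(coph_a[np.ix_(perm, perm)], coph_b, atol=1e-12)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            average_linkage_dendrogram(_frame(d))


def _two_block_dissimilarity(n_per_block=40, within=0.05, between=0.95):
    n = 2 * n_per_block
    d = np.full((n, n), between)
    d[:n_per_block, :n_per_block] = within
    d[n_per_block:, n_per_block:] = within
    np.fill_diagonal(d, 0.0)
    return _frame(d)


class TestCutModules:
    def test_two_planted_blocks_recovered(self):
        d = _two_block_dissimilarity()
        Z = average_linkage_dendrogram(d)
        labels = cut_modules(Z, d.index, NetworkParams(cut_height=0.5))
        assert GREY not in set(labels)
        assert labels.nunique() == 2
        # canonical naming: both modules size 40, names from the color order
        assert set(labels) == {"turquoise", "blue"}

    def test_small_cluster_goes_grey(self):
        d = _two_block_dissimilarity(n_per_block=10)
        Z = average_linkage_dendrogram(d)
        labels = cut_modules(Z, d.index, NetworkParams(cut_height=0.5))
        assert set(labels) == {GREY}

    def test_cut_at_one_yields_single_module(self, rng):
        n = 40
        d = rng.uniform(0.1, 0.8, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        Z = average_linkage_dendrogram(_frame(d))
        labels = cut_modules(Z, _frame(d).index, NetworkParams(cut_height=1.0))
        assert labels.nunique() == 1 and GREY not in set(labels)

    def test_invalid_cut_height_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(cut_height=1.5)


class TestEigengenes:
    def test_identical_genes_give_standardized_profile(self, rng):
        x = rng.normal(size=10)
        expr = _expr(np.vstack([x, x, x]))
        labels = pd.Series("turquoise", index=expr.index)
        me = module_eigengenes(expr, labels)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(np.abs(me.loc["turquoise"]), np.abs(z), atol=1e-10)
        assert np.corrcoef(me.loc["turquoise"], x)[0, 1] > 0

    def test_matches_full_svd_oracle(self, rng):
        """|dot| between eigengene and the SVD top component >= 1 - 1e-10."""
        expr = _expr(rng.normal(size=(20, 12)))
        labels = pd.Series("blue", index=expr.index)
        me = module_eigengenes(expr, labels).loc["blue"].to_numpy()
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z)
        pc1 = vt[0] / vt[0].std(ddof=1)
        cos = abs(me @ pc1) / (np.linalg.norm(me) * np.linalg.norm(pc1))
        assert cos >= 1 - 1e-10

    def test_orientation_mean_member_correlation_nonnegative(self, rng):
        expr = _expr(rng.normal(size=(15, 10)))
        labels = pd.Series("brown", index=expr.index)
        me = module_eigengenes(expr, labels)
        cors = [
            np.corrcoef(expr.iloc[i], me.loc["brown"])[0, 1] for i in range(15)
        ]
        assert np.mean(cors) >= 0
        flipped = module_eigengenes(-expr, labels)
        cors_f = [
            np.corrcoef((-expr).iloc[i], flipped.loc["brown"])[0, 1]
            for i in range(15)
        ]
        assert np.mean(cors_f) >= 0

    def test_unit_variance(self, rng):
        expr = _expr(rng.normal(size=(8, 9)))
        labels = pd.Series("yellow", index=expr.index)
        me = module_eigengenes(expr, labels)
        assert me.loc["yellow"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_gene_module_raises(self):
        expr = _expr(np.ones((3, 5)))
        labels = pd.Series("turquoise", index=expr.index)
        with pytest.raises(ValueError):
            module_eigengenes(expr, labels)


class TestMergeModules:
    def _expr_with_factors(self, rng, cors):
        """Three 10-gene modules driven by factors with given correlations."""
        n_samples = 40
        base = rng.normal(size=n_samples)
        factors = []
        for c in cors:
            noise = rng.normal(size=n_samples)
            f = c * base + np.sqrt(max(1 - c * c, 0)) * noise
            factors.append(f)
        rows, labels = [], []
        for m, f in enumerate(factors):
            for g in range(10):
                rows.append(f + rng.normal(scale=0.05, size=n_samples))
                labels.append(f"mod{m}")
        expr = _expr(np.array(rows))
        return expr, pd.Series(labels, index=expr.index)

    def test_high_correlation_pair_merged(self, rng):
        expr, labels = self._expr_with_factors(rng, [0.995, 0.995, -0.9])
        merged, me = merge_close_modules(expr, labels, NetworkParams())
        assert merged[labels == "mod0"].nunique() == 1
        assert set(merged[labels == "mod0"]) == set(merged[labels == "mod1"])
        assert set(merged[labels == "mod2"]) != set(merged[labels == "mod0"])

    def test_low_correlation_pair_unmerged(self, rng):
        expr, labels = self._expr_with_factors(rng, [0.3, -0.3, 0.0])
        merged, _ = merge_close_modules(expr, labels, NetworkParams())
        assert merged.nunique() == 3

    def test_three_mutually_close_modules_collapse_to_one(self, rng):
        expr, labels = self._expr_with_factors(rng, [0.99, 0.99, 0.99])
        merged, me = merge_close_modules(expr, labels, NetworkParams())
        assert merged.nunique() == 1
        assert me.shape[0] == 1


class TestStability:
    def _planted_expr(self, rng, n_per_module=40, noise=0.2, n_samples=30):
        f1, f2 = rng.normal(size=(2, n_samples)) * 3
        rows = [f1 + rng.normal(scale=noise, size=n_samples) for _ in range(n_per_module)]
        rows += [f2 + rng.normal(scale=noise, size=n_samples) for _ in range(n_per_module)]
        rows += [rng.normal(size=n_samples) for _ in range(20)]
        return _expr(np.array(rows))

    def test_strong_modules_are_stable(self, rng):
        expr = self._planted_expr(rng)
        params = NetworkParams(soft_power=6, cut_height=0.95, min_module_size=20)
        net = CoexpressionNetwork(expr, params)
        result = net.fit()
        stab = module_stability(
            expr, result.labels, params, StabilityParams(n_iterations=9, seed=5)
        )
        planted = [m for m in stab.index]
        assert len(planted) >= 2
        assert (stab >= 0.8).sum() >= 2

    def test_values_bounded_and_seeded(self, rng):
        expr = self._planted_expr(rng, noise=0.5)
        params = NetworkParams(soft_power=4, cut_height=0.95, min_module_size=20)
        labels = CoexpressionNetwork(expr, params).fit().labels
        sp = StabilityParams(n_iterations=5, seed=7)
        a = module_stability(expr, labels, params, sp)
        b = module_stability(expr, labels, params, sp)
        pd.testing.assert_series_equal(a, b)
        assert ((a >= 0) & (a <= 1)).all()

    def test_too_small_subsample_raises(self, rng):
        expr = self._planted_expr(rng)[["s0", "s1", "s2"]]
        with pytest.raises(ValueError):
            module_stability(
                expr,
                pd.Series(GREY, index=expr.index),
                NetworkParams(),
                StabilityParams(subsample_fraction=0.5),
            )


class TestPipelineDeterminism:
    def test_fit_is_deterministic(self, rng):
        x = rng.normal(size=(60, 20))
        expr = _expr(x)
        params = NetworkParams(soft_power=6, min_module_size=10)
        r1 = CoexpressionNetwork(expr, params).fit()
        r2 = CoexpressionNetwork(expr.copy(), params).fit()
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.dendrogram, r2.dendrogram)
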