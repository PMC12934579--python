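"""Signed co-expression network: bicor, adjacency, TOM, module detection,
eigengenes, kME, and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from retinova import simulate
from retinova.network import (
    CoexpressionNetwork,
    NetworkParams,
    adjacency,
    bicor,
    bicor_matrix,
    detect_modules,
    kme,
    me_group_test,
    merge_modules,
    module_eigengene,
    module_trait,
    pick_power,
    scale_free_fit_index,
    tom_mean,
)


def _block_expr(sizes, r=0.8, n=40, seed=0, noise_sd=None):
    """Samples x genes with block-correlated groups plus background noise."""
    rng = np.random.default_rng(seed)
    cols = []
    labels = []
    for b, size in enumerate(sizes):
        z = rng.standard_normal(n)
        lam = np.sqrt(r)
        for g in range(size):
            cols.append(lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(n))
            labels.append(f"B{b}")
    x = np.array(cols).T
    genes = [f"g{i}" for i in range(x.shape[1])]
    return pd.DataFrame(x, columns=genes), pd.Series(labels, index=genes)


class TestBicor:
    def test_self_and_negated(self):
        x = np.random.default_rng(0).normal(size=60)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bicor(np.ones(5), np.ones(6))

    def test_robust_to_single_contaminant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = 0.8 * x + 0.6 * rng.normal(size=100)
        clean_pearson = np.corrcoef(x, y)[0, 1]
        xc, yc = x.copy(), y.copy()
        xc[0], yc[0] = 15.0, -15.0
        contaminated_pearson = np.corrcoef(xc, yc)[0, 1]
        assert abs(bicor(xc, yc) - clean_pearson) < abs(contaminated_pearson - clean_pearson)

    def test_equals_pearson_when_no_truncation(self):
        # symmetric, tightly clustered data: all biweights stay inside 9 MADs
        x = np.array([-2, -1, 0, 1, 2], dtype=float)
        y = np.array([-1.9, -1.1, 0.0, 1.1, 1.9])
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.01)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 5))
        m = bicor_matrix(x)
        for i in range(5):
            for j in range(5):
                assert m[i, j] == pytest.approx(bicor(x[:, i], x[:, j]), abs=1e-10)


class TestAdjacency:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**8)]
    )
    def test_signed_values(self, r, expected):
        corr = np.array([[1.0, r], [r, 1.0]])
        a = adjacency(corr, power=8)
        assert a[0, 1] == pytest.approx(expected)
        assert a[0, 0] == 1.0


class TestScaleFree:
    def test_power_law_connectivity_fits_well(self):
        rng = np.random.default_rng(0)
        k = (1 - rng.uniform(size=4000)) ** (-1 / 1.5)  # Pareto tail, gamma ~ 2.5
        fit, slope = scale_free_fit_index(k)
        assert fit > 0.8 and slope < 0

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit_index(np.full(100, 3.0))

    def test_zero_threshold_returns_smallest_candidate(self):
        expr, _ = _block_expr([60, 60], seed=3)
        beta, fit, reached = pick_power(expr.to_numpy(), r2_min=0.0)
        assert beta == 1.0 and reached

    def test_reports_index_and_flag_on_module_data(self):
        expr, _ = _block_expr([80, 80], seed=4)
        beta, fit, reached = pick_power(expr.to_numpy(), r2_min=0.8)
        assert 1 <= beta <= 20 and np.isfinite(fit)


class TestTOM:
    def test_identical_neighborhoods_give_zero_dissimilarity(self):
        a = np.ones((4, 4))
        d = tom_mean(a)
        assert d[0, 1] == pytest.approx(0.0)

    def test_identity_adjacency_gives_unit_dissimilarity(self):
        d = tom_mean(np.eye(5))
        off = d[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 11)
            r = rng.uniform(0, 1, (n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            d = tom_mean(a)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert d[i, j] == 0.0
                        continue
                    s = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                    ki = sum(a[i, u] for u in range(n) if u != i)
                    kj = sum(a[j, u] for u in range(n) if u != j)
                    tom = (s + a[i, j]) / ((ki + kj) / 2 + 1 - a[i, j])
                    assert d[i, j] == pytest.approx(1 - tom, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_mean(a)


def _diss_from(expr):
    corr = bicor_matrix(expr.to_numpy())
    return tom_mean(adjacency(corr, 8))


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, labels = _block_expr([100, 100], r=0.8, seed=6)
        assignment = detect_modules(_diss_from(expr), gene_ids=list(expr.columns))
        assert len(assignment.modules) == 2
        ari = adjusted_rand_score(labels, assignment.labels[labels.index])
        assert ari >= 0.95

    def test_noise_mostly_unassigned(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(40, 300)))
        assignment = detect_modules(_diss_from(expr), gene_ids=list(expr.columns))
        assert (assignment.labels == "grey").mean() > 0.5

    def test_small_block_below_min_size_unassigned(self):
        expr, _ = _block_expr([30], r=0.9, seed=8)
        rng = np.random.default_rng(9)
        noise = pd.DataFrame(
            rng.normal(size=(40, 100)), columns=[f"n{i}" for i in range(100)]
        )
        full = pd.concat([expr, noise], axis=1)
        assignment = detect_modules(_diss_from(full), gene_ids=list(full.columns))
        assert assignment.modules == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(power=0.5)
        with pytest.raises(ValueError):
            NetworkParams(merge_cut_height=1.5)
        with pytest.raises(ValueError):
            NetworkParams(deep_split=7)


class TestEigengene:
    def test_identical_genes_give_common_profile(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=30)
        expr = pd.DataFrame({f"g{i}": z for i in range(5)})
        me = module_eigengene(expr, expr.columns)
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(me, expr.mean(axis=1))[0, 1] > 0

    def test_sign_flip_of_all_genes_is_invariant(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(size=(30, 6)))
        me1 = module_eigengene(expr, expr.columns)
        me2 = module_eigengene(-expr, expr.columns)
        # alignment to the (flipped) module mean flips the score identically
        np.testing.assert_allclose(me1.to_numpy(), -me2.to_numpy(), atol=1e-10)

    def test_planted_latent_factor_recovered(self, small_dataset, normalized):
        _, _, truth = small_dataset
        norm, *_ = normalized
        expr = norm.values.T
        genes = [g for g, m in truth.module_membership.items() if m == "M1"]
        me = module_eigengene(expr, genes)
        z = truth.latent_scores.loc["M1", expr.index]
        assert abs(np.corrcoef(me, z)[0, 1]) >= 0.9

    def test_trivial_module_rejected(self):
        expr = pd.DataFrame({"g0": np.ones(10)})
        with pytest.raises(ValueError):
            module_eigengene(expr, ["g0"])


class TestMerge:
    def test_artificially_split_factor_merged_back(self):
        expr, labels = _block_expr([120], r=0.8, seed=12)
        split = labels.copy()
        split.iloc[:60] = "blue"
        split.iloc[60:] = "brown"
        from retinova.network import ModuleAssignment

        merged = merge_modules(ModuleAssignment(split), expr)
        assert len(merged.modules) == 1

    def test_distinct_factors_not_merged(self):
        expr, labels = _block_expr([80, 80], r=0.85, seed=13)
        from retinova.network import ModuleAssignment

        named = labels.map({"B0": "blue", "B1": "brown"})
        merged = merge_modules(ModuleAssignment(named), expr)
        assert len(merged.modules) == 2


class TestKme:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(rng.normal(size=(30, 4)), index=[f"s{i}" for i in range(30)])
        me = module_eigengene(expr, expr.columns)
        expr["hub"] = me
        table = kme(expr, pd.DataFrame({"mod": me}).T.set_axis(["mod"]))
        assert table.loc["hub", "mod"] == pytest.approx(1.0, abs=1e-6)

    def test_planted_module_genes_are_hubs(self, small_dataset, normalized):
        _, _, truth = small_dataset
        norm, *_ = normalized
        expr = norm.values.T
        genes = [g for g, m in truth.module_membership.items() if m == "M1"]
        me = module_eigengene(expr, genes)
        table = kme(expr, pd.DataFrame({"M1": me}).T.set_axis(["M1"]))
        assert table.loc[genes, "M1"].median() >= 0.7


class TestModuleTrait:
    def _me(self, n=40, seed=15):
        rng = np.random.default_rng(seed)
        me = rng.normal(size=n)
        return pd.DataFrame([me], index=["blue"], columns=[f"s{i}" for i in range(n)])

    def test_exact_trait_passes_with_unit_r(self):
        me = self._me()
        traits = pd.DataFrame({"t": me.loc["blue"]})
        out = module_trait(me, traits)
        assert out.r.iloc[0] == pytest.approx(1.0) and bool(out.passes.iloc[0])

    def test_zero_variance_trait_flagged(self):
        me = self._me()
        traits = pd.DataFrame({"t": np.ones(40)}, index=me.columns)
        out = module_trait(me, traits)
        assert np.isnan(out.r.iloc[0]) and not bool(out.passes.iloc[0])

    def test_null_pass_rate_bounded(self):
        hits = 0
        for seed in range(50):
            me = self._me(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            traits = pd.DataFrame({"t": rng.normal(size=40)}, index=me.columns)
            hits += int(module_trait(me, traits).passes.iloc[0])
        # joint |r|>0.3 & p<0.05 rule at n=40: roughly the r-threshold tail
        assert hits / 50 <= 0.15

    def test_planted_correlation_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=40)
            trait = 0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=40)
            me = pd.DataFrame([z], index=["blue"], columns=[f"s{i}" for i in range(40)])
            traits = pd.DataFrame({"t": trait}, index=me.columns)
            hits += int(module_trait(me, traits).passes.iloc[0])
        assert hits / 20 >= 0.9


class TestMEGroupTest:
    def test_planted_group_shift_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            groups = pd.Series(
                ["A"] * 10 + ["B"] * 10, index=[f"s{i}" for i in range(20)]
            )
            me = rng.normal(size=20)
            me[10:] += 1.5  # 1.5 SD shift; a two-sample t-test at n=10/group
            # has ~88% power here (a 1 SD shift gives only ~56%)
            table = pd.DataFrame([me], index=["blue"], columns=groups.index)
            out = me_group_test(table, groups, [("B", "A")])
            detected += int(out.padj.iloc[0] < 0.05)
        assert detected / 10 >= 0.8

    def test_identical_groups_near_uniform(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            groups = pd.Series(["A"] * 8 + ["B"] * 8, index=[f"s{i}" for i in range(16)])
            table = pd.DataFrame([rng.normal(size=16)], index=["m"], columns=groups.index)
            ps.append(me_group_test(table, groups, [("B", "A")]).pvalue.iloc[0])
        assert 0.2 <= np.mean(np.array(ps) < 0.5) <= 0.8

    def test_singleton_group_rejected(self):
        groups = pd.Series(["A"] * 5 + ["B"], index=[f"s{i}" for i in range(6)])
        table = pd.DataFrame([np.arange(6.0)], index=["m"], columns=groups.index)
        with pytest.raises(ValueError):
            me_group_test(table, groups, [("B", "A")])


class TestEstimator:
    def test_full_pipeline_recovers_planted_modules(self, small_dataset, normalized):
        _, meta, truth = small_dataset
        norm, *_ = normalized
        net = CoexpressionNetwork().fit(norm.values.T)
        genes = list(truth.module_membership)
        ari = adjusted_rand_score(
            [truth.module_membership[g] for g in genes], net.labels_[genes]
        )
        assert ari >= 0.8
        assert net.eigengenes_ is not None and (net.kme_.abs() <= 1 + 1e-9).all().all()

    def test_adjacency_and_tom_ranges(self):
        expr, _ = _block_expr([60, 60], seed=16)
        corr = bicor_matrix(expr.to_numpy())
        a = adjacency(corr, 8)
        assert a.min() >= 0 and a.max() <= 1 and np.allclose(a, a.T)
        d = tom_mean(a)
        assert d.min() >= 0 and d.max() <= 1 and np.allclose(np.diag(d), 0)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = CoexpressionNetwork(power=6, min_module_size=30)
        assert clone(est).get_params() == est.get_params()
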