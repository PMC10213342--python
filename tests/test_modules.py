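import numpy as np
import pandas as pd
import pytest

from foldnet import modules as mod, simulate
from foldnet.io import ExpressionMatrix, Scale
from tests.conftest import make_matrix


class TestSpearman:
    def test_monotone_pairs(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0], [4.0, 3.0, 2.0, 1.0]])
        C = mod.spearman_matrix(m)
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(-1.0)

    def test_ties_match_pandas_reference(self, rng):
        values = rng.integers(0, 4, size=(6, 12)).astype(float)  # many ties
        m = make_matrix(values)
        C = mod.spearman_matrix(m)
        ref = pd.DataFrame(values.T).corr(method="spearman").to_numpy()
        np.testing.assert_allclose(C, ref, atol=1e-10)

    def test_constant_gene_warns_and_zeroes(self, rng):
        values = rng.standard_normal((3, 8))
        values[1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            C = mod.spearman_matrix(make_matrix(values))
        assert C[1, 0] == 0.0 and C[1, 1] == 1.0


class TestSoftAdjacency:
    def test_power_values(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = mod.soft_adjacency(corr, beta=8)
        assert a.matrix[0, 1] == 0.00390625  # 0.5 ** 8 exactly

    def test_unsigned_convention_for_negative_correlation(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        a = mod.soft_adjacency(corr, beta=8)
        assert a.matrix[0, 1] == 0.00390625

    def test_perfect_correlation_stays_one(self):
        a = mod.soft_adjacency(np.ones((2, 2)), beta=8)
        np.testing.assert_array_equal(a.matrix, np.ones((2, 2)))

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            mod.soft_adjacency(np.eye(2), beta=0)

    def test_bounds_and_symmetry_for_random_input(self, rng):
        C = np.clip((lambda M: (M + M.T) / 2)(rng.uniform(-1, 1, (20, 20))), -1, 1)
        np.fill_diagonal(C, 1.0)
        a = mod.soft_adjacency(C, beta=7).matrix
        assert a.min() >= 0.0 and a.max() <= 1.0
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_array_equal(np.diag(a), 1.0)


@pytest.fixture(scope="module")
def hub_corr():
    # single-factor model with spread loadings -> heavy-tailed connectivity
    rng = np.random.default_rng(4)
    a_load = rng.uniform(0.2, 0.95, 150)
    f = rng.standard_normal(60)
    X = a_load[:, None] * f + np.sqrt(1 - a_load**2)[:, None] * rng.standard_normal((150, 60))
    return mod.spearman_matrix(make_matrix(2.5 + 0.3 * X))


class TestPickSoftPower:
    def test_heavy_tailed_network_reaches_fit_threshold(self, hub_corr):
        beta, table = mod.pick_soft_power(hub_corr)
        assert beta is not None
        assert table.loc[table.beta == beta, "fit_rsq"].iloc[0] >= 0.8

    def test_mean_connectivity_decreases_with_beta(self, hub_corr):
        _, table = mod.pick_soft_power(hub_corr)
        assert (np.diff(table["mean_connectivity"]) < 0).all()

    def test_single_candidate_eight(self, hub_corr):
        beta, _ = mod.pick_soft_power(hub_corr, candidates=(8,))
        assert beta == 8

    def test_complete_equal_graph_has_no_scale_free_fit(self):
        C = np.full((50, 50), 0.9)
        np.fill_diagonal(C, 1.0)
        with pytest.warns(UserWarning, match="soft power"):
            beta, table = mod.pick_soft_power(C, candidates=(2, 4, 8))
        assert beta is None
        assert table["fit_rsq"].max() < 0.8


@pytest.fixture(scope="module")
def correlated_blocks():
    # two 40-gene blocks whose latent factors correlate 0.9
    rng = np.random.default_rng(7)
    ns = 40
    f1 = rng.standard_normal(ns)
    f2 = 0.9 * f1 + np.sqrt(1 - 0.81) * rng.standard_normal(ns)
    sig = np.sqrt(1 / 0.8 - 1)
    rows = [f1 + sig * rng.standard_normal(ns) for _ in range(40)] + [
        f2 + sig * rng.standard_normal(ns) for _ in range(40)
    ]
    return make_matrix(2.5 + 0.3 * np.asarray(rows))


class TestDetectModules:
    def test_planted_partition_recovery(self, module_sim):
        from sklearn.metrics import adjusted_rand_score

        em = module_sim.expression
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        assign = mod.detect_modules(adj, min_size=30, merge_cut=0.25, expression=em)
        truth = [module_sim.truth.labels[g] for g in assign.gene_ids]
        assert adjusted_rand_score(truth, assign.labels) >= 0.8
        assert len(assign.modules) == 3
        # all non-sink modules respect the size floor
        assert all(v >= 30 for k, v in assign.module_sizes.items() if k != mod.UNASSIGNED)

    def test_independent_noise_goes_to_sink(self, rng):
        X = 2.5 + 0.3 * rng.standard_normal((60, 30))
        em = make_matrix(X)
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        assign = mod.detect_modules(adj, min_size=30, merge_cut=0.25, expression=em)
        assert set(assign.labels) == {mod.UNASSIGNED}

    def test_highly_correlated_blocks_merge_at_default_cut(self, correlated_blocks):
        em = correlated_blocks
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        assign = mod.detect_modules(adj, min_size=30, merge_cut=0.25, expression=em)
        assert len(assign.modules) == 1

    def test_merging_is_monotone_in_cut(self, correlated_blocks):
        em = correlated_blocks
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        counts = []
        for cut in (0.02, 0.25, 0.6):
            assign = mod.detect_modules(adj, min_size=30, merge_cut=cut, expression=em)
            counts.append(len(assign.modules))
        assert counts[0] >= counts[1] >= counts[2]

    def test_fewer_genes_than_min_size_all_sink(self, rng):
        em = make_matrix(2.5 + rng.standard_normal((5, 10)))
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        with pytest.warns(UserWarning, match="min_size"):
            assign = mod.detect_modules(adj, min_size=30, merge_cut=0.25)
        assert set(assign.labels) == {mod.UNASSIGNED}


class TestModuleEigengene:
    def test_identical_rows_give_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        Xm = np.tile(profile, (4, 1))
        e = mod.module_eigengene(Xm)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(e, z / np.linalg.norm(z), atol=1e-10)

    def test_negating_module_flips_eigengene(self, rng):
        Xm = rng.standard_normal((5, 12))
        e1 = mod.module_eigengene(Xm)
        e2 = mod.module_eigengene(-Xm)
        np.testing.assert_allclose(e2, -e1, atol=1e-10)

    def test_planted_factor_is_recovered(self, rng):
        f = rng.standard_normal(25)
        Xm = np.array([f + 0.4 * rng.standard_normal(25) for _ in range(30)])
        e = mod.module_eigengene(Xm)
        assert abs(np.corrcoef(e, f)[0, 1]) >= 0.95

    def test_constant_submatrix_errors(self):
        with pytest.raises(ValueError, match="constant"):
            mod.module_eigengene(np.full((3, 6), 2.0))


class TestModuleTrait:
    def test_eigengene_equal_to_trait_gives_unit_correlation(self, rng):
        t = rng.standard_normal(20)
        eig = pd.DataFrame({"module_1": t}, index=[f"s{i}" for i in range(20)])
        traits = pd.DataFrame({"group": t}, index=eig.index)
        mt = mod.module_trait_correlation(eig, traits)
        assert mt.correlations.loc["module_1", "group"] == pytest.approx(1.0)
        assert mt.p_values.loc["module_1", "group"] < 1e-10

    def test_constant_trait_warns(self, rng):
        eig = pd.DataFrame({"m": rng.standard_normal(10)}, index=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"sex": np.ones(10)}, index=eig.index)
        with pytest.warns(UserWarning, match="constant trait"):
            mt = mod.module_trait_correlation(eig, traits)
        assert mt.correlations.loc["m", "sex"] == 0.0

    def test_group_coded_factor_module_ranks_top(self):
        group = np.repeat([1, 2, 3, 4], 8).astype(float)
        sim = simulate.simulate_background_modules(
            simulate.CohortSimConfig(seed=9), trait=group
        )
        em = sim.expression
        adj = mod.soft_adjacency(mod.spearman_matrix(em), 8, em.gene_ids)
        assign = mod.detect_modules(adj, min_size=30, merge_cut=0.25, expression=em)
        eig = pd.DataFrame(
            {
                m: mod.module_eigengene(em.subset_genes(assign.genes_in(m)).values)
                for m in assign.modules
            },
            index=em.sample_ids,
        )
        traits = pd.DataFrame({"group": group}, index=em.sample_ids)
        mt = mod.module_trait_correlation(eig, traits)
        strengths = mt.correlations["group"].abs()
        # the module planted on the group code must show the strongest link
        top = strengths.idxmax()
        genes = set(assign.genes_in(top))
        planted = {g for g, l in sim.truth.labels.items() if l == "module_1"}
        assert len(genes & planted) / len(planted) > 0.8
        assert strengths[top] > 0.8
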