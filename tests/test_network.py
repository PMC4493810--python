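"""Network construction: soft threshold, adjacency, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from neurocoex.network import (
    CoexpressionNetwork,
    adjacency_matrix,
    compute_kme,
    detect_modules,
    export_edge_list,
    identify_hubs,
    module_eigengenes,
    pick_soft_threshold,
    tom_matrix,
)


def brute_force_tom(a):
    """Oracle: triple-loop evaluation of the TOM formula."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_powers_of_correlation(self, rng):
        base = rng.normal(size=20)
        expr = pd.DataFrame(
            [base, -base, rng.normal(size=20)], index=["g1", "g2", "g3"]
        )
        adj = adjacency_matrix(expr, power=7)
        assert adj.loc["g1", "g2"] == pytest.approx(1.0)  # |cor| = 1
        assert adj.loc["g1", "g1"] == 1.0
        r = abs(np.corrcoef(expr.loc["g1"], expr.loc["g3"])[0, 1])
        assert adj.loc["g1", "g3"] == pytest.approx(r**7)

    def test_half_correlation_arithmetic(self):
        assert 0.5**7 == pytest.approx(0.0078125)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"], dtype=float)
        with pytest.raises(ValueError):
            adjacency_matrix(expr, 7)


class TestTOM:
    def test_two_node_saturated(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert tom_matrix(a)[0, 1] == pytest.approx(1.0)

    def test_empty_network_zero_offdiag(self):
        tom = tom_matrix(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            a = random_adjacency(rng, n)
            assert np.allclose(tom_matrix(a), brute_force_tom(a), atol=1e-12)

    def test_range_and_symmetry(self, rng):
        a = random_adjacency(rng, 12)
        tom = tom_matrix(a)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
        assert np.allclose(tom, tom.T)

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError):
            tom_matrix(a)


class TestSoftThreshold:
    def test_returns_smallest_passing_power(self, planted_cohort):
        _cfg, expr, _meta, _truth = planted_cohort
        power, table = pick_soft_threshold(expr, candidate_powers=range(1, 13))
        passing = table[table["r2"] >= 0.8]["power"]
        if len(passing):
            assert power == passing.iloc[0]
        assert set(table.columns) == {"power", "r2", "slope", "mean_connectivity"}
        assert table["r2"].between(0, 1).all()

    def test_input_guards(self, rng):
        small = pd.DataFrame(rng.normal(size=(10, 10)))
        with pytest.raises(ValueError, match="30 genes"):
            pick_soft_threshold(small)


class TestModules:
    def test_planted_modules_recovered(self, planted_cohort):
        _cfg, expr, meta, truth = planted_cohort
        ctrl = expr.loc[:, (meta["diagnosis"] == "control").to_numpy()]
        res = CoexpressionNetwork(ctrl, power=7).fit()
        t = [truth.module_membership[g] for g in expr.index]
        assert adjusted_rand_score(t, res.modules.to_numpy()) >= 0.9
        # noise genes predominantly unassigned
        noise = [g for g, m in truth.module_membership.items() if m == "unassigned"]
        assert (res.modules.loc[noise] == "unassigned").mean() > 0.8

    def test_small_module_goes_unassigned(self):
        from neurocoex.simulate import ModuleSpec, SimCohortConfig, gen_brain_cohort

        cfg = SimCohortConfig(
            n_genes=120,
            module_specs=[ModuleSpec(40, 0.9, True), ModuleSpec(10, 0.9, True)],
            seed=9,
        )
        expr, _meta, truth = gen_brain_cohort(cfg)
        res = CoexpressionNetwork(expr, power=7, min_module_size=20).fit()
        small = [g for g, m in truth.module_membership.items() if m == "M2"]
        assert (res.modules.loc[small] == "unassigned").all()

    def test_determinism(self, planted_cohort):
        _cfg, expr, _meta, _truth = planted_cohort
        adj = adjacency_matrix(expr, 7)
        d = 1.0 - tom_matrix(adj)
        a = detect_modules(d)
        b = detect_modules(d)
        assert a.equals(b)

    def test_height_cut_fallback_agrees_on_planted_modules(self, planted_cohort):
        # the static cut keeps some dendrogram fringe (it has no gap
        # trimming), so equivalence means: every planted module lands almost
        # entirely inside one distinct static cluster, matching the hybrid
        _cfg, expr, meta, truth = planted_cohort
        ctrl = expr.loc[:, (meta["diagnosis"] == "control").to_numpy()]
        static = CoexpressionNetwork(ctrl, power=7, tree_cut="height").fit()
        hybrid = CoexpressionNetwork(ctrl, power=7, tree_cut="hybrid").fit()
        t = pd.Series(
            [truth.module_membership[g] for g in expr.index], index=expr.index
        )
        homes = {}
        for planted in ("M1", "M2", "M3"):
            members = t.index[t == planted]
            for res in (static, hybrid):
                top = res.modules.loc[members].mode()[0]
                assert top != "unassigned"
                frac = (res.modules.loc[members] == top).mean()
                assert frac >= 0.95
                homes.setdefault(id(res), {})[planted] = top
        # distinct planted modules map to distinct clusters in both methods
        for mapping in homes.values():
            assert len(set(mapping.values())) == 3


class TestEigengenes:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=25)
        expr = pd.DataFrame(
            [profile * 2 + 1, profile * 0.5 - 3, profile],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(25)],
        )
        assign = pd.Series("m1", index=expr.index)
        eig, varexp = module_eigengenes(expr, assign)
        assert varexp["m1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        v = eig["m1"].to_numpy()
        assert abs(np.corrcoef(z, v)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(v) == pytest.approx(1.0)  # unit norm

    def test_invariant_to_gene_order_and_matches_eigensolver(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 30)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(30)],
        )
        assign = pd.Series("m1", index=expr.index)
        eig1, ve1 = module_eigengenes(expr, assign)
        shuffled = expr.sample(frac=1.0, random_state=3)
        eig2, ve2 = module_eigengenes(shuffled, assign.loc[shuffled.index])
        assert np.allclose(np.abs(eig1["m1"]), np.abs(eig2["m1"]))
        # oracle: dense eigendecomposition of the standardized covariance
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=0)).T.to_numpy()
        evals = np.linalg.eigvalsh(z @ z.T)
        assert ve1["m1"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_sign_orientation_nonnegative_mean_cor(self, planted_cohort):
        _cfg, expr, _meta, _truth = planted_cohort
        res = CoexpressionNetwork(expr, power=7).fit()
        for m in res.eigengenes.columns:
            members = res.modules.index[res.modules == m]
            mean_cor = res.kme.loc[members, m].mean()
            assert mean_cor >= 0


class TestKmeHubs:
    def test_kme_limits(self, rng):
        e = rng.normal(size=40)
        expr = pd.DataFrame(
            [e, rng.normal(size=40)], index=["same", "indep"],
            columns=[f"s{i}" for i in range(40)],
        )
        eig = pd.DataFrame({"m1": (e - e.mean()) / np.linalg.norm(e - e.mean())},
                           index=expr.columns)
        kme = compute_kme(expr, eig)
        assert kme.loc["same", "m1"] == pytest.approx(1.0)
        assert abs(kme.loc["indep", "m1"]) < 0.4

    def test_hub_threshold_strict_and_monotone(self):
        kme = pd.DataFrame({"m1": [0.75, 0.76, 0.9]}, index=["a", "b", "c"])
        assign = pd.Series("m1", index=kme.index)
        hubs = identify_hubs(kme, assign, threshold=0.75)
        assert hubs["m1"] == ["b", "c"]  # 0.75 exactly is not a hub
        tighter = identify_hubs(kme, assign, threshold=0.85)
        assert set(tighter["m1"]) <= set(hubs["m1"])


class TestEdges:
    def test_complete_and_empty(self, planted_cohort):
        _cfg, expr, _meta, _truth = planted_cohort
        res = CoexpressionNetwork(expr, power=7).fit()
        module = res.module_sizes.drop("unassigned").index[0]
        m = res.module_sizes[module]
        edges = res.edge_list(module, min_weight=0.0)
        assert len(edges) == m * (m - 1) // 2
        assert export_edge_list(res.adjacency, res.modules, module, 1.01).empty
        # weights match adjacency entries
        row = edges.iloc[0]
        assert row["weight"] == res.adjacency.loc[row["source"], row["target"]]

    def test_summary_mentions_modules(self, planted_cohort):
        _cfg, expr, _meta, _truth = planted_cohort
        res = CoexpressionNetwork(expr, power=7).fit()
        text = res.summary()
        assert "soft power: 7" in text
        for m in res.module_sizes.index:
            assert m in text
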