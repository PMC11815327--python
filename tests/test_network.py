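"""Network construction, module detection and module statistics.

Exact operations (adjacency, TOM, eigengene, correlations, t-tests) are
checked against independent brute-force / closed-form oracles; module
detection is checked by planted-partition recovery.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from comethnet.network import (
    NetworkParams,
    build_adjacency,
    cut_modules,
    detect_modules,
    hub_probes,
    merge_modules,
    mm_ps_correlation,
    module_eigengenes,
    module_membership,
    module_trait_test,
    partition_blocks,
    pick_soft_threshold,
    probe_significance,
    select_candidate_modules,
    compute_module_stats,
    tom_similarity,
)
from comethnet.simulate import simulate_cohort
from comethnet.types import ModuleSpec, SimulationConfig

from conftest import make_residual_matrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop TOM evaluation, the independent oracle."""
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        k_i = sum(a[i, u] for u in range(n) if u != i)
        for j in range(n):
            if i == j:
                continue
            k_j = sum(a[j, u] for u in range(n) if u != j)
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


class TestAdjacency:
    def test_anticorrelated_pair_has_unit_adjacency(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        adj = build_adjacency(make_residual_matrix(x), NetworkParams(power=3))
        np.testing.assert_allclose(adj, 1.0, atol=1e-12)

    def test_power_one_equals_abs_pearson(self, rng):
        x = rng.normal(size=(5, 12))
        adj = build_adjacency(make_residual_matrix(x), NetworkParams(power=1))
        np.testing.assert_allclose(adj, np.abs(np.corrcoef(x)), atol=1e-12)

    def test_matches_per_pair_pearson_oracle(self):
        x = np.array(
            [[0.3, 1.2, -0.5, 0.9], [2.0, -1.0, 0.4, 0.1], [0.0, 0.5, 1.5, -2.0]]
        )
        adj = build_adjacency(make_residual_matrix(x), NetworkParams(power=3))
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else abs(stats.pearsonr(x[i], x[j])[0]) ** 3
                assert abs(adj[i, j] - expected) < 1e-12

    def test_zero_variance_cpg_rejected(self, rng):
        x = rng.normal(size=(4, 10))
        x[2] = 7.0
        with pytest.raises(ValueError, match="cg00002"):
            build_adjacency(make_residual_matrix(x), NetworkParams())

    def test_symmetry_range_diagonal(self, rng):
        x = rng.normal(size=(20, 15))
        adj = build_adjacency(make_residual_matrix(x), NetworkParams(power=3))
        tom = tom_similarity(adj)
        for m in (adj, tom):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            assert m.min() >= 0 and m.max() <= 1 + 1e-12
            np.testing.assert_allclose(np.diag(m), 1.0)


class TestTom:
    def test_two_node_reduction(self):
        for a12 in (0.2, 0.5, 0.9):
            a = np.array([[1.0, a12], [a12, 1.0]])
            np.testing.assert_allclose(tom_similarity(a)[0, 1], a12, atol=1e-12)

    def test_duplicated_node_has_full_overlap(self):
        # binary adjacency, nodes 0 and 1 share every neighbour and each other
        a = np.array(
            [
                [1.0, 1.0, 1.0, 0.0],
                [1.0, 1.0, 1.0, 0.0],
                [1.0, 1.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
            ]
        )
        assert abs(tom_similarity(a)[0, 1] - 1.0) < 1e-12

    def test_matches_brute_force_oracle(self, rng):
        r = rng.uniform(0.05, 0.95, size=(6, 6))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), brute_force_tom(a), atol=1e-12)


class TestSoftThreshold:
    def test_power_law_connectivity_fits_well(self, rng):
        # construct data whose connectivity follows a discrete power law by
        # planting modules of power-law-distributed sizes
        sizes = [150, 60, 35, 22, 15, 11, 8, 6]
        rows, n = [], 60
        for s in sizes:
            f = rng.normal(size=n)
            rows.extend(0.95 * f + 0.31 * rng.normal(size=n) for _ in range(s))
        mat = make_residual_matrix(np.array(rows))
        table = pick_soft_threshold(mat, powers=[6], seed=0)
        assert table.loc[0, "scale_free_r2"] >= 0.8

    def test_power_zero_is_degenerate(self, rng):
        mat = make_residual_matrix(rng.normal(size=(50, 20)))
        with pytest.raises(ValueError):
            NetworkParams(power=0)
        table = pick_soft_threshold(mat, powers=[1e-9], seed=0)
        assert bool(table.loc[0, "degenerate"]) is True or table.loc[0, "scale_free_r2"] == 0

    def test_mean_connectivity_decreasing_in_power(self, rng):
        mat = make_residual_matrix(rng.normal(size=(100, 30)))
        table = pick_soft_threshold(mat, powers=[1, 2, 3, 4], seed=1)
        k = table["mean_connectivity"].to_numpy()
        assert (np.diff(k) < 0).all()


class TestPartitionBlocks:
    def test_single_block_when_small(self, rng):
        mat = make_residual_matrix(rng.normal(size=(50, 10)))
        blocks = partition_blocks(mat, 30000)
        assert len(blocks) == 1 and len(blocks[0]) == 50

    def test_partition_contract(self, rng):
        mat = make_residual_matrix(rng.normal(size=(50, 10)))
        blocks = partition_blocks(mat, 20, seed=0)
        assert len(blocks) == 3
        assert all(len(b) <= 20 for b in blocks)
        assert sorted(np.concatenate(blocks)) == list(range(50))

    def test_planted_groups_stay_together(self):
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            f1, f2 = rng.normal(size=n), rng.normal(size=n)
            rows = [0.9 * f1 + 0.44 * rng.normal(size=n) for _ in range(30)]
            rows += [0.9 * f2 + 0.44 * rng.normal(size=n) for _ in range(30)]
            mat = make_residual_matrix(np.array(rows))
            blocks = partition_blocks(mat, 30, seed=seed)
            ok = all(
                len({0 if i < 30 else 1 for i in b}) == 1 for b in blocks
            )
            kept += ok
        assert kept >= 18


class TestCutAndMerge:
    def _planted(self, seed, n_cpgs=300, module=100, r=0.9, n=60):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(2):
            f = rng.normal(size=n)
            rows.extend(
                np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=n)
                for _ in range(module)
            )
        rows.extend(rng.normal(size=n) for _ in range(n_cpgs - 2 * module))
        return make_residual_matrix(np.array(rows))

    def test_two_planted_blocks_recovered_pure(self):
        mat = self._planted(0)
        params = NetworkParams(min_module_size=50)
        adj = build_adjacency(mat, params)
        labels = cut_modules(1.0 - tom_similarity(adj), params)
        found = set(labels) - {0}
        assert len(found) == 2
        for m in found:
            members = np.flatnonzero(labels == m)
            assert len({i // 100 for i in members if i < 200}) == 1

    def test_all_noise_stays_grey(self):
        grey = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mat = make_residual_matrix(rng.normal(size=(300, 60)))
            params = NetworkParams(min_module_size=100)
            adj = build_adjacency(mat, params)
            labels = cut_modules(1.0 - tom_similarity(adj), params)
            grey += (labels == 0).all()
        assert grey >= 18

    def test_order_invariance(self, rng):
        mat = self._planted(3)
        params = NetworkParams(min_module_size=50)
        labels = cut_modules(1.0 - tom_similarity(build_adjacency(mat, params)), params)
        perm = rng.permutation(len(mat.cpg_ids))
        mat_p = make_residual_matrix(mat.values[perm])
        labels_p = cut_modules(
            1.0 - tom_similarity(build_adjacency(mat_p, params)), params
        )
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_split_factor_remerged(self):
        rng = np.random.default_rng(5)
        n = 60
        f = rng.normal(size=n)
        rows = [0.85 * f + 0.53 * rng.normal(size=n) for _ in range(80)]
        mat = make_residual_matrix(np.array(rows))
        labels = np.array([1] * 40 + [2] * 40)  # artificially split one factor
        merged = merge_modules(mat, labels, merge_cut_height=0.15)
        assert len(merged.module_ids) == 1

    def test_zero_merge_height_keeps_labels(self):
        mat = self._planted(7)
        labels = np.array([1] * 100 + [2] * 100 + [0] * 100)
        merged = merge_modules(mat, labels, merge_cut_height=0.0)
        assert adjusted_rand_score(labels, merged.labels.to_numpy()) == 1.0


class TestEigengenes:
    def test_identical_rows_give_perfect_correlation(self):
        row = np.array([0.5, -1.0, 2.0, 0.3, -0.8])
        mat = make_residual_matrix(np.tile(row, (4, 1)))
        me = module_eigengenes(mat, np.ones(4, dtype=int))
        r = np.corrcoef(me.loc[1], row)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12 and r > 0

    def test_sign_convention(self, rng):
        mat = make_residual_matrix(rng.normal(size=(30, 20)))
        labels = np.repeat([1, 2, 3], 10)
        me = module_eigengenes(mat, labels)
        z = (mat.values - mat.values.mean(1, keepdims=True)) / mat.values.std(
            1, keepdims=True
        )
        for m in (1, 2, 3):
            members = np.flatnonzero(labels == m)
            cors = [np.corrcoef(z[i], me.loc[m])[0, 1] for i in members]
            assert np.mean(cors) >= 0

    def test_two_cpg_module_matches_closed_form_svd(self):
        # 2x3 matrix: first right singular vector via the 2x2 Gram matrix's
        # characteristic polynomial, computed independently
        x = np.array([[1.0, 0.0, -1.0], [2.0, -1.0, -1.0]])
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        g = z @ z.T  # 2x2
        tr, det = g[0, 0] + g[1, 1], g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        lam = (tr + np.sqrt(tr**2 - 4 * det)) / 2
        # left singular vector u solves (G - lam I) u = 0
        u = np.array([g[0, 1], lam - g[0, 0]])
        u /= np.linalg.norm(u)
        v = z.T @ u
        v /= np.linalg.norm(v)
        mat = make_residual_matrix(x)
        me = module_eigengenes(mat, np.ones(2, dtype=int)).loc[1].to_numpy()
        assert min(np.abs(me - v).max(), np.abs(me + v).max()) < 1e-10


class TestModuleStatistics:
    def test_membership_extremes_and_closed_form(self, rng):
        n = 10
        me_vec = rng.normal(size=n)
        x0 = me_vec.copy()                       # equals its eigengene
        x1 = rng.normal(size=n)
        x1 -= (x1 @ (me_vec - me_vec.mean())) / ((me_vec - me_vec.mean()) @ (me_vec - me_vec.mean())) * (me_vec - me_vec.mean())
        x1 -= x1.mean()                          # orthogonal to the eigengene
        x2 = rng.normal(size=n)
        mat = make_residual_matrix(np.array([x0, x1, x2]))
        me = pd.DataFrame([me_vec], index=[1], columns=mat.sample_ids)
        mm, mm_p = module_membership(mat, me)
        assert abs(mm.iloc[0, 0] - 1.0) < 1e-12
        assert mm_p.iloc[0, 0] < 1e-12
        assert abs(mm.iloc[1, 0]) < 1e-12
        # closed form for the generic row
        r_expected, p_expected = stats.pearsonr(x2, me_vec)
        assert abs(mm.iloc[2, 0] - r_expected) < 1e-10
        assert abs(mm_p.iloc[2, 0] - p_expected) < 1e-10

    def test_probe_significance_equals_two_sample_t(self, rng):
        trait = np.array([0] * 6 + [1] * 6)
        x = rng.normal(size=(1, 12))
        mat = make_residual_matrix(x)
        ps, ps_p = probe_significance(mat, trait)
        t_pooled, p_pooled = stats.ttest_ind(x[0, trait == 1], x[0, trait == 0])
        r = ps.iloc[0]
        t_from_r = r * np.sqrt(10 / (1 - r**2))
        assert abs(t_from_r - t_pooled) < 1e-10
        assert abs(ps_p.iloc[0] - p_pooled) < 1e-10
        # exact indicator gives r = 1
        ps2, _ = probe_significance(make_residual_matrix(trait[None, :].astype(float)), trait)
        assert abs(ps2.iloc[0] - 1.0) < 1e-12
        with pytest.raises(ValueError):
            probe_significance(mat, np.ones(12))

    def test_trait_test_matches_hand_welch(self):
        me = pd.DataFrame([[1.0, 2.0, 3.0, 6.0, 7.0, 10.0]], index=[1])
        trait = np.array([0, 0, 0, 1, 1, 1])
        out = module_trait_test(me, trait)
        x1, x0 = np.array([6.0, 7.0, 10.0]), np.array([1.0, 2.0, 3.0])
        v1, v0 = x1.var(ddof=1) / 3, x0.var(ddof=1) / 3
        t_hand = (x1.mean() - x0.mean()) / np.sqrt(v1 + v0)
        df_hand = (v1 + v0) ** 2 / (v1**2 / 2 + v0**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert abs(out.loc[1, "t"] - t_hand) < 1e-10
        assert abs(out.loc[1, "p"] - p_hand) < 1e-10

    def test_trait_test_identical_groups_and_separation(self, rng):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        me = pd.DataFrame([vals], index=[1])
        out = module_trait_test(me, np.array([0, 0, 0, 1, 1, 1]))
        assert abs(out.loc[1, "t"]) < 1e-12 and out.loc[1, "p"] > 0.999
        shifted = np.concatenate([rng.normal(0, 1, 20), rng.normal(10, 1, 20)])
        me2 = pd.DataFrame([shifted], index=[1])
        out2 = module_trait_test(me2, np.array([0] * 20 + [1] * 20))
        assert out2.loc[1, "p"] < 1e-10

    def test_mm_ps_correlation_oracle_and_degenerate(self, rng):
        labels = pd.Series(
            np.ones(10, dtype=int), index=[f"cg{i:05d}" for i in range(10)]
        )
        mm_vals = rng.uniform(-1, 1, 10)
        ps_vals = rng.uniform(-1, 1, 10)
        mm = pd.DataFrame({1: mm_vals}, index=labels.index)
        ps = pd.Series(ps_vals, index=labels.index)
        r, p, degen = mm_ps_correlation(mm, ps, labels, 1)
        r_exp, p_exp = stats.pearsonr(np.abs(mm_vals), np.abs(ps_vals))
        assert not degen and abs(r - r_exp) < 1e-12 and abs(p - p_exp) < 1e-12
        # identical vectors -> r = 1
        r1, _, _ = mm_ps_correlation(mm, pd.Series(mm_vals, index=labels.index), labels, 1)
        assert abs(r1 - 1.0) < 1e-12
        # constant |PS| -> degenerate
        r0, p0, degen0 = mm_ps_correlation(
            mm, pd.Series(0.5, index=labels.index), labels, 1
        )
        assert degen0 and r0 == 0.0 and p0 == 1.0

    def test_candidate_selection_rules(self):
        import types as _t

        stats_ = _t.SimpleNamespace(
            trait_test=pd.DataFrame({"t": [2.0, 1.0, 2.5], "p": [0.046, 0.2, 0.01]},
                                    index=[1, 2, 3]),
            mmps=pd.DataFrame({"r": [0.12, 0.5, -0.3], "p": [1.9e-4, 1e-6, 1e-6]},
                              index=[1, 2, 3]),
        )
        assert select_candidate_modules(stats_) == [1]  # 2 fails trait, 3 fails r>0
        assert select_candidate_modules(stats_, alpha=0.0) == []


class TestHubs:
    def _stats(self, mm_vals, ps_vals, ids):
        import types as _t

        mm = pd.DataFrame({1: mm_vals}, index=ids)
        ps = pd.Series(ps_vals, index=ids)
        return _t.SimpleNamespace(mm=mm, ps=ps)

    def test_identical_ranking_gives_exact_quarter(self):
        ids = pd.Index([f"cg{i:05d}" for i in range(100)])
        vals = np.linspace(0.99, 0.01, 100)
        labels = pd.Series(1, index=ids)
        hubs = hub_probes(self._stats(vals, vals, ids), labels, 1)
        assert len(hubs) == 25
        assert set(hubs) == set(ids[:25])

    def test_opposite_ranking_gives_empty(self):
        ids = pd.Index([f"cg{i:05d}" for i in range(100)])
        vals = np.linspace(0.99, 0.01, 100)
        labels = pd.Series(1, index=ids)
        assert hub_probes(self._stats(vals, vals[::-1], ids), labels, 1) == []

    def test_independent_ranks_give_binomial_fraction(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ids = pd.Index([f"cg{i:05d}" for i in range(1024)])
            labels = pd.Series(1, index=ids)
            hubs = hub_probes(
                self._stats(rng.uniform(size=1024), rng.uniform(size=1024), ids),
                labels, 1,
            )
            counts.append(len(hubs))
        assert 40 < np.mean(counts) < 90  # ~ 1024/16 = 64 expected


class TestFullDetection:
    def test_planted_modules_recovered(self, small_cohort):
        resid, samples, truth = small_cohort
        assignment = detect_modules(resid, NetworkParams(min_module_size=80), seed=0)
        ari = adjusted_rand_score(
            truth.true_module_labels.to_numpy(), assignment.labels.to_numpy()
        )
        assert ari >= 0.8

    def test_stats_pipeline_flags_trait_module(self, small_cohort):
        resid, samples, truth = small_cohort
        assignment = detect_modules(resid, NetworkParams(min_module_size=80), seed=0)
        stats_ = compute_module_stats(resid, assignment, samples["trait"].to_numpy())
        candidates = select_candidate_modules(stats_)
        # the planted trait-associated module (largest overlap with truth==1)
        overlap = {
            m: (truth.true_module_labels[assignment.labels == m] == 1).mean()
            for m in assignment.module_ids
        }
        trait_module = max(overlap, key=overlap.get)
        assert trait_module in candidates
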