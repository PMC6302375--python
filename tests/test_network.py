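"""Weighted correlation network: adjacency, TOM, clustering, modules."""

import warnings

import numpy as np
import pytest

from metaboregion import (
    NetworkParams,
    SymmetricMatrix,
    SyntheticConfig,
    choose_beta,
    connectivity,
    correlation_matrix,
    cut_tree_dynamic,
    detect_modules,
    dissimilarity,
    eigen_metabolite,
    eigen_region_anova,
    generate_dataset,
    hierarchical_cluster,
    module_hub,
    planted_factors,
    recovery_score,
    region_correlation_panels,
    scale_free_fit,
    soft_threshold,
    topological_overlap,
)
from conftest import make_profile


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def tom_triple_loop(a):
    """Literal triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            omega[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return omega


def complete_linkage_naive(D):
    """O(n^3) agglomeration; returns sorted merge heights."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


def random_adjacency(rng, n):
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def adjacency_matrix(a):
    return SymmetricMatrix(
        ids=[f"m{i}" for i in range(a.shape[0])], values=a, role="adjacency"
    )


def distance_matrix(d):
    return SymmetricMatrix(
        ids=[f"m{i}" for i in range(d.shape[0])], values=d, role="dissimilarity"
    )


# ---------------------------------------------------------------------------
# Matrix container
# ---------------------------------------------------------------------------

class TestSymmetricMatrix:
    def test_role_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            SymmetricMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]), "correlation")
        with pytest.raises(ValueError, match="diagonal"):
            SymmetricMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]), "adjacency")
        with pytest.raises(ValueError, match="outside"):
            SymmetricMatrix(["a", "b"], np.array([[0.0, 1.7], [1.7, 0.0]]), "adjacency")


class TestCorrelation:
    def test_duplicate_and_negated_rows(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        prof = make_profile(
            np.vstack([base, base, -base]) + 10.0,
            groups=["A"] * 3 + ["B"] * 3,
        )
        S = correlation_matrix(prof, log_transform=False)
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert S.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_pearson_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 5))
        prof = make_profile(vals, groups=["A"] * 2 + ["B"] * 3)
        S = correlation_matrix(prof, log_transform=False)
        for i in range(4):
            for j in range(4):
                x, y = vals[i], vals[j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert S.values[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_constant_row_rejected(self):
        prof = make_profile([[1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="m0"):
            correlation_matrix(prof, log_transform=False)


class TestSoftThreshold:
    @pytest.mark.parametrize("s, beta, expected", [(1.0, 5, 1.0), (0.0, 5, 0.0), (0.5, 2, 0.25)])
    def test_direct_powers(self, s, beta, expected):
        S = SymmetricMatrix(["a", "b"], np.array([[1.0, s], [s, 1.0]]), "correlation")
        A = soft_threshold(S, NetworkParams(beta=beta))
        assert A.values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert A.values[0, 0] == 0.0

    def test_unsigned_uses_absolute_value(self):
        S = SymmetricMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]), "correlation")
        A = soft_threshold(S, NetworkParams(beta=2))
        assert A.values[0, 1] == pytest.approx(0.25)

    def test_signed_mode_clips_with_warning(self):
        S = SymmetricMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]), "correlation")
        with pytest.warns(UserWarning, match="clipping"):
            A = soft_threshold(S, NetworkParams(beta=3, adjacency_mode="signed"))
        assert A.values[0, 1] == 0.0

    def test_beta_below_one_rejected(self):
        S = SymmetricMatrix(["a"], np.array([[1.0]]), "correlation")
        with pytest.raises(ValueError):
            soft_threshold(S, NetworkParams(beta=0.5))


class TestConnectivity:
    def test_complete_graph(self):
        a = np.ones((3, 3)) - np.eye(3)
        k = connectivity(adjacency_matrix(a))
        np.testing.assert_allclose(k.k, [2.0, 2.0, 2.0])

    def test_zero_adjacency(self):
        k = connectivity(adjacency_matrix(np.zeros((4, 4))))
        np.testing.assert_allclose(k.k, 0.0)

    def test_matches_row_sums(self):
        rng = np.random.default_rng(2)
        a = random_adjacency(rng, 5)
        k = connectivity(adjacency_matrix(a))
        expected = [sum(a[i, u] for u in range(5) if u != i) for i in range(5)]
        np.testing.assert_allclose(k.k, expected, atol=1e-12)


class TestScaleFreeFit:
    def test_exact_power_law_bins(self):
        # place counts proportional to center^-2 at the actual bin centers
        # so the binned log-log points are collinear by construction
        values = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        _, edges = np.histogram(values, bins=5)
        centers = (edges[:-1] + edges[1:]) / 2
        counts = np.round(1e5 * centers**-2.0).astype(int)
        k = np.repeat(values, counts)
        fit = scale_free_fit(k, n_bins=5)
        assert fit.r_squared >= 0.999
        assert fit.gamma_hat == pytest.approx(2.0, rel=0.01)

    def test_two_bins_fit_exactly(self):
        k = np.array([1.0] * 10 + [9.0] * 3)
        fit = scale_free_fit(k, n_bins=2)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            fit = scale_free_fit(rng.uniform(0.5, 30.0, size=100))
            assert 0.0 <= fit.r_squared <= 1.0

    def test_degenerate_connectivity_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(10, 3.0))


class TestChooseBeta:
    def _correlation(self, seed=4, n=40):
        rng = np.random.default_rng(seed)
        prof = make_profile(rng.normal(size=(n, 12)), groups=["A"] * 6 + ["B"] * 6)
        return correlation_matrix(prof, log_transform=False)

    def test_override_bypasses_selection(self):
        S = self._correlation()
        sel = choose_beta(S, override=11)
        assert sel.beta == 11.0 and not sel.warned

    def test_vacuous_threshold_returns_smallest(self):
        S = self._correlation()
        sel = choose_beta(S, candidates=[3, 1, 7], r2_min=0.0)
        assert sel.beta == 1.0

    def test_candidate_order_irrelevant(self):
        S = self._correlation()
        a = choose_beta(S, candidates=[2, 4, 6, 8], r2_min=0.5)
        b = choose_beta(S, candidates=[8, 6, 2, 4], r2_min=0.5)
        assert a.beta == b.beta

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            choose_beta(self._correlation(), candidates=[])


class TestTopologicalOverlap:
    def test_complete_unit_graph_is_fully_overlapping(self):
        a = np.ones((3, 3)) - np.eye(3)
        omega = topological_overlap(adjacency_matrix(a))
        np.testing.assert_allclose(omega.values, 1.0, atol=1e-12)

    def test_empty_network(self):
        omega = topological_overlap(adjacency_matrix(np.zeros((4, 4))))
        np.testing.assert_allclose(omega.values, np.eye(4), atol=1e-12)

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_adjacency(rng, int(rng.integers(3, 9)))
            omega = topological_overlap(adjacency_matrix(a))
            np.testing.assert_allclose(omega.values, tom_triple_loop(a), atol=1e-12)

    def test_range(self):
        rng = np.random.default_rng(6)
        a = random_adjacency(rng, 12)
        omega = topological_overlap(adjacency_matrix(a))
        assert omega.values.min() >= 0.0 and omega.values.max() <= 1.0


class TestDissimilarity:
    def test_complements_overlap(self):
        rng = np.random.default_rng(7)
        a = random_adjacency(rng, 6)
        omega = topological_overlap(adjacency_matrix(a))
        D = dissimilarity(omega)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(D.values[off], 1.0 - omega.values[off], atol=1e-15)
        np.testing.assert_allclose(np.diag(D.values), 0.0)


class TestHierarchicalCluster:
    def test_three_point_structure(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = hierarchical_cluster(distance_matrix(d))
        np.testing.assert_allclose(dend.heights, [0.1, 0.9], atol=1e-12)

    def test_pair(self):
        d = np.array([[0.0, 0.42], [0.42, 0.0]])
        dend = hierarchical_cluster(distance_matrix(d))
        assert dend.heights[0] == pytest.approx(0.42)

    def test_matches_naive_agglomerator(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = rng.uniform(0.05, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dend = hierarchical_cluster(distance_matrix(d))
            np.testing.assert_allclose(
                sorted(dend.heights), complete_linkage_naive(d), atol=1e-12
            )

    def test_heights_monotone(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(size=(15, 15))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = hierarchical_cluster(distance_matrix(d))
        assert np.all(np.diff(dend.heights) >= -1e-12)


def block_dissimilarity(sizes, within, between, n_noise=0, rng=None):
    """Block-structured dissimilarity with optional noisy background."""
    n = sum(sizes) + n_noise
    d = np.full((n, n), between, dtype=float)
    start = 0
    for sz in sizes:
        d[start : start + sz, start : start + sz] = within
        start += sz
    if rng is not None and n_noise:
        noise = rng.uniform(between - 0.02, between, size=(n, n))
        noise = (noise + noise.T) / 2
        d[start:, :] = noise[start:, :]
        d[:, start:] = noise[:, start:]
    np.fill_diagonal(d, 0.0)
    return d


class TestCutTreeDynamic:
    def test_two_separated_blocks(self):
        d = block_dissimilarity([12, 12], within=0.05, between=0.95)
        dend = hierarchical_cluster(distance_matrix(d))
        labels = cut_tree_dynamic(dend, NetworkParams())
        assert len(set(labels)) == 2 and -1 not in labels
        # oracle: connected components of the graph thresholded at the cut
        first_block = labels[:12]
        assert len(set(first_block)) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_small_block_stays_unassigned(self):
        d = block_dissimilarity([8], within=0.05, between=0.95, n_noise=5,
                                rng=np.random.default_rng(0))
        dend = hierarchical_cluster(distance_matrix(d))
        labels = cut_tree_dynamic(dend, NetworkParams())
        assert np.all(labels == -1)

    def test_structureless_overlap_dendrogram_yields_nothing(self):
        # TOM dissimilarity of pure noise: merge heights pile up at ~1
        rng = np.random.default_rng(1)
        prof = make_profile(
            np.exp(rng.normal(2.0, 1.0, size=(60, 24))),
            groups=[g for g in "ABCD" for _ in range(6)],
        )
        S = correlation_matrix(prof)
        A = soft_threshold(S, NetworkParams())
        D = dissimilarity(topological_overlap(A))
        labels = cut_tree_dynamic(hierarchical_cluster(D), NetworkParams())
        assert np.all(labels == -1)

    def test_invalid_quantile_rejected(self):
        d = block_dissimilarity([12], within=0.1, between=0.9)
        dend = hierarchical_cluster(distance_matrix(d))
        with pytest.raises(ValueError):
            cut_tree_dynamic(dend, NetworkParams(cut_height_quantile=1.5))


class TestDetectModules:
    def test_benchmark_recovery(self, default_dataset):
        profile, truth = default_dataset
        assignment = detect_modules(profile)
        assert len(assignment.modules) == 5
        assert recovery_score(assignment, truth) >= 0.9

    def test_pure_noise_gives_no_modules(self):
        cfg = SyntheticConfig(seed=2, n_modules=0, module_sizes=(), n_affected=0)
        profile, _ = generate_dataset(cfg)
        assignment = detect_modules(profile)
        assert assignment.modules == []
        assert all(v is None for v in assignment.labels.values())

    def test_single_perfect_module_with_noise_background(self):
        rng = np.random.default_rng(3)
        factor = rng.normal(size=24)
        rows = [factor * rng.uniform(0.5, 2.0) + rng.normal(0, 0.05, 24) + 5
                for _ in range(12)]
        rows += [rng.normal(5, 1, 24) for _ in range(5)]
        prof = make_profile(
            np.exp(np.array(rows) * 0.3),
            groups=[g for g in "ABCD" for _ in range(6)],
        )
        assignment = detect_modules(prof)
        assert len(assignment.modules) == 1
        assert set(assignment.modules[0].members) == {f"m{i}" for i in range(12)}

    def test_deterministic(self, default_dataset):
        profile, _ = default_dataset
        a1 = detect_modules(profile)
        a2 = detect_modules(profile)
        assert a1.labels == a2.labels
        assert [m.members for m in a1.modules] == [m.members for m in a2.modules]

    def test_module_size_rule_on_fuzzed_inputs(self):
        params = NetworkParams()
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(15, 60))
            vals = np.exp(rng.normal(1.0, 1.0, size=(n, 24)))
            if seed % 2:  # plant a partial block to stress the boundary
                block = rng.integers(5, 15)
                f = rng.normal(size=24)
                vals[:block] = np.exp(f * 0.9 + rng.normal(0, 0.3, (block, 24)))
            prof = make_profile(vals, groups=[g for g in "ABCD" for _ in range(6)])
            assignment = detect_modules(prof, params)
            for mod in assignment.modules:
                assert mod.size > params.min_module_size_exclusive

    def test_recovery_monotone_in_module_loading(self):
        means = []
        for lam in (0.3, 0.5, 0.7, 0.9):
            scores = []
            for seed in range(5):
                cfg = SyntheticConfig(seed=seed, module_loading=lam)
                profile, truth = generate_dataset(cfg)
                scores.append(recovery_score(detect_modules(profile), truth))
            means.append(np.mean(scores))
        assert np.all(np.diff(means) >= -1e-9)

    def test_too_few_metabolites_rejected(self):
        prof = make_profile(np.exp(np.random.default_rng(0).normal(size=(5, 8))))
        with pytest.raises(ValueError):
            detect_modules(prof)


class TestEigenMetabolite:
    def test_identical_members(self):
        row = np.random.default_rng(0).normal(size=12)
        prof = make_profile(np.exp(np.vstack([row, row, row])),
                            groups=["A"] * 6 + ["B"] * 6)
        eig = eigen_metabolite(prof, ["m0", "m1", "m2"])
        assert eig.variance_explained == pytest.approx(1.0, abs=1e-10)
        logv = np.log(prof.values[0])
        corr = np.corrcoef(logv, eig.scores)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_unit_norm_and_orientation(self, default_dataset):
        profile, truth = default_dataset
        members = truth.module_members()["planted_1"]
        eig = eigen_metabolite(profile, members)
        assert np.linalg.norm(eig.scores) == pytest.approx(1.0, abs=1e-10)
        logv = np.log2(profile.values)
        idx = [profile.metabolite_ids.index(m) for m in members]
        corrs = [np.corrcoef(logv[i], eig.scores)[0, 1] for i in idx]
        assert np.mean(corrs) >= 0

    def test_variance_explained_bounds(self, default_dataset):
        profile, truth = default_dataset
        for members in truth.module_members().values():
            eig = eigen_metabolite(profile, members)
            assert 1 / len(members) <= eig.variance_explained <= 1.0

    def test_recovers_planted_factor(self):
        cfg = SyntheticConfig(seed=6, module_loading=0.9)
        profile, truth = generate_dataset(cfg)
        factors = planted_factors(cfg)
        for j in range(cfg.n_modules):
            members = truth.module_members()[f"planted_{j + 1}"]
            eig = eigen_metabolite(profile, members)
            corr = abs(np.corrcoef(eig.scores, factors[j])[0, 1])
            assert corr >= 0.95

    def test_singleton_rejected(self, default_dataset):
        profile, _ = default_dataset
        with pytest.raises(ValueError):
            eigen_metabolite(profile, [profile.metabolite_ids[0]])


class TestModuleHub:
    def test_identical_members_lexicographic_tie(self):
        row = np.random.default_rng(1).normal(size=12)
        prof = make_profile(
            np.exp(np.vstack([row, row, row])),
            metabolite_ids=["zeta", "alpha", "mid"],
            groups=["A"] * 6 + ["B"] * 6,
        )
        eig = eigen_metabolite(prof, ["zeta", "alpha", "mid"])
        hub, scores = module_hub(prof, ["zeta", "alpha", "mid"], eig)
        assert hub == "alpha"
        assert all(s == pytest.approx(1.0, abs=1e-10) for s in scores.values())

    def test_scores_in_unit_interval(self, default_dataset):
        profile, truth = default_dataset
        members = truth.module_members()["planted_2"]
        eig = eigen_metabolite(profile, members)
        _, scores = module_hub(profile, members, eig)
        assert all(0.0 <= s <= 1.0 for s in scores.values())

    def test_cleanest_factor_copy_is_hub(self):
        rng = np.random.default_rng(2)
        factor = rng.normal(size=24)
        rows = [factor + rng.normal(0, 1.0, 24) for _ in range(11)]
        rows.insert(0, factor + rng.normal(0, 0.01, 24))  # m0: near-pure copy
        prof = make_profile(np.exp(np.array(rows) * 0.4),
                            groups=[g for g in "ABCD" for _ in range(6)])
        members = [f"m{i}" for i in range(12)]
        eig = eigen_metabolite(prof, members)
        hub, scores = module_hub(prof, members, eig)
        assert hub == "m0"
        assert scores["m0"] == max(scores.values())


class TestEigenRegionAnova:
    def test_strong_group_shift_detected(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 0.05, size=24)
        scores[:6] += 2.0
        from metaboregion.network import EigenMetabolite

        eig = EigenMetabolite(
            sample_ids=[f"s{i}" for i in range(24)],
            scores=scores / np.linalg.norm(scores),
            variance_explained=0.5,
        )
        p = eigen_region_anova(eig, [g for g in "ABCD" for _ in range(6)])
        assert p < 1e-3

    def test_null_scores_not_significant_on_average(self):
        rng = np.random.default_rng(4)
        from metaboregion.network import EigenMetabolite

        ps = []
        for _ in range(200):
            s = rng.normal(size=24)
            eig = EigenMetabolite(
                sample_ids=[f"s{i}" for i in range(24)],
                scores=s / np.linalg.norm(s),
                variance_explained=0.5,
            )
            ps.append(eigen_region_anova(eig, [g for g in "ABCD" for _ in range(6)]))
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.05


class TestRegionPanels:
    def test_pair_counts_and_merged_consistency(self, default_dataset):
        profile, _ = default_dataset
        assignment = detect_modules(profile)
        panels = region_correlation_panels(profile, assignment)
        mod = assignment.modules[0]
        n_pairs = mod.size * (mod.size - 1) // 2
        sub = panels[panels["module"] == mod.name]
        assert set(sub["panel"]) == {"OB", "FCX", "HC", "CBL", "merged"}
        assert (sub["panel"] == "merged").sum() == n_pairs
        # merged panel equals the full correlation matrix restricted to members
        S = correlation_matrix(profile.subset(mod.members))
        merged = sub[sub["panel"] == "merged"]
        for _, row in merged.head(20).iterrows():
            i = mod.members.index(row["metabolite_a"])
            j = mod.members.index(row["metabolite_b"])
            assert row["correlation"] == pytest.approx(S.values[i, j], abs=1e-12)

    def test_group_specific_structure_differs(self):
        # module correlated only within group A samples
        rng = np.random.default_rng(5)
        n = 14
        vals = rng.normal(0, 1.0, size=(n, 24))
        factor = rng.normal(size=6)
        vals[:12, :6] = factor * 1.5 + rng.normal(0, 0.2, size=(12, 6))
        prof = make_profile(np.exp(vals * 0.4),
                            groups=[g for g in "ABCD" for _ in range(6)])
        from metaboregion.network import Module, ModuleAssignment

        members = [f"m{i}" for i in range(12)]
        assignment = ModuleAssignment(
            labels={m: ("x" if m in members else None) for m in prof.metabolite_ids},
            modules=[Module(name="x", members=members, iteration_found=1)],
            iteration_count=1,
        )
        panels = region_correlation_panels(prof, assignment)
        corr_a = panels[panels["panel"] == "A"]["correlation"].to_numpy()
        corr_b = panels[panels["panel"] == "B"]["correlation"].to_numpy()
        from scipy.stats import ks_2samp

        assert ks_2samp(corr_a, corr_b).statistic > 0.2
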