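"""Pattern sweep, CSPA consensus, silhouette, and module-count selection."""

import numpy as np
import pytest

from xtaxnet import (
    build_tom,
    consensus_matrix,
    optimal_modules,
    select_patterns,
    sweep_module_patterns,
)
from xtaxnet.consensus_modules import (
    ModuleSolution,
    PatternSweep,
    _comembership,
    average_silhouette,
    silhouette_curve,
    silhouette_samples_precomputed,
)

from conftest import block_correlation


def three_block_dissim(block_size: int = 15, rho: float = 0.8) -> np.ndarray:
    r = block_correlation(3 * block_size, {b: (range(b * block_size, (b + 1) * block_size), rho) for b in range(3)})
    return build_tom(r).dissim


def silhouette_brute_force(dissim: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = dissim.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        own_members = [j for j in range(n) if labels[j] == own and j != i]
        if not own_members:
            continue
        a = np.mean([dissim[i, j] for j in own_members])
        b = min(
            np.mean([dissim[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels)
            if other != own
        )
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


class TestPatternSweep:
    def test_three_separated_blocks_recovered(self):
        sweep = sweep_module_patterns(three_block_dissim())
        for ms in range(3, 16):
            assert sweep.n_modules[ms] == 3

    def test_oversized_min_size_collapses(self):
        sweep = sweep_module_patterns(three_block_dissim())
        for ms in range(16, 41):
            assert sweep.n_modules[ms] <= 2

    def test_relabeled_partition_detected_as_duplicate(self):
        lab = np.array([1, 1, 2, 2, 3, 3])
        relabeled = np.array([3, 3, 1, 1, 2, 2])
        assert np.array_equal(_comembership(lab), _comembership(relabeled))

    def test_too_few_taxa_errors(self):
        with pytest.raises(ValueError, match="3 taxa"):
            sweep_module_patterns(np.zeros((2, 2)))


def stub_sweep(n_modules_per_pattern: dict) -> PatternSweep:
    """Sweep stub with prescribed module counts, one label vector each."""
    labels = {}
    for ms, k in n_modules_per_pattern.items():
        lab = np.arange(max(k, 1)).repeat(2) + 1 if k else np.zeros(4, int)
        labels[ms] = lab
    return PatternSweep(
        min_sizes=list(n_modules_per_pattern),
        labels=labels,
        n_modules=dict(n_modules_per_pattern),
        is_unique={ms: True for ms in n_modules_per_pattern},
    )


class TestSelectPatterns:
    def test_default_bar_at_ten_modules(self):
        sweep = stub_sweep({3: 23, 5: 17, 8: 12, 12: 9, 20: 6})
        assert select_patterns(sweep, min_modules=10) == [3, 5, 8]

    def test_manual_override(self):
        sweep = stub_sweep({3: 23, 5: 17, 7: 12})
        assert select_patterns(sweep, manual=[5, 7]) == [5, 7]

    def test_min_modules_one_selects_all_unique(self):
        sweep = stub_sweep({3: 4, 5: 3, 8: 2})
        assert select_patterns(sweep, min_modules=1) == [3, 5, 8]

    def test_empty_selection_errors(self):
        sweep = stub_sweep({3: 4})
        with pytest.raises(ValueError, match="min_modules"):
            select_patterns(sweep, min_modules=10)


class TestConsensusMatrix:
    def test_identical_partitions_give_binary_consensus(self):
        lab = np.array([1, 1, 2, 2, 3, 3])
        sweep = PatternSweep(
            min_sizes=[3, 4],
            labels={3: lab, 4: lab.copy()},
            n_modules={3: 3, 4: 3},
            is_unique={3: True, 4: False},
        )
        cons = consensus_matrix(sweep, [3, 4])
        assert set(np.unique(cons.C)) <= {0.0, 1.0}

    def test_half_comembership(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 2, 1])
        sweep = PatternSweep([3, 4], {3: a, 4: b}, {3: 2, 4: 2}, {3: True, 4: True})
        cons = consensus_matrix(sweep, [3, 4])
        assert cons.C[0, 1] == 0.5

    def test_entries_are_multiples_of_reciprocal_pattern_count(self):
        rng = np.random.default_rng(21)
        labs = {m: rng.integers(0, 4, size=12) for m in range(3, 8)}
        sweep = PatternSweep(
            list(labs), labs, {m: 3 for m in labs}, {m: True for m in labs}
        )
        cons = consensus_matrix(sweep, list(labs))
        scaled = cons.C * cons.n_patterns
        assert np.allclose(scaled, np.round(scaled))

    def test_label_zero_taxa_never_comembers(self):
        lab = np.array([0, 0, 1, 1])
        sweep = PatternSweep([3], {3: lab}, {3: 1}, {3: True})
        cons = consensus_matrix(sweep, [3])
        assert cons.C[0, 1] == 0.0  # both unassigned: not co-members
        assert cons.C[0, 0] == 1.0  # diagonal forced

    def test_invariant_to_label_permutation(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([2, 2, 3, 3, 1, 1])
        s1 = PatternSweep([3], {3: a}, {3: 3}, {3: True})
        s2 = PatternSweep([3], {3: b}, {3: 3}, {3: True})
        assert np.array_equal(
            consensus_matrix(s1, [3]).C, consensus_matrix(s2, [3]).C
        )


class TestSilhouette:
    def test_perfect_blocks_score_one_at_true_k(self):
        c = _comembership(np.array([1] * 4 + [2] * 4 + [3] * 4))
        np.fill_diagonal(c, 1.0)
        d = 1.0 - c
        assert average_silhouette(d, np.array([1] * 4 + [2] * 4 + [3] * 4)) == 1.0
        merged = np.array([1] * 8 + [2] * 4)
        assert average_silhouette(d, merged) < 1.0

    def test_singleton_contributes_zero(self):
        d = np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]
        )
        s = silhouette_samples_precomputed(d, np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            d = rng.random((12, 12))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = rng.integers(0, 3, size=12)
            if len(set(labels)) < 2:
                continue
            impl = silhouette_samples_precomputed(d, labels)
            oracle = silhouette_brute_force(d, labels)
            assert np.max(np.abs(impl - oracle)) < 1e-12

    def test_matches_sklearn_on_nonsingleton_instances(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(23)
        for _ in range(20):
            d = rng.random((15, 15))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = np.repeat([0, 1, 2], 5)
            rng.shuffle(labels)
            impl = silhouette_samples_precomputed(d, labels)
            ref = silhouette_samples(d, labels, metric="precomputed")
            assert np.max(np.abs(impl - ref)) < 1e-10


def solution_from_curve(curve: dict, zero_prop: dict | None = None) -> ModuleSolution:
    ks = list(curve)
    return ModuleSolution(
        k_opt=None,
        labels=None,
        silhouette_curve=dict(curve),
        zero_proportion=zero_prop or {k: {1: 0.0} for k in ks},
        labels_per_k={k: np.arange(k) for k in ks},
    )


class TestOptimalModules:
    def test_first_local_maximum(self):
        sol = optimal_modules(solution_from_curve({2: 0.50, 3: 0.71, 4: 0.65, 5: 0.68}))
        assert sol.k_opt == 3

    def test_monotone_curve_takes_endpoint(self):
        sol = optimal_modules(solution_from_curve({2: 0.3, 3: 0.5, 4: 0.7}))
        assert sol.k_opt == 4

    def test_zero_proportion_gate_excludes_candidates(self):
        zp = {2: {1: 0.5}, 3: {1: 0.0, 2: 0.0}, 4: {1: 0.0, 2: 0.0, 3: 0.0}}
        sol = optimal_modules(
            solution_from_curve({2: 0.9, 3: 0.7, 4: 0.6}, zp)
        )
        assert sol.k_opt == 3  # k=2 gated out despite higher silhouette

    def test_gate_failure_reports_violations(self):
        zp = {2: {1: 0.5}, 3: {1: 0.4, 2: 0.2}}
        with pytest.raises(ValueError, match="zero-proportion"):
            optimal_modules(solution_from_curve({2: 0.9, 3: 0.7}, zp))

    def test_manual_k_overrides(self):
        sol = optimal_modules(
            solution_from_curve({2: 0.5, 3: 0.9, 4: 0.2}), manual_k=4
        )
        assert sol.k_opt == 4 and sol.selection_mode == "manual"

    def test_block_consensus_end_to_end(self):
        labels_true = np.repeat([1, 2, 3], 6)
        c = _comembership(labels_true)
        np.fill_diagonal(c, 1.0)
        from xtaxnet.consensus_modules import ConsensusMatrix

        cons = ConsensusMatrix(C=c, patterns_used=[3], n_patterns=1)
        sol = optimal_modules(silhouette_curve(cons))
        assert sol.k_opt == 3
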