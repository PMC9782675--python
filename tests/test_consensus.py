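"""Consensus wrapper, base clusterers, diagnostics, k-selection."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from txclust import (
    CohortError,
    ConsensusConfig,
    ConsensusMatrix,
    DistanceMatrix,
    base_cluster,
    compute_diagnostics,
    run_consensus,
    select_k,
)
from txclust.consensus import KSelectionDiagnostics, _assign_from_consensus


def _dm(D):
    return DistanceMatrix(values=D, subject_ids=list(range(len(D))))


class TestBaseCluster:
    def test_k_equals_n_singletons(self):
        D = np.random.default_rng(1).uniform(0.1, 0.9, (5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = base_cluster(_dm(D / D.max()), k=5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_k_above_n_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(CohortError):
            base_cluster(_dm(D), k=4)

    @pytest.mark.parametrize("method", ["pam", "hierarchical_average"])
    def test_two_blobs_recovered(self, two_blob_distance, method):
        D, truth = two_blob_distance
        labels = base_cluster(_dm(D), k=2, method=method)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_pam_matches_exhaustive_two_partition(self):
        """PAM's 2-cluster partition attains the exhaustive minimum of the
        medoid objective on a small instance."""
        rng = np.random.default_rng(3)
        n = 9
        pts = np.concatenate([rng.normal(0, 1, (5, 2)), rng.normal(4, 1, (4, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        D /= D.max()
        labels = base_cluster(_dm(D), k=2, method="pam")

        def cost(medoids):
            return D[list(medoids)].min(axis=0).sum()

        best = min(cost(m) for m in itertools.combinations(range(n), 2))
        med_cost = min(
            cost((i, j))
            for i in np.flatnonzero(labels == 1)
            for j in np.flatnonzero(labels == 2)
        )
        # the partition induced by PAM's medoids achieves the global optimum
        achieved = min(
            cost(m)
            for m in itertools.combinations(range(n), 2)
            if adjusted_rand_score(labels, D[list(m)].argmin(axis=0)) == 1.0
        )
        assert achieved == pytest.approx(best, abs=1e-12)
        assert med_cost >= best - 1e-12

    @pytest.mark.parametrize("method", ["pam", "hierarchical_average"])
    def test_deterministic(self, two_blob_distance, method):
        D, _ = two_blob_distance
        a = base_cluster(_dm(D), k=3, method=method, seed=5)
        b = base_cluster(_dm(D), k=3, method=method, seed=5)
        assert np.array_equal(a, b)

    def test_all_clusters_nonempty(self, two_blob_distance):
        D, _ = two_blob_distance
        for k in range(2, 7):
            labels = base_cluster(_dm(D), k=k)
            assert set(labels) == set(range(1, k + 1))


class TestRunConsensus:
    def test_two_blobs_perfect_consensus(self, two_blob_distance):
        D, truth = two_blob_distance
        config = ConsensusConfig(
            k_min=2, k_max=3, n_iterations=50, subsample_fraction=0.8, seed=0
        )
        runs = run_consensus(_dm(D), config)
        m = runs[2][0].values
        within = (truth[:, None] == truth[None, :])
        iu = np.triu_indices(len(D), k=1)
        assert np.all(m[iu][within[iu]] == 1.0)
        assert np.all(m[iu][~within[iu]] == 0.0)
        assert adjusted_rand_score(truth, runs[2][1].labels) == 1.0

    def test_matrix_symmetric_unit_diagonal(self, two_blob_distance):
        D, _ = two_blob_distance
        config = ConsensusConfig(k_min=2, k_max=4, n_iterations=10, seed=1)
        runs = run_consensus(_dm(D), config)
        for k, (matrix, _) in runs.items():
            assert np.allclose(matrix.values, matrix.values.T)
            assert np.all(np.diag(matrix.values) == 1.0)
            assert matrix.values.min() >= 0 and matrix.values.max() <= 1

    def test_oracle_equivalence_full_subsample(self, two_blob_distance):
        """With subsample fraction 1 every iteration sees the same data, so
        consensus entries are exactly 0/1 and the final partition equals
        the single-shot base clustering."""
        D, _ = two_blob_distance
        config = ConsensusConfig(
            k_min=2, k_max=4, n_iterations=7, subsample_fraction=1.0, seed=3
        )
        runs = run_consensus(_dm(D), config)
        for k, (matrix, assignment) in runs.items():
            iu = np.triu_indices(matrix.n, k=1)
            assert set(np.unique(matrix.values[iu])) <= {0.0, 1.0}
            single = base_cluster(_dm(D), k=k)
            assert adjusted_rand_score(single, assignment.labels) == 1.0

    def test_default_config_matches_study_settings(self):
        config = ConsensusConfig()
        assert (config.k_min, config.k_max) == (2, 10)
        assert config.n_iterations == 100
        assert config.subsample_fraction == 0.8
        assert (config.pac_lower, config.pac_upper) == (0.1, 0.9)

    def test_seeded_determinism(self, two_blob_distance):
        D, _ = two_blob_distance
        config = ConsensusConfig(k_min=2, k_max=3, n_iterations=5, seed=11)
        a = run_consensus(_dm(D), config)
        b = run_consensus(_dm(D), config)
        for k in a:
            assert np.array_equal(a[k][0].values, b[k][0].values)
            assert np.array_equal(a[k][1].labels, b[k][1].labels)

    def test_subsample_smaller_than_k_rejected(self):
        D = np.zeros((12, 12))
        config = ConsensusConfig(k_min=2, k_max=10, subsample_fraction=0.5)
        with pytest.raises(CohortError, match="subsample"):
            run_consensus(_dm(D), config)

    def test_cluster_sizes_sum_to_n(self, two_blob_distance):
        D, _ = two_blob_distance
        config = ConsensusConfig(k_min=2, k_max=5, n_iterations=10, seed=2)
        runs = run_consensus(_dm(D), config)
        for k, (_, assignment) in runs.items():
            assert sum(assignment.sizes.values()) == len(D)
            # relabeled by descending size
            sizes = [assignment.sizes[c] for c in sorted(assignment.sizes)]
            assert sizes == sorted(sizes, reverse=True)


def _random_consensus_matrix(rng, n=10, k=2):
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return ConsensusMatrix(values=v, cosample_counts=np.full((n, n), 5), k=k)


class TestDiagnostics:
    def test_pac_and_cluster_consensus_match_bruteforce(self):
        """PAC and within-cluster consensus equal explicit pair
        enumeration on random 10x10 matrices."""
        rng = np.random.default_rng(5)
        config = ConsensusConfig(k_min=2, k_max=3)
        for _ in range(5):
            runs = {k: _random_consensus_matrix(rng, k=k) for k in (2, 3)}
            diag = compute_diagnostics(runs, config)
            for k in (2, 3):
                m = runs[k].values
                n = m.shape[0]
                pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
                pac = sum(0.1 < m[i, j] < 0.9 for i, j in pairs) / len(pairs)
                assert diag.pac[k] == pytest.approx(pac, abs=1e-12)
                labels = _assign_from_consensus(m, k)
                for c, score in diag.cluster_consensus[k].items():
                    members = [i for i in range(n) if labels[i] == c]
                    within = [
                        m[i, j]
                        for i, j in pairs
                        if labels[i] == c and labels[j] == c
                    ]
                    expected = np.mean(within) if within else 1.0
                    assert score == pytest.approx(expected, abs=1e-12)

    def test_pac_boundary_cases(self):
        config = ConsensusConfig(k_min=2, k_max=2)
        crisp = np.zeros((6, 6))
        crisp[:3, :3] = 1.0
        crisp[3:, 3:] = 1.0
        np.fill_diagonal(crisp, 1.0)
        runs = {2: ConsensusMatrix(crisp, np.full((6, 6), 5), 2)}
        diag = compute_diagnostics(runs, ConsensusConfig(k_min=2, k_max=2))
        assert diag.pac[2] == 0.0

        fuzzy = np.full((6, 6), 0.5)
        np.fill_diagonal(fuzzy, 1.0)
        runs = {2: ConsensusMatrix(fuzzy, np.full((6, 6), 5), 2)}
        diag = compute_diagnostics(runs, config)
        assert diag.pac[2] == 1.0

    def test_pac_direct_count(self):
        # 5 subjects -> 10 pairs; place exactly 3 ambiguous values
        v = np.zeros((5, 5))
        ambiguous = [(0, 1), (1, 2), (2, 3)]
        for i, j in ambiguous:
            v[i, j] = v[j, i] = 0.5
        np.fill_diagonal(v, 1.0)
        runs = {2: ConsensusMatrix(v, np.full((5, 5), 5), 2)}
        diag = compute_diagnostics(runs, ConsensusConfig(k_min=2, k_max=2))
        assert diag.pac[2] == pytest.approx(0.3)

    def test_cdf_monotone_zero_to_one(self, two_blob_distance):
        D, _ = two_blob_distance
        config = ConsensusConfig(k_min=2, k_max=4, n_iterations=20, seed=4)
        runs = run_consensus(_dm(D), config)
        diag = compute_diagnostics({k: m for k, (m, _) in runs.items()}, config)
        for k in diag.ks:
            cdf = diag.cdf[k]
            assert np.all(np.diff(cdf) >= 0)
            assert cdf[-1] == 1.0

    def test_pac_never_increases_under_sharpening(self):
        """Replacing every consensus value v by 1{v >= 0.5} removes all
        ambiguity, so PAC cannot increase."""
        rng = np.random.default_rng(9)
        config = ConsensusConfig(k_min=2, k_max=2)
        for _ in range(10):
            m = _random_consensus_matrix(rng)
            sharp_vals = (m.values >= 0.5).astype(float)
            np.fill_diagonal(sharp_vals, 1.0)
            sharp = ConsensusMatrix(sharp_vals, m.cosample_counts, 2)
            pac = compute_diagnostics({2: m}, config).pac[2]
            pac_sharp = compute_diagnostics({2: sharp}, config).pac[2]
            assert pac_sharp <= pac

    def test_delta_area_convention(self):
        rng = np.random.default_rng(13)
        config = ConsensusConfig(k_min=2, k_max=4)
        runs = {k: _random_consensus_matrix(rng, k=k) for k in (2, 3, 4)}
        diag = compute_diagnostics(runs, config)
        assert diag.delta_area[2] == pytest.approx(diag.area[2])
        assert diag.delta_area[3] == pytest.approx(
            (diag.area[3] - diag.area[2]) / diag.area[2]
        )


class TestSelectK:
    def _diag(self, mean_cons, pac, delta):
        ks = sorted(mean_cons)
        return KSelectionDiagnostics(
            ks=ks,
            cdf={k: np.linspace(0, 1, 101) for k in ks},
            area={k: 0.5 for k in ks},
            delta_area=delta,
            pac=pac,
            cluster_consensus={k: {1: mean_cons[k]} for k in ks},
            mean_cluster_consensus=mean_cons,
        )

    def test_mean_consensus_argmax(self):
        diag = self._diag(
            {2: 0.7, 3: 0.8, 4: 0.75, 5: 0.85, 6: 0.95, 7: 0.9},
            {k: 0.2 for k in range(2, 8)},
            {k: 0.1 for k in range(2, 8)},
        )
        assert select_k(diag) == 6

    def test_tie_goes_to_smallest_k(self):
        diag = self._diag(
            {3: 0.9, 4: 0.9}, {3: 0.1, 4: 0.1}, {3: 0.1, 4: 0.1}
        )
        assert select_k(diag) == 3

    def test_pac_rule_argmin(self):
        diag = self._diag(
            {2: 0.5, 3: 0.5, 4: 0.5},
            {2: 0.4, 3: 0.1, 4: 0.2},
            {k: 0.1 for k in (2, 3, 4)},
        )
        assert select_k(diag, rule="pac") == 3

    def test_composite_rank_sum(self):
        diag = self._diag(
            {2: 0.6, 3: 0.9, 4: 0.7},
            {2: 0.4, 3: 0.05, 4: 0.2},
            {2: 0.5, 3: 0.02, 4: 0.3},
        )
        assert select_k(diag, rule="composite") == 3
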