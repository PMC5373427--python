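"""The four cluster-number estimators and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrocut import (
    DataMatrix,
    GapParams,
    GapProfile,
    InsufficientMergesError,
    InputError,
    ModeParams,
    compute_linkage,
    cut_to_k,
    elbow_estimate,
    estimate_k,
    gap_estimate,
    gap_profile,
    generate_clusters,
    maxdiff_estimate,
    mode_estimate,
    within_cluster_dispersion,
    SimulationScenario,
)
from conftest import merges_from_heights


class TestElbow:
    @pytest.mark.parametrize(
        "heights,expected_k",
        [
            ([1, 2, 3, 20], 2),  # accelerations 0, 16 -> last merge wins
            ([1, 2, 3, 4], 3),   # all zero, tie broken to smallest index
            ([1, 1, 10], 2),
        ],
    )
    def test_hand_computed_examples(self, heights, expected_k):
        assert elbow_estimate(merges_from_heights(heights)).k_hat == expected_k

    def test_three_merge_input_stays_in_range(self, rng):
        for _ in range(20):
            merges = compute_linkage(DataMatrix(rng.normal(size=(4, 2))))
            assert elbow_estimate(merges).k_hat in (2, 3)

    def test_too_few_merges(self):
        with pytest.raises(InsufficientMergesError):
            elbow_estimate(merges_from_heights([1, 2]))


class TestMaxdiff:
    @pytest.mark.parametrize(
        "heights,expected_k",
        [
            ([1.0, 1.1, 1.2, 9.0], 2),  # largest jump at the last merge
            ([1.0, 9.0], 2),            # single candidate
            ([2, 2, 2, 2], 4),          # all ties -> smallest index -> k = m
        ],
    )
    def test_hand_computed_examples(self, heights, expected_k):
        assert maxdiff_estimate(merges_from_heights(heights)).k_hat == expected_k

    def test_too_few_merges(self):
        with pytest.raises(InsufficientMergesError):
            maxdiff_estimate(merges_from_heights([1.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(4, 15), st.integers(0, 2**31 - 1))
    def test_agrees_with_cut_gap_oracle(self, n, seed):
        """The chosen k maximises the height gap bounding its cut."""
        rng = np.random.default_rng(seed)
        merges = compute_linkage(DataMatrix(rng.normal(size=(n, 2))))
        d = merges.heights
        gaps = np.diff(d)
        # brute force: among all cuts between consecutive distinct heights,
        # pick the one whose bounding gap is largest
        best_gap, best_k = -1.0, None
        for i in range(1, len(d)):
            if gaps[i - 1] > best_gap:
                best_gap = gaps[i - 1]
                best_k = len(d) + 1 - i  # clusters left after merges 1..i
        assert maxdiff_estimate(merges).k_hat == best_k


class TestMode:
    def test_large_alpha_reaches_single_cluster(self):
        merges = merges_from_heights([1, 1, 1, 1, 10])
        est = mode_estimate(merges, ModeParams(alpha=3))
        assert est.k_hat == 1
        assert est.diagnostics["threshold"] > 10

    def test_zero_alpha_cuts_at_the_mode(self):
        merges = merges_from_heights([1, 1, 1, 1, 10])
        est = mode_estimate(merges, ModeParams(alpha=0))
        assert est.k_hat == 2

    def test_equal_heights_collapse_to_one_cluster(self):
        est = mode_estimate(merges_from_heights([2.0, 2.0, 2.0]),
                            ModeParams(alpha=0))
        assert est.diagnostics["sigma"] == 0
        assert est.k_hat == 1

    def test_negative_alpha_rejected(self):
        with pytest.raises(InputError):
            ModeParams(alpha=-1)


class TestWithinClusterDispersion:
    def test_two_point_cluster_is_half_distance(self):
        data = DataMatrix(np.array([[0.0], [4.0]]))
        merges = compute_linkage(data)
        w = within_cluster_dispersion(data, cut_to_k(merges, 1))
        assert w == pytest.approx(2.0)

    def test_singletons_have_zero_dispersion(self):
        data = DataMatrix(np.array([[0.0], [1.0], [5.0]]))
        merges = compute_linkage(data)
        assert within_cluster_dispersion(data, cut_to_k(merges, 3)) == 0.0

    def test_three_collinear_points(self):
        data = DataMatrix(np.array([[0.0], [1.0], [2.0]]))
        merges = compute_linkage(data)
        w = within_cluster_dispersion(data, cut_to_k(merges, 1))
        assert w == pytest.approx(4.0 / 3.0)


class TestGapProfile:
    def test_seeded_determinism(self, rng):
        data = DataMatrix(rng.normal(size=(30, 2)))
        params = GapParams(k_max=5, n_reference=10, rng_seed=42)
        a = gap_profile(data, params)
        b = gap_profile(data, params)
        np.testing.assert_array_equal(a.gap, b.gap)
        np.testing.assert_array_equal(a.s_k, b.s_k)

    def test_s_k_non_negative(self, rng):
        data = DataMatrix(rng.normal(size=(25, 2)))
        profile = gap_profile(data, GapParams(k_max=4, n_reference=5, rng_seed=0))
        assert np.all(profile.s_k >= 0)

    def test_uniform_data_has_near_zero_gap(self, rng):
        # data itself uniform on a box: Gap(k) ~ 0 within Monte-Carlo error
        data = DataMatrix(rng.uniform(0, 1, size=(80, 2)))
        profile = gap_profile(data, GapParams(k_max=4, n_reference=30, rng_seed=1))
        assert np.all(np.abs(profile.gap) <= 3 * np.maximum(profile.s_k, 1e-6) + 0.15)

    def test_k_max_must_be_below_n(self, rng):
        data = DataMatrix(rng.normal(size=(5, 2)))
        with pytest.raises(InputError):
            gap_profile(data, GapParams(k_max=5))


class TestGapEstimate:
    def _profile(self, gap, s):
        gap = np.asarray(gap, dtype=float)
        s = np.asarray(s, dtype=float)
        return GapProfile(log_wk=np.zeros_like(gap), expected_log_wk=gap,
                          gap=gap, s_k=s)

    def test_first_comparison_holds(self):
        est = gap_estimate(self._profile([5, 1, 1], [0.1, 0.1, 0.1]))
        assert est.k_hat == 1 and not est.diagnostics["no_elbow"]

    def test_rule_never_fires_returns_kmax_with_flag(self):
        est = gap_estimate(self._profile([0, 1, 2], [1e-6, 1e-6, 1e-6]))
        assert est.k_hat == 3 and est.diagnostics["no_elbow"]

    def test_stepwise_application(self):
        est = gap_estimate(self._profile([0, 0.5, 0.4], [0.01, 0.01, 0.2]))
        assert est.k_hat == 2

    def test_length_one_profile_rejected(self):
        with pytest.raises(InputError):
            gap_estimate(self._profile([1.0], [0.1]))


class TestEstimatorInvariants:
    """Structural guarantees shared by the four rules."""

    @pytest.mark.parametrize("method", ["elbow", "maxdiff"])
    def test_never_returns_single_cluster(self, method, rng):
        # neither rule can detect the one-cluster case by construction
        for _ in range(10):
            data = DataMatrix(rng.normal(size=(12, 2)))
            est = estimate_k(data, method)
            assert 2 <= est.k_hat < data.n_points

    def test_mode_and_gap_can_return_one(self, rng):
        data = DataMatrix(rng.normal(size=(40, 2)))
        assert mode_estimate(compute_linkage(data), ModeParams(alpha=10)).k_hat == 1
        est = estimate_k(data, "gap", gap_params=GapParams(k_max=5, n_reference=20),
                         rng=np.random.default_rng(0))
        assert est.k_hat == 1

    @pytest.mark.parametrize("method", ["elbow", "maxdiff", "mode"])
    def test_translation_invariance(self, method, rng):
        base = rng.normal(size=(20, 3))
        shifted = base + np.array([100.0, -40.0, 7.0])
        k1 = estimate_k(DataMatrix(base), method).k_hat
        k2 = estimate_k(DataMatrix(shifted), method).k_hat
        assert k1 == k2

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(InputError):
            estimate_k(DataMatrix(rng.normal(size=(10, 2))), "kmeans")


class TestWellSeparatedClusters:
    def test_perfect_success_at_large_separation(self):
        """With clusters 20 units apart both jump rules always find k=4."""
        scenario = SimulationScenario(k_true=4, separation=20.0)
        seeds = np.random.SeedSequence(99).spawn(50)
        for child in seeds:
            rng = np.random.default_rng(child)
            data = generate_clusters(scenario, rng=rng)
            merges = compute_linkage(data)
            assert elbow_estimate(merges).k_hat == 4
            assert maxdiff_estimate(merges).k_hat == 4
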