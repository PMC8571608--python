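"""Emigration rules, prospecting subsets, and the settlement processes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from informed_dispersal import dispersal as disp
from informed_dispersal.demography import (
    STATUS_FAILED,
    STATUS_NONE,
    STATUS_SUCCESSFUL,
)


class TestEmigrationProbability:
    @pytest.mark.parametrize(
        "beta_fail, alpha_fail, lbs, expected",
        [
            (0.5, -0.45, 1.0, 0.05),
            (0.5, -0.45, 0.0, 0.5),
            (0.2, -0.45, 1.0, 0.0),  # raw -0.25 clamped to 0
        ],
    )
    def test_failed_breeder_reaction_norm(self, beta_fail, alpha_fail, lbs, expected):
        geno = {"beta_fail": beta_fail, "alpha_fail": alpha_fail,
                "beta_succ": 0.05, "alpha_succ": 0.0}
        p = disp.emigration_probability(geno, "personal_public", STATUS_FAILED, lbs)
        assert p == pytest.approx(expected)

    def test_personal_strategy_reads_status(self):
        geno = {"e_succ": 0.05, "e_fail": 0.5}
        assert disp.emigration_probability(geno, "personal", STATUS_SUCCESSFUL) == 0.05
        assert disp.emigration_probability(geno, "personal", STATUS_FAILED) == 0.5

    def test_recruits_use_failed_breeder_rule(self):
        geno = {"e_succ": 0.05, "e_fail": 0.5,
                "beta_fail": 0.5, "alpha_fail": -0.45,
                "beta_succ": 0.05, "alpha_succ": 0.0}
        assert disp.emigration_probability(geno, "personal", STATUS_NONE) == 0.5
        assert disp.emigration_probability(
            geno, "personal_public", STATUS_NONE, 0.5
        ) == pytest.approx(0.5 - 0.45 * 0.5)

    def test_uninformed_ignores_status_and_clamps(self):
        assert disp.emigration_probability({"e": 1.3}, "uninformed", STATUS_FAILED) == 1.0
        assert disp.emigration_probability({"e": 0.5}, "uninformed", STATUS_SUCCESSFUL) == 0.5

    def test_public_strategy_requires_lbs(self):
        with pytest.raises(ValueError):
            disp.emigration_probability(
                {"beta_fail": 0.5, "alpha_fail": -0.45,
                 "beta_succ": 0.05, "alpha_succ": 0.0},
                "personal_public",
                STATUS_FAILED,
            )


class TestCandidatesAndProspecting:
    def test_excludes_only_the_current_patch(self):
        cand = disp.candidate_patches(5, 25)
        assert cand.size == 24
        assert 5 not in cand

    def test_single_patch_network_gives_empty_set(self):
        assert disp.candidate_patches(0, 1).size == 0

    def test_no_prospecting_gives_empty_set(self, rng):
        assert disp.draw_prospected_set(np.arange(9), 0, rng).size == 0

    def test_allele_exceeding_candidates_truncates(self, rng):
        got = disp.draw_prospected_set(np.arange(9), 24, rng)
        assert sorted(got) == list(range(9))

    def test_subset_is_uniform(self, rng):
        counts = np.zeros(9)
        for _ in range(3000):
            counts[disp.draw_prospected_set(np.arange(9), 3, rng)] += 1
        freq = counts / 3000
        assert np.allclose(freq, 3 / 9, atol=0.03)


class TestSettlementProbabilities:
    def test_inaccurate_proportional_to_lbs(self):
        p = disp.settlement_probabilities(np.array([0.2, 0.3, 0.5]), "inaccurate")
        np.testing.assert_allclose(p, [0.2, 0.3, 0.5])

    def test_deterministic_puts_mass_on_best(self):
        p = disp.settlement_probabilities(np.array([0.1, 0.9, 0.4]), "deterministic")
        np.testing.assert_allclose(p, [0.0, 1.0, 0.0])

    def test_deterministic_ties_split_uniformly(self):
        p = disp.settlement_probabilities(np.array([0.9, 0.9, 0.1]), "deterministic")
        np.testing.assert_allclose(p, [0.5, 0.5, 0.0])

    def test_accurate_softmax_by_hand(self):
        p = disp.settlement_probabilities(np.array([0.0, 0.1]), "accurate")
        e5 = np.exp(5.0)
        np.testing.assert_allclose(p, [1 / (1 + e5), e5 / (1 + e5)], rtol=1e-12)

    def test_inaccurate_all_zero_falls_back_to_uniform(self):
        p = disp.settlement_probabilities(np.zeros(3), "inaccurate")
        np.testing.assert_allclose(p, [1 / 3] * 3)

    def test_zero_accuracy_reduces_to_uniform(self):
        lbs = np.array([0.0, 0.2, 0.9, 0.4])
        p = disp.settlement_probabilities(lbs, "accurate", accuracy=0.0)
        np.testing.assert_allclose(p, 0.25)

    def test_empty_prospected_set_rejected(self):
        with pytest.raises(ValueError):
            disp.settlement_probabilities(np.array([]), "inaccurate")

    @settings(deadline=None, max_examples=60)
    @given(
        lbs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        process=st.sampled_from(disp.PROCESSES),
    )
    def test_always_a_probability_vector(self, lbs, process):
        p = disp.settlement_probabilities(np.array(lbs), process)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_accurate_is_increasing_in_lbs(self):
        lbs = np.array([0.1, 0.4, 0.2, 0.8])
        p = disp.settlement_probabilities(lbs, "accurate")
        assert np.all(np.diff(p[np.argsort(lbs)]) > 0)


class TestProspectingSurvival:
    def test_costless_always_survives(self, rng):
        assert disp.prospecting_survival(np.full(1000, 24), 0.0, rng).all()
        assert disp.prospecting_survival(np.zeros(1000, dtype=int), 0.01, rng).all()

    def test_death_fraction_matches_cost(self, rng):
        alive = disp.prospecting_survival(np.full(100_000, 24), 0.01, rng)
        assert abs((1 - alive.mean()) - 0.24) < 0.005

    def test_cost_above_one_rejected(self, rng):
        with pytest.raises(ValueError):
            disp.prospecting_survival(np.array([30]), 0.05, rng)


class TestSettle:
    def test_single_prospected_patch_is_random_settlement(self, rng):
        lbs = np.linspace(0, 1, 25)
        for _ in range(20):
            prospected = disp.draw_prospected_set(np.arange(1, 25), 1, rng)
            dest = disp.settle(0, np.arange(1, 25), prospected, lbs, "deterministic", rng)
            assert dest == prospected[0]

    def test_deterministic_picks_highest_lbs(self, rng):
        lbs = np.zeros(25)
        lbs[[3, 8]] = [0.2, 0.8]
        dest = disp.settle(0, np.array([3, 8]), np.array([3, 8]), lbs, "deterministic", rng)
        assert dest == 8

    def test_no_prospecting_is_uniform_over_candidates(self, rng):
        counts = np.zeros(25)
        cand = np.arange(1, 10)
        for _ in range(4000):
            counts[disp.settle(0, cand, cand[:0], np.zeros(25), "inaccurate", rng)] += 1
        np.testing.assert_allclose(counts[1:10] / 4000, 1 / 9, atol=0.03)

    def test_no_candidates_forces_stay(self, rng):
        assert disp.settle(7, np.array([]), np.array([]), np.zeros(25), "accurate", rng) == 7


class TestDisperseBatch:
    def test_never_returns_home(self, rng):
        lbs = np.where(np.arange(25) < 10, rng.random(25), np.nan)
        patch = rng.integers(0, 10, size=2000)
        n_p = rng.integers(0, 25, size=2000)
        dest, died = disp.disperse_batch(patch, n_p, lbs, "inaccurate", 0.01, rng)
        assert np.all(dest != patch)
        assert np.all((dest >= 0) & (dest < 25))

    def test_informed_settlers_avoid_empty_patches(self, rng):
        # patches without adults read LBS 0; proportional weighting never
        # sends a prospector there while any sampled patch had success
        lbs = np.array([0.5, 0.6, 0.7] + [np.nan] * 22)
        dest, _ = disp.disperse_batch(
            np.zeros(5000, dtype=int), np.full(5000, 24), lbs, "inaccurate", 0.0, rng
        )
        assert set(np.unique(dest)) <= {1, 2}

    def test_random_settlers_can_recolonize_empty_patches(self, rng):
        lbs = np.array([0.5, 0.6] + [np.nan] * 23)
        dest, _ = disp.disperse_batch(
            np.zeros(5000, dtype=int), np.zeros(5000, dtype=int), lbs,
            "deterministic", 0.0, rng,
        )
        assert (np.asarray(dest) >= 2).any()  # empty patches reachable at random

    def test_single_patch_network_forces_stay(self, rng):
        dest, died = disp.disperse_batch(
            np.array([0, 0]), np.array([5, 0]), np.array([0.4]),
            "deterministic", 0.0, rng,
        )
        np.testing.assert_array_equal(dest, [0, 0])
        assert not died.any()

    def test_batch_deterministic_agrees_with_scalar_path(self, rng):
        # single emigrant, full prospecting: the batch path must pick the
        # same patch as the scalar settlement operation
        lbs = rng.random(25)
        dest, _ = disp.disperse_batch(
            np.array([0]), np.array([24]), lbs, "deterministic", 0.0, rng
        )
        expected = disp.settle(
            0, np.arange(1, 25), np.arange(1, 25), lbs, "deterministic", rng
        )
        assert dest[0] == expected

    def test_death_fraction_in_batch(self, rng):
        _, died = disp.disperse_batch(
            np.zeros(100_000, dtype=int),
            np.full(100_000, 24),
            np.linspace(0, 1, 25),
            "accurate",
            0.01,
            rng,
        )
        assert abs(died.mean() - 0.24) < 0.005

    def test_batch_distribution_matches_settlement_probabilities(self, rng):
        # inaccurate process over a fully prospected 4-patch network:
        # settlement frequencies converge to LBS / sum(LBS)
        lbs = np.array([0.2, 0.3, 0.5, 0.0])
        n = 30_000
        dest, _ = disp.disperse_batch(
            np.full(n, 3), np.full(n, 3), lbs, "inaccurate", 0.0, rng
        )
        freq = np.bincount(dest, minlength=4)[:3] / n
        np.testing.assert_allclose(freq, [0.2, 0.3, 0.5], atol=0.01)

    def test_more_prospecting_finds_better_patches(self, rng):
        # deterministic process: E[max LBS of a uniform k-subset] is
        # non-decreasing in k; exact values by enumeration over subsets
        lbs_vals = np.array([0.05, 0.2, 0.35, 0.5, 0.65, 0.8])  # candidates 0..5
        lbs = np.concatenate([lbs_vals, [0.0]])
        sim_means, exact_means = [], []
        for k in range(1, 7):
            n = 20_000
            dest, _ = disp.disperse_batch(
                np.full(n, 6), np.full(n, k), lbs, "deterministic", 0.0, rng
            )
            sim_means.append(lbs[dest].mean())
            subsets = list(itertools.combinations(range(6), k))
            exact_means.append(np.mean([lbs_vals[list(s)].max() for s in subsets]))
        np.testing.assert_allclose(sim_means, exact_means, atol=0.02)
        assert np.all(np.diff(exact_means) > 0)
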