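"""Jensen-Shannon dataset distance: histograms, divergences, ranking."""

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon as scipy_jensenshannon

from paox import (SpectraDataset, build_histograms, correlate_djs_error, djs_bar,
                  default_grid, generate_dataset, js_divergence, kl_divergence,
                  rank_training_sets, subset_wavelengths, variant, zscore)
from paox.distribution import MAX_JS_DISTANCE, N_BINS


def _zds(values_by_column, n, seed=0):
    """Synthetic z-score-like dataset with a given per-column generator."""
    rng = np.random.default_rng(seed)
    amps = values_by_column(rng, n)
    grid = default_grid()
    return SpectraDataset(amps, np.ones((n, 41), bool), np.full(n, 0.5),
                          np.zeros(n), grid, "Z", {"seed": seed})


class TestBuildHistograms:
    def test_point_mass_in_central_bin(self):
        ds = _zds(lambda rng, n: np.zeros((n, 41)), 50)
        hs = build_histograms(ds)
        assert np.all(hs.densities[:, 50] == 1.0)
        assert np.all(hs.densities.sum(axis=1) == pytest.approx(1.0))

    def test_right_edge_value_counted_in_last_bin(self):
        amps = np.zeros((10, 41))
        amps[:, 0] = 3.0  # exactly at the +3 sigma boundary
        ds = _zds(lambda rng, n: amps, 10)
        hs = build_histograms(ds)
        assert hs.densities[0, -1] == 1.0

    def test_out_of_range_mass_excluded(self):
        ds = _zds(lambda rng, n: rng.standard_normal((n, 41)), 100_000, seed=1)
        hs = build_histograms(ds)
        in_range_fraction = hs.n_samples / 100_000
        np.testing.assert_allclose(in_range_fraction, 0.9973, atol=0.001)

    def test_masked_entries_never_counted(self, base_small):
        sub = zscore(subset_wavelengths(base_small, [700, 800, 900]))
        hs = build_histograms(sub)
        assert hs.present.sum() == 3
        assert not hs.present[1]

    def test_empty_dataset_rejected(self, base_small):
        with pytest.raises(ValueError):
            build_histograms(base_small.take(np.array([], dtype=int)))


class TestKlDivergence:
    def test_identity_is_zero(self):
        p = np.full(N_BINS, 1.0 / N_BINS)
        assert kl_divergence(p, p) == 0.0

    def test_two_bin_hand_value(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2.0))

    def test_disjoint_support_is_infinite(self):
        assert kl_divergence([1.0, 0.0], [0.0, 1.0]) == np.inf

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0, 0.0], [1.0, 0.0, 0.0])


class TestJsDivergence:
    def test_identity_and_maximum(self):
        assert js_divergence([1.0, 0.0], [1.0, 0.0]) == 0.0
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.log(2.0))
        assert js_divergence([1.0, 0.0], [0.0, 1.0], distance=True) == pytest.approx(
            MAX_JS_DISTANCE, abs=1e-9)

    def test_two_bin_direct_summation(self):
        p = np.array([0.75, 0.25])
        q = np.array([0.25, 0.75])
        m = 0.5 * (p + q)
        expected = 0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
        assert js_divergence(p, q) == pytest.approx(expected, abs=1e-15)

    def test_brute_force_oracle_on_random_densities(self, rng):
        for _ in range(20):
            p = rng.random(N_BINS)
            q = rng.random(N_BINS)
            p[rng.random(N_BINS) < 0.3] = 0.0  # exercise empty bins
            q[rng.random(N_BINS) < 0.3] = 0.0
            p /= p.sum()
            q /= q.sum()
            m = 0.5 * (p + q)
            direct = 0.0
            for x in range(N_BINS):  # independent elementwise summation
                if p[x] > 0:
                    direct += 0.5 * p[x] * np.log(p[x] / m[x])
                if q[x] > 0:
                    direct += 0.5 * q[x] * np.log(q[x] / m[x])
            assert js_divergence(p, q) == pytest.approx(direct, abs=1e-12)

    def test_agrees_with_library_distance(self, rng):
        p = rng.random(N_BINS)
        q = rng.random(N_BINS)
        p /= p.sum()
        q /= q.sum()
        assert js_divergence(p, q, distance=True) == pytest.approx(
            float(scipy_jensenshannon(p, q)), abs=1e-9)

    def test_symmetry(self, rng):
        p = rng.random(N_BINS); p /= p.sum()
        q = rng.random(N_BINS); q /= q.sum()
        assert js_divergence(p, q) == pytest.approx(js_divergence(q, p), abs=1e-15)


class TestDjsBar:
    def test_self_distance_zero_with_full_sampling(self, base_small_z):
        res = djs_bar(base_small_z, base_small_z, n_subsample=None)
        assert res.djs_bar == 0.0
        assert res.n_lambda_used == 41

    def test_symmetric_without_subsampling(self, base_small_z):
        other = zscore(generate_dataset(variant("SKIN", n_spectra=1500, seed=3)))
        a = djs_bar(base_small_z, other, n_subsample=None).djs_bar
        b = djs_bar(other, base_small_z, n_subsample=None).djs_bar
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounded(self, base_small_z):
        other = zscore(generate_dataset(variant("WATER_4cm", n_spectra=1500, seed=3)))
        d = djs_bar(base_small_z, other, n_subsample=None).djs_bar
        assert 0.0 <= d <= MAX_JS_DISTANCE

    def test_distribution_shift_exceeds_split_half_null(self):
        base = zscore(generate_dataset(variant("BASE", n_spectra=10_000, seed=71)))
        w4 = zscore(generate_dataset(variant("WATER_4cm", n_spectra=10_000, seed=72)))
        half_a = base.take(np.arange(0, 5000))
        half_b = base.take(np.arange(5000, 10_000))
        null = djs_bar(half_a, half_b, n_subsample=2000, repeats=8, seed=0)
        shift = djs_bar(base, w4, n_subsample=2000, repeats=8, seed=0)
        spread = max(float(np.std(null.repeats)), 1e-6)
        assert shift.djs_bar > null.djs_bar + 3 * spread

    def test_subsampling_noise_shrinks_with_n(self):
        a = zscore(generate_dataset(variant("BASE", n_spectra=20_000, seed=81)))
        b = zscore(generate_dataset(variant("SKIN", n_spectra=20_000, seed=82)))
        sd_small = np.std(djs_bar(a, b, n_subsample=1000, repeats=8, seed=1).repeats)
        sd_large = np.std(djs_bar(a, b, n_subsample=10_000, repeats=8, seed=1).repeats)
        assert sd_large < sd_small

    def test_wavelength_intersection_contract(self, base_small):
        # wavelengths present in only one dataset never enter the aggregate:
        # masking them out of the other dataset (z-scoring held fixed)
        # leaves the result bit-identical
        narrow = zscore(subset_wavelengths(base_small, [700, 800, 900]))
        other = zscore(generate_dataset(variant("SKIN", n_spectra=2000, seed=3)))
        other_pruned = other.take(slice(None))
        other_pruned.mask = other.mask.copy()
        keep = np.zeros(41, bool)
        keep[[0, 20, 30, 40]] = True  # intersection {700, 800, 900} plus one extra
        other_pruned.mask &= keep
        other_pruned.amplitudes = np.where(other_pruned.mask, other.amplitudes, 0.0)
        d_full = djs_bar(narrow, other, n_subsample=None)
        d_pruned = djs_bar(narrow, other_pruned, n_subsample=None)
        assert d_full.djs_bar == d_pruned.djs_bar
        assert d_full.n_lambda_used == d_pruned.n_lambda_used == 3

    def test_empty_intersection_rejected(self, base_small):
        a = zscore(subset_wavelengths(base_small, [700, 705]))
        b = zscore(subset_wavelengths(base_small, [895, 900]))
        with pytest.raises(ValueError):
            djs_bar(a, b, n_subsample=None)

    def test_deterministic_given_seed(self, base_small_z):
        other = zscore(generate_dataset(variant("SKIN", n_spectra=2000, seed=3)))
        r1 = djs_bar(base_small_z, other, n_subsample=500, repeats=3, seed=9)
        r2 = djs_bar(base_small_z, other, n_subsample=500, repeats=3, seed=9)
        np.testing.assert_array_equal(r1.repeats, r2.repeats)


class TestRanking:
    def test_identity_candidate_ranks_first(self, base_small_z):
        cands = [zscore(generate_dataset(variant(v, n_spectra=2000, seed=4)))
                 for v in ("SKIN", "WATER_4cm")]
        ranking = rank_training_sets(base_small_z, cands + [base_small_z],
                                     n_subsample=None)
        assert ranking[0][0] == "BASE"
        assert ranking[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_stable_tie_break_preserves_input_order(self, base_small_z):
        twin_a = base_small_z.take(slice(None))
        twin_a.variant = "first"
        twin_b = base_small_z.take(slice(None))
        twin_b.variant = "second"
        ranking = rank_training_sets(base_small_z, [twin_a, twin_b], n_subsample=None)
        assert [r[0] for r in ranking] == ["first", "second"]


class TestPearson:
    def test_exact_values(self):
        assert correlate_djs_error([0, 1, 2], [1, 3, 5]) == pytest.approx(1.0)
        assert correlate_djs_error([0, 1, 2], [5, 3, 1]) == pytest.approx(-1.0)
        assert correlate_djs_error([0, 1, 2], [1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate_djs_error([1, 1, 1], [1, 2, 3])
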