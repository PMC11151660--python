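"""Surrogate tissue generator: fluence model, dataset generation, variants."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from paox import (TissueVariantConfig, analytic_config, builtin_variants,
                  generate_dataset, linear_unmixing_dataset, variant)
from paox.synthgen import fluence_at_depth, SpectraDataset
from paox.chromophores import default_table


def _noattenuation_config(**kw):
    base = dict(name="X", bg_so2_dist=(0.7, 0.7), bg_bvf=0.0, bg_water_fraction=0.0,
                skin_thickness=0.0, water_layer=0.0, illumination_spread=0.0,
                quantize_to_grid=False, noise_sigma=0.0, n_spectra=10, seed=0)
    base.update(kw)
    return TissueVariantConfig(**base)


class TestFluence:
    def test_no_attenuation_is_unity(self, table):
        cfg = _noattenuation_config()
        assert fluence_at_depth(0.0, 0, cfg, table, 0.7, 0.0) == pytest.approx(1.0)
        # with zero layers and zero spread, depth still decays through background blood
        cfg2 = _noattenuation_config(bg_bvf=0.0, bg_water_fraction=0.0)
        assert fluence_at_depth(5.0, 20, cfg2, table, 0.7, 0.0) == pytest.approx(1.0)

    def test_water_layer_monotonicity(self, table):
        c1 = _noattenuation_config(water_layer=10.0)
        c2 = _noattenuation_config(water_layer=20.0)
        for lam in range(0, 41, 10):
            assert (fluence_at_depth(1.0, lam, c2, table, 0.7, 0.0)
                    < fluence_at_depth(1.0, lam, c1, table, 0.7, 0.0))

    def test_matches_closed_form_hand_evaluation(self, table):
        # water-dominated background, depth 2 mm: Phi = exp(-mu_eff * z)
        cfg = _noattenuation_config(bg_water_fraction=1.0, bg_bvf=0.0)
        for nm, lam in ((700, 0), (900, 40)):
            mua = table.mu_a_water[lam]
            mu_eff = np.sqrt(3.0 * mua * (mua + table.mu_s_prime_bg[lam]))
            expected = np.exp(-mu_eff * 2.0)
            assert fluence_at_depth(2.0, lam, cfg, table, 0.7, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_decreasing_in_depth(self, table):
        cfg = variant("BASE")
        vals = [fluence_at_depth(z, 20, cfg, table, 0.7, 0.0) for z in (0.5, 2.0, 5.0, 9.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestGenerateDataset:
    def test_determinism_bit_identical(self):
        cfg = variant("BASE", n_spectra=500, seed=21)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(d1.amplitudes, d2.amplitudes)
        assert np.array_equal(d1.so2, d2.so2)

    def test_shapes_and_label_range(self, base_small):
        assert base_small.amplitudes.shape == (2000, 41)
        assert base_small.mask.all()
        assert np.all((base_small.so2 >= 0) & (base_small.so2 <= 1))
        assert np.all(np.isfinite(base_small.amplitudes))

    def test_label_uniformity_ks(self):
        ds = generate_dataset(variant("BASE", n_spectra=10_000, seed=33))
        assert stats.kstest(ds.so2, "uniform").pvalue > 0.01

    def test_analytic_limit_lu_recovers_exactly(self, analytic_ds):
        est = linear_unmixing_dataset(analytic_ds)
        assert np.max(np.abs(est - analytic_ds.so2)) < 1e-6

    def test_spectral_coloring_increases_with_depth(self, table):
        # fixed sO2 vessel: the blue/red amplitude ratio falls monotonically
        # with depth wherever the background attenuation drops toward the
        # red, e.g. a deoxygenated blood-dominated background (in the BASE
        # background the water term makes mu_eff rise with wavelength, so
        # the ratio moves the other way there)
        cfg = _noattenuation_config(bg_bvf=0.05, bg_so2_dist=(0.0, 0.0))
        r = []
        for z in (1.0, 3.0, 6.0, 9.0):
            phi_blue = fluence_at_depth(z, 0, cfg, table, 0.0, 0.0)
            phi_red = fluence_at_depth(z, 40, cfg, table, 0.0, 0.0)
            r.append(phi_blue / phi_red)
        assert all(a > b for a, b in zip(r, r[1:]))

    def test_skin_variant_changes_spectral_slope(self):
        n = 5000
        base = generate_dataset(variant("BASE", n_spectra=n, seed=44))
        skin = generate_dataset(variant("SKIN", n_spectra=n, seed=44))
        slope = lambda d: (d.amplitudes[:, -1] - d.amplitudes[:, 0]) / np.abs(d.amplitudes).sum(1)
        assert stats.mannwhitneyu(slope(base), slope(skin)).pvalue < 0.01

    def test_counter_based_streams_are_prefix_stable(self):
        small = generate_dataset(variant("BASE", n_spectra=100, seed=9))
        large = generate_dataset(variant("BASE", n_spectra=400, seed=9))
        np.testing.assert_array_equal(small.so2, large.so2[:100])
        np.testing.assert_array_equal(small.amplitudes, large.amplitudes[:100])


class TestConfigValidation:
    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            TissueVariantConfig(bg_so2_dist=(0.8, 0.2))
        with pytest.raises(ValueError):
            TissueVariantConfig(melanosome_fraction_dist=(0.0, 1.5))
        with pytest.raises(ValueError):
            TissueVariantConfig(grid_spacing=0.0)
        with pytest.raises(ValueError):
            TissueVariantConfig(skin_thickness=1.0, vessel_depth_dist=(0.5, 9.0))

    def test_rejects_nonpositive_count(self):
        cfg = variant("BASE")
        with pytest.raises(ValueError):
            generate_dataset(dataclasses.replace(cfg, n_spectra=0))

    def test_yaml_round_trip(self):
        cfg = variant("SKIN", n_spectra=77, seed=5)
        again = TissueVariantConfig.from_yaml(cfg.to_yaml())
        assert again == cfg


class TestBuiltinVariants:
    def test_at_least_twelve_named(self):
        names = {c.name for c in builtin_variants()}
        required = {"BASE", "BG_0-100", "BG_60-80", "BG_H2O", "HET_0-100", "HET_60-80",
                    "SKIN", "SMALL", "RES_0.6", "RES_1.2", "ILLUM_5mm", "ILLUM_POINT",
                    "WATER_2cm", "WATER_4cm"}
        assert required <= names
        assert len(names) >= 12

    def test_base_background_parameters(self):
        base = variant("BASE")
        assert base.bg_bvf == 0.01
        assert base.bg_so2_dist == (0.70, 0.70)

    def test_deltas_from_base(self):
        # every variant differs from BASE in exactly its defining fields
        expected_deltas = {
            "BG_0-100": {"bg_so2_dist"},
            "BG_60-80": {"bg_so2_dist"},
            "BG_H2O": {"bg_bvf", "bg_water_fraction"},
            "HET_0-100": {"bg_so2_dist", "bg_heterogeneous"},
            "HET_60-80": {"bg_so2_dist", "bg_heterogeneous"},
            "RES_0.15": {"grid_spacing"},
            "RES_0.15_SMALL": {"grid_spacing", "vessel_radius_dist"},
            "RES_0.6": {"grid_spacing"},
            "RES_1.2": {"grid_spacing"},
            "SKIN": {"skin_thickness", "melanosome_fraction_dist"},
            "ILLUM_5mm": {"illumination_spread", "illumination_z0"},
            "ILLUM_POINT": {"illumination_spread"},
            "SMALL": {"vessel_radius_dist"},
            "WATER_2cm": {"water_layer"},
            "WATER_4cm": {"water_layer"},
        }
        base = variant("BASE")
        for cfg in builtin_variants():
            if cfg.name == "BASE":
                continue
            diff = {f.name for f in dataclasses.fields(cfg)
                    if getattr(cfg, f.name) != getattr(base, f.name)} - {"name"}
            assert diff == expected_deltas[cfg.name], cfg.name

    def test_small_and_water_values(self):
        assert variant("SMALL").vessel_radius_dist == (0.075, 0.5)
        assert variant("WATER_4cm").water_layer == 40.0
        assert variant("WATER_2cm").water_layer == 20.0


class TestSpectraDataset:
    def test_take_and_concatenate(self, base_small):
        sub = base_small.take(np.arange(10))
        assert len(sub) == 10
        combo = SpectraDataset.concatenate([sub, sub])
        assert len(combo) == 20 and combo.variant == "ALL"

    def test_row_access(self, base_small):
        spec = base_small[3]
        assert spec.variant == "BASE"
        assert 0.0 <= spec.so2_true <= 1.0
        np.testing.assert_array_equal(spec.amplitudes, base_small.amplitudes[3])

    def test_requires_provenance(self, base_small, grid):
        with pytest.raises(ValueError):
            SpectraDataset(base_small.amplitudes, base_small.mask, base_small.so2,
                           base_small.depth, grid, "X", {})
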