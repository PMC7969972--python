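import numpy as np
import pandas as pd
import pytest

from drsix.chromophores import PARAM_NAMES, TissueParams
from drsix.synth import (CHANNEL_CENTERS, Spectrum, add_noise, downsample,
                         forward_spectrum, forward_spectra, generate_dataset,
                         make_responsivity, parameter_grid, wavelength_grid)


class TestResponsivity:
    def test_rows_sum_to_one(self):
        resp = make_responsivity()
        assert np.allclose(resp.weights.sum(axis=1), 1.0, atol=1e-12)

    def test_row_peak_at_nearest_grid_point(self):
        resp = make_responsivity()
        for i, c in enumerate(resp.centers):
            nearest = np.argmin(np.abs(resp.grid - c))
            assert resp.weights[i].argmax() == nearest

    def test_neighbouring_channels_overlap(self):
        # 550 and 570 nm rows share grid points with non-trivial weight
        resp = make_responsivity()
        both = (resp.weights[2] > 1e-6) & (resp.weights[3] > 1e-6)
        assert both.sum() > 5

    def test_invalid_fwhm_raises(self):
        with pytest.raises(ValueError):
            make_responsivity(fwhm=0.0)

    def test_center_outside_grid_raises(self):
        with pytest.raises(ValueError):
            make_responsivity(centers=[400.0], fwhm=40.0)


class TestDownsample:
    def test_flat_spectrum_maps_to_constant(self):
        resp = make_responsivity()
        spec = Spectrum(resp.grid, np.full(resp.grid.size, 0.37))
        out = downsample(spec, resp)
        assert out.values.shape == (6,)
        assert np.allclose(out.values, 0.37, rtol=1e-12)
        assert np.array_equal(out.wavelengths, resp.centers)

    def test_commutes_with_scaling(self):
        resp = make_responsivity()
        rng = np.random.default_rng(1)
        vals = rng.random(resp.grid.size)
        a = downsample(Spectrum(resp.grid, 3.0 * vals), resp).values
        b = 3.0 * downsample(Spectrum(resp.grid, vals), resp).values
        assert np.allclose(a, b, rtol=1e-12)

    def test_linear_spectrum_interior_channel_effective_wavelength(self):
        resp = make_responsivity()
        spec = Spectrum(resp.grid, 0.001 * resp.grid)  # linear in wavelength
        out = downsample(spec, resp)
        step = resp.grid[1] - resp.grid[0]
        for k in range(1, 5):  # interior channels only (edges truncate)
            lam_eff = out.values[k] / 0.001
            assert abs(lam_eff - resp.centers[k]) < step

    def test_grid_mismatch_raises(self):
        resp = make_responsivity()
        with pytest.raises(ValueError):
            downsample(Spectrum(np.linspace(400, 700, 50), np.ones(50)), resp)


class TestForwardModel:
    def test_spectrum_shape_and_codomain(self, toy_lut, chromo):
        spec = forward_spectrum(TissueParams.midrange(), toy_lut, chromo)
        assert spec.values.shape == (100,)
        assert np.all((spec.values >= 0) & (spec.values <= 1))

    def test_forward_matches_manual_lut_queries(self, toy_lut, chromo):
        from drsix.chromophores import mua_at, musp_at

        p = TissueParams.midrange()
        grid = wavelength_grid()
        spec = forward_spectrum(p, toy_lut, chromo)
        k = 37
        expected = toy_lut.query(mua_at(p, grid[k], chromo),
                                 musp_at(p, grid[k]))
        assert spec.values[k] == pytest.approx(expected, rel=1e-12)

    def test_more_blood_never_brightens_hemoglobin_band(self, mc_lut, chromo):
        lo = forward_spectrum(TissueParams(0.01, 20, 1.9, 1.0, 0.8),
                              mc_lut, chromo)
        hi = forward_spectrum(TissueParams(0.05, 20, 1.9, 1.0, 0.8),
                              mc_lut, chromo)
        k550 = np.argmin(np.abs(lo.wavelengths - 550))
        assert hi.values[k550] <= lo.values[k550]

    def test_out_of_lut_coverage_raises_with_rows(self, toy_lut, chromo):
        df = pd.DataFrame([dict(bvf=0.9, mus630=20, b=1.9, mel=0, so2=0.8)])
        with pytest.raises(ValueError, match="outside the LUT grid"):
            forward_spectra(df, toy_lut, chromo)


class TestNoise:
    def test_zero_sigma_is_identity(self):
        spec = Spectrum(wavelength_grid(), np.linspace(0.1, 0.9, 100))
        out = add_noise(spec, 0.0, seed=1)
        assert np.array_equal(out.values, spec.values)

    def test_negative_sigma_raises(self):
        spec = Spectrum(wavelength_grid(), np.ones(100))
        with pytest.raises(ValueError):
            add_noise(spec, -0.1)

    def test_same_seed_identical(self):
        spec = Spectrum(wavelength_grid(), np.linspace(0.1, 0.9, 100))
        a = add_noise(spec, 0.05, seed=9).values
        b = add_noise(spec, 0.05, seed=9).values
        assert np.array_equal(a, b)

    def test_replicate_mean_recovers_original(self):
        """Law of large numbers: the mean of many noisy replicates matches the
        clean spectrum within 4 standard errors per wavelength."""
        vals = np.linspace(0.2, 0.8, 100)
        spec = Spectrum(wavelength_grid(), vals)
        n = 10_000
        reps = np.stack([add_noise(spec, 0.05, seed=s).values
                         for s in range(50)])
        # vectorised equivalent of many replicates: one big draw
        rng = np.random.default_rng(123)
        noisy = vals * (1 + 0.05 * rng.standard_normal((n, 100)))
        noisy = np.maximum(noisy, 0)
        se = noisy.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(noisy.mean(axis=0) - vals) < 4 * se)
        assert reps.shape == (50, 100)  # seeded replicates all valid

    def test_never_negative(self):
        spec = Spectrum(wavelength_grid(), np.full(100, 1e-4))
        out = add_noise(spec, 5.0, seed=2)  # huge noise to force clipping
        assert np.all(out.values >= 0)


class TestGenerateDataset:
    def test_reduced_design_counts(self, toy_lut, chromo):
        ds = generate_dataset(toy_lut, chromo, levels=5, seed=3)
        assert len(ds.params) == 5 ** 5 == 3125
        assert ds.spectra100.shape == (3125, 100)
        assert ds.spectra6.shape == (3125, 6)

    def test_split_sizes_scale_and_are_disjoint(self, toy_lut, chromo):
        ds = generate_dataset(toy_lut, chromo, levels=5, seed=3)
        tr, te = ds.split_index("train"), ds.split_index("test")
        assert len(tr) == round(10_000 * 3125 / 100_000)
        assert len(te) == round(30_000 * 3125 / 100_000)
        assert len(np.intersect1d(tr, te)) == 0

    def test_levels_exactly_on_linear_grid(self, toy_lut, chromo):
        ds = generate_dataset(toy_lut, chromo, levels=5, seed=3)
        for name, levels in ds.levels.items():
            lo, hi = levels[0], levels[-1]
            assert len(levels) == 5
            assert np.array_equal(levels, np.linspace(lo, hi, 5))

    def test_bit_reproducible(self, toy_lut, chromo):
        a = generate_dataset(toy_lut, chromo, levels=4, seed=11)
        b = generate_dataset(toy_lut, chromo, levels=4, seed=11)
        assert np.array_equal(a.spectra6, b.spectra6)
        assert np.array_equal(a.spectra100, b.spectra100)
        assert a.params.equals(b.params)

    def test_persistence_roundtrip(self, toy_lut, chromo, tmp_path):
        ds = generate_dataset(toy_lut, chromo, levels=3, seed=2)
        prefix = str(tmp_path / "ds")
        ds.to_files(prefix)
        back = ds.from_files(prefix)
        assert np.allclose(back.spectra6, ds.spectra6, rtol=1e-9)
        assert list(back.params["split"]) == list(ds.params["split"])


def test_parameter_grid_is_full_factorial():
    grid = parameter_grid(levels=3)
    assert len(grid) == 3 ** 5
    assert not grid.duplicated().any()
    assert list(grid.columns) == list(PARAM_NAMES)
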