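import numpy as np
import pytest

from drsix.mc import (LUT, MCConfig, ProbeGeometry, build_lut, default_axes,
                      simulate_reflectance)

from _analog import analog_node


class TestSimulateReflectance:
    def test_absorption_dominated_limit_is_zero(self):
        val, se = simulate_reflectance(
            1e4, 10.0, cfg=MCConfig(n_photons=2000, seed=1, kill_depth=1.0))
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_pure_absorber_returns_zero(self):
        assert simulate_reflectance(5.0, 0.0) == (0.0, 0.0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            simulate_reflectance(-1.0, 10.0)
        with pytest.raises(ValueError):
            MCConfig(n_photons=0)
        with pytest.raises(ValueError):
            MCConfig(g=1.5)

    def test_seeded_determinism(self):
        cfg = MCConfig(n_photons=5000, seed=7, kill_depth=1.0)
        a = simulate_reflectance(2.56, 20.48, cfg=cfg)
        b = simulate_reflectance(2.56, 20.48, cfg=cfg)
        assert a == b

    def test_two_seeds_agree_within_three_combined_se(self):
        cfg1 = MCConfig(n_photons=100_000, seed=11, kill_depth=1.0)
        cfg2 = MCConfig(n_photons=100_000, seed=97, kill_depth=1.0)
        v1, s1 = simulate_reflectance(2.56, 10.24, cfg=cfg1)
        v2, s2 = simulate_reflectance(2.56, 10.24, cfg=cfg2)
        assert abs(v1 - v2) <= 3 * np.hypot(s1, s2)


class TestEnergyConservation:
    def test_total_reflectance_unity_without_absorption(self):
        """mua = 0, matched boundary, whole-surface detector, no aperture
        cut: every packet must eventually exit, so detected weight -> 1.
        A reflecting deep boundary bounds the walk without destroying weight,
        making the check sharp."""
        geom = ProbeGeometry(source_radius=0.02, detector_radius=1e6,
                             center_separation=0.0,
                             numerical_aperture=1.4 - 1e-7,
                             n_tissue=1.4, n_above=1.4)
        cfg = MCConfig(n_photons=20_000, g=0.0, seed=3, kill_depth=2.0,
                       deep_boundary="mirror", max_steps=10_000_000)
        val, se, lost = simulate_reflectance(0.0, 10.0, geom, cfg,
                                             full_output=True)
        assert abs(val - 1.0) <= 3 * max(se, 1e-9)
        assert lost == 0.0


class TestAnalogEquivalence:
    @pytest.mark.parametrize("mua,musp", [(7.68, 25.6)])
    def test_weighted_estimator_matches_naive_analog(self, mua, musp):
        geom = ProbeGeometry()
        cfg = MCConfig(n_photons=150_000, seed=5,
                       kill_depth=min(2.0, max(0.2, 10.0 / musp)))
        v, s = simulate_reflectance(mua, musp, geom, cfg)
        va, sa = analog_node(mua, musp, geom, n_photons=300_000, seed=17)
        assert abs(v - va) <= 3 * np.hypot(s, sa)


class TestBuildLut:
    def test_shape_and_metadata(self, mc_lut):
        assert mc_lut.reflectance.shape == (40, 40)
        assert mc_lut.meta["mode"] == "scaled"
        assert np.all(mc_lut.reflectance >= 0)
        assert np.all(mc_lut.reflectance <= 1)

    def test_monotone_nonincreasing_in_mua(self, mc_lut):
        """Scaled columns are exactly non-increasing along ascending mua."""
        R = mc_lut.reflectance
        assert np.all(np.diff(R, axis=0) <= 1e-15)

    def test_zero_absorption_row_dominates(self, mc_lut):
        R = mc_lut.reflectance
        assert np.all(R[0] >= R[1:] - 3 * mc_lut.se[1:])

    def test_musp_zero_column_is_zero(self, mc_lut):
        assert np.all(mc_lut.reflectance[:, 0] == 0.0)

    def test_rebuild_same_seed_bitwise_identical(self):
        cfg = MCConfig(n_photons=2000, seed=42)
        ax = default_axes()[:8]
        a = build_lut(ax, ax, cfg=cfg)
        b = build_lut(ax, ax, cfg=cfg)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.se, b.se)

    def test_per_node_mode_agrees_with_scaled(self):
        ax = np.array([0.0, 2.56, 7.68])
        ay = np.array([10.24, 25.6])
        cfg = MCConfig(n_photons=30_000, seed=9)
        scaled = build_lut(ax, ay, cfg=cfg, mode="scaled")
        node = build_lut(ax, ay, cfg=cfg, mode="per_node")
        diff = np.abs(scaled.reflectance - node.reflectance)
        tol = 3 * np.hypot(scaled.se, node.se)
        assert np.all(diff <= tol + 1e-12)

    def test_invalid_axes_raise(self):
        with pytest.raises(ValueError):
            build_lut(np.array([1.0, 0.5]), default_axes(),
                      cfg=MCConfig(n_photons=10))
        with pytest.raises(ValueError):
            build_lut(np.array([-1.0, 2.0]), default_axes(),
                      cfg=MCConfig(n_photons=10))


class TestLutQueries:
    def test_exact_at_nodes(self, toy_lut):
        for i in (0, 7, 39):
            for j in (0, 11, 39):
                assert toy_lut.query(toy_lut.mua_axis[i],
                                     toy_lut.musp_axis[j]) == pytest.approx(
                    toy_lut.reflectance[i, j], rel=1e-14)

    def test_cell_center_is_corner_mean(self, toy_lut):
        i, j = 5, 9
        ax, ay = toy_lut.mua_axis, toy_lut.musp_axis
        center = toy_lut.query(0.5 * (ax[i] + ax[i + 1]),
                               0.5 * (ay[j] + ay[j + 1]))
        corners = toy_lut.reflectance[i:i + 2, j:j + 2].mean()
        assert center == pytest.approx(corners, rel=1e-12)

    def test_out_of_grid_raises(self, toy_lut):
        with pytest.raises(ValueError):
            toy_lut.query(toy_lut.mua_axis[-1] + 1.0, 10.0)
        with pytest.raises(ValueError):
            toy_lut.query(10.0, -0.5)

    def test_vectorised_query_matches_scalar(self, toy_lut):
        rng = np.random.default_rng(0)
        mua = rng.uniform(0, 99, 50)
        musp = rng.uniform(0, 99, 50)
        vec = toy_lut.query(mua, musp)
        scal = [toy_lut.query(a, s) for a, s in zip(mua, musp)]
        assert np.allclose(vec, scal, rtol=1e-14)

    def test_json_roundtrip_and_tsv_export(self, toy_lut, tmp_path):
        p = tmp_path / "lut.json"
        toy_lut.to_json(p)
        back = LUT.from_json(p)
        assert np.array_equal(back.reflectance, toy_lut.reflectance)
        assert np.array_equal(back.mua_axis, toy_lut.mua_axis)
        toy_lut.to_table(tmp_path / "lut.tsv")
        assert (tmp_path / "lut.tsv").stat().st_size > 0


def test_geometry_validation():
    with pytest.raises(ValueError):
        ProbeGeometry(source_radius=0.0)
    with pytest.raises(ValueError):
        ProbeGeometry(numerical_aperture=2.0)
    with pytest.raises(ValueError):
        ProbeGeometry(n_tissue=0.5)
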