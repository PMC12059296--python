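"""Unit-level Monte Carlo tests: sampling, transport, scoring, determinism.

These run at small history counts; the statistically demanding checks
(narrow-beam oracle at full scale, buildup trends, ceiling scatter) live in
the acceptance suite.
"""

import numpy as np
import pytest

from nmshield import mc, xs
from nmshield.errors import ConfigError, DomainError, GeometryError


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="module")
def air_world():
    return mc.make_infinite_world("lead", 0.0)


@pytest.fixture(scope="module")
def lead_world():
    return mc.make_infinite_world("lead", 2.0)


class TestCrossSections:
    def test_klein_nishina_thomson_limit(self):
        assert xs.klein_nishina_total(0.1) == pytest.approx(6.652e-25, rel=5e-3)

    def test_klein_nishina_decreasing(self):
        grid = np.geomspace(15, 700, 50)
        assert np.all(np.diff(xs.klein_nishina_total(grid)) < 0)

    def test_element_grid_covers_range_and_is_positive(self):
        tab = xs.element_table("Pb")
        assert tab.energies_kev[0] <= 15.0 and tab.energies_kev[-1] >= 700.0
        assert np.all(np.diff(tab.energies_kev) > 0)
        assert np.all(tab.pe > 0) and np.all(tab.incoherent > 0)

    def test_material_mu_sanity_anchors(self):
        """Order-of-magnitude anchors against well-known attenuation values
        (the synthetic photoelectric model is approximate by design)."""
        assert xs.material_xs("lead").mu_total(140.0) / 11.35 == pytest.approx(2.4, rel=0.25)
        assert xs.material_xs("muscle").mu_total(140.0) / 1.05 == pytest.approx(0.15, rel=0.25)
        assert xs.material_xs("air").mu_total(140.0) == pytest.approx(1.6e-4, rel=0.3)

    def test_mixture_rule_scales_with_density(self):
        lw = xs.material_xs("lw_concrete").mu_total(300.0)
        nw = xs.material_xs("nw_concrete").mu_total(300.0)
        assert nw / lw == pytest.approx(2.3 / 1.6, rel=1e-9)  # same composition


class TestEmissionSampling:
    def test_tc99m_always_140_kev(self, rng):
        e, d = mc.sample_emission("Tc-99m", rng, 1000)
        assert np.all(e == 140.0)

    def test_direction_faces_barrier(self, rng):
        _, d = mc.sample_emission("Lu-177", rng, 5000)
        assert np.all(d[:, 2] > 0)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)

    def test_lu177_line_mixture(self, rng):
        e, _ = mc.sample_emission("Lu-177", rng, 40000)
        frac_208 = np.mean(e == 208.0)
        p = 0.11 / 0.17
        assert abs(frac_208 - p) < 3 * np.sqrt(p * (1 - p) / 40000)


class TestTransport:
    def test_vacuum_like_crossing_deposits_nothing(self, air_world):
        # Sideways through air only: interaction probability ~1.6e-2; with a
        # seeded generator the photon crosses cleanly.
        deps = mc.transport_photon(140.0, (0, 0, 0), (1, 0, 0), air_world,
                                   np.random.default_rng(0))
        assert deps == []

    def test_photoelectric_dominated_medium_single_full_deposit(self, lead_world):
        """16 keV photons in lead are ~99.9% photoelectric: one deposition
        carrying the full energy."""
        rng = np.random.default_rng(3)
        full = 0
        for _ in range(200):
            deps = mc.transport_photon(16.0, (0, 0, 99.2), (0, 0, 1), lead_world, rng)
            assert sum(e for _, e in deps) <= 16.0 + 1e-9
            if len(deps) == 1 and deps[0][1] == pytest.approx(16.0):
                full += 1
        assert full >= 196

    def test_energy_below_cutoff_rejected(self, air_world, rng):
        with pytest.raises(DomainError):
            mc.transport_photon(10.0, (0, 0, 0), (0, 0, 1), air_world, rng)

    def test_origin_outside_world_is_geometry_error(self, air_world, rng):
        with pytest.raises(GeometryError):
            mc.transport_photon(140.0, (0, 0, 400.0), (0, 0, 1), air_world, rng)

    def test_energy_conserved_per_history(self, lead_world):
        rng = np.random.default_rng(11)
        e0, d0 = mc.sample_emission("I-131", rng, 300)
        for e, d in zip(e0, d0):
            deps = mc.transport_photon(float(e), (0, 0, 0), tuple(d), lead_world, rng)
            assert sum(de for _, de in deps) <= e + 1e-9

    def test_first_interaction_depth_is_exponential(self, rng):
        """Mean free path through lead matches 1/mu from the embedded tables."""
        world = mc.make_infinite_world("lead", 400.0)  # 40 cm slab: nothing escapes
        mu = float(xs.material_xs("lead").mu_total(140.0))
        n = 3000
        depths = []
        for _ in range(n):
            deps = mc.transport_photon(140.0, (0, 0, 85.0), (0, 0, 1), world, rng)
            # first deposition marks the first interaction past the origin
            depths.append(deps[0][0][2] - 85.0)
        mean = np.mean(depths)
        assert mean == pytest.approx(1 / mu, rel=4 / np.sqrt(n))


class TestScoring:
    def test_empty_depositions_score_zero(self, air_world):
        assert mc.score_roi_dose([], air_world, 100) == 0.0

    def test_uniform_unit_energy_closed_form(self, air_world):
        """1 keV in every ROI voxel center -> mean dose = 1 keV / voxel mass."""
        sc = air_world.scorer
        deps = []
        mask = sc._lat_mask()
        o = sc._lat_origin
        for plane in range(2):
            # centers of the second and third 5 mm depth planes
            z = sc.face + (1.5 + plane) * sc.depth_voxel
            for iu, iv in zip(*np.nonzero(mask)):
                x = o[0] + (iu + 0.5) * sc.lat_voxel
                y = o[1] + (iv + 0.5) * sc.lat_voxel
                deps.append(((x, y, z), 1.0))
        expected = 1.0 * mc.KEV_TO_J / (sc.voxel_mass_g * 1e-3)
        assert mc.score_roi_dose(deps, air_world, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_depositions_outside_roi_ignored(self, air_world):
        deps = [((50.0, 50.0, 180.9), 100.0), ((0.0, 0.0, 50.0), 100.0)]
        assert mc.score_roi_dose(deps, air_world, 1.0) == 0.0


class TestSimulation:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            mc.SimConfig("Tc-99m", "lead", 1.0, n_histories=0, seed=1)
        with pytest.raises(ConfigError):
            mc.SimConfig("Tc-99m", "lead", 1.0, n_histories=10, seed=1,
                         geometry_variant="ceiling-floor", ceiling_height_m=2.5)
        with pytest.raises(ConfigError):
            mc.SimConfig("Tc-99m", "lead", 1.0, n_histories=10, seed=1,
                         ceiling_height_m=3.05)
        with pytest.raises(ConfigError):
            mc.SimConfig("Tc-99m", "lead", 1.0, n_histories=10, seed=1,
                         geometry_variant="spherical")

    def test_seeded_determinism(self):
        cfg = mc.SimConfig("Tc-99m", "lead", 1.0, n_histories=40000, seed=123)
        assert mc.simulate_transmission(cfg) == mc.simulate_transmission(cfg)

    def test_narrow_beam_matches_analytic_at_small_scale(self):
        cfg = mc.SimConfig("Tc-99m", "lead", 0.5, n_histories=60000, seed=5,
                           narrow_beam=True)
        res = mc.simulate_transmission(cfg)
        ana = mc.narrow_beam_transmission("Tc-99m", "lead", 0.5)
        assert abs(res.transmission - ana) <= 3 * res.relative_sd * res.transmission
        assert res.buildup is None

    def test_buildup_factor_interface(self):
        cfg = mc.SimConfig("Tc-99m", "lead", 0.5, n_histories=60000, seed=6,
                           narrow_beam=True)
        narrow = mc.simulate_transmission(cfg)
        with pytest.raises(DomainError):
            mc.buildup_factor(narrow, 2.4, 0.5)

    def test_run_curve_empty(self):
        curve = mc.run_curve("Lu-177", "lead", [], 1000, seed=1)
        assert len(curve) == 0

    def test_run_curve_feeds_fitting(self):
        curve = mc.run_curve("Tc-99m", "lead", [0.2, 0.5], 400_000, seed=9)
        assert len(curve) == 2
        assert all(0 < t < 2 for t in curve.transmission)
        assert curve.sd is not None
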