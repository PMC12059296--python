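"""Workload/dose/occupancy barrier-solver chain."""

import numpy as np
import pytest

from nmshield import archer, data, dose
from nmshield.errors import DomainError, UnknownNuclideError


def make_scenario(workload_mci_h=4000.0, distance=240.0, limit=20.0, occ=1.0,
                  nuclide="Lu-177", material="lead"):
    return dose.ShieldingScenario(
        workload=dose.Workload(nuclide=nuclide, activity_time_product=workload_mci_h),
        distance_cm=distance,
        goal=dose.DesignGoal(weekly_dose_limit=limit, occupancy_factor=occ),
        material=material,
    )


class TestUnshieldedDose:
    def test_treatment_room_example(self):
        w = dose.Workload("Lu-177", 4000.0)
        assert dose.unshielded_weekly_dose(w, 240.0) == pytest.approx(120.3, abs=0.05)

    def test_matches_direct_arithmetic(self):
        # Independent arithmetic: W * Gamma * f[Gy/R] / d^2, in uGy.
        expected = 18000.0 * 0.181 * 9.57e-3 / 73.2**2 * 1e6
        w = dose.Workload("Lu-177", 18000.0)
        assert dose.unshielded_weekly_dose(w, 73.2) == pytest.approx(expected, rel=1e-12)

    def test_zero_workload_gives_zero(self):
        assert dose.unshielded_weekly_dose(dose.Workload("Tc-99m", 0.0), 100.0) == 0.0

    def test_inverse_square_exact(self):
        w = dose.Workload("I-131", 1234.0)
        d1 = dose.unshielded_weekly_dose(w, 100.0)
        d2 = dose.unshielded_weekly_dose(w, 200.0)
        assert d2 == d1 / 4.0

    def test_bad_distance(self):
        with pytest.raises(DomainError):
            dose.unshielded_weekly_dose(dose.Workload("F-18", 1.0), 0.0)


class TestWorkload:
    def test_decay_off_is_plain_product(self):
        w = dose.decay_corrected_workload(200.0, 4.0, 5.0, "Lu-177", apply_decay=False)
        assert w.activity_time_product == 4000.0
        assert not w.decay_corrected

    def test_decay_on_session_average(self):
        w = dose.decay_corrected_workload(200.0, 4.0, 5.0, "Lu-177", apply_decay=True)
        lam = np.log(2) / (6.65 * 24)
        expected = 4000.0 * (1 - np.exp(-lam * 4)) / (lam * 4)
        assert w.activity_time_product == pytest.approx(expected, rel=1e-12)
        assert abs(w.activity_time_product - 3965) <= 1.0

    def test_decay_factor_tends_to_one(self):
        w = dose.decay_corrected_workload(100.0, 1e-9, 1.0, "Tc-99m", apply_decay=True)
        assert w.activity_time_product == pytest.approx(100.0 * 1e-9, rel=1e-6)

    def test_unknown_nuclide(self):
        with pytest.raises(UnknownNuclideError):
            dose.decay_corrected_workload(1.0, 1.0, 1.0, "Ra-226")

    def test_gbq_conversion_is_exact(self):
        assert dose.activity_mci(activity_GBq=7.4) == pytest.approx(200.0, rel=1e-12)
        with pytest.raises(DomainError):
            dose.activity_mci(200.0, 7.4)


class TestRequiredTransmission:
    def test_public_limit_example(self):
        assert dose.required_transmission(120.3, dose.DesignGoal(20.0)) == pytest.approx(
            0.166, abs=5e-4
        )

    def test_extreme_scenario(self):
        t = dose.required_transmission(5818.9, dose.DesignGoal(20.0))
        assert float(f"{t:.2g}") == 0.0034

    def test_caps_at_one(self):
        assert dose.required_transmission(10.0, dose.DesignGoal(20.0)) == 1.0

    def test_occupancy_scales_transmission(self):
        full = dose.required_transmission(1000.0, dose.DesignGoal(20.0, 1.0))
        fifth = dose.required_transmission(1000.0, dose.DesignGoal(20.0, 0.2))
        assert fifth == pytest.approx(5 * full)


class TestSolveBarrier:
    def test_treatment_room_end_to_end(self):
        sol = dose.solve_barrier(make_scenario())
        assert float(f"{sol.required_thickness:.3g}") == 1.48
        assert sol.material == "lead"
        assert not sol.warnings

    def test_extreme_scenario_warns_about_scatter(self):
        sol = dose.solve_barrier(make_scenario(workload_mci_h=18000.0, distance=73.2))
        assert float(f"{sol.required_transmission:.2g}") == 0.0034
        assert any("scatter" in w.lower() for w in sol.warnings)

    def test_no_shielding_needed(self):
        sol = dose.solve_barrier(make_scenario(limit=1000.0))
        assert sol.required_transmission == 1.0
        assert sol.required_thickness == 0.0

    def test_occupancy_monotonicity(self):
        thicknesses = [
            dose.solve_barrier(make_scenario(occ=o)).required_thickness
            for o in (1.0, 0.5, 0.2, 0.05)
        ]
        assert all(a > b for a, b in zip(thicknesses, thicknesses[1:]))

    def test_pure_function(self):
        s = make_scenario()
        assert dose.solve_barrier(s) == dose.solve_barrier(s)


class TestCompositeTransmission:
    def test_empty_stack_transmits_everything(self):
        assert dose.composite_transmission([], "Tc-99m") == 1.0

    def test_single_layer_matches_transmission(self):
        p = data.get_archer_params("Tc-99m", "lead")
        assert dose.composite_transmission([("lead", 1.3)], "Tc-99m") == pytest.approx(
            archer.transmission(p, 1.3), rel=1e-12
        )

    def test_product_rule_is_an_approximation(self):
        """Stacking two HVLs of gypsum is not the same as one QVL: the
        product rule (0.25) overestimates the true two-HVL transmission."""
        p = data.get_archer_params("Tc-99m", "gypsum")
        hvl = archer.required_thickness(p, 0.5)
        prod = dose.composite_transmission([("gypsum", hvl), ("gypsum", hvl)], "Tc-99m")
        exact = archer.transmission(p, 2 * hvl)
        assert prod == pytest.approx(0.25, rel=1e-9)
        assert prod > exact  # beta < 0: early slope is shallower than asymptotic
        # The non-additivity is a few tens of percent for gypsum, which is
        # exactly why composite stacks carry an approximation caveat.
        assert 0.1 < (prod - exact) / prod < 0.35
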