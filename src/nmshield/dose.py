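"""Shielding-design chain: workload -> dose rate -> required transmission
-> required barrier thickness.

The weekly unshielded tissue dose at a point of concern a distance d (cm)
from a point source with weekly workload W (mCi*h/week) is::

    D [Gy/week] = W * Gamma * f / d^2

with Gamma the exposure-rate constant at 1 cm (R*cm^2/(mCi*h)) and f the
exposure-to-dose conversion expressed in Gy/R.  Dividing the design goal P
(uGy/week), de-rated by the occupancy factor O of the protected area, by D
gives the required barrier transmission T = P/(O*D), capped at 1; the
closed-form inverse Archer model then converts T into a thickness of the
chosen barrier material.

The engine reports dose in uGy/week as a deep-dose-equivalent surrogate
(uGy and uSv are treated as equal for these photon emitters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import archer, data
from .errors import DomainError

__all__ = [
    "MBQ_PER_MCI",
    "SCATTER_TRANSMISSION_LIMIT",
    "Workload",
    "Geometry",
    "DesignGoal",
    "ShieldingScenario",
    "BarrierSolution",
    "unshielded_weekly_dose",
    "decay_corrected_workload",
    "required_transmission",
    "solve_barrier",
    "composite_transmission",
]

#: Exact activity-unit conversion: 1 mCi = 37 MBq.
MBQ_PER_MCI = 37.0

#: Below this transmission, scatter over the barrier off ceilings and floors
#: dominates the dose and thickening the primary barrier stops helping.
SCATTER_TRANSMISSION_LIMIT = 0.01

SCATTER_WARNING = (
    "Required transmission is below 0.01: scatter from ceilings and floors "
    "severely limits the ability to shield below 1% transmission; the "
    "computed primary-barrier thickness alone is unlikely to achieve the "
    "design goal (consider barriers extending to the deck above)."
)

COMPOSITE_WARNING = (
    "Composite-barrier transmission is the product of single-material Archer "
    "transmissions; this ignores spectral hardening between layers and is an "
    "approximation."
)


@dataclass(frozen=True)
class Workload:
    """Weekly activity-time product at a fixed location."""

    nuclide: str
    activity_time_product: float  # mCi*h per week
    description: str = ""
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if self.activity_time_product < 0:
            raise DomainError("Workload must be non-negative")


@dataclass(frozen=True)
class Geometry:
    """Straight-line source-to-point-of-concern geometry (cm)."""

    source_to_barrier: float
    barrier_to_poc: float
    wall_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.source_to_barrier <= 0 or self.barrier_to_poc <= 0:
            raise DomainError("Distances must be positive")
        if self.wall_thickness < 0:
            raise DomainError("Wall thickness must be non-negative")

    @property
    def total_distance(self) -> float:
        return self.source_to_barrier + self.wall_thickness + self.barrier_to_poc


@dataclass(frozen=True)
class DesignGoal:
    """Weekly dose limit (uGy/week) and occupancy of the protected area."""

    weekly_dose_limit: float
    occupancy_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.weekly_dose_limit <= 0:
            raise DomainError("Dose limit must be positive")
        if not 0 < self.occupancy_factor <= 1:
            raise DomainError("Occupancy factor must be in (0, 1]")


@dataclass(frozen=True)
class ShieldingScenario:
    """Complete input to the barrier solver."""

    workload: Workload
    distance_cm: float
    goal: DesignGoal
    material: str

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise DomainError("Distance must be positive")


@dataclass(frozen=True)
class BarrierSolution:
    unshielded_weekly_dose: float  # uGy/week
    required_transmission: float
    material: str
    required_thickness: float  # mm
    decay_correction_applied: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)


def activity_mci(activity_mCi: float | None = None, activity_GBq: float | None = None) -> float:
    """Resolve an activity given in mCi or GBq to mCi (37 MBq/mCi exactly)."""
    if (activity_mCi is None) == (activity_GBq is None):
        raise DomainError("Specify exactly one of activity_mCi or activity_GBq")
    if activity_GBq is not None:
        return activity_GBq * 1000.0 / MBQ_PER_MCI
    return float(activity_mCi)


def unshielded_weekly_dose(workload: Workload, distance_cm: float) -> float:
    """Weekly tissue dose (uGy/week) at ``distance_cm`` with no barrier.

    Inverse-square in distance, linear in workload.
    """
    if distance_cm <= 0:
        raise DomainError("Distance must be positive")
    nuc = data.get_nuclide(workload.nuclide)
    f_gy_per_r = nuc.f_factor / 100.0  # cGy/R -> Gy/R
    dose_gy = (
        workload.activity_time_product
        * nuc.gamma_constant
        * f_gy_per_r
        / distance_cm**2
    )
    return dose_gy * 1e6


def decay_corrected_workload(
    activity_mCi: float,
    hours_per_session: float,
    sessions_per_week: float,
    nuclide: str,
    apply_decay: bool = False,
) -> Workload:
    """Weekly workload from per-session activity, duration and frequency.

    With ``apply_decay=False`` the workload is the plain product
    A * t * sessions.  With ``apply_decay=True`` each session is multiplied
    by the session-averaged decay factor (1 - e^(-lambda t))/(lambda t),
    which tends to 1 as t -> 0 and is strictly below 1 for t > 0.
    """
    if activity_mCi < 0 or hours_per_session < 0 or sessions_per_week < 0:
        raise DomainError("Workload inputs must be non-negative")
    nuc = data.get_nuclide(nuclide)
    w = activity_mCi * hours_per_session * sessions_per_week
    factor = 1.0
    if apply_decay and hours_per_session > 0:
        lam = math.log(2.0) / nuc.half_life_hours
        lt = lam * hours_per_session
        factor = -math.expm1(-lt) / lt
    return Workload(
        nuclide=nuc.name,
        activity_time_product=w * factor,
        description=(
            f"{sessions_per_week:g}/week x {activity_mCi:g} mCi x "
            f"{hours_per_session:g} h"
            + (", decay-corrected" if apply_decay else ", ignoring decay")
        ),
        decay_corrected=apply_decay,
    )


def required_transmission(unshielded_dose: float, goal: DesignGoal) -> float:
    """Barrier transmission needed to meet the design goal, capped at 1.

    T = P / (O * D) with P the weekly limit, O the occupancy factor and D
    the unshielded weekly dose.
    """
    if unshielded_dose <= 0:
        raise DomainError("Unshielded dose must be positive")
    return min(1.0, goal.weekly_dose_limit / (goal.occupancy_factor * unshielded_dose))


def solve_barrier(scenario: ShieldingScenario) -> BarrierSolution:
    """End-to-end barrier solution for one scenario.

    Pure function of its input: computes the unshielded weekly dose, the
    required transmission under the dose limit and occupancy, and the
    required single-material barrier thickness via the inverse Archer model.
    The thickness is 0 when no shielding is needed (T >= 1); a warning is
    attached when the required transmission falls below the 1% scatter limit.
    """
    dose = unshielded_weekly_dose(scenario.workload, scenario.distance_cm)
    t_req = required_transmission(dose, scenario.goal)
    warnings: list[str] = []
    if t_req < SCATTER_TRANSMISSION_LIMIT:
        warnings.append(SCATTER_WARNING)
    if t_req >= 1.0:
        thickness = 0.0
        material = data.get_material(scenario.material).name
    else:
        params = data.get_archer_params(scenario.workload.nuclide, scenario.material)
        material = params.material
        thickness = archer.required_thickness(params, t_req)
    return BarrierSolution(
        unshielded_weekly_dose=dose,
        required_transmission=t_req,
        material=material,
        required_thickness=thickness,
        decay_correction_applied=scenario.workload.decay_corrected,
        warnings=tuple(warnings),
    )


def composite_transmission(
    layers: list[tuple[str, float]], nuclide: str
) -> float:
    """Product-rule transmission of a stack of (material, thickness_mm) layers.

    Approximation: each layer is evaluated with its own single-material
    Archer parameters and the results are multiplied, which ignores the
    spectral hardening of the beam between layers.  An empty stack
    transmits 1 and a single layer reduces to :func:`archer.transmission`.
    """
    t = 1.0
    for material, thickness_mm in layers:
        params = data.get_archer_params(nuclide, material)
        t *= archer.transmission(params, thickness_mm)
    return t
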