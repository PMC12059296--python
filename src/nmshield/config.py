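"""Scenario configuration files (YAML/JSON) for the barrier solver.

A scenario file names the nuclide, the weekly workload (either a direct
activity-time product or activity x hours x sessions, with optional decay
correction), the geometry (a straight-line distance or its components),
the weekly dose limit, the occupancy (a number or a tabulated area key),
and the barrier material::

    nuclide: Lu-177
    workload:
      activity_mCi: 200        # or activity_GBq
      hours: 4
      sessions_per_week: 5
      apply_decay: false
    source_to_barrier_cm: 198
    wall_thickness_cm: 11.4
    barrier_to_poc_cm: 30
    limit_uGy_per_week: 20
    occupancy: office          # or a number in (0, 1]
    material: lead
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import data, dose
from .errors import ConfigError


class WorkloadConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    activity_mCi: float | None = None
    activity_GBq: float | None = None
    hours: float | None = None
    sessions_per_week: float | None = None
    apply_decay: bool = False
    workload_mCi_h: float | None = None  # direct activity-time product

    @model_validator(mode="after")
    def _check(self) -> "WorkloadConfig":
        direct = self.workload_mCi_h is not None
        composed = self.hours is not None and (
            self.activity_mCi is not None or self.activity_GBq is not None
        )
        if direct == composed:
            raise ValueError(
                "Give either workload_mCi_h or activity (mCi or GBq) + hours "
                "(+ sessions_per_week)"
            )
        return self


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nuclide: str
    workload: WorkloadConfig
    material: str
    limit_uGy_per_week: float
    occupancy: float | str = 1.0
    distance_cm: float | None = None
    source_to_barrier_cm: float | None = None
    barrier_to_poc_cm: float | None = None
    wall_thickness_cm: float = 0.0

    @model_validator(mode="after")
    def _check_distance(self) -> "ScenarioConfig":
        direct = self.distance_cm is not None
        composed = (
            self.source_to_barrier_cm is not None
            and self.barrier_to_poc_cm is not None
        )
        if direct == composed:
            raise ValueError(
                "Give either distance_cm or source_to_barrier_cm + "
                "barrier_to_poc_cm (+ wall_thickness_cm)"
            )
        return self

    def total_distance_cm(self) -> float:
        if self.distance_cm is not None:
            return self.distance_cm
        return dose.Geometry(
            source_to_barrier=self.source_to_barrier_cm,
            barrier_to_poc=self.barrier_to_poc_cm,
            wall_thickness=self.wall_thickness_cm,
        ).total_distance

    def occupancy_factor(self) -> float:
        if isinstance(self.occupancy, str):
            return data.get_occupancy(self.occupancy)
        return float(self.occupancy)

    def to_scenario(self) -> dose.ShieldingScenario:
        w = self.workload
        if w.workload_mCi_h is not None:
            workload = dose.Workload(
                nuclide=data.get_nuclide(self.nuclide).name,
                activity_time_product=w.workload_mCi_h,
                description="direct activity-time product",
            )
        else:
            workload = dose.decay_corrected_workload(
                activity_mCi=dose.activity_mci(w.activity_mCi, w.activity_GBq),
                hours_per_session=w.hours,
                sessions_per_week=w.sessions_per_week if w.sessions_per_week is not None else 1.0,
                nuclide=self.nuclide,
                apply_decay=w.apply_decay,
            )
        return dose.ShieldingScenario(
            workload=workload,
            distance_cm=self.total_distance_cm(),
            goal=dose.DesignGoal(
                weekly_dose_limit=self.limit_uGy_per_week,
                occupancy_factor=self.occupancy_factor(),
            ),
            material=self.material,
        )


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Parse a YAML or JSON scenario file (YAML is a JSON superset here)."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"Cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    try:
        return ScenarioConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"Invalid scenario in {path}: {exc}") from exc
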