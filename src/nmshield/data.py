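"""Authoritative in-package data tables and lookups.

Every other module obtains physical constants exclusively through this
module: radionuclide properties (half-life, exposure-rate constant,
f-factor, dominant photon lines), barrier material definitions (density and
elemental mass fractions), fitted Archer transmission parameters per
nuclide/material pair, and recommended occupancy factors.

The tables are shipped as versioned JSON/CSV resources under
``nmshield/data/`` and loaded once per process.  All returned records are
frozen dataclasses; mutating package data is not supported.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

from .errors import (
    MissingArcherPairError,
    UnknownAreaError,
    UnknownMaterialError,
    UnknownNuclideError,
)

_HOURS_PER_UNIT = {"h": 1.0, "min": 1.0 / 60.0, "d": 24.0}

#: Nuclide/material pairs deliberately absent from the parameter table:
#: gypsum in practical thicknesses offers negligible attenuation for these
#: emitters and was excluded as a significant barrier material for them.
EXCLUDED_PAIRS = {("F-18", "gypsum"), ("I-131", "gypsum")}


@dataclass(frozen=True)
class Nuclide:
    """Physical constants of one radionuclide.

    Attributes
    ----------
    gamma_constant : float
        Exposure-rate constant at 1 cm, R*cm^2/(mCi*h), so that the exposure
        rate at distance d cm from A mCi is ``A * gamma_constant / d**2`` R/h.
    f_factor : float
        Exposure-to-tissue-dose conversion, cGy/R.
    photon_lines : tuple of (energy_keV, yield_per_decay)
        Dominant gamma/annihilation lines above 15 keV and 100 ppm yield.
    """

    name: str
    half_life: float
    half_life_unit: str
    decay_mode: str
    gamma_constant: float
    f_factor: float
    photon_lines: tuple[tuple[float, float], ...]
    ss_hvl_lead_mm: float | None = None
    ss_tvl_lead_mm: float | None = None

    @property
    def half_life_hours(self) -> float:
        return self.half_life * _HOURS_PER_UNIT[self.half_life_unit]

    @property
    def photons_per_decay(self) -> float:
        """Mean number of modeled photons emitted per decay."""
        return sum(y for _, y in self.photon_lines)


@dataclass(frozen=True)
class Material:
    """A shielding or target material: density and elemental mass fractions."""

    name: str
    display: str
    density: float  # g/cm^3
    composition: Mapping[str, float] = field(default_factory=dict)
    tabulated: bool = True  # False for additions beyond the source tables (lead)

    @property
    def composition_sum(self) -> float:
        return sum(self.composition.values())


@dataclass(frozen=True)
class ArcherParams:
    """The (alpha, beta, gamma) triple of the three-parameter Archer
    transmission model for one nuclide/material pair.

    alpha and beta are in 1/mm (thicknesses in millimetres); gamma is
    dimensionless.  ``source_tag`` distinguishes the fits shipped with this
    package ("this report") from the TG-108 comparison rows.
    """

    nuclide: str
    material: str
    alpha: float
    beta: float
    gamma_exp: float
    source_tag: str = "this report"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.gamma_exp <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma_exp}")


@dataclass(frozen=True)
class OccupancyEntry:
    area_description: str
    occupancy_factor: float
    keywords: tuple[str, ...] = ()


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "", name.lower())


def _data_text(filename: str) -> str:
    return resources.files("nmshield").joinpath("data").joinpath(filename).read_text()


@lru_cache(maxsize=None)
def _nuclide_index() -> dict[str, Nuclide]:
    raw = json.loads(_data_text("nuclides.json"))["nuclides"]
    index: dict[str, Nuclide] = {}
    for name, rec in raw.items():
        nuc = Nuclide(
            name=name,
            half_life=rec["half_life"],
            half_life_unit=rec["half_life_unit"],
            decay_mode=rec["decay_mode"],
            gamma_constant=rec["gamma_constant"],
            f_factor=rec["f_factor"],
            photon_lines=tuple((e, y) for e, y in rec["photon_lines"]),
            ss_hvl_lead_mm=rec.get("ss_hvl_lead_mm"),
            ss_tvl_lead_mm=rec.get("ss_tvl_lead_mm"),
        )
        index[_norm(name)] = nuc
        for alias in rec.get("aliases", []):
            index[_norm(alias)] = nuc
    return index


@lru_cache(maxsize=None)
def _material_index() -> dict[str, Material]:
    raw = json.loads(_data_text("materials.json"))["materials"]
    index: dict[str, Material] = {}
    for key, rec in raw.items():
        mat = Material(
            name=key,
            display=rec["display"],
            density=rec["density"],
            composition=dict(rec["composition"]),
            tabulated=rec["tabulated"],
        )
        index[_norm(key)] = mat
        index[_norm(rec["display"])] = mat
        for alias in rec.get("aliases", []):
            index[_norm(alias)] = mat
    return index


@lru_cache(maxsize=None)
def _archer_rows() -> tuple[ArcherParams, ...]:
    reader = csv.DictReader(_data_text("archer_params.csv").splitlines())
    rows = tuple(
        ArcherParams(
            nuclide=r["nuclide"],
            material=r["material"],
            alpha=float(r["alpha"]),
            beta=float(r["beta"]),
            gamma_exp=float(r["gamma"]),
            source_tag=r["source"],
        )
        for r in reader
    )
    return rows


@lru_cache(maxsize=None)
def _occupancy_entries() -> tuple[OccupancyEntry, ...]:
    raw = json.loads(_data_text("occupancy.json"))["entries"]
    return tuple(
        OccupancyEntry(
            area_description=e["area"],
            occupancy_factor=e["factor"],
            keywords=tuple(e["keywords"]),
        )
        for e in raw
    )


def list_nuclides() -> list[str]:
    """Canonical names of the shipped nuclides."""
    seen: dict[str, None] = {}
    for nuc in _nuclide_index().values():
        seen.setdefault(nuc.name)
    return list(seen)


def get_nuclide(name: str) -> Nuclide:
    """Look up a radionuclide by name (case- and punctuation-insensitive).

    Accepts common alias spellings such as ``"Lu177"``, ``"177Lu"`` or
    ``"lu-177"``.
    """
    try:
        return _nuclide_index()[_norm(name)]
    except KeyError:
        raise UnknownNuclideError(
            f"Unknown nuclide {name!r}; supported nuclides: {', '.join(list_nuclides())}"
        ) from None


def list_materials() -> list[str]:
    seen: dict[str, None] = {}
    for mat in _material_index().values():
        seen.setdefault(mat.name)
    return list(seen)


def get_material(name: str) -> Material:
    """Look up a material definition (density + elemental mass fractions)."""
    try:
        return _material_index()[_norm(name)]
    except KeyError:
        raise UnknownMaterialError(
            f"Unknown material {name!r}; known materials: {', '.join(list_materials())}"
        ) from None


def _canonical_material_key(name: str) -> str:
    # Archer rows may reference "iron" (a comparison-only barrier) which has
    # no entry in the material composition table.
    if _norm(name) == "iron":
        return "iron"
    return get_material(name).name


def list_archer_pairs(source: str = "this report") -> list[tuple[str, str]]:
    """(nuclide, material) pairs available from the given parameter source."""
    return [
        (r.nuclide, r.material) for r in _archer_rows() if r.source_tag == source
    ]


def get_archer_params(
    nuclide: str, material: str, source: str = "this report"
) -> ArcherParams:
    """Fitted Archer parameters for a nuclide/material pair.

    The TG-108 comparison rows are returned only when requested explicitly
    via ``source="TG-108"``; they are never used by the barrier solver.
    """
    nuc = get_nuclide(nuclide).name
    mat = _canonical_material_key(material)
    for row in _archer_rows():
        if row.nuclide == nuc and row.material == mat and row.source_tag == source:
            return row
    if (nuc, mat) in EXCLUDED_PAIRS:
        raise MissingArcherPairError(
            f"{nuc} through gypsum is not parameterized: gypsum in practical "
            "thicknesses offers negligible attenuation for this emitter and "
            "was excluded as a significant barrier material."
        )
    pairs = ", ".join(f"{n}/{m}" for n, m in list_archer_pairs(source))
    raise MissingArcherPairError(
        f"No Archer parameters for {nuc}/{mat} (source {source!r}). "
        f"Available pairs: {pairs}"
    )


def occupancy_table() -> tuple[OccupancyEntry, ...]:
    return _occupancy_entries()


def get_occupancy(area_key: str) -> float:
    """Occupancy factor for an area, by keyword match over area descriptions.

    The longest keyword contained in (or containing) the query wins, so
    "corridor door" resolves to 1/8 while "corridor" resolves to 1/5.
    """
    query = " ".join(area_key.lower().split())
    best: tuple[int, float] | None = None
    for entry in _occupancy_entries():
        for kw in entry.keywords:
            if kw in query:
                cand = (len(kw), entry.occupancy_factor)
                if best is None or cand[0] > best[0]:
                    best = cand
    if best is None:
        areas = "; ".join(e.area_description for e in _occupancy_entries())
        raise UnknownAreaError(
            f"No occupancy entry matches {area_key!r}. Tabulated areas: {areas}"
        )
    return best[1]
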