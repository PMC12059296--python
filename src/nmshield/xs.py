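"""Synthetic photon cross-section library for the Monte Carlo module.

Two interaction channels are modeled over 15-700 keV, the range spanned by
the shipped photon lines:

* **Incoherent (Compton) scattering** — the exact Klein-Nishina total cross
  section per electron in the free-electron approximation, scaled by Z/A
  electrons per gram.  This is the dominant channel for all the shipped
  materials above ~100 keV and is accurate there to a few percent (binding
  effects are neglected).
* **Photoelectric absorption** — a *synthetic* parametric model: a power law
  in atomic number and energy,

      sigma_pe(Z, E) = sigma_ref * (Z/82)^4.1 * (200 keV / E)^s(Z),
      s(Z) = 3.2 - 0.7 * Z/82,

  calibrated so that lead and low-Z elements reproduce representative
  photoelectric mass attenuation values near 100-200 keV, with a K-edge
  step (Moseley-law edge energy, jump ratio 8) for elements whose K edge
  lies inside the grid.  This is an approximation constructed for this
  package, not a transcription of an evaluated data library; it supports
  the qualitative broad-beam behavior the simulator is used for (buildup,
  scatter trends, internal narrow-beam consistency), not reference
  dosimetry.

Coherent (Rayleigh) scattering is omitted: at these energies and for these
materials it contributes little to energy transport and nothing to energy
deposition.  Total attenuation therefore runs a few percent low relative to
evaluated libraries.

Per-element grids are tabulated on a logarithmic energy mesh and the
transport code interpolates log-log, mirroring how evaluated libraries are
consumed; material coefficients combine elements by the mass-fraction
mixture rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .data import Material, get_material
from .errors import DomainError

__all__ = [
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
    "ELEMENTS",
    "CrossSectionTable",
    "klein_nishina_total",
    "photoelectric_sigma",
    "element_table",
    "MaterialXS",
    "material_xs",
]

ENERGY_MIN_KEV = 15.0
ENERGY_MAX_KEV = 700.0

ELECTRON_REST_KEV = 510.998950
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

#: Element -> (Z, atomic mass g/mol) for every element appearing in the
#: shipped material compositions.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "B": (5, 10.81),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Cr": (24, 51.996),
    "Mn": (25, 54.938),
    "Fe": (26, 55.845),
    "Zr": (40, 91.224),
    "Mo": (42, 95.95),
    "Pb": (82, 207.2),
}

# Photoelectric calibration: cross section per lead atom at 200 keV (cm^2),
# chosen to reproduce a photoelectric mass coefficient of ~0.85 cm^2/g.
_SIGMA_PE_REF_CM2 = 2.925e-22
_PE_Z_EXPONENT = 4.1
_KEDGE_JUMP = 8.0


def _k_edge_kev(Z: int) -> float:
    """Moseley-law K-edge energy estimate in keV."""
    return 0.0136 * (Z - 1) ** 2


def klein_nishina_total(energy_kev) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron (cm^2)."""
    e = np.asarray(energy_kev, dtype=float)
    k = e / ELECTRON_REST_KEV
    r2 = CLASSICAL_ELECTRON_RADIUS_CM**2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    out = 2 * np.pi * r2 * (t1 + t2 + t3)
    return out if out.ndim else float(out)


def photoelectric_sigma(Z: int, energy_kev) -> np.ndarray:
    """Synthetic photoelectric cross section per atom (cm^2)."""
    e = np.asarray(energy_kev, dtype=float)
    s = 3.2 - 0.7 * Z / 82.0
    sigma = _SIGMA_PE_REF_CM2 * (Z / 82.0) ** _PE_Z_EXPONENT * (200.0 / e) ** s
    edge = _k_edge_kev(Z)
    if edge > ENERGY_MIN_KEV:
        sigma = np.where(e < edge, sigma / _KEDGE_JUMP, sigma)
    out = sigma
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CrossSectionTable:
    """Per-element mass attenuation grid with log-log interpolation.

    ``energies_kev`` are strictly increasing and cover 15-700 keV;
    ``pe`` and ``incoherent`` are mass coefficients in cm^2/g.
    """

    element: str
    energies_kev: np.ndarray
    pe: np.ndarray
    incoherent: np.ndarray

    def interp(self, energy_kev) -> tuple[np.ndarray, np.ndarray]:
        """(photoelectric, incoherent) mass coefficients at given energies."""
        loge = np.log(np.asarray(energy_kev, dtype=float))
        grid = np.log(self.energies_kev)
        pe = np.exp(np.interp(loge, grid, np.log(self.pe)))
        inc = np.exp(np.interp(loge, grid, np.log(self.incoherent)))
        return pe, inc


@lru_cache(maxsize=None)
def element_table(symbol: str, n_points: int = 96) -> CrossSectionTable:
    """Tabulate the synthetic cross sections for one element.

    The grid is log-spaced over 15-700 keV with mesh points inserted just
    below and above the K edge where one falls inside the range, so the
    log-log interpolation does not smear the edge step.
    """
    if symbol not in ELEMENTS:
        raise DomainError(f"No cross-section data for element {symbol!r}")
    Z, A = ELEMENTS[symbol]
    grid = np.geomspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, n_points)
    edge = _k_edge_kev(Z)
    if ENERGY_MIN_KEV < edge < ENERGY_MAX_KEV:
        grid = np.unique(np.concatenate([grid, [edge * (1 - 1e-6), edge * (1 + 1e-6)]]))
    atoms_per_g = AVOGADRO / A
    pe = photoelectric_sigma(Z, grid) * atoms_per_g
    inc = klein_nishina_total(grid) * Z * atoms_per_g
    return CrossSectionTable(element=symbol, energies_kev=grid, pe=pe, incoherent=inc)


class MaterialXS:
    """Linear attenuation coefficients of one material (1/cm).

    Combines the per-element tables with the mass-fraction mixture rule and
    the material density.  Evaluation is vectorized over photon energies.
    """

    def __init__(self, material: Material):
        self.material = material
        self.density = material.density
        self._tables = [
            (frac, element_table(sym)) for sym, frac in material.composition.items()
        ]

    def mass_coefficients(self, energy_kev) -> tuple[np.ndarray, np.ndarray]:
        """(photoelectric, incoherent) mass attenuation, cm^2/g."""
        e = np.asarray(energy_kev, dtype=float)
        pe = np.zeros_like(e)
        inc = np.zeros_like(e)
        for frac, tab in self._tables:
            p, i = tab.interp(e)
            pe += frac * p
            inc += frac * i
        return pe, inc

    def mu_parts(self, energy_kev) -> tuple[np.ndarray, np.ndarray]:
        """(mu_photoelectric, mu_incoherent) linear coefficients, 1/cm."""
        pe, inc = self.mass_coefficients(energy_kev)
        return pe * self.density, inc * self.density

    def mu_total(self, energy_kev) -> np.ndarray:
        pe, inc = self.mu_parts(energy_kev)
        return pe + inc

    def p_photoelectric(self, energy_kev) -> np.ndarray:
        """Probability that an interaction at this energy is photoelectric."""
        pe, inc = self.mu_parts(energy_kev)
        return pe / (pe + inc)


@lru_cache(maxsize=None)
def material_xs(name: str) -> MaterialXS:
    """Cached :class:`MaterialXS` for a named material."""
    return MaterialXS(get_material(name))
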