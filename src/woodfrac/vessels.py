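"""Vessel lumen morphometrics and Hagen-Poiseuille hydraulic conductivity.

Per-vessel ellipse measurements (major/minor *radii* in micrometres) yield the
circle-equivalent diameter d, the hydraulically weighted mean diameter d_h
(Sigma d^5 / Sigma d^4, which weights flow-dominating wide conduits), vessel
density VD, the cumulative lumen fraction A_lumen, and the theoretical
conductivities K_h and area-specific K_S in kg m^-1 MPa^-1 s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VesselMeasure",
    "HydraulicConstants",
    "VesselPopulation",
    "VesselSummary",
    "equivalent_diameter",
    "hydraulically_weighted_diameter",
    "theoretical_conductivity",
    "population_summary",
]

_UM_TO_M = 1e-6
_PA_TO_MPA = 1e6  # K per Pa -> K per MPa multiplies by 1e6


@dataclass(frozen=True)
class HydraulicConstants:
    """Water properties at 20 degC used in the Hagen-Poiseuille term."""

    viscosity_pa_s: float = 1.002e-3
    density_kg_m3: float = 998.2

    def __post_init__(self):
        if self.viscosity_pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class VesselMeasure:
    """One vessel lumen as an ellipse with major radius a and minor radius b (um)."""

    a_um: float
    b_um: float

    def __post_init__(self):
        if not (self.a_um >= self.b_um > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a_um}, b={self.b_um}")

    @property
    def d_um(self) -> float:
        return equivalent_diameter(self.a_um, self.b_um)

    @property
    def lumen_area_um2(self) -> float:
        return float(np.pi * self.a_um * self.b_um)


@dataclass(frozen=True)
class VesselPopulation:
    """All vessels of one analysed cross-section (bark and pith excluded)."""

    vessels: tuple[VesselMeasure, ...]
    analyzed_area_mm2: float
    organ: str = "stem"  # stem | twig

    def __post_init__(self):
        if self.analyzed_area_mm2 <= 0:
            raise ValueError("analyzed_area_mm2 must be positive")
        object.__setattr__(self, "vessels", tuple(self.vessels))

    @property
    def analyzed_area_m2(self) -> float:
        return self.analyzed_area_mm2 * 1e-6

    def diameters_um(self) -> np.ndarray:
        return np.array([v.d_um for v in self.vessels])


@dataclass(frozen=True)
class VesselSummary:
    n_vessels: int
    vd_per_mm2: float
    d_mean_um: float
    d_max_um: float
    d_h_um: float
    lumen_fraction_pct: float
    k_h: float  # kg m MPa^-1 s^-1
    k_s: float  # kg m^-1 MPa^-1 s^-1


def equivalent_diameter(a_um, b_um):
    """Circle-equivalent lumen diameter d = (32 (ab)^3 / (a^2 + b^2))^(1/4).

    a and b are the major and minor radii; a circular lumen of radius r gives
    d = 2r exactly.
    """
    a = np.asarray(a_um, dtype=float)
    b = np.asarray(b_um, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("radii must be positive")
    d = (32.0 * (a * b) ** 3 / (a**2 + b**2)) ** 0.25
    return float(d) if d.ndim == 0 else d


def hydraulically_weighted_diameter(diameters_um) -> float:
    """Hydraulically weighted mean diameter d_h = Sigma d^5 / Sigma d^4 (um).

    Lies in [min d, max d] and equals d for a uniform population; weighting by
    d^4 reflects the fourth-power dependence of laminar flow on diameter.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    return float(np.sum(d**5) / np.sum(d**4))


def theoretical_conductivity(
    pop: VesselPopulation, consts: HydraulicConstants = HydraulicConstants()
) -> tuple[float, float]:
    """Hagen-Poiseuille K_h and area-specific K_S of a vessel population.

    K_h = (pi Sigma r^4 / 8 eta) rho with r = d/2 in metres, expressed per MPa
    of pressure gradient (kg m MPa^-1 s^-1); K_S = K_h / analysed area
    (kg m^-1 MPa^-1 s^-1), the unit regime of the study's trait table.
    Additive over disjoint vessel sets.
    """
    r_m = pop.diameters_um() / 2.0 * _UM_TO_M
    sum_r4 = float(np.sum(r_m**4)) if r_m.size else 0.0
    k_h_pa = np.pi * sum_r4 / (8.0 * consts.viscosity_pa_s) * consts.density_kg_m3
    k_h = k_h_pa * _PA_TO_MPA
    k_s = k_h / pop.analyzed_area_m2
    return k_h, k_s


def population_summary(
    pop: VesselPopulation, consts: HydraulicConstants = HydraulicConstants()
) -> VesselSummary:
    """VD, d_max, d_h, lumen fraction and conductivities for one section."""
    n = len(pop.vessels)
    if n == 0:
        warnings.warn("empty vessel population: summary is all zeros",
                      stacklevel=2)
        return VesselSummary(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    d = pop.diameters_um()
    lumen_um2 = sum(v.lumen_area_um2 for v in pop.vessels)
    area_um2 = pop.analyzed_area_mm2 * 1e6
    k_h, k_s = theoretical_conductivity(pop, consts)
    return VesselSummary(
        n_vessels=n,
        vd_per_mm2=n / pop.analyzed_area_mm2,
        d_mean_um=float(np.mean(d)),
        d_max_um=float(np.max(d)),
        d_h_um=hydraulically_weighted_diameter(d),
        lumen_fraction_pct=100.0 * lumen_um2 / area_um2,
        k_h=k_h,
        k_s=k_s,
    )
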