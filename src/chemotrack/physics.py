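"""Hydrodynamic theory: Stokes-Einstein, globular radii, Faxén wall drag.

Predictions here provide the theoretical column against which measured
diffusion coefficients are compared: a sphere's free diffusion coefficient
D = kB*T / (6*pi*eta*r), the radius of a globular protein of given mass at
density 1.35 g/cm³, the near-wall viscosity increase described by Faxén's
series, and number-weighted averages over oligomeric mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "DALTON_KG",
    "PhysicalContext",
    "FaxenCorrection",
    "stokes_einstein",
    "globular_radius",
    "faxen_viscosity",
    "mixture_weighted_d",
]

BOLTZMANN = 1.380649e-23  # J/K
DALTON_KG = 1.66053907e-27
_PI = 3.141592653589793


@dataclass
class PhysicalContext:
    """Temperature and solvent viscosity for hydrodynamic predictions.

    Defaults: room temperature 293 K and the 0.005 Pa·s viscosity of a 10%
    Ficoll 400 solution.
    """

    temperature_k: float = 293.0
    viscosity_pa_s: float = 0.005

    def __post_init__(self) -> None:
        if self.temperature_k <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("temperature and viscosity must be positive")


@dataclass
class FaxenCorrection:
    gamma: float  # r/h
    p: float  # series value P(gamma)
    eta_h: float  # corrected viscosity, Pa·s


def stokes_einstein(
    radius_m: float, ctx: PhysicalContext | None = None
) -> float:
    """Free diffusion coefficient of a sphere, in µm²/s.

    D = kB*T / (6*pi*eta*r); exactly inverse-linear in viscosity and radius.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    c = ctx or PhysicalContext()
    d_si = BOLTZMANN * c.temperature_k / (6.0 * _PI * c.viscosity_pa_s * radius_m)
    return d_si * 1e12  # m²/s -> µm²/s


def globular_radius(mass_da: float, density_g_cm3: float = 1.35) -> float:
    """Radius (m) of a sphere of the given mass at globular-protein density."""
    if mass_da <= 0:
        raise ValueError("mass must be positive")
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    mass_kg = mass_da * DALTON_KG
    volume = mass_kg / (density_g_cm3 * 1000.0)  # m³
    return (3.0 * volume / (4.0 * _PI)) ** (1.0 / 3.0)


def _p_series_printed(g: float) -> float:
    # published fifth-order form with exponents applied to whole factors
    return -9.0 * g / 16.0 + (g / 8.0) ** 3 - (45.0 * g / 256.0) ** 4 + (g / 16.0) ** 5


def _p_series_standard(g: float) -> float:
    # conventional parallel-to-wall drag series
    return -(9.0 / 16.0) * g + (1.0 / 8.0) * g**3 - (45.0 / 256.0) * g**4 - (1.0 / 16.0) * g**5


def faxen_viscosity(
    eta_inf: float, radius_m: float, h_m: float, mode: str = "printed"
) -> FaxenCorrection:
    """Effective viscosity at height h above a wall: eta(h) = eta_inf/(1+P).

    gamma = r/h must lie in (0, 1).  mode selects the fifth-order series:
    ``printed`` uses the published form (exponents on whole bracketed
    factors); ``standard`` the conventional wall-drag polynomial.  Both give
    P→0 (hence eta→eta_inf) far from the wall.
    """
    if h_m <= radius_m:
        raise ValueError("h must exceed the particle radius")
    if eta_inf <= 0:
        raise ValueError("eta_inf must be positive")
    g = radius_m / h_m
    if mode == "printed":
        p = _p_series_printed(g)
    elif mode == "standard":
        p = _p_series_standard(g)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FaxenCorrection(gamma=g, p=p, eta_h=eta_inf / (1.0 + p))


def mixture_weighted_d(components: list[tuple[float, float]]) -> float:
    """Number-weighted average D over (D, count_fraction) components."""
    if not components:
        raise ValueError("empty component list")
    total = sum(f for _, f in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return sum(d * f for d, f in components)
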