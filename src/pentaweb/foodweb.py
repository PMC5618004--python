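"""Closed-form steady states of the pentagon food web.

Under steady state ("growth = loss" for every compartment) with linear
functional responses, the food web collapses to simple closed forms in the
ciliate biomass C (nmol-P L^-1):

* prokaryote biomass        ``B  = alpha_C * C / (Y_H * alpha_H)``
* free phosphate            ``P  = (alpha_C / alpha_A) * C``
* prokaryote growth rate    ``mu = alpha_B * P``

Bacterial carbon demand (BCD) follows as production over yield,
``BCD_P = mu * B / Y_BC = k * C**2`` with
``k = alpha_B * alpha_C**2 / (Y_BC * Y_H * alpha_H * alpha_A)``, capped by
the labile-DOC supply rate psi:

    ``BCD = min(k * C**2, psi)``

The cap partitions the C axis into two growth-limitation regimes for the
prokaryotes: mineral-nutrient limitation (MNL, quadratic branch) below the
crossover ``C* = sqrt(psi / k)`` and organic-carbon limitation (OCL,
plateau) above it.  Ties at the crossover are classified OCL, making the
regime label right-continuous in C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import FoodWebParameters

__all__ = [
    "MNL",
    "OCL",
    "SteadyStatePrediction",
    "prokaryote_biomass",
    "free_phosphate",
    "prokaryote_growth_rate",
    "bcd_quadratic_coefficient",
    "bcd_mineral_limited",
    "bcd",
    "classify_regime",
    "crossover_ciliate_density",
    "ciliate_p_content",
    "cells_to_biomass",
    "bcd_cells",
    "temperature_scale",
    "steady_state",
]

MNL = "MNL"
OCL = "OCL"


def _check_ciliates(C):
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("ciliate biomass must be non-negative")
    return C


def _maybe_scalar(value, like):
    arr = np.asarray(value)
    if np.isscalar(like) or np.ndim(like) == 0:
        return arr.item()
    return arr


@dataclass(frozen=True)
class SteadyStatePrediction:
    """Steady-state food-web prediction at a given ciliate biomass.

    All biomasses in nmol-P L^-1, ``mu`` in h^-1, ``bcd`` in
    nmol-C L^-1 h^-1.  ``regime`` is ``"MNL"`` or ``"OCL"``.
    """

    C: float
    B: float
    P: float
    mu: float
    bcd: float
    regime: str


def prokaryote_biomass(C, params: FoodWebParameters):
    """Steady-state prokaryote biomass B = alpha_C*C/(Y_H*alpha_H).

    Follows from the nanoflagellate balance
    ``Y_H*alpha_H*B*H = alpha_C*H*C``: HNF growth on prokaryotes equals
    their loss to ciliates.  Linear in C.
    """
    C = _check_ciliates(C)
    return _maybe_scalar(params.alpha_C / (params.Y_H * params.alpha_H) * C, C)


def free_phosphate(C, params: FoodWebParameters):
    """Steady-state free phosphate P = (alpha_C/alpha_A)*C.

    Follows from the autotroph balance ``alpha_A*P*A = alpha_C*A*C``.
    """
    C = _check_ciliates(C)
    return _maybe_scalar(params.alpha_C / params.alpha_A * C, C)


def prokaryote_growth_rate(C, params: FoodWebParameters):
    """Phosphate-limited prokaryote growth rate mu = alpha_B * P(C)."""
    C = _check_ciliates(C)
    return _maybe_scalar(params.alpha_B * np.asarray(free_phosphate(C, params)), C)


def bcd_quadratic_coefficient(params: FoodWebParameters) -> float:
    """Coefficient k of the MNL branch BCD_P = k*C**2.

    ``k = alpha_B*alpha_C**2 / (Y_BC*Y_H*alpha_H*alpha_A)`` in
    nmol-C L^-1 h^-1 per (nmol-P L^-1)^2.
    """
    return (params.alpha_B * params.alpha_C ** 2
            / (params.Y_BC * params.Y_H * params.alpha_H * params.alpha_A))


def bcd_mineral_limited(C, params: FoodWebParameters):
    """Bacterial carbon demand on the mineral-limited branch, k*C**2.

    Equal to production over yield, ``mu(C)*B(C)/Y_BC``.
    """
    C = _check_ciliates(C)
    return _maybe_scalar(bcd_quadratic_coefficient(params) * C ** 2, C)


def bcd(C, params: FoodWebParameters):
    """Bacterial carbon demand min(k*C**2, psi).

    Continuous, non-decreasing in C and bounded above by the labile-DOC
    supply rate psi.
    """
    C = _check_ciliates(C)
    return _maybe_scalar(
        np.minimum(bcd_quadratic_coefficient(params) * C ** 2, params.psi), C)


def classify_regime(C, params: FoodWebParameters):
    """Growth-limitation regime at ciliate biomass C.

    ``"MNL"`` where ``k*C**2 < psi`` and ``"OCL"`` where ``k*C**2 >= psi``
    (the tie at the crossover is assigned OCL, so the label is
    right-continuous).
    """
    C = _check_ciliates(C)
    quad = bcd_quadratic_coefficient(params) * C ** 2
    return _maybe_scalar(np.where(quad >= params.psi, OCL, MNL), C)


def crossover_ciliate_density(params: FoodWebParameters) -> float:
    """Ciliate biomass C* = sqrt(psi/k) where the two BCD branches cross."""
    return math.sqrt(params.psi / bcd_quadratic_coefficient(params))


def ciliate_p_content(diameter_um: float,
                      carbon_density_pg_um3: float = 0.13,
                      molar_c_to_p: float = 106.0,
                      carbon_molar_mass: float = 12.011) -> float:
    """Phosphorus content per ciliate cell (nmol-P cell^-1).

    A spherical cell of the given equivalent diameter, a volumetric carbon
    density (default 0.13 pg-C um^-3) and Redfield biomass stoichiometry
    (molar C:P = 106) give

        sigma = (pi/6) d^3 * rho_C / M_C / (C:P)

    With the defaults and d = 20 um this evaluates to ~4.3e-4, the
    published conversion factor.  Cubic in diameter.
    """
    if diameter_um < 0:
        raise ValueError("diameter must be non-negative")
    for name, value in (("carbon_density_pg_um3", carbon_density_pg_um3),
                        ("molar_c_to_p", molar_c_to_p),
                        ("carbon_molar_mass", carbon_molar_mass)):
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive")
    volume_um3 = math.pi / 6.0 * diameter_um ** 3
    carbon_pg = volume_um3 * carbon_density_pg_um3
    carbon_nmol = carbon_pg * 1e-12 / carbon_molar_mass * 1e9  # pg -> g -> mol -> nmol
    return carbon_nmol / molar_c_to_p


def cells_to_biomass(cells_per_ml, sigma: float):
    """Convert a cell concentration (cells mL^-1) to biomass (nmol-P L^-1).

    cells mL^-1 * sigma (nmol-P cell^-1) * 1000 (mL per L).
    """
    cells = np.asarray(cells_per_ml, dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell concentration must be non-negative")
    return _maybe_scalar(cells * sigma * 1000.0, cells_per_ml)


def bcd_cells(C_cells, params: FoodWebParameters, temperature: float | None = None):
    """Bacterial carbon demand from ciliate abundance in cells mL^-1.

    Converts counts to biomass via sigma, applies a net temperature factor
    ``f = Q10**((T - T_ref)/10)`` to the quadratic coefficient, and caps at
    psi.  At ``T = T_ref`` this reduces exactly to
    ``bcd(cells_to_biomass(C_cells, sigma), params)``.
    """
    C = np.asarray(cells_to_biomass(C_cells, params.sigma), dtype=float)
    f = 1.0 if temperature is None else params.q10_factor(temperature)
    quad = f * bcd_quadratic_coefficient(params) * C ** 2
    return _maybe_scalar(np.minimum(quad, params.psi), C_cells)


def temperature_scale(params: FoodWebParameters, temperature: float) -> FoodWebParameters:
    """Parameter set with all affinity/clearance rates Q10-scaled to ``temperature``.

    Yields, sigma and psi are unchanged; ``T_ref`` is updated so that
    scaling is composable (+10 then -10 degC returns the original rates).
    """
    f = params.q10_factor(temperature)
    return params.replace(alpha_B=params.alpha_B * f,
                          alpha_A=params.alpha_A * f,
                          alpha_H=params.alpha_H * f,
                          alpha_C=params.alpha_C * f,
                          T_ref=temperature)


def steady_state(C: float, params: FoodWebParameters,
                 cells_per_ml: bool = False,
                 temperature: float | None = None) -> SteadyStatePrediction:
    """Full steady-state prediction at one ciliate level.

    With ``cells_per_ml=True`` the input is an abundance in cells mL^-1
    (converted through sigma); otherwise a biomass in nmol-P L^-1.  An
    optional temperature Q10-scales the rates before evaluation.
    """
    p = params if temperature is None else temperature_scale(params, temperature)
    C_biomass = cells_to_biomass(C, params.sigma) if cells_per_ml else float(C)
    return SteadyStatePrediction(
        C=C_biomass,
        B=prokaryote_biomass(C_biomass, p),
        P=free_phosphate(C_biomass, p),
        mu=prokaryote_growth_rate(C_biomass, p),
        bcd=bcd(C_biomass, p),
        regime=classify_regime(C_biomass, p),
    )
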