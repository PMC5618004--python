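"""Parameter set for the pentagon microbial food web.

The pentagon couples five planktonic compartments — free phosphate (P),
autotrophic flagellates (A), heterotrophic prokaryotes (B), heterotrophic
nanoflagellates (H) and ciliates (C) — through linear (type-I) uptake and
clearance terms.  All biomasses are expressed in phosphorus units
(nmol-P L^-1), so yields are dimensionless P:P ratios except the prokaryote
yield on dissolved organic carbon (``Y_BC``, nmol-P nmol-C^-1).

Two quantities are deliberately *not* given defaults: ``Y_BC`` and the
labile-DOC supply rate ``psi``.  They are free parameters of the theory and
must be supplied by configuration; :func:`example_parameters` ships one
illustrative choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class FoodWebParameters:
    """Rate constants, yields and conversion factors of the food web.

    Parameters
    ----------
    alpha_B :
        Heterotrophic prokaryote affinity for phosphate (L nmol-P^-1 h^-1).
    alpha_A :
        Autotrophic flagellate affinity for phosphate (L nmol-P^-1 h^-1).
    alpha_H :
        Nanoflagellate clearance rate for prokaryotes (L nmol-P^-1 h^-1).
    alpha_C :
        Ciliate clearance rate for flagellates (L nmol-P^-1 h^-1).
    Y_H :
        Nanoflagellate yield on prokaryotes (nmol-P nmol-P^-1), in (0, 1].
    Y_BC :
        Prokaryote yield on labile DOC (nmol-P nmol-C^-1).  No canonical
        value exists; must be configured.
    sigma :
        Phosphorus content per ciliate cell (nmol-P cell^-1), used to
        convert cell counts (cells mL^-1) to biomass (nmol-P L^-1).
    Q10 :
        Factor by which the affinity/clearance rates change per 10 degC.
    psi :
        Supply rate of labile dissolved organic carbon
        (nmol-C L^-1 h^-1); the ceiling on sustainable bacterial carbon
        demand.  Must be configured.
    T_ref :
        Temperature (degC) at which the alpha values are stated.
    """

    alpha_B: float
    alpha_A: float
    alpha_H: float
    alpha_C: float
    Y_H: float
    Y_BC: float
    sigma: float
    Q10: float
    psi: float
    T_ref: float = 17.0

    def __post_init__(self) -> None:
        for name in ("alpha_B", "alpha_A", "alpha_H", "alpha_C",
                     "Y_BC", "sigma", "psi"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0 < self.Y_H <= 1:
            raise ValueError(f"Y_H must lie in (0, 1], got {self.Y_H!r}")
        if not self.Q10 >= 1:
            raise ValueError(f"Q10 must be >= 1, got {self.Q10!r}")

    def q10_factor(self, temperature: float) -> float:
        """Rate multiplier ``Q10**((T - T_ref)/10)`` at ``temperature`` degC."""
        return float(self.Q10 ** ((temperature - self.T_ref) / 10.0))

    def replace(self, **changes) -> "FoodWebParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Published rate constants and conversion factors at 17 degC.  ``Y_BC`` and
#: ``psi`` are intentionally absent: the theory leaves them free.
REFERENCE_RATES = {
    "alpha_B": 0.08,     # L nmol-P^-1 h^-1
    "alpha_A": 0.04,     # L nmol-P^-1 h^-1
    "alpha_H": 0.0015,   # L nmol-P^-1 h^-1
    "alpha_C": 0.0005,   # L nmol-P^-1 h^-1
    "Y_H": 0.3,          # nmol-P nmol-P^-1
    "sigma": 0.00043,    # nmol-P cell^-1 (20 um cell, 0.13 pg-C um^-3, C:P 106)
    "Q10": 1.3,
    "T_ref": 17.0,
}


def reference_parameters(Y_BC: float, psi: float, **overrides) -> FoodWebParameters:
    """Published rates completed with user-supplied ``Y_BC`` and ``psi``."""
    values = dict(REFERENCE_RATES)
    values.update(overrides)
    return FoodWebParameters(Y_BC=Y_BC, psi=psi, **values)


def example_parameters() -> FoodWebParameters:
    """An illustrative, fully-specified parameter set.

    ``Y_BC = 0.006`` nmol-P nmol-C^-1 corresponds to a bacterial growth
    efficiency of roughly 0.3 combined with a molar biomass C:P of ~50.
    ``psi = 3.0`` nmol-C L^-1 h^-1 places the MNL/OCL crossover near
    4 nmol-P L^-1 of ciliate biomass (~9 cells mL^-1), mid-range of the
    ciliate abundances the synthetic mesocosms span.  These two numbers are
    package choices, not measured values.
    """
    return reference_parameters(Y_BC=0.006, psi=3.0)
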