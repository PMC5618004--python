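"""Lotka-Volterra reconstruction of the pentagon food web.

The closed-form steady states in :mod:`pentaweb.foodweb` are roots of a
dynamic system that is only sketched by the pentagon topology: linear
(type-I) grazing, phosphate uptake proportional to free phosphate, and a
labile-DOC pool feeding Liebig-limited prokaryote growth.  This module is
an explicit reconstruction of such a system, constrained so that the
nanoflagellate and autotroph balances vanish exactly on the closed forms.

State vector (all P pools in nmol-P L^-1, D in nmol-C L^-1)::

    P  free phosphate          A  autotrophic flagellates
    B  heterotrophic prokaryotes   H  heterotrophic nanoflagellates
    C  ciliates                D  labile DOC
    S  sink pool (egestion + copepod export), tracked for P conservation

Model equations (the invented closure terms live in :func:`derivatives`
and nowhere else)::

    dA/dt = alpha_A*P*A - alpha_C*A*C
    dB/dt = mu_B*B - alpha_H*B*H,   mu_B = min(alpha_B*P, Y_BC*a_D*D)
    dH/dt = Y_H*alpha_H*B*H - alpha_C*H*C
    dC/dt = Y_C*alpha_C*(A+H)*C - delta_cop*C      (or 0 when clamped)
    dP/dt = r_P - alpha_A*P*A - mu_B*B
    dD/dt = psi - mu_B*B/Y_BC                      (+ glucose impulses)
    dS/dt = (1-Y_H)*alpha_H*B*H + (1-Y_C)*alpha_C*(A+H)*C + delta_cop*C

Total phosphorus P+A+B+H+C+S is conserved exactly when r_P = 0.
Copepods act as a fixed specific loss rate ``delta_cop`` on ciliates; the
ciliate yield ``Y_C`` defaults to ``Y_H``.  ``a_D`` is the cell-specific
DOC clearance; its value only sets how hard the DOC pool is drawn down,
not the steady states themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import foodweb
from .parameters import FoodWebParameters

__all__ = [
    "FoodWebState",
    "ForcingSchedule",
    "ClosureParameters",
    "derivatives",
    "simulate",
    "steady_state_check",
    "equilibrium_state",
    "SteadyStateReport",
]

STATE_VARS = ("P", "D", "A", "B", "H", "C", "S")

HOURS_PER_DAY = 24.0
REDFIELD_C_TO_P = 106.0

#: relative magnitudes below which a negative excursion is treated as
#: numerical noise and clipped to zero: solvers probe trial states slightly
#: outside the feasible set, so the right-hand side is more permissive than
#: the reported trajectory
_NEGATIVE_TOL_RHS = 1e-6
_NEGATIVE_TOL_OUT = 1e-8


@dataclass(frozen=True)
class FoodWebState:
    """Instantaneous food-web state (P pools nmol-P L^-1, D nmol-C L^-1)."""

    P: float
    D: float
    A: float
    B: float
    H: float
    C: float
    S: float = 0.0

    def __post_init__(self):
        for name in STATE_VARS:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "FoodWebState":
        return cls(**dict(zip(STATE_VARS, map(float, arr))))


@dataclass(frozen=True)
class ForcingSchedule:
    """External forcing of one mesocosm tank.

    Parameters
    ----------
    phosphate_dose :
        Daily mineral-P addition (nmol-P L^-1 d^-1).  Applied as a
        continuous rate by default; set ``phosphate_mode="impulse"`` for
        instantaneous additions at ``dose_times``.
    glucose_multiplier :
        Glucose-C addition as a multiple of the Redfield carbon equivalent
        of the phosphate dose (106 * phosphate_dose nmol-C per event).
        The mesocosm design uses {0, 0.5, 1, 2, 3}.  Always an impulse.
    psi :
        Autochthonous labile-DOC supply (nmol-C L^-1 h^-1); ``None`` uses
        the parameter set's psi.
    copepod_clearance :
        Specific loss rate imposed on ciliates (h^-1).
    duration_days, dose_times :
        Experiment length and the times (days) of the daily additions;
        ``dose_times=None`` means one addition per day at t = 1, 2, ... d.
    clamp_ciliates :
        Hold C fixed (dC/dt = 0), treating ciliates as a boundary
        condition set by the copepod stock.
    """

    phosphate_dose: float = 0.0
    glucose_multiplier: float = 0.0
    psi: float | None = None
    copepod_clearance: float = 0.0
    duration_days: float = 12.0
    dose_times: tuple | None = None
    phosphate_mode: str = "continuous"
    clamp_ciliates: bool = False

    def __post_init__(self):
        if self.phosphate_dose < 0 or self.glucose_multiplier < 0:
            raise ValueError("doses must be non-negative")
        if self.copepod_clearance < 0:
            raise ValueError("copepod clearance must be non-negative")
        if self.phosphate_mode not in ("continuous", "impulse"):
            raise ValueError("phosphate_mode must be 'continuous' or 'impulse'")

    def effective_psi(self, params: FoodWebParameters) -> float:
        return params.psi if self.psi is None else self.psi

    def dose_times_hours(self) -> np.ndarray:
        if self.dose_times is not None:
            days = np.asarray(self.dose_times, dtype=float)
        else:
            days = np.arange(1.0, np.floor(self.duration_days) + 0.5)
        return days * HOURS_PER_DAY

    def phosphate_rate(self) -> float:
        """Continuous-mode P supply rate (nmol-P L^-1 h^-1)."""
        if self.phosphate_mode != "continuous":
            return 0.0
        return self.phosphate_dose / HOURS_PER_DAY

    def glucose_dose_per_event(self) -> float:
        """Glucose-C added per dosing event (nmol-C L^-1)."""
        return self.glucose_multiplier * REDFIELD_C_TO_P * self.phosphate_dose


@dataclass(frozen=True)
class ClosureParameters:
    """Terms of the reconstruction that the steady-state theory leaves open.

    ``doc_affinity`` (a_D, L nmol-P^-1 h^-1): cell-specific DOC clearance;
    C-limited growth is ``Y_BC * a_D * D``.  ``Y_C``: ciliate yield on
    flagellate prey; ``None`` means equal to ``Y_H``.
    """

    doc_affinity: float = 0.005
    Y_C: float | None = None

    def ciliate_yield(self, params: FoodWebParameters) -> float:
        return params.Y_H if self.Y_C is None else self.Y_C


def derivatives(state, params: FoodWebParameters,
                forcing: ForcingSchedule,
                t: float = 0.0,
                closure: ClosureParameters = ClosureParameters()) -> np.ndarray:
    """Time derivative of the state vector (per hour).

    Accepts a :class:`FoodWebState` or a 7-array in ``STATE_VARS`` order.
    Bilinear grazing and uptake terms follow the pentagon topology; the
    prokaryote growth rate is the Liebig minimum of P-limited
    (``alpha_B*P``) and C-limited (``Y_BC*a_D*D``) rates.  On the
    closed-form steady states the H- and A-balances vanish identically.
    """
    if isinstance(state, FoodWebState):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
        if np.any(y < -_NEGATIVE_TOL_RHS * (1.0 + np.abs(y).max())):
            raise ValueError("state components must be non-negative")
        y = np.maximum(y, 0.0)
    P, D, A, B, H, C, S = y

    Y_C = closure.ciliate_yield(params)
    mu_B = min(params.alpha_B * P, params.Y_BC * closure.doc_affinity * D)

    graze_HB = params.alpha_H * B * H          # P-flux prokaryotes -> HNF
    graze_C = params.alpha_C * (A + H) * C     # P-flux flagellates -> ciliates
    uptake_A = params.alpha_A * P * A
    uptake_B = mu_B * B
    cop_loss = forcing.copepod_clearance * C

    dA = uptake_A - params.alpha_C * A * C
    dB = uptake_B - graze_HB
    dH = params.Y_H * graze_HB - params.alpha_C * H * C
    dC = 0.0 if forcing.clamp_ciliates else Y_C * graze_C - cop_loss
    dP = forcing.phosphate_rate() - uptake_A - uptake_B
    dD = forcing.effective_psi(params) - uptake_B / params.Y_BC
    dS = (1.0 - params.Y_H) * graze_HB + (1.0 - Y_C) * graze_C + cop_loss

    return np.array([dP, dD, dA, dB, dH, dC, dS])


def _integrate_segment(y0, t0, t1, params, forcing, closure, t_eval, options):
    fun = lambda t, y: derivatives(y, params, forcing, t, closure)
    sol = solve_ivp(fun, (t0, t1), y0, t_eval=t_eval, **options)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed on [{t0}, {t1}] h: {sol.message}")
    return sol


def simulate(initial: FoodWebState,
             params: FoodWebParameters,
             forcing: ForcingSchedule,
             t_grid=None,
             closure: ClosureParameters = ClosureParameters(),
             solver_options: dict | None = None) -> pd.DataFrame:
    """Integrate the food web and return a trajectory table.

    ``t_grid`` is an increasing array of output times in hours (default:
    hourly over ``forcing.duration_days``).  Dosing impulses (glucose
    always; phosphate when ``phosphate_mode="impulse"``) are applied
    between integration segments.  Returns a DataFrame with columns
    ``time_h`` plus the state variables; a small negative solver excursion
    (relative magnitude below 1e-8) is clipped to zero, anything larger
    raises.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, forcing.duration_days * HOURS_PER_DAY + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    options = dict(method="LSODA", rtol=1e-8, atol=1e-10)
    if solver_options:
        options.update(solver_options)

    t_end = t_grid[-1]
    dose_hours = forcing.dose_times_hours()
    dose_hours = dose_hours[(dose_hours > t_grid[0]) & (dose_hours < t_end)]
    breakpoints = np.concatenate([[t_grid[0]], dose_hours, [t_end]])

    glucose_event = forcing.glucose_dose_per_event()
    phosphate_event = (forcing.phosphate_dose
                       if forcing.phosphate_mode == "impulse" else 0.0)

    y = initial.to_array()
    times, states = [], []
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        mask = (t_grid >= t0) & (t_grid <= t1)
        t_eval = np.unique(np.concatenate([[t0], t_grid[mask], [t1]]))
        sol = _integrate_segment(y, t0, t1, params, forcing, closure,
                                 t_eval, options)
        scale = 1.0 + np.abs(sol.y).max()
        if sol.y.min() < -_NEGATIVE_TOL_OUT * scale:
            raise RuntimeError(
                f"trajectory went negative (min {sol.y.min():.3e}) on "
                f"[{t0}, {t1}] h; tighten solver tolerances")
        ys = np.maximum(sol.y, 0.0)
        keep = np.isin(sol.t, t_grid[mask])
        times.append(sol.t[keep])
        states.append(ys[:, keep])
        y = ys[:, -1].copy()
        if t1 < t_end:  # dosing impulse at the segment boundary
            y[0] += phosphate_event
            y[1] += glucose_event

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    # segments share their boundary point; keep the first occurrence
    _, first = np.unique(t_all, return_index=True)
    frame = pd.DataFrame(y_all[:, first].T, columns=list(STATE_VARS))
    frame.insert(0, "time_h", t_all[first])
    return frame.reset_index(drop=True)


@dataclass(frozen=True)
class SteadyStateReport:
    """Relative residuals of the closed-form balances over a late-time window."""

    residual_B: float
    residual_P: float
    residual_mu: float
    window_start_h: float
    passed: bool

    def max_residual(self) -> float:
        return max(self.residual_B, self.residual_P, self.residual_mu)


def steady_state_check(trajectory: pd.DataFrame,
                       params: FoodWebParameters,
                       tol: float = 1e-3,
                       window: float = 0.1) -> SteadyStateReport:
    """Compare the tail of a trajectory with the closed-form steady states.

    Over the final ``window`` fraction of the trajectory, computes the
    maximum relative deviations of B, P and mu = alpha_B*P from their
    closed-form values at the trajectory's own ciliate biomass.  An
    all-zero tail is a degenerate equilibrium and reports zero residuals.
    """
    if len(trajectory) < 3:
        raise ValueError("trajectory too short for a steady-state check")
    if not 0 < window <= 1:
        raise ValueError("window must lie in (0, 1]")
    n_tail = max(2, int(np.ceil(window * len(trajectory))))
    tail = trajectory.iloc[-n_tail:]

    C = tail["C"].to_numpy()
    B = tail["B"].to_numpy()
    P = tail["P"].to_numpy()
    if np.allclose(tail[list("PABHC")].to_numpy(), 0.0):
        return SteadyStateReport(0.0, 0.0, 0.0,
                                 float(tail["time_h"].iloc[0]), True)

    B_pred = foodweb.prokaryote_biomass(C, params)
    P_pred = foodweb.free_phosphate(C, params)
    mu_pred = foodweb.prokaryote_growth_rate(C, params)

    def rel(obs, pred):
        denom = np.maximum(np.abs(pred), 1e-300)
        return float(np.max(np.abs(obs - pred) / denom))

    res_B = rel(B, B_pred)
    res_P = rel(P, P_pred)
    res_mu = rel(params.alpha_B * P, mu_pred)
    passed = max(res_B, res_P, res_mu) < tol
    return SteadyStateReport(res_B, res_P, res_mu,
                             float(tail["time_h"].iloc[0]), passed)


def equilibrium_state(C: float,
                      params: FoodWebParameters,
                      forcing: ForcingSchedule,
                      closure: ClosureParameters = ClosureParameters(),
                      D: float | None = None) -> FoodWebState:
    """Closed-form equilibrium consistent with a continuous phosphate supply.

    Places B, P and H on the closed forms at ciliate biomass ``C`` and
    sizes the autotroph pool so that total P uptake balances the supply
    rate: ``A* = (r_P - mu*B) / (alpha_A * P*)``.  The supply must exceed
    the prokaryote demand.  ``D`` defaults to the level at which the
    C-limited growth rate equals the realized growth rate: exactly the
    OCL equilibrium when demand exceeds psi, and a carbon-replete level
    (so P stays limiting) in the MNL regime.
    """
    if C <= 0:
        raise ValueError("equilibrium_state requires C > 0")
    B = foodweb.prokaryote_biomass(C, params)
    P = foodweb.free_phosphate(C, params)
    mu_P = foodweb.prokaryote_growth_rate(C, params)
    psi = forcing.effective_psi(params)

    # realized growth rate: P-limited below the crossover, capped so that
    # carbon consumption mu*B/Y_BC never exceeds the supply psi above it
    mu = min(mu_P, psi * params.Y_BC / B)
    r_P = forcing.phosphate_rate()
    if r_P <= mu * B:
        raise ValueError(
            "continuous phosphate supply must exceed prokaryote demand "
            f"(supply {r_P:.4g}, demand {mu * B:.4g} nmol-P L^-1 h^-1)")
    A = (r_P - mu * B) / (params.alpha_A * P)
    H = mu / params.alpha_H
    if D is None:
        if mu < mu_P:  # OCL: DOC drawn down until uptake matches supply
            D = mu / (params.Y_BC * closure.doc_affinity)
        else:          # MNL: carbon replete; 2x the indifference level
            D = 2.0 * mu_P / (params.Y_BC * closure.doc_affinity)
    return FoodWebState(P=P, D=D, A=A, B=B, H=H, C=C)
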