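"""Synthetic mesocosm data emulating the two-experiment enrichment design.

No measurement data from the enrichment mesocosms is deposited anywhere,
so every stage of the pipeline is exercised on synthetic inputs generated
here: the tank/treatment layout of the two experiments, ODE-driven
abundance time series with low- vs high-ciliate predator regimes,
flow-cytometry-like virus group counts, and paired host/virus band
matrices with tunable treatment effect and host-virus coupling.

All generators are bit-reproducible under a fixed seed.  What they emulate
and, importantly, what they do not (gel physics, band co-migration, real
fingerprint noise structure) is laid out in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import dynamics
from .dynamics import ClosureParameters, ForcingSchedule, HOURS_PER_DAY
from .fingerprints import BandMatrix
from .parameters import FoodWebParameters

__all__ = [
    "TankTreatment",
    "ExperimentDesign",
    "CouplingSpec",
    "CellQuotas",
    "generate_design",
    "simulate_experiment",
    "generate_band_matrices",
    "BcdFit",
    "fit_bcd_curve",
]


@dataclass(frozen=True)
class TankTreatment:
    """One mesocosm unit: glucose level, silicate flag and nitrogen source."""

    tank_id: str
    glucose_x: float
    silicate: bool
    nitrogen_source: str


@dataclass(frozen=True)
class ExperimentDesign:
    """Tank grid of one enrichment experiment."""

    name: str
    tanks: tuple
    volume_l: float
    duration_days: int
    sampling_days: tuple

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.tanks]).set_index("tank_id")


#: glucose gradients of the two experiments (x Redfield C)
_PAME_I_GRADIENT = (0.0, 0.5, 1.0, 3.0)
_PAME_II_NH4_GRADIENT = (0.0, 0.5, 1.0, 2.0, 3.0)
_PAME_II_NO3_GRADIENT = (0.0, 0.5, 1.0, 3.0)


def generate_design(experiment: str) -> ExperimentDesign:
    """Tank layout of experiment ``"PAME-I"`` or ``"PAME-II"``.

    PAME-I: eight 700 L units, two four-point glucose gradients
    (0/0.5/1/3 x Redfield C), one gradient with silicate addition, NH4+ as
    nitrogen source.  PAME-II: nine 900 L units, a five-point NH4+ gradient
    (0/0.5/1/2/3) plus a four-point NO3- gradient, all silicate-replete.
    Sampling days 0-12 in both.
    """
    sampling_days = tuple(range(13))
    if experiment == "PAME-I":
        tanks = tuple(
            TankTreatment(f"I-{i + 1}", g, si, "NH4")
            for i, (g, si) in enumerate(
                [(g, False) for g in _PAME_I_GRADIENT]
                + [(g, True) for g in _PAME_I_GRADIENT]))
        return ExperimentDesign("PAME-I", tanks, 700.0, 12, sampling_days)
    if experiment == "PAME-II":
        tanks = tuple(
            TankTreatment(f"II-{i + 1}", g, True, n)
            for i, (g, n) in enumerate(
                [(g, "NH4") for g in _PAME_II_NH4_GRADIENT]
                + [(g, "NO3") for g in _PAME_II_NO3_GRADIENT]))
        return ExperimentDesign("PAME-II", tanks, 900.0, 12, sampling_days)
    raise ValueError(f"unknown experiment {experiment!r}; "
                     "expected 'PAME-I' or 'PAME-II'")


@dataclass(frozen=True)
class CellQuotas:
    """Per-cell phosphorus quotas (nmol-P cell^-1) for count conversion.

    Defaults assume ~20 fg-C prokaryote and ~3 um nanoflagellate cells at
    0.13 pg-C um^-3 and molar C:P = 106; the ciliate quota is the sigma
    conversion factor of the steady-state theory.
    """

    prokaryote: float = 1.6e-8
    hnf: float = 1.4e-6
    ciliate: float = 0.00043


@dataclass(frozen=True)
class VirusModel:
    """Stylized FCM virus-group generator.

    Group I (small viruses, mainly prokaryote-infecting) tracks the
    prokaryote count with a virus-to-prokaryote ratio that rises with
    ciliate abundance (base ~10, doubling at ``ciliate_ref`` cells mL^-1),
    which reproduces the positive ciliate-VPR association the pipeline is
    meant to detect.  Groups II-IV are fixed fractions of group I, with
    group III additionally boosted by glucose.
    """

    vpr_base: float = 10.0
    ciliate_gain: float = 1.0
    ciliate_ref: float = 10.0
    group_fractions: tuple = (0.2, 0.05, 0.01)  # II, III, IV relative to I
    glucose_boost_iii: float = 0.3

    def group_counts(self, prokaryotes, ciliate_cells, glucose_x):
        ratio = self.vpr_base * (1.0 + self.ciliate_gain
                                 * ciliate_cells / self.ciliate_ref)
        g1 = ratio * prokaryotes
        f2, f3, f4 = self.group_fractions
        return {
            "virus_I": g1,
            "virus_II": f2 * g1,
            "virus_III": f3 * (1.0 + self.glucose_boost_iii * glucose_x) * g1,
            "virus_IV": f4 * g1,
        }


#: ciliate biomass (nmol-P L^-1) imposed in the two predator regimes:
#: "high" sits above the example-parameter crossover (~4), "low" below it
REGIME_CILIATES = {"low": 1.0, "high": 7.0}

#: daily mineral-P dose (nmol-P L^-1 d^-1) used by the tank simulations
DEFAULT_DOSE_P = 25.0


def simulate_experiment(design: ExperimentDesign,
                        params: FoodWebParameters,
                        ciliate_regime: str = "low",
                        noise_cv: float = 0.2,
                        seed: int | None = None,
                        dose_p: float = DEFAULT_DOSE_P,
                        quotas: CellQuotas = CellQuotas(),
                        virus_model: VirusModel = VirusModel(),
                        closure: ClosureParameters = ClosureParameters(),
                        initial_doc: float = 100.0) -> pd.DataFrame:
    """Per-tank abundance time series for one experiment.

    Each tank runs the Lotka-Volterra reconstruction from the closed-form
    quasi-steady state at the regime's ciliate biomass (ciliates clamped:
    the predator boundary condition), with its own glucose impulse
    schedule.  Biomasses are converted to cells mL^-1 through the cell
    quotas, virus groups I-IV are derived from the prokaryote and ciliate
    counts, and multiplicative lognormal observation noise with the given
    CV is applied.  Deterministic given ``seed``.

    Returns a tidy frame with columns tank_id, day, variable, value
    (counts mL^-1 for abundances) plus the tank metadata.
    """
    if ciliate_regime not in REGIME_CILIATES:
        raise ValueError(f"ciliate_regime must be one of {set(REGIME_CILIATES)}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    C_biomass = REGIME_CILIATES[ciliate_regime]
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log1p(noise_cv ** 2))  # lognormal with unit mean

    records = []
    for tank in design.tanks:
        forcing = ForcingSchedule(phosphate_dose=dose_p,
                                  glucose_multiplier=tank.glucose_x,
                                  duration_days=design.duration_days,
                                  clamp_ciliates=True)
        initial = dynamics.equilibrium_state(C_biomass, params, forcing,
                                             closure, D=initial_doc)
        t_grid = np.asarray(design.sampling_days, dtype=float) * HOURS_PER_DAY
        if t_grid[0] != 0.0:
            t_grid = np.concatenate([[0.0], t_grid])
        traj = dynamics.simulate(initial, params, forcing, t_grid, closure)
        day = (traj["time_h"] / HOURS_PER_DAY).round().astype(int)

        prok = traj["B"].to_numpy() / 1000.0 / quotas.prokaryote
        hnf = traj["H"].to_numpy() / 1000.0 / quotas.hnf
        cil = traj["C"].to_numpy() / 1000.0 / quotas.ciliate
        series = {"prokaryotes": prok, "hnf": hnf, "ciliates": cil}
        series.update(virus_model.group_counts(prok, cil, tank.glucose_x))

        for variable, values in series.items():
            noise = (np.exp(rng.normal(-0.5 * sigma_ln ** 2, sigma_ln,
                                       size=len(values)))
                     if noise_cv > 0 else np.ones(len(values)))
            for d, v in zip(day, values * noise):
                records.append({
                    "tank_id": tank.tank_id, "day": int(d),
                    "variable": variable, "value": float(v),
                    "glucose_x": tank.glucose_x, "silicate": tank.silicate,
                    "nitrogen_source": tank.nitrogen_source,
                })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# paired band matrices


@dataclass(frozen=True)
class CouplingSpec:
    """Generator settings for a paired host/virus fingerprint dataset.

    ``treatment_effect`` shifts band-presence probabilities between the
    two glucose groups (0 = no treatment structure); ``coupling`` is the
    probability that a virus band mirrors its mapped host band rather
    than varying independently; ``flip_rate`` adds symmetric bit-flip
    noise after the mapping.
    """

    n_samples: int = 12
    n_bands_host: int = 30
    n_bands_virus: int = 20
    treatment_effect: float = 0.0
    coupling: float = 0.0
    flip_rate: float = 0.0
    base_presence: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        for name in ("treatment_effect", "coupling", "flip_rate", "base_presence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_samples < 2 or self.n_bands_host < 1 or self.n_bands_virus < 1:
            raise ValueError("need >= 2 samples and >= 1 band per matrix")


_RESAMPLE_CAP = 100


def _draw_rows(rng, probs):
    """Bernoulli matrix with no all-zero rows (bounded resampling)."""
    out = (rng.random(probs.shape) < probs).astype(np.int8)
    for i in np.flatnonzero(out.sum(axis=1) == 0):
        for _ in range(_RESAMPLE_CAP):
            row = (rng.random(probs.shape[1]) < probs[i]).astype(np.int8)
            if row.sum() > 0:
                out[i] = row
                break
        else:
            raise RuntimeError(
                f"could not draw a non-empty fingerprint row after "
                f"{_RESAMPLE_CAP} attempts (presence probabilities too low)")
    return out


def _flip_rows(rng, matrix, rate, probs):
    if rate == 0:
        return matrix
    flipped = np.where(rng.random(matrix.shape) < rate, 1 - matrix, matrix)
    for i in np.flatnonzero(flipped.sum(axis=1) == 0):
        for _ in range(_RESAMPLE_CAP):
            row = np.where(rng.random(matrix.shape[1]) < rate,
                           1 - matrix[i], matrix[i])
            if row.sum() > 0:
                flipped[i] = row
                break
        else:
            raise RuntimeError("bit-flip noise produced an empty row that "
                               f"{_RESAMPLE_CAP} redraws could not repair")
    return flipped.astype(np.int8)


def generate_band_matrices(spec: CouplingSpec,
                           design: ExperimentDesign | None = None
                           ) -> tuple[BandMatrix, BandMatrix]:
    """Paired host (DGGE-like) and virus (PFGE-like) band matrices.

    Samples alternate between a 0x and a 3x glucose group (or, when a
    design is given, are drawn as tank x day combinations of its 0x and
    3x tanks).  Host bands are independent Bernoulli draws whose presence
    probability is shifted by +/- ``treatment_effect``/2 with a random
    band-specific sign between the groups.  Each virus band is mapped to
    one host band and copies it with probability ``coupling``, otherwise
    it is an independent draw; symmetric bit-flip noise at ``flip_rate``
    is applied last.  Rows that come out empty are redrawn (cap 100).
    """
    rng = np.random.default_rng(spec.seed)

    if design is not None:
        extreme = [t for t in design.tanks if t.glucose_x in (0.0, 3.0)]
        days = np.linspace(0, design.duration_days,
                           max(2, spec.n_samples // max(len(extreme), 1)),
                           dtype=int)
        combos = [(t, int(d)) for t in extreme for d in days][:spec.n_samples]
        sample_ids = [f"{t.tank_id}-d{d}" for t, d in combos]
        glucose = np.array([t.glucose_x for t, _ in combos])
        meta = pd.DataFrame({
            "day": [d for _, d in combos],
            "glucose_x": glucose,
            "silicate": [t.silicate for t, _ in combos],
            "nitrogen_source": [t.nitrogen_source for t, _ in combos],
        }, index=sample_ids)
    else:
        sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
        glucose = np.where(np.arange(spec.n_samples) % 2 == 0, 0.0, 3.0)
        meta = pd.DataFrame({"day": np.arange(spec.n_samples) // 2,
                             "glucose_x": glucose,
                             "silicate": False,
                             "nitrogen_source": "NH4"}, index=sample_ids)

    group = np.where(glucose > 0, 0.5, -0.5)  # contrast between glucose groups
    sign_host = rng.choice([-1.0, 1.0], size=spec.n_bands_host)
    p_host = np.clip(spec.base_presence
                     + spec.treatment_effect * np.outer(group, sign_host),
                     0.0, 1.0)
    host = _draw_rows(rng, p_host)

    band_map = (np.arange(spec.n_bands_virus) % spec.n_bands_host
                if spec.n_bands_virus <= spec.n_bands_host
                else rng.integers(0, spec.n_bands_host, spec.n_bands_virus))
    coupled = rng.random((spec.n_samples, spec.n_bands_virus)) < spec.coupling
    independent = _draw_rows(
        rng, np.full((spec.n_samples, spec.n_bands_virus), spec.base_presence))
    virus = np.where(coupled, host[:, band_map], independent).astype(np.int8)
    virus = _flip_rows(rng, virus, spec.flip_rate,
                       np.full(virus.shape, spec.base_presence))
    if np.any(virus.sum(axis=1) == 0):  # coupled empty rows: re-draw host row too
        raise RuntimeError("virus matrix has an empty sample; adjust the "
                           "generator settings")

    host_bm = BandMatrix(
        pd.DataFrame(host, index=sample_ids,
                     columns=[f"dgge_{j + 1:02d}" for j in range(spec.n_bands_host)]),
        meta.copy())
    virus_bm = BandMatrix(
        pd.DataFrame(virus, index=sample_ids,
                     columns=[f"pfge_{j + 1:02d}" for j in range(spec.n_bands_virus)]),
        meta.copy())
    return host_bm, virus_bm


# ---------------------------------------------------------------------------
# inverse problem for the piecewise BCD law


@dataclass(frozen=True)
class BcdFit:
    """Least-squares fit of BCD = min(k*C^2, psi).

    ``crossover`` is the implied sqrt(psi/k).  A branch with fewer than
    two observations is flagged unidentifiable; its estimate is then
    essentially unconstrained by the data.
    """

    k: float
    psi: float
    crossover: float
    k_identifiable: bool
    psi_identifiable: bool
    residual_norm: float


def fit_bcd_curve(C, bcd_obs, init: tuple | None = None,
                  tol: float = 1e-12) -> BcdFit:
    """Recover (k, psi) of the piecewise carbon-demand law from data.

    Fits ``min(k*C**2, psi)`` to observed (ciliate biomass, BCD) pairs by
    nonlinear least squares in log-parameters (both strictly positive).
    Continuity at the crossover is built into the functional form.  Needs
    at least 4 pairs; identifiability of each branch is judged from how
    many observations fall on each side of the fitted crossover.
    """
    C = np.asarray(C, dtype=float)
    y = np.asarray(bcd_obs, dtype=float)
    if C.shape != y.shape or C.ndim != 1:
        raise ValueError("C and bcd_obs must be 1-D arrays of equal length")
    if len(C) < 4:
        raise ValueError("need at least 4 (C, BCD) pairs")
    if np.any(C <= 0) or np.any(y <= 0):
        raise ValueError("observations must be strictly positive")

    if init is None:
        psi0 = float(np.quantile(y, 0.9))
        low = C <= np.quantile(C, 0.4)
        k0 = float(np.median(y[low] / C[low] ** 2))
    else:
        k0, psi0 = init
        if k0 <= 0 or psi0 <= 0:
            raise ValueError("initial k and psi must be positive")

    def residuals(theta):
        k, psi = np.exp(theta)
        return np.minimum(k * C ** 2, psi) - y

    sol = least_squares(residuals, x0=np.log([k0, psi0]),
                        xtol=tol, ftol=tol, gtol=tol)
    k_hat, psi_hat = np.exp(sol.x)
    crossover = float(np.sqrt(psi_hat / k_hat))
    n_below = int(np.sum(C < crossover))
    n_above = len(C) - n_below
    return BcdFit(k=float(k_hat), psi=float(psi_hat), crossover=crossover,
                  k_identifiable=n_below >= 2, psi_identifiable=n_above >= 2,
                  residual_norm=float(np.linalg.norm(sol.fun)))
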