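"""Steady-state parameter estimation from continuation measurements.

The forward model's equilibria admit an analytic inverse: given a TetR level
and candidate parameters, the IPTG concentration that makes it an equilibrium
follows in closed form by unwinding the steady-state relations one Hill
function at a time.  A candidate parameter set is scored by the summed
squared distance (in normalized coordinates) between each measured steady
state and its nearest point on the candidate's predicted equilibrium curve;
candidates whose inversion leaves the real domain for the requested TetR grid
are discarded.  A seeded evolutionary (genetic-algorithm-style) search over
14 free parameters (degradation rates pinned) minimizes that cost.

The open-loop parameter sweep — stepping the inducer through fixed levels and
recording where the system settles — serves as the experimental baseline; it
only ever reaches stable branches, so model fits from sweep data alone tend
to miss the bistable structure that the controlled experiments expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .continuation import StepControl, continue_equilibria
from .model import (
    InputSchedule,
    ToggleParams,
    simulate_ode,
    simulate_sde,
    steady_state,
    TETR,
)

__all__ = [
    "THETA_FIELDS",
    "ThetaEstimate",
    "MeasuredPointSet",
    "GAConfig",
    "equilibrium_input",
    "predicted_curve",
    "estimation_cost",
    "estimate_parameters",
    "run_sweep",
    "check_bistability",
    "default_bounds",
]

#: the 14 free parameters, in conventional order
THETA_FIELDS = ("kLm0", "kLm", "thetaaTc", "etaaTc", "thetaTetR", "etaTetR",
                "kTm0", "kTm", "thetaIPTG", "etaIPTG", "thetaLacI", "etaLacI",
                "kLp", "kTp")

#: parameters held fixed at their nominal values during estimation
FIXED_FIELDS = ("gTm", "gLm", "gLp", "gTp")


@dataclass(frozen=True)
class ThetaEstimate:
    """A candidate value of the 14 free toggle parameters.

    Degradation/dilution rates are not part of the search; they stay pinned
    to the reference values of the base parameter set used in
    :meth:`to_params`.
    """

    kLm0: float
    kLm: float
    thetaaTc: float
    etaaTc: float
    thetaTetR: float
    etaTetR: float
    kTm0: float
    kTm: float
    thetaIPTG: float
    etaIPTG: float
    thetaLacI: float
    etaLacI: float
    kLp: float
    kTp: float

    def __post_init__(self):
        for name in THETA_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in THETA_FIELDS])

    @classmethod
    def from_array(cls, x) -> "ThetaEstimate":
        return cls(**dict(zip(THETA_FIELDS, np.asarray(x, dtype=float))))

    @classmethod
    def from_params(cls, p: ToggleParams) -> "ThetaEstimate":
        return cls(**{f: getattr(p, f) for f in THETA_FIELDS})

    def to_params(self, base: ToggleParams = ToggleParams()) -> ToggleParams:
        return base.replace(**{f: getattr(self, f) for f in THETA_FIELDS})


@dataclass
class MeasuredPointSet:
    """Measured (TetR_ss, IPTG_ss) pairs with provenance and the
    normalization constants used for costing (IPTG normalized into [0, 1] by
    the maximum applied input; TetR by the maximum measured level)."""

    TetR: np.ndarray
    IPTG: np.ndarray
    provenance: str = "cbc-p"          # cbc-p | cbc-mpc | sweep
    iptg_norm: float = 1.0
    tetr_norm: float | None = None

    def __post_init__(self):
        self.TetR = np.atleast_1d(np.asarray(self.TetR, dtype=float))
        self.IPTG = np.atleast_1d(np.asarray(self.IPTG, dtype=float))
        if len(self.TetR) != len(self.IPTG) or len(self.TetR) == 0:
            raise ValueError("need equal-length, nonempty TetR and IPTG records")
        if self.tetr_norm is None:
            self.tetr_norm = float(self.TetR.max())

    def __len__(self) -> int:
        return len(self.TetR)

    def normalized(self) -> np.ndarray:
        return np.column_stack([self.TetR / self.tetr_norm,
                                self.IPTG / self.iptg_norm])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"TetR_ss": self.TetR, "IPTG_ss": self.IPTG,
                             "provenance": self.provenance})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasuredPointSet":
        df = pd.read_csv(path)
        prov = df["provenance"].iloc[0] if "provenance" in df else "cbc-p"
        return cls(df["TetR_ss"].to_numpy(), df["IPTG_ss"].to_numpy(), prov)

    @classmethod
    def from_cbc(cls, result, provenance: str | None = None) -> "MeasuredPointSet":
        prov = provenance or f"cbc-{result.controller}"
        return cls(np.array([p.TetR_ss for p in result.points]),
                   np.array([p.IPTG_ss for p in result.points]), prov)


# ---------------------------------------------------------------------------
# Analytic equilibrium inverse
# ---------------------------------------------------------------------------

def equilibrium_input(TetR, theta: ThetaEstimate, aTc_ext: float = 25.0,
                      base: ToggleParams = ToggleParams()):
    """IPTG level that makes the given TetR an equilibrium, or NaN.

    Unwinds the steady state analytically: TetR fixes mRNA_TetR, which fixes
    the required repression level of the TetR promoter, hence the effective
    (IPTG-modulated) LacI; LacI itself follows from its own steady state
    given TetR and aTc; the Hill relation then yields IPTG.  Vectorized over
    TetR; any step leaving the positive real domain marks the entry invalid
    (NaN) rather than raising.
    """
    T = np.asarray(TetR, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T).astype(float)
    if (T <= 0).any():
        raise ValueError("TetR must be positive")
    gTm, gLm, gLp, gTp = base.gTm, base.gLm, base.gLp, base.gTp
    out = np.full(T.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mT = gTp * T / theta.kTp
        v = (gTm * mT - theta.kTm0) / theta.kTm           # required Hill value
        ok = (v > 0) & (v < 1)
        laci_eff = theta.thetaLacI * (1.0 / v - 1.0) ** (1.0 / theta.etaLacI)
        # LacI from its own steady state at this TetR and fixed aTc
        tetr_free = T / (1.0 + (aTc_ext / theta.thetaaTc) ** theta.etaaTc)
        mL = (theta.kLm0 + theta.kLm /
              (1.0 + (tetr_free / theta.thetaTetR) ** theta.etaTetR)) / gLm
        laci = theta.kLp * mL / gLp
        ratio = laci / laci_eff
        ok &= ratio > 1.0
        iptg = theta.thetaIPTG * (ratio - 1.0) ** (1.0 / theta.etaIPTG)
        out[ok] = iptg[ok]
    return float(out[0]) if scalar else out


def predicted_curve(theta: ThetaEstimate, TetR_grid, aTc_ext: float = 25.0,
                    iptg_norm: float = 1.0,
                    base: ToggleParams = ToggleParams()) -> np.ndarray:
    """Candidate equilibrium curve as (TetR, IPTG/iptg_norm) rows.

    Grid entries with no real positive inverse, or whose required input lies
    beyond the normalization constant (outside the explored input range), are
    dropped.  Raises if nothing remains.
    """
    T = np.atleast_1d(np.asarray(TetR_grid, dtype=float))
    iptg = equilibrium_input(T, theta, aTc_ext, base=base)
    keep = np.isfinite(iptg) & (iptg <= iptg_norm)
    if not keep.any():
        raise ValueError("no valid equilibrium inverse on the requested grid")
    return np.column_stack([T[keep], iptg[keep] / iptg_norm])


def estimation_cost(theta: ThetaEstimate, measured: MeasuredPointSet,
                    TetR_grid, aTc_ext: float = 25.0,
                    base: ToggleParams = ToggleParams()) -> float:
    """Sum of squared nearest-point distances, normalized coordinates.

    Each measured steady state is matched to its closest point on the
    candidate curve; parameter sets with no valid curve get a large penalty
    (the search treats them as discarded).
    """
    try:
        curve = predicted_curve(theta, TetR_grid, aTc_ext,
                                iptg_norm=measured.iptg_norm, base=base)
    except ValueError:
        return 1e6 * len(measured)
    curve_n = np.column_stack([curve[:, 0] / measured.tetr_norm, curve[:, 1]])
    pts = measured.normalized()
    d2 = ((pts[:, None, :] - curve_n[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


# ---------------------------------------------------------------------------
# Evolutionary search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Evolutionary-search budget for parameter estimation."""

    population: int = 105
    generations: int = 80
    tol: float = 1e-10


def default_bounds(base: ToggleParams = ToggleParams()) -> dict[str, tuple[float, float]]:
    """Search bounds: a factor of 10 around nominal for rates and thresholds,
    [1, 4] for Hill coefficients."""
    bounds = {}
    for f in THETA_FIELDS:
        nominal = getattr(base, f)
        if f.startswith("eta"):
            bounds[f] = (1.0, 4.0)
        else:
            bounds[f] = (0.1 * nominal, 10.0 * nominal)
    return bounds


def estimate_parameters(measured: MeasuredPointSet,
                        bounds: dict[str, tuple[float, float]] | None = None,
                        ga: GAConfig = GAConfig(), seed: int = 0,
                        aTc_ext: float = 25.0, grid_size: int = 400,
                        base: ToggleParams = ToggleParams()):
    """Seeded evolutionary minimization of the nearest-point curve cost.

    Rate and threshold parameters are searched on a log scale (their bounds
    span two decades); Hill coefficients on a linear scale.  Returns the best
    :class:`ThetaEstimate`, its cost, and the per-generation best-cost trace.
    """
    if bounds is None:
        bounds = default_bounds(base)
    grid = np.linspace(measured.TetR.min(), measured.TetR.max(), grid_size)
    grid = np.clip(grid, 1e-6, None)

    log_mask = np.array([not f.startswith("eta") for f in THETA_FIELDS])
    lo = np.array([bounds[f][0] for f in THETA_FIELDS])
    hi = np.array([bounds[f][1] for f in THETA_FIELDS])
    z_lo = np.where(log_mask, np.log10(lo), lo)
    z_hi = np.where(log_mask, np.log10(hi), hi)

    def decode(z):
        x = np.where(log_mask, 10.0 ** z, z)
        return ThetaEstimate.from_array(x)

    def cost(z):
        return estimation_cost(decode(z), measured, grid, aTc_ext, base=base)

    trace: list[float] = []

    def record(xk, convergence=None):
        trace.append(cost(xk))

    popsize = max(5, int(np.ceil(ga.population / len(THETA_FIELDS))))
    result = differential_evolution(
        cost, bounds=list(zip(z_lo, z_hi)),
        maxiter=ga.generations, popsize=popsize, tol=ga.tol,
        seed=seed, polish=True, init="latinhypercube",
        callback=record, updating="immediate",
    )
    return decode(result.x), float(result.fun), np.array(trace)


# ---------------------------------------------------------------------------
# Baseline sweep and bistability check
# ---------------------------------------------------------------------------

def run_sweep(params: ToggleParams, IPTG_levels, plant: str = "ode",
              directions: Sequence[str] = ("up", "down"),
              aTc_ext: float = 25.0, settle_min: float = 3000.0,
              sample_period: float = 5.0, seed: int = 0,
              dt: float = 0.1) -> MeasuredPointSet:
    """Open-loop parameter sweep: settle at each inducer level, record TetR.

    Levels are visited in ascending and/or descending order with the state
    carrying over, which exposes the hysteresis loop: inside the bistable
    window the two directions settle on different stable branches.  No
    unstable steady state can be observed this way.
    """
    levels = np.sort(np.asarray(IPTG_levels, dtype=float))
    tetr, iptg = [], []
    rng = np.random.default_rng(seed)
    for direction in directions:
        seq = levels if direction == "up" else levels[::-1]
        x = steady_state(params, aTc_ext, seq[0])
        for lv in seq:
            sched = InputSchedule(aTc=aTc_ext, IPTG=lv, period=sample_period)
            if plant == "ode":
                traj = simulate_ode(params, sched, x, settle_min,
                                    sample_period=sample_period)
            else:
                traj = simulate_sde(params, sched, x, settle_min, dt=dt,
                                    sample_period=sample_period, rng=rng)
            x = traj.states[-1]
            tail = traj.states[-12:, TETR]
            tetr.append(float(tail.mean()))
            iptg.append(float(lv))
    return MeasuredPointSet(np.array(tetr), np.array(iptg), provenance="sweep",
                            iptg_norm=max(1.0, levels.max()))


def check_bistability(theta: ThetaEstimate, aTc_ext: float = 25.0,
                      IPTG_bounds: tuple[float, float] = (0.0, 1.0),
                      base: ToggleParams = ToggleParams()) -> bool:
    """True iff the model with these parameters shows two folds at fixed aTc.

    Runs numerical continuation on the candidate model (degradation rates
    pinned); any continuation failure is reported as non-bistable with a
    warning rather than raised.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diagram = continue_equilibria(theta.to_params(base), aTc_ext,
                                          IPTG_bounds,
                                          step=StepControl(max_steps=2000))
    except Exception as exc:
        warnings.warn(f"continuation failed for candidate parameters: {exc}")
        return False
    return len(diagram.folds) == 2
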