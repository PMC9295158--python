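"""Deterministic and stochastic models of the inducible genetic toggle switch.

The circuit couples two mutually repressing genes, *lacI* and *tetR*.  Each
repressor is antagonized by a diffusible inducer: aTc sequesters TetR and IPTG
sequesters LacI.  The deterministic model tracks six states,

    (mRNA_LacI, mRNA_TetR, LacI, TetR, aTc_in, IPTG_in)

with Hill-type repression of transcription, first-order translation and
degradation/dilution, and asymmetric membrane exchange of the two inducers
(different influx and efflux rate constants).  Proteins and mRNAs are measured
in arbitrary fluorescence-calibrated units, aTc in ng/mL, IPTG in mM, time in
minutes.

The stochastic variant is a chemical Langevin equation built from the eight
biochemical pseudoreactions (two transcription, two translation, four
degradation events); inducer exchange is kept deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "STATE_NAMES",
    "ToggleParams",
    "ToggleState",
    "InputSchedule",
    "Trajectory",
    "hill",
    "hill_deriv",
    "toggle_rhs",
    "simulate_ode",
    "propensities",
    "STOICHIOMETRY",
    "simulate_sde",
    "jacobian",
    "jacobian_reduced",
    "steady_state",
    "find_equilibria",
    "IntegrationError",
    "ConvergenceError",
]

STATE_NAMES = ("mRNA_LacI", "mRNA_TetR", "LacI", "TetR", "aTc_in", "IPTG_in")

#: index of TetR (the controlled output) in the state vector
TETR = 3
LACI = 2


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the time of failure."""

    def __init__(self, message: str, t: float):
        super().__init__(message)
        self.t = t


class ConvergenceError(RuntimeError):
    """Root finding did not converge."""


@dataclass(frozen=True)
class ToggleParams:
    """Kinetic, Hill and membrane-exchange constants of the toggle switch.

    Defaults are the nominal values of the inducible toggle switch
    characterized in *E. coli* that this package models.  Transcription
    rates in mRNA/min, translation in a.u./(mRNA*min), degradation in 1/min,
    Hill thresholds in the units of their ligand (TetR and LacI thresholds in
    a.u., aTc in ng/mL, IPTG in mM), exchange rates in 1/min.
    """

    kLm0: float = 3.20e-2
    kTm0: float = 1.19e-1
    kLm: float = 8.30
    kTm: float = 2.06
    kLp: float = 9.726e-1
    kTp: float = 1.170
    gLm: float = 1.386e-1
    gTm: float = 1.386e-1
    gLp: float = 1.65e-2
    gTp: float = 1.65e-2
    thetaLacI: float = 31.94
    etaLacI: float = 2.00
    thetaIPTG: float = 9.06e-2
    etaIPTG: float = 2.00
    thetaTetR: float = 30.00
    etaTetR: float = 2.00
    thetaaTc: float = 11.65
    etaaTc: float = 2.00
    kIPTGin: float = 2.75e-2
    kIPTGout: float = 1.11e-1
    kaTcin: float = 1.62e-1
    kaTcout: float = 2.00e-2

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")

    def replace(self, **kwargs) -> "ToggleParams":
        return replace(self, **kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump({f.name: float(getattr(self, f.name)) for f in fields(self)},
                              sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ToggleParams":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls(**(data or {}))


class ToggleState(NamedTuple):
    """One point in state space; all components are nonnegative."""

    mRNA_LacI: float
    mRNA_TetR: float
    LacI: float
    TetR: float
    aTc_in: float
    IPTG_in: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, x) -> "ToggleState":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError("state vector must have 6 components")
        return cls(*x)


def _as_state_array(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise ValueError("state vector must have 6 components")
    return x


class InputSchedule:
    """Piecewise-constant external inducer levels on a fixed (5 min) grid.

    ``aTc`` and ``IPTG`` may each be a scalar (held constant) or a sequence of
    per-slot values; slot ``k`` covers ``[k*period, (k+1)*period)`` and the
    last value extends indefinitely.
    """

    def __init__(self, aTc=25.0, IPTG=0.0, period: float = 5.0):
        if period <= 0:
            raise ValueError("period must be positive")
        self.period = float(period)
        self.aTc = np.atleast_1d(np.asarray(aTc, dtype=float))
        self.IPTG = np.atleast_1d(np.asarray(IPTG, dtype=float))
        if (self.aTc < 0).any() or (self.IPTG < 0).any():
            raise ValueError("external inducer levels must be nonnegative")

    def at(self, t: float) -> tuple[float, float]:
        k = int(t / self.period + 1e-9)
        a = self.aTc[min(k, len(self.aTc) - 1)]
        i = self.IPTG[min(k, len(self.IPTG) - 1)]
        return float(a), float(i)


@dataclass
class Trajectory:
    """Sampled trajectory: times (min), states (n,6) and applied inputs (n,2).

    ``inputs[k]`` is the (aTc_ext, IPTG_ext) pair in force on the sampling
    interval starting at ``times[k]``.
    """

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray
    clamp_count: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.inputs = np.asarray(self.inputs, dtype=float)
        n = len(self.times)
        if self.states.shape[0] != n or self.inputs.shape[0] != n:
            raise ValueError("times, states and inputs must have equal length")
        if n > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.times)
        df["aTc_ext"] = self.inputs[:, 0]
        df["IPTG_ext"] = self.inputs[:, 1]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(),
                   df[list(STATE_NAMES)].to_numpy(),
                   df[["aTc_ext", "IPTG_ext"]].to_numpy())


# ---------------------------------------------------------------------------
# Hill kinetics and the vector field
# ---------------------------------------------------------------------------

def hill(x, theta: float, eta: float):
    """Decreasing Hill function ``1 / (1 + (x/theta)**eta)``.

    ``x`` may be scalar or array; returns values in (0, 1], equal to 1 at
    ``x = 0`` and 1/2 at ``x = theta``.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("hill: ligand concentration must be nonnegative")
    if theta <= 0 or eta <= 0:
        raise ValueError("hill: theta and eta must be positive")
    out = 1.0 / (1.0 + (x / theta) ** eta)
    return out if out.shape else float(out)


def hill_deriv(x, theta: float, eta: float):
    """d/dx of :func:`hill`; zero at x=0 for eta > 1."""
    x = np.asarray(x, dtype=float)
    h = 1.0 / (1.0 + (x / theta) ** eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(x > 0, -(eta / theta) * (x / theta) ** (eta - 1.0) * h * h, 0.0)
    return d if d.shape else float(d)


def _hill_ext(x, theta: float, eta: float):
    """Hill function extended evenly to negative arguments.

    Physical states are nonnegative; the even extension only matters for
    intermediate iterates of Newton-type solvers, which may momentarily step
    below zero, and coincides with :func:`hill` on the physical domain.
    """
    return 1.0 / (1.0 + (np.abs(x) / theta) ** eta)


def _regulated_rates(x: np.ndarray, p: ToggleParams) -> tuple[float, float]:
    """Transcription rates of the two mRNAs at internal inducer levels."""
    mL, mT, L, T, a, i = x
    tetr_free = T * _hill_ext(a, p.thetaaTc, p.etaaTc)
    laci_free = L * _hill_ext(i, p.thetaIPTG, p.etaIPTG)
    v_lac = p.kLm0 + p.kLm * _hill_ext(tetr_free, p.thetaTetR, p.etaTetR)
    v_tet = p.kTm0 + p.kTm * _hill_ext(laci_free, p.thetaLacI, p.etaLacI)
    return v_lac, v_tet


def toggle_rhs(x, aTc_ext: float, IPTG_ext: float, p: ToggleParams) -> np.ndarray:
    """Time derivative of the six-state toggle switch.

    Membrane exchange uses the influx rate constant when the external level
    exceeds the internal one and the efflux constant otherwise, in both cases
    multiplying (external - internal).
    """
    x = _as_state_array(x)
    mL, mT, L, T, a, i = x
    v_lac, v_tet = _regulated_rates(x, p)
    k_a = p.kaTcin if aTc_ext > a else p.kaTcout
    k_i = p.kIPTGin if IPTG_ext > i else p.kIPTGout
    return np.array([
        v_lac - p.gLm * mL,
        v_tet - p.gTm * mT,
        p.kLp * mL - p.gLp * L,
        p.kTp * mT - p.gTp * T,
        k_a * (aTc_ext - a),
        k_i * (IPTG_ext - i),
    ])


def jacobian(x, aTc_ext: float, IPTG_ext: float, p: ToggleParams) -> np.ndarray:
    """Analytic 6x6 Jacobian of :func:`toggle_rhs` with respect to the state.

    The exchange terms are piecewise linear in the internal inducer; the
    one-sided derivative consistent with the current sign of
    (external - internal) is used (efflux branch at equality).
    """
    x = _as_state_array(x)
    mL, mT, L, T, a, i = x

    def dh(x_, theta, eta):  # derivative of the evenly extended Hill function
        return float(np.sign(x_)) * hill_deriv(abs(x_), theta, eta)

    ha = _hill_ext(a, p.thetaaTc, p.etaaTc)
    hi = _hill_ext(i, p.thetaIPTG, p.etaIPTG)
    w_t = T * ha
    w_l = L * hi
    dh_t = dh(w_t, p.thetaTetR, p.etaTetR)
    dh_l = dh(w_l, p.thetaLacI, p.etaLacI)
    dha = dh(a, p.thetaaTc, p.etaaTc)
    dhi = dh(i, p.thetaIPTG, p.etaIPTG)
    k_a = p.kaTcin if aTc_ext > a else p.kaTcout
    k_i = p.kIPTGin if IPTG_ext > i else p.kIPTGout
    J = np.zeros((6, 6))
    J[0, 0] = -p.gLm
    J[0, 3] = p.kLm * dh_t * ha
    J[0, 4] = p.kLm * dh_t * T * dha
    J[1, 1] = -p.gTm
    J[1, 2] = p.kTm * dh_l * hi
    J[1, 5] = p.kTm * dh_l * L * dhi
    J[2, 0] = p.kLp
    J[2, 2] = -p.gLp
    J[3, 1] = p.kTp
    J[3, 3] = -p.gTp
    J[4, 4] = -k_a
    J[5, 5] = -k_i
    return J


def jacobian_reduced(y4, aTc_in: float, IPTG_in: float, p: ToggleParams) -> np.ndarray:
    """4x4 Jacobian of the biochemical subsystem at fixed internal inducers.

    Because the inducer rows of the full Jacobian do not depend on the
    biochemical states, the full spectrum is this block's eigenvalues plus the
    two (negative) exchange rates; stability is decided here.
    """
    x = np.concatenate([np.asarray(y4, dtype=float), [aTc_in, IPTG_in]])
    return jacobian(x, aTc_in, IPTG_in, p)[:4, :4]


# ---------------------------------------------------------------------------
# Deterministic simulation
# ---------------------------------------------------------------------------

def simulate_ode(p: ToggleParams, schedule: InputSchedule, x0, t_end: float,
                 sample_period: float = 5.0, rtol: float = 1e-7,
                 atol: float = 1e-9, method: str = "LSODA") -> Trajectory:
    """Integrate the deterministic model under a piecewise-constant schedule.

    Adaptive integration between samples; the returned trajectory is sampled
    on the ``sample_period`` grid and states are clipped of roundoff-level
    negative excursions.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = _as_state_array(x0)
    n = int(round(t_end / sample_period))
    times = np.arange(n + 1) * sample_period
    inputs = np.array([schedule.at(t) for t in times[:-1]] + [schedule.at(times[-1])])
    states = np.empty((n + 1, 6))
    states[0] = x0

    # group consecutive samples sharing the same input so each group is one
    # solve_ivp call
    k = 0
    x = x0.copy()
    while k < n:
        k2 = k
        while k2 + 1 < n and np.array_equal(inputs[k2 + 1], inputs[k]):
            k2 += 1
        a_e, i_e = inputs[k]
        t_eval = times[k:k2 + 2]
        sol = solve_ivp(lambda t, y: toggle_rhs(y, a_e, i_e, p),
                        (times[k], times[k2 + 1]), x, t_eval=t_eval[1:],
                        method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"integration failed near t={sol.t[-1] if len(sol.t) else times[k]:g} min: {sol.message}",
                                   t=float(sol.t[-1] if len(sol.t) else times[k]))
        states[k + 1:k2 + 2] = sol.y.T
        x = states[k2 + 1].copy()
        k = k2 + 1
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times, states, inputs)


# ---------------------------------------------------------------------------
# Chemical Langevin model
# ---------------------------------------------------------------------------

#: columns: transcription mRNA_LacI / mRNA_TetR, translation LacI / TetR,
#: degradation mRNA_LacI / mRNA_TetR / LacI / TetR
STOICHIOMETRY = np.array([
    [1, 0, 0, 0, -1, 0, 0, 0],
    [0, 1, 0, 0, 0, -1, 0, 0],
    [0, 0, 1, 0, 0, 0, -1, 0],
    [0, 0, 0, 1, 0, 0, 0, -1],
], dtype=float)


def propensities(x, p: ToggleParams) -> np.ndarray:
    """Eight reaction propensities at the given state (internal inducers taken
    from the state vector)."""
    x = _as_state_array(x)
    if (x < 0).any():
        raise ValueError("propensities: state components must be nonnegative")
    mL, mT, L, T, a, i = x
    v_lac, v_tet = _regulated_rates(x, p)
    return np.array([
        v_lac, v_tet,
        p.kLp * mL, p.kTp * mT,
        p.gLm * mL, p.gTm * mT,
        p.gLp * L, p.gTp * T,
    ])


def simulate_sde(p: ToggleParams, schedule: InputSchedule, x0, t_end: float,
                 dt: float = 0.1, sample_period: float = 5.0,
                 seed=None, rng: np.random.Generator | None = None,
                 noise_scale: float = 1.0) -> Trajectory:
    """Euler-Maruyama integration of the chemical Langevin toggle model.

    The four biochemical states evolve as dX = S a(X) dt + S diag(sqrt(a)) dW
    with eight independent Wiener increments; internal inducers follow the
    deterministic exchange dynamics.  States are clamped at zero after each
    step (the number of clamped components is reported on the trajectory).
    Identical seeds give bit-identical trajectories.
    """
    if dt <= 0 or dt > sample_period + 1e-12:
        raise ValueError("dt must be positive and at most the sample period")
    if rng is None:
        rng = np.random.default_rng(seed)
    x0 = _as_state_array(x0)
    n = int(round(t_end / sample_period))
    steps = int(round(sample_period / dt))
    times = np.arange(n + 1) * sample_period
    inputs = np.array([schedule.at(t) for t in times[:-1]] + [schedule.at(times[-1])])
    states = np.empty((n + 1, 6))
    states[0] = x0
    x = x0.copy()
    sqrt_dt = np.sqrt(dt)
    clamped = 0
    S = STOICHIOMETRY
    for k in range(n):
        a_e, i_e = inputs[k]
        for _ in range(steps):
            a = propensities(x, p)
            dW = rng.standard_normal(8) * sqrt_dt
            drift = S @ a
            diff = S @ (np.sqrt(a) * dW)
            x[:4] += drift * dt + noise_scale * diff
            k_a = p.kaTcin if a_e > x[4] else p.kaTcout
            k_i = p.kIPTGin if i_e > x[5] else p.kIPTGout
            x[4] += k_a * (a_e - x[4]) * dt
            x[5] += k_i * (i_e - x[5]) * dt
            neg = x < 0
            if neg.any():
                clamped += int(neg.sum())
                x[neg] = 0.0
        states[k + 1] = x
    return Trajectory(times, states, inputs, clamp_count=clamped)


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

def _rhs4(y4, aTc: float, iptg: float, p: ToggleParams) -> np.ndarray:
    x = np.concatenate([y4, [aTc, iptg]])
    return toggle_rhs(x, aTc, iptg, p)[:4]


def steady_state(p: ToggleParams, aTc_ext: float, IPTG_ext: float,
                 guess=None, tol: float = 1e-9) -> np.ndarray:
    """Newton-type equilibrium of the toggle switch at fixed external inducers.

    At any equilibrium the internal inducers equal the external levels, so the
    root is found on the 4-state biochemical subsystem and assembled into a
    full 6-state vector.  Raises :class:`ConvergenceError` if no root with
    residual norm below ``tol`` is found from the given guess.
    """
    if aTc_ext < 0 or IPTG_ext < 0:
        raise ValueError("external inducer levels must be nonnegative")
    if guess is None:
        # extreme-branch guesses: full derepression of one gene at a time
        mL_hi = (p.kLm0 + p.kLm) / p.gLm
        mT_hi = (p.kTm0 + p.kTm) / p.gTm
        guesses = [
            np.array([mL_hi, p.kTm0 / p.gTm,
                      p.kLp * mL_hi / p.gLp, p.kTp * p.kTm0 / p.gTm / p.gTp]),
            np.array([p.kLm0 / p.gLm, mT_hi,
                      p.kLp * p.kLm0 / p.gLm / p.gLp, p.kTp * mT_hi / p.gTp]),
            np.array([1.0, 1.0, 100.0, 100.0]),
        ]
    else:
        g = np.asarray(guess, dtype=float)
        guesses = [g[:4] if g.size >= 4 else g]
    res = np.inf
    for y0 in guesses:
        sol = root(_rhs4, y0, args=(aTc_ext, IPTG_ext, p),
                   jac=lambda y, a, i, q: jacobian_reduced(y, a, i, q),
                   method="hybr", tol=1e-13)
        y = np.abs(sol.x)  # equilibria are nonnegative; reflect stray signs
        res = np.linalg.norm(_rhs4(y, aTc_ext, IPTG_ext, p))
        if res <= tol:
            return np.concatenate([y, [aTc_ext, IPTG_ext]])
    raise ConvergenceError(
        f"steady_state did not converge (residual {res:.2e}); try a different guess")


def find_equilibria(p: ToggleParams, aTc_ext: float, IPTG_ext: float,
                    n_starts: int = 40, seed: int = 0,
                    atol: float = 1e-3) -> list[np.ndarray]:
    """Multi-start root finding; returns distinct equilibria sorted by TetR.

    Used as an independent oracle for the continuation module: the number of
    distinct roots changes 1 -> 3 -> 1 across each fold of the bistable
    window.
    """
    rng = np.random.default_rng(seed)
    # deterministic extreme guesses plus random log-uniform ones
    mL_hi = (p.kLm0 + p.kLm) / p.gLm
    mT_hi = (p.kTm0 + p.kTm) / p.gTm
    guesses = [
        np.array([mL_hi, p.kTm0 / p.gTm, p.kLp * mL_hi / p.gLp, p.kTp * p.kTm0 / p.gTm / p.gTp]),
        np.array([p.kLm0 / p.gLm, mT_hi, p.kLp * p.kLm0 / p.gLm / p.gLp, p.kTp * mT_hi / p.gTp]),
    ]
    for _ in range(n_starts - 2):
        fm = 10 ** rng.uniform(-2, 0.3, size=2)
        y = np.array([mL_hi * fm[0], mT_hi * fm[1], 0.0, 0.0])
        y[2] = p.kLp * y[0] / p.gLp
        y[3] = p.kTp * y[1] / p.gTp
        guesses.append(y)
    roots: list[np.ndarray] = []
    for g in guesses:
        try:
            x = steady_state(p, aTc_ext, IPTG_ext, g)
        except ConvergenceError:
            continue
        if not any(np.linalg.norm(x[:4] - r[:4]) / (1 + np.linalg.norm(r[:4])) < atol
                   for r in roots):
            roots.append(x)
    roots.sort(key=lambda r: r[TETR])
    return roots
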