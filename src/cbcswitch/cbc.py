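"""The control-based continuation loop.

Steps a control reference through the output range of interest, runs the
controlled plant one 5-min sampling interval at a time (the input is held
constant within each interval), declares steady state either after a fixed
dwell or by a slope test on the error and control signals, and records each
equilibrium as the 12-sample average of the output and the applied input.
Because the control input *is* the bifurcation parameter, a settled constant
input is noninvasive: the collected (TetR_ss, IPTG_ss) pair is an open-loop
equilibrium of the uncontrolled system.

A one-dimensional fold normal-form testbed (x' = mu + u - x^2) exercises the
same loop where the equilibrium curve is known in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .controllers import PController, PControllerConfig
from .model import (
    STOICHIOMETRY,
    ToggleParams,
    propensities,
    steady_state,
    toggle_rhs,
    LACI,
    TETR,
)

__all__ = [
    "CBCConfig",
    "CBCPoint",
    "CBCResult",
    "OdeTogglePlant",
    "SdeTogglePlant",
    "FoldPlant",
    "make_reference_schedule",
    "detect_steady_state",
    "collect_point",
    "run_cbc",
    "cbc_fold_demo",
]

log = logging.getLogger("cbcswitch.cbc")


def make_reference_schedule(start: float, end: float, n: int) -> np.ndarray:
    """n equally spaced reference values from start to end (descending by
    default when start > end)."""
    if n < 2:
        raise ValueError("need at least 2 reference points")
    return np.linspace(start, end, n)


def detect_steady_state(error_window, control_window,
                        tol_error: float, tol_control: float):
    """Least-squares slope test on the trailing error and control windows.

    Returns ``(steady, slope_error, slope_control)``; steady iff both slopes
    are below their tolerances in magnitude.  Slopes are per sample.
    """
    e = np.asarray(error_window, dtype=float)
    u = np.asarray(control_window, dtype=float)
    if len(e) < 2 or len(u) < 2:
        raise ValueError("windows must contain at least 2 samples")
    k_e = np.arange(len(e))
    k_u = np.arange(len(u))
    s_e = float(np.polyfit(k_e, e, 1)[0])
    s_u = float(np.polyfit(k_u, u, 1)[0])
    return (abs(s_e) < tol_error and abs(s_u) < tol_control), s_e, s_u


@dataclass
class CBCPoint:
    """One collected steady state: averaged output and input, the reference
    that produced it, dwell spent, and the plant state at collection time."""

    reference: float
    TetR_ss: float
    IPTG_ss: float
    dwell_min: float
    converged: bool
    state: np.ndarray | None = None


def collect_point(output_tail, input_tail, reference: float,
                  window: int = 12, dwell_min: float = 0.0,
                  converged: bool = True, state=None) -> CBCPoint:
    """Average the last ``window`` samples of output and applied input."""
    y = np.asarray(output_tail, dtype=float)
    u = np.asarray(input_tail, dtype=float)
    if len(y) < window or len(u) < window:
        raise ValueError(f"need at least {window} samples to collect a point")
    return CBCPoint(reference, float(y[-window:].mean()), float(u[-window:].mean()),
                    dwell_min, converged, state)


@dataclass(frozen=True)
class CBCConfig:
    """Continuation-experiment protocol settings.

    The default protocol matches the long-form experiments: 30 references from
    1800 a.u. down to 0, fixed dwell of 9 h 55 min per reference, 5-min
    sampling, and 12-sample steady-state averaging.  In ``detect`` dwell mode
    the reference advances as soon as the trailing-window slopes of the error
    and control signals drop below tolerance, checked after a 3-h minimum.
    """

    references: Sequence[float] | None = None
    start: float = 1800.0
    end: float = 0.0
    n_points: int = 30
    sample_period: float = 5.0
    dwell_mode: str = "fixed"          # "fixed" | "detect"
    dwell: float = 595.0               # 9 h 55 min
    min_dwell: float = 180.0
    detection_window: int = 12
    slope_tol_error: float = 0.5       # a.u. per sample
    slope_tol_control: float = 1e-4    # mM per sample
    averaging_window: int = 12
    seed: int | None = None

    def __post_init__(self):
        if self.references is None and self.n_points < 2:
            raise ValueError("need at least 2 reference points")
        if self.dwell_mode not in ("fixed", "detect"):
            raise ValueError("dwell_mode must be 'fixed' or 'detect'")
        max_win = int(self.dwell / self.sample_period)
        if self.detection_window > max_win or self.averaging_window > max_win:
            raise ValueError("windows must fit within the dwell")

    def reference_values(self) -> np.ndarray:
        if self.references is not None:
            return np.asarray(self.references, dtype=float)
        return make_reference_schedule(self.start, self.end, self.n_points)


@dataclass
class CBCResult:
    """Full outcome of one CBC experiment."""

    points: list[CBCPoint]
    times: np.ndarray
    outputs: np.ndarray          # measured outputs per sample
    inputs: np.ndarray           # applied control input per sample
    references: np.ndarray       # reference in force per sample
    states: np.ndarray | None    # full plant state per sample when available
    controller: str
    config: CBCConfig
    total_time_min: float

    @property
    def total_hours(self) -> float:
        return self.total_time_min / 60.0

    def points_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "reference": [p.reference for p in self.points],
            "TetR_ss": [p.TetR_ss for p in self.points],
            "IPTG_ss": [p.IPTG_ss for p in self.points],
            "converged": [p.converged for p in self.points],
            "dwell_min": [p.dwell_min for p in self.points],
        })

    def summary(self) -> dict:
        return {
            "controller": self.controller,
            "n_points": len(self.points),
            "total_simulated_hours": self.total_hours,
            "n_converged": int(sum(p.converged for p in self.points)),
        }


# ---------------------------------------------------------------------------
# Plants
# ---------------------------------------------------------------------------

class OdeTogglePlant:
    """Deterministic toggle-switch plant advanced one sampling interval at a
    time with the IPTG input held constant (aTc fixed)."""

    kind = "ode"

    def __init__(self, params: ToggleParams, aTc_ext: float = 25.0,
                 x0=None, rtol: float = 1e-7, atol: float = 1e-9):
        self.params = params
        self.aTc_ext = aTc_ext
        if x0 is None:
            x0 = steady_state(params, aTc_ext, 0.0)
        self.state = np.asarray(x0, dtype=float).copy()
        self.rtol, self.atol = rtol, atol

    def output(self) -> np.ndarray:
        return self.state[[LACI, TETR]].copy()

    def advance(self, iptg: float, dt: float) -> None:
        sol = solve_ivp(lambda t, y: toggle_rhs(y, self.aTc_ext, iptg, self.params),
                        (0.0, dt), self.state, method="LSODA",
                        rtol=self.rtol, atol=self.atol)
        self.state = np.clip(sol.y[:, -1], 0.0, None)


class SdeTogglePlant:
    """Chemical-Langevin toggle plant (Euler-Maruyama, seeded)."""

    kind = "sde"

    def __init__(self, params: ToggleParams, aTc_ext: float = 25.0, x0=None,
                 dt: float = 0.1, seed: int | None = 0,
                 rng: np.random.Generator | None = None):
        self.params = params
        self.aTc_ext = aTc_ext
        if x0 is None:
            x0 = steady_state(params, aTc_ext, 0.0)
        self.state = np.asarray(x0, dtype=float).copy()
        self.dt = dt
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.clamp_count = 0

    def output(self) -> np.ndarray:
        return self.state[[LACI, TETR]].copy()

    def advance(self, iptg: float, dt: float) -> None:
        p = self.params
        x = self.state
        steps = int(round(dt / self.dt))
        h = self.dt
        sqrt_h = np.sqrt(h)
        S = STOICHIOMETRY
        for _ in range(steps):
            a = propensities(x, p)
            dW = self.rng.standard_normal(8) * sqrt_h
            x[:4] += (S @ a) * h + S @ (np.sqrt(a) * dW)
            k_a = p.kaTcin if self.aTc_ext > x[4] else p.kaTcout
            k_i = p.kIPTGin if iptg > x[5] else p.kIPTGout
            x[4] += k_a * (self.aTc_ext - x[4]) * h
            x[5] += k_i * (iptg - x[5]) * h
            neg = x < 0
            if neg.any():
                self.clamp_count += int(neg.sum())
                x[neg] = 0.0


class FoldPlant:
    """Fold normal form x' = mu + u - x**2 (scalar testbed).

    Advanced by fixed-step RK4 substeps; the open-loop divergence rate near
    the unstable branch is O(2 sqrt(mu)) per unit time, so sampled feedback
    must run well below that time scale (see :func:`cbc_fold_demo`).
    """

    kind = "fold"

    def __init__(self, mu: float, x0: float | None = None, max_step: float = 0.01):
        self.mu = mu
        self.state = np.array([np.sqrt(mu) if x0 is None else x0], dtype=float)
        self.max_step = max_step

    def output(self) -> np.ndarray:
        return self.state.copy()

    def advance(self, u: float, dt: float) -> None:
        n = max(1, int(np.ceil(dt / self.max_step)))
        h = dt / n
        x = float(self.state[0])
        f = lambda x_: self.mu + u - x_ * x_
        for _ in range(n):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        self.state[0] = x


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def run_cbc(plant, controller, cfg: CBCConfig = CBCConfig()) -> CBCResult:
    """Run the full control-based continuation experiment.

    For each reference value, sampling intervals are iterated (controller
    evaluation, then plant advance with the input held) until the dwell
    elapses (fixed mode) or the steady-state slope test fires after the
    minimum dwell; a point is then collected as the averaging-window mean of
    the output and applied input, and the plant state carries over to the
    next reference.  A controller failure aborts the run with the partial
    result attached to the raised exception.
    """
    refs = cfg.reference_values()
    sp = cfg.sample_period
    n_max = int(round(cfg.dwell / sp))
    n_min = int(round(cfg.min_dwell / sp))
    window = cfg.detection_window

    times, outputs, inputs, ref_log, states = [], [], [], [], []
    points: list[CBCPoint] = []
    has_state = hasattr(plant, "state")
    t = 0.0

    def partial_result() -> CBCResult:
        return CBCResult(points, np.array(times),
                         np.array(outputs), np.array(inputs), np.array(ref_log),
                         np.array(states) if has_state else None,
                         getattr(controller, "name", "custom"), cfg, t)

    for ref in refs:
        y_hist: list[float] = []
        u_hist: list[float] = []
        k = 0
        steady = False
        while True:
            y = plant.output()
            try:
                u = controller.step(ref, y)
            except Exception as exc:
                exc.partial_result = partial_result()
                raise
            times.append(t)
            outputs.append(y)
            inputs.append(u)
            ref_log.append(ref)
            if has_state:
                states.append(np.atleast_1d(plant.state).copy())
            y_hist.append(float(np.atleast_1d(y)[-1]))
            u_hist.append(u)
            plant.advance(u, sp)
            k += 1
            t += sp
            if cfg.dwell_mode == "detect" and k >= max(n_min, window):
                err_win = ref - np.array(y_hist[-window:])
                steady, _, _ = detect_steady_state(err_win, u_hist[-window:],
                                                   cfg.slope_tol_error,
                                                   cfg.slope_tol_control)
            if steady or k >= n_max:
                break
        if not steady:  # report convergence of the fixed-dwell tail too
            err_win = ref - np.array(y_hist[-window:])
            steady, _, _ = detect_steady_state(err_win, u_hist[-window:],
                                               cfg.slope_tol_error,
                                               cfg.slope_tol_control)
        pt = collect_point(y_hist, u_hist, ref, cfg.averaging_window,
                           dwell_min=k * sp, converged=bool(steady),
                           state=np.atleast_1d(plant.state).copy() if has_state else None)
        points.append(pt)
        controller.register_steady_input(pt.IPTG_ss)
        log.info("reference %.1f: dwell %.0f min, converged=%s, "
                 "TetR_ss=%.2f, IPTG_ss=%.5f",
                 ref, pt.dwell_min, pt.converged, pt.TetR_ss, pt.IPTG_ss)
    return partial_result()


def cbc_fold_demo(mu: float = 1.0, Kp: float | None = None,
                  references: Sequence[float] | None = None,
                  dwell: float = 25.0, sample_period: float = 0.05):
    """CBC on the fold normal form; returns collected points with the shifted
    parameter.

    Each collected point reports the steady state ``x_ss``, the settled
    control ``u_ss`` and the effective bifurcation parameter
    ``mu_eff = mu + u_ss``; on the equilibrium curve ``x_ss**2 = mu_eff``
    on both the stable (x > 0) and unstable (x < 0) branches.  The gain must
    exceed ``2*sqrt(mu_eff)`` along the path; the default is comfortably
    above it.
    """
    s = np.sqrt(mu)
    if Kp is None:
        Kp = 6.0 * s
    if references is None:
        references = np.linspace(1.3 * s, -1.1 * s, 13)
    plant = FoldPlant(mu)
    ctrl = PController(PControllerConfig(Kp=Kp, input_bounds=(-10.0 * mu - 10.0,
                                                              10.0 * mu + 10.0)))
    cfg = CBCConfig(references=list(references), sample_period=sample_period,
                    dwell_mode="fixed", dwell=dwell,
                    min_dwell=min(60.0, dwell / 2),
                    averaging_window=12, detection_window=12)
    result = run_cbc(plant, ctrl, cfg)
    pts = [(p.TetR_ss, mu + p.IPTG_ss, p.IPTG_ss) for p in result.points]
    return pts, result
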