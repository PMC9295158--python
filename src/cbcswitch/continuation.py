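"""Model-based numerical continuation of toggle-switch equilibria.

Traces the S-shaped equilibrium curve TetR(IPTG) at fixed aTc with a
pseudo-arclength predictor-corrector, classifies stability from the Jacobian
spectrum, and locates the two saddle-node (fold) bifurcations that bound the
bistable window.  This curve is the model-based reference against which
control-based continuation measurements are compared.

The continuation runs on the 4-state biochemical subsystem with the internal
inducers pinned to their external values, which is exact at equilibrium and
removes the two always-stable exchange directions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import ToggleParams, TETR, _rhs4, jacobian_reduced, steady_state

__all__ = [
    "EquilibriumPoint",
    "FoldPoint",
    "BifurcationDiagram",
    "continue_curve",
    "continue_equilibria",
    "detect_folds",
    "classify_stability",
    "StepControl",
]


@dataclass(frozen=True)
class StepControl:
    """Arclength step-size policy (steps are in scaled coordinates)."""

    initial: float = 0.01
    minimum: float = 1e-5
    maximum: float = 0.05
    grow: float = 1.3
    shrink: float = 0.5
    max_steps: int = 3000


@dataclass
class EquilibriumPoint:
    """One equilibrium on the curve: parameter value, full 6-state vector,
    stability label and the leading (largest real part) eigenvalue."""

    IPTG: float
    state: np.ndarray
    stability: str
    leading_eigenvalue: float

    @property
    def TetR(self) -> float:
        return float(self.state[TETR])


@dataclass
class FoldPoint:
    IPTG: float
    TetR: float
    state: np.ndarray


def classify_stability(J: np.ndarray, marginal_tol: float = 1e-9) -> tuple[str, float]:
    """Stability from the Jacobian spectrum.

    Returns ``(label, leading_real_part)`` with label ``stable`` when every
    eigenvalue has negative real part, ``unstable`` otherwise, and
    ``marginal`` when the leading real part sits within ``marginal_tol`` of
    zero.
    """
    lead = float(np.max(np.linalg.eigvals(J).real))
    if abs(lead) <= marginal_tol:
        return "marginal", lead
    return ("stable" if lead < 0 else "unstable"), lead


@dataclass
class BifurcationDiagram:
    """Ordered equilibrium points along arclength plus fold markers."""

    points: list[EquilibriumPoint]
    folds: list[FoldPoint]
    aTc: float = 25.0
    complete: bool = True

    @property
    def IPTG(self) -> np.ndarray:
        return np.array([p.IPTG for p in self.points])

    @property
    def TetR(self) -> np.ndarray:
        return np.array([p.TetR for p in self.points])

    @property
    def stability(self) -> np.ndarray:
        return np.array([p.stability for p in self.points])

    def branch_slices(self) -> list[slice]:
        """Maximal runs of the point list on which IPTG is monotone."""
        p = self.IPTG
        if len(p) < 3:
            return [slice(0, len(p))]
        sgn = np.sign(np.diff(p))
        sgn[sgn == 0] = 1
        cuts = [0] + [i + 1 for i in range(len(sgn) - 1) if sgn[i + 1] != sgn[i]] + [len(p)]
        return [slice(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b - a >= 2]

    def tetr_at(self, iptg: float) -> np.ndarray:
        """TetR value of every branch crossing the given IPTG (interpolated)."""
        out = []
        p, t = self.IPTG, self.TetR
        for sl in self.branch_slices():
            pb, tb = p[sl], t[sl]
            lo, hi = min(pb[0], pb[-1]), max(pb[0], pb[-1])
            if lo - 1e-12 <= iptg <= hi + 1e-12:
                order = np.argsort(pb)
                out.append(float(np.interp(iptg, pb[order], tb[order])))
        return np.array(sorted(out))

    def roots_at(self, iptg: float, params: ToggleParams) -> np.ndarray:
        """TetR of every branch crossing the given IPTG, polished to machine
        precision by a Newton solve seeded from the interpolated branch state."""
        out = []
        p = self.IPTG
        states = np.array([pt.state for pt in self.points])
        for sl in self.branch_slices():
            pb = p[sl]
            lo, hi = min(pb[0], pb[-1]), max(pb[0], pb[-1])
            if lo - 1e-12 <= iptg <= hi + 1e-12:
                order = np.argsort(pb)
                guess = np.array([np.interp(iptg, pb[order], states[sl][order, j])
                                  for j in range(4)])
                x = steady_state(params, self.aTc, iptg, guess)
                out.append(float(x[TETR]))
        return np.array(sorted(out))

    def distance_to(self, tetr, iptg, tetr_scale: float | None = None,
                    iptg_scale: float = 1.0) -> np.ndarray:
        """Distance of measured (TetR, IPTG) pairs to the curve polyline in
        normalized coordinates (TetR by the diagram maximum unless given,
        IPTG by ``iptg_scale``)."""
        ts = tetr_scale if tetr_scale is not None else float(self.TetR.max())
        P = np.column_stack([self.TetR / ts, self.IPTG / iptg_scale])
        Q = np.column_stack([np.atleast_1d(tetr) / ts, np.atleast_1d(iptg) / iptg_scale])
        A, B = P[:-1], P[1:]
        AB = B - A
        denom = (AB ** 2).sum(axis=1)
        denom[denom == 0] = 1.0
        d = np.empty(len(Q))
        for i, q in enumerate(Q):
            tpar = np.clip(((q - A) * AB).sum(axis=1) / denom, 0.0, 1.0)
            proj = A + tpar[:, None] * AB
            d[i] = np.sqrt(((proj - q) ** 2).sum(axis=1).min())
        return d

    def to_frame(self) -> pd.DataFrame:
        states = np.array([p.state for p in self.points])
        df = pd.DataFrame({
            "IPTG": self.IPTG,
            "mRNA_LacI": states[:, 0],
            "mRNA_TetR": states[:, 1],
            "LacI": states[:, 2],
            "TetR": states[:, 3],
            "stability": self.stability,
        })
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def fold_summary(self) -> dict:
        return {"aTc": self.aTc,
                "n_folds": len(self.folds),
                "folds": [{"IPTG": f.IPTG, "TetR": f.TetR} for f in self.folds]}

    def fold_summary_json(self, path=None) -> str:
        text = json.dumps(self.fold_summary(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Generic pseudo-arclength predictor-corrector
# ---------------------------------------------------------------------------

def _numjac(F: Callable, z: np.ndarray, f0: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    J = np.empty((len(f0), len(z)))
    for j in range(len(z)):
        dz = eps * max(1.0, abs(z[j]))
        zp = z.copy()
        zp[j] += dz
        J[:, j] = (F(zp) - f0) / dz
    return J


def continue_curve(F: Callable[[np.ndarray, float], np.ndarray],
                   y0: np.ndarray, p0: float,
                   p_bounds: tuple[float, float],
                   scales: np.ndarray,
                   step: StepControl = StepControl(),
                   jac: Callable | None = None,
                   corrector_tol: float = 1e-11,
                   direction: int = +1):
    """Pseudo-arclength continuation of ``F(y, p) = 0`` from ``(y0, p0)``.

    Works in scaled coordinates ``u = (y, p) / scales`` so that arclength
    steps are balanced across states and parameter.  Returns
    ``(points, tangents, complete)`` where points are ``(y, p)`` tuples and
    tangents the unit predictor directions in scaled coordinates; ``complete``
    is False when the run stopped on the step budget or minimum step size.

    The curve is followed from the starting point towards increasing
    (``direction=+1``) or decreasing (``-1``) ``p`` and terminates once ``p``
    leaves ``p_bounds`` (after any folds have been traversed).
    """
    y0 = np.asarray(y0, dtype=float)
    scales = np.asarray(scales, dtype=float)
    ny = len(y0)

    def Fu(u: np.ndarray) -> np.ndarray:
        z = u * scales
        return F(z[:ny], z[ny])

    def tangent(u: np.ndarray, prev: np.ndarray | None) -> np.ndarray:
        f0 = Fu(u)
        if jac is not None:
            z = u * scales
            J = jac(z[:ny], z[ny]) * scales[None, :]
        else:
            J = _numjac(Fu, u, f0)
        _, _, Vt = np.linalg.svd(J)
        t = Vt[-1]
        if prev is None:
            if direction * t[ny] < 0:  # orient the first step
                t = -t
        elif np.dot(t, prev) < 0:
            t = -t
        return t / np.linalg.norm(t)

    u = np.concatenate([y0, [p0]]) / scales
    t = tangent(u, None)
    points = [(u[:ny] * scales[:ny], u[ny] * scales[ny])]
    tangents = [t]
    ds = step.initial
    complete = True
    for _ in range(step.max_steps):
        accepted = False
        while ds >= step.minimum:
            u_pred = u + ds * t

            def G(v):
                return np.concatenate([Fu(v), [np.dot(t, v - u_pred)]])

            sol = root(G, u_pred, method="hybr", tol=1e-13)
            ok = sol.success and np.linalg.norm(Fu(sol.x)) < corrector_tol
            if ok:
                accepted = True
                break
            ds *= step.shrink
        if not accepted:
            warnings.warn("continuation stopped: step size below minimum")
            complete = False
            break
        u_new = sol.x
        t = tangent(u_new, t)
        u = u_new
        points.append((u[:ny] * scales[:ny], u[ny] * scales[ny]))
        tangents.append(t)
        ds = min(ds * step.grow, step.maximum)
        p = u[ny] * scales[ny]
        if p > p_bounds[1] + 1e-12 or p < p_bounds[0] - 1e-12:
            # land the final point exactly on the boundary
            pb = p_bounds[1] if p > p_bounds[1] else p_bounds[0]
            sol_b = root(lambda y: F(y, pb), u[:ny] * scales[:ny],
                         method="hybr", tol=1e-13)
            if sol_b.success:
                points[-1] = (sol_b.x, pb)
            break
    else:
        warnings.warn("continuation stopped: maximum number of steps reached")
        complete = False
    return points, tangents, complete


def detect_folds(points, tangents, F, ny: int,
                 jac_y: Callable | None = None,
                 F_full=None) -> list[tuple[np.ndarray, float]]:
    """Folds of a continued curve: sign changes of the tangent's parameter
    component, refined by a bordered (Moore-Spence) Newton solve on the
    augmented system  F(y,p)=0,  J_y(y,p) v = 0,  ||v||^2 = 1.

    Returns refined ``(y, p)`` fold locations.  The refinement localizes the
    fold far below the 1e-5 parameter resolution of the detection bracket.
    """
    if len(points) < 3:
        return []
    folds = []
    for i in range(len(tangents) - 1):
        if tangents[i][ny] * tangents[i + 1][ny] < 0:
            y_b, p_b = points[i]
            Jy = (jac_y(y_b, p_b) if jac_y is not None
                  else _numjac(lambda y: F(y, p_b), y_b, F(y_b, p_b)))
            _, _, Vt = np.linalg.svd(Jy)
            v0 = Vt[-1]

            def MS(z):
                y, p, v = z[:ny], z[ny], z[ny + 1:]
                Jy_ = (jac_y(y, p) if jac_y is not None
                       else _numjac(lambda w: F(w, p), y, F(y, p)))
                return np.concatenate([F(y, p), Jy_ @ v, [v @ v - 1.0]])

            sol = root(MS, np.concatenate([y_b, [p_b], v0]), method="hybr", tol=1e-13)
            if sol.success:
                folds.append((sol.x[:ny], float(sol.x[ny])))
            else:  # fall back to the bracket midpoint
                y2, p2 = points[i + 1]
                folds.append(((y_b + y2) / 2, float((p_b + p2) / 2)))
    return folds


# ---------------------------------------------------------------------------
# Toggle-switch specialization
# ---------------------------------------------------------------------------

def continue_equilibria(p: ToggleParams, aTc_ext: float = 25.0,
                        IPTG_bounds: tuple[float, float] = (0.0, 1.0),
                        step: StepControl = StepControl(),
                        guess=None) -> BifurcationDiagram:
    """Trace the full equilibrium curve TetR(IPTG) at fixed aTc.

    Starts from the equilibrium at the lower IPTG bound and follows the curve
    upward through both folds.  Every returned point satisfies the steady
    state residual contract; stability is classified from the biochemical
    Jacobian block.
    """
    lo, hi = IPTG_bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("IPTG_bounds must satisfy 0 <= lo < hi <= 1")
    x_start = steady_state(p, aTc_ext, lo, guess=guess)
    y0 = x_start[:4]

    F = lambda y, par: _rhs4(y, aTc_ext, par, p)
    jac_ext = None

    def jac_full(y, par):
        Jy = jacobian_reduced(y, aTc_ext, par, p)
        # d rhs4 / d IPTG at internal == parameter (regulation channel only)
        eps = 1e-7 * max(1.0, abs(par))
        col = (F(y, par + eps) - F(y, par)) / eps
        return np.column_stack([Jy, col])

    # scales: mRNAs by their maximal levels, proteins by 1000-ish, IPTG by 0.25
    scales = np.array([
        (p.kLm0 + p.kLm) / p.gLm,
        (p.kTm0 + p.kTm) / p.gTm,
        (p.kLm0 + p.kLm) / p.gLm * p.kLp / p.gLp,
        1000.0,
        0.25,
    ])
    pts, tans, complete = continue_curve(F, y0, lo, IPTG_bounds, scales,
                                         step=step, jac=jac_full)
    fold_raw = detect_folds(pts, tans, F, ny=4,
                            jac_y=lambda y, par: jacobian_reduced(y, aTc_ext, par, p))
    points = []
    for y, par in pts:
        par_c = min(max(par, 0.0), 1.0)
        J = jacobian_reduced(y, aTc_ext, par_c, p)
        label, lead = classify_stability(J)
        points.append(EquilibriumPoint(float(par_c),
                                       np.concatenate([y, [aTc_ext, par_c]]),
                                       label, lead))
    folds = [FoldPoint(par, float(y[TETR]), np.concatenate([y, [aTc_ext, par]]))
             for y, par in fold_raw]
    folds.sort(key=lambda f: f.IPTG)
    return BifurcationDiagram(points, folds, aTc=aTc_ext, complete=complete)
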