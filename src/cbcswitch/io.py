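"""Configuration, result serialization and plotting glue.

A single YAML file configures a whole run: model-parameter overrides, plant
mode, controller choice and settings, continuation-experiment protocol and
estimation budget.  Unknown keys are rejected so typos fail loudly.  Results
are written with deterministic file names plus a JSON summary carrying the
seed and a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cbc import CBCConfig, CBCResult
from .continuation import BifurcationDiagram
from .controllers import MPCConfig, PControllerConfig
from .estimation import GAConfig, MeasuredPointSet, ThetaEstimate, THETA_FIELDS
from .model import ToggleParams

__all__ = ["RunConfig", "load_config", "write_results", "plot_diagram"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CBCSettings(_Strict):
    start: float = 1800.0
    end: float = 0.0
    n_points: int = Field(default=30, ge=2)
    sample_period: float = Field(default=5.0, gt=0)
    dwell_mode: Literal["fixed", "detect"] = "fixed"
    dwell: float = Field(default=595.0, gt=0)
    min_dwell: float = Field(default=180.0, gt=0)
    detection_window: int = Field(default=12, ge=2)
    slope_tol_error: float = Field(default=0.5, gt=0)
    slope_tol_control: float = Field(default=1e-4, gt=0)
    averaging_window: int = Field(default=12, ge=1)

    def build(self, seed=None) -> CBCConfig:
        return CBCConfig(seed=seed, **self.model_dump())


class PSettings(_Strict):
    kp: float = 0.0016
    input_bounds: tuple[float, float] = (0.0, 1.0)

    @field_validator("kp")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("kp must be positive")
        return v

    def build(self) -> PControllerConfig:
        return PControllerConfig(Kp=self.kp, input_bounds=self.input_bounds)


class MPCSettings(_Strict):
    horizon: int = Field(default=144, ge=1)
    gamma: float = Field(default=0.3, gt=0, le=1)
    population: int = Field(default=40, ge=4)
    generations: int = Field(default=30, ge=1)
    input_bounds: tuple[float, float] = (0.0, 1.0)
    u_init: float = 1.0
    id_order: int = Field(default=2, ge=1)
    id_seed: int = 1
    id_duration: float = Field(default=6000.0, gt=0)

    def build(self, seed=None, aTc_ext: float = 25.0) -> MPCConfig:
        return MPCConfig(horizon=self.horizon, gamma=self.gamma,
                         population=self.population, generations=self.generations,
                         seed=self.id_seed if seed is None else seed,
                         input_bounds=self.input_bounds, u_init=self.u_init,
                         aTc_ext=aTc_ext)


class EstimationSettings(_Strict):
    population: int = Field(default=105, ge=10)
    generations: int = Field(default=80, ge=1)
    grid_size: int = Field(default=400, ge=10)

    def build(self) -> GAConfig:
        return GAConfig(population=self.population, generations=self.generations)


class RunConfig(_Strict):
    """Complete run configuration; every field has a working default."""

    params: dict[str, float] = Field(default_factory=dict)
    aTc_ext: float = Field(default=25.0, ge=0)
    plant: Literal["ode", "sde"] = "ode"
    sde_dt: float = Field(default=0.1, gt=0)
    controller: Literal["p", "mpc"] = "p"
    p: PSettings = Field(default_factory=PSettings)
    mpc: MPCSettings = Field(default_factory=MPCSettings)
    cbc: CBCSettings = Field(default_factory=CBCSettings)
    estimation: EstimationSettings = Field(default_factory=EstimationSettings)
    seed: int = 0
    outdir: str = "results"

    def toggle_params(self) -> ToggleParams:
        return ToggleParams().replace(**self.params)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; an empty file (or missing
    keys) yields all defaults, unknown keys raise with the offending name."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**(data or {}))


def write_results(result, outdir, seed=None, config: RunConfig | None = None) -> list[str]:
    """Serialize a result object into ``outdir``; returns the file manifest.

    Dispatches on type: CBC results produce a points CSV, trajectory CSV and
    summary JSON; bifurcation diagrams a curve CSV and fold-summary JSON;
    parameter estimates a JSON file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _write_json(name, payload):
        path = out / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        manifest.append(str(path))

    meta = {"seed": seed}
    if config is not None:
        meta["config_hash"] = config.config_hash()
        meta["config"] = config.model_dump()

    if isinstance(result, CBCResult):
        pts = out / "cbc_points.csv"
        result.points_frame().to_csv(pts, index=False)
        manifest.append(str(pts))
        traj = out / "cbc_trajectory.csv"
        import pandas as pd
        df = pd.DataFrame({"time_min": result.times,
                           "reference": result.references,
                           "IPTG_applied": result.inputs})
        outs = np.atleast_2d(result.outputs)
        names = ["LacI", "TetR"] if outs.shape[1] == 2 else [f"y{i}" for i in range(outs.shape[1])]
        for j, nm in enumerate(names):
            df[nm] = outs[:, j]
        df.to_csv(traj, index=False)
        manifest.append(str(traj))
        _write_json("cbc_summary.json", {**result.summary(), **meta})
    elif isinstance(result, BifurcationDiagram):
        curve = out / "bifurcation_diagram.csv"
        result.to_csv(curve)
        manifest.append(str(curve))
        _write_json("fold_summary.json", {**result.fold_summary(), **meta})
    elif isinstance(result, ThetaEstimate):
        _write_json("theta_estimate.json",
                    {"theta": {f: getattr(result, f) for f in THETA_FIELDS}, **meta})
    elif isinstance(result, MeasuredPointSet):
        pts = out / f"points_{result.provenance}.csv"
        result.to_csv(pts)
        manifest.append(str(pts))
    else:
        raise TypeError(f"do not know how to serialize {type(result).__name__}")

    _write_json("manifest.json", {"files": sorted(set(manifest))})
    return sorted(set(manifest))


def plot_diagram(diagram: BifurcationDiagram, points=None, path=None):
    """Equilibrium curve TetR(IPTG) with stability styling and optional
    measured points; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sl in diagram.branch_slices():
        seg_stab = diagram.stability[sl]
        style = "--" if (seg_stab == "unstable").mean() < 0.5 else "-"
        color = "tab:red" if (seg_stab == "unstable").mean() >= 0.5 else "tab:gray"
        ax.plot(diagram.IPTG[sl], diagram.TetR[sl], style, color=color, lw=1.5)
    for f in diagram.folds:
        ax.plot(f.IPTG, f.TetR, "k*", ms=10)
    if points is not None:
        tetr, iptg = points
        ax.plot(iptg, tetr, "o", color="tab:blue", ms=4, alpha=0.7)
    ax.set_xlabel("IPTG (mM)")
    ax.set_ylabel("TetR (a.u.)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
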