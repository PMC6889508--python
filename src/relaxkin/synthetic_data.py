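"""Seeded generators emulating the instrument data the fitters consume.

Stopped-flow trace sets are produced by evaluating a global kinetic
model's Arrhenius laws at each temperature of an experiment design,
propagating the exact transient at each ligand concentration, censoring
the dead time, and adding seeded homoscedastic Gaussian noise scaled to
the total signal change. Denaturation and titration curves come from the
corresponding equilibrium models plus the same noise treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from relaxkin.equilibrium_assays import (
    DenaturationCurve,
    DenaturationParams,
    TitrationCurve,
    TitrationParams,
    _denaturation_signal,
)
from relaxkin.global_fit import GlobalKineticModel
from relaxkin.kinetics_core import ObservableModel, Trace, simulate_trace

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "gen_stopped_flow_dataset",
    "gen_denaturation_curve",
    "gen_titration_curve",
]

#: default temperature grid, 5-30 C in 5 K steps
DEFAULT_TEMPS = (278.15, 283.15, 288.15, 293.15, 298.15, 303.15)
#: default ligand grid, uM (tens of uM, pseudo-first-order regime)
DEFAULT_LIGANDS = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, sd = ``fraction`` of the total signal change."""

    fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("noise fraction must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.fraction == 0:
            return signal
        scale = float(np.ptp(signal))
        if scale == 0:
            scale = max(abs(float(signal[0])), 1.0)
        return signal + rng.normal(0.0, self.fraction * scale, size=signal.shape)


@dataclass(frozen=True)
class ExperimentDesign:
    """Grid layout of a stopped-flow experiment.

    Logarithmic time grids resolve the fast phase while still sampling
    the approach to the asymptote; ``duration=None`` auto-scales each
    trace to five times the slowest relaxation of its cell.
    """

    ligands: tuple[float, ...] = DEFAULT_LIGANDS
    temperatures: tuple[float, ...] = DEFAULT_TEMPS
    points_per_trace: int = 400
    duration: float | None = None
    dead_time: float = 1e-3

    def __post_init__(self) -> None:
        if not self.ligands or not self.temperatures:
            raise ValueError("ligand and temperature grids must be nonempty")
        if any(l < 0 for l in self.ligands):
            raise ValueError("ligand concentrations must be >= 0")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be > 0 K")
        if self.points_per_trace < 10:
            raise ValueError("need at least 10 points per trace")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.duration is not None and self.duration <= self.dead_time:
            raise ValueError("duration must exceed the dead time")

    def time_grid(self, slowest_rate: float) -> np.ndarray:
        end = self.duration if self.duration is not None else 5.0 / slowest_rate
        start = max(self.dead_time, 1e-5)
        if end <= start:
            end = 10.0 * start
        return np.geomspace(start, end, self.points_per_trace)


def gen_stopped_flow_dataset(
    model: GlobalKineticModel,
    obs: ObservableModel | None = None,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
) -> list[Trace]:
    """One seeded transient per (ligand, temperature) cell of the design.

    Rate constants are evaluated per temperature from the model's
    Arrhenius laws; traces are exact matrix-exponential propagations with
    dead-time censoring, plus additive Gaussian noise from a single
    generator seeded once (so the full dataset is reproducible
    bit-for-bit under a fixed seed).
    """
    obs = obs if obs is not None else ObservableModel()
    design = design if design is not None else ExperimentDesign()
    noise = noise if noise is not None else NoiseModel()
    rng = noise.rng()
    traces: list[Trace] = []
    for T in design.temperatures:
        mech = model.mechanism_at(T)
        for L in design.ligands:
            rates = model.predicted_relaxations(L, T)
            slowest = min(r for r in rates if r > 0)
            grid = design.time_grid(slowest)
            trace = simulate_trace(
                mech, obs, L, grid, dead_time=design.dead_time, temperature=T
            )
            signal = noise.apply(trace.signal, rng)
            traces.append(
                Trace(
                    time=trace.time,
                    signal=signal,
                    ligand_conc=L,
                    temperature=T,
                    dead_time=design.dead_time,
                )
            )
    return traces


def gen_denaturation_curve(
    params: DenaturationParams,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    temperature: float = 293.15,
) -> DenaturationCurve:
    """Two-state LEM curve on a denaturant grid plus seeded noise."""
    noise = noise if noise is not None else NoiseModel()
    if grid is None:
        grid = np.linspace(0.0, max(2.0 * params.midpoint, params.midpoint + 1.5), 25)
    d = np.asarray(grid, dtype=float)
    if d.size == 0:
        raise ValueError("denaturant grid must be nonempty")
    signal = _denaturation_signal(params, d, temperature)
    signal = noise.apply(signal, noise.rng())
    return DenaturationCurve(denaturant=d, signal=signal, temperature=temperature)


def gen_titration_curve(
    params: TitrationParams,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> TitrationCurve:
    """Hyperbolic titration curve on a concentration grid plus seeded noise."""
    noise = noise if noise is not None else NoiseModel()
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(params.Kd / 8, 8 * params.Kd, 14)])
    c = np.asarray(grid, dtype=float)
    if c.size == 0:
        raise ValueError("concentration grid must be nonempty")
    signal = params.predict(c)
    signal = noise.apply(signal, noise.rng())
    return TitrationCurve(concentration=c, signal=signal)
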