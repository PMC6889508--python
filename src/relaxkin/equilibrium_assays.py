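"""Two-state chemical denaturation and hyperbolic cation-titration fitting.

Denaturation follows the linear extrapolation model (LEM): the folding
free energy is linear in denaturant, dG_fold(D) = m * (D50 - D), so the
unfolded fraction is a logistic in D centered at the midpoint D50. The
observed fluorescence interpolates between linear folded and unfolded
baselines. Cation titrations are fit to a rectangular hyperbola
F = F0 + dFmax * [X] / (Kd + [X]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from relaxkin.global_fit import GAS_CONSTANT_KCAL

__all__ = [
    "DenaturationCurve",
    "DenaturationParams",
    "TitrationCurve",
    "TitrationParams",
    "fraction_unfolded",
    "fit_denaturation",
    "stabilization_shift",
    "fit_titration",
    "affinity_fold_change",
]

#: assay temperature for denaturation, K (20 C)
DENATURATION_T = 293.15


@dataclass(frozen=True)
class DenaturationCurve:
    """Fluorescence vs denaturant concentration (GuHCl, molar)."""

    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = DENATURATION_T

    def __post_init__(self) -> None:
        d = np.asarray(self.denaturant, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "signal", s)
        if d.ndim != 1 or s.ndim != 1 or d.size != s.size:
            raise ValueError("denaturant and signal must be 1-D arrays of equal length")
        if d.size < 8:
            raise ValueError("denaturation curve needs at least 8 points")
        if np.any(d < 0):
            raise ValueError("denaturant concentrations must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("denaturant grid must be increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class DenaturationParams:
    """Two-state LEM parameters with linear fluorescence baselines.

    ``midpoint`` is [GuHCl]50 in M, ``m_value`` in kcal/mol/M; each
    baseline is (intercept, slope) in signal units (per M for the slope).
    """

    midpoint: float
    m_value: float
    folded_baseline: tuple[float, float] = (1.0, 0.0)
    unfolded_baseline: tuple[float, float] = (0.0, 0.0)
    stderr: tuple[float, ...] | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError("midpoint must be > 0")
        if self.m_value <= 0:
            raise ValueError("m_value must be > 0")


@dataclass(frozen=True)
class TitrationCurve:
    """Fluorescence vs cation concentration (mM)."""

    concentration: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "signal", s)
        if c.ndim != 1 or s.ndim != 1 or c.size != s.size:
            raise ValueError("concentration and signal must be 1-D arrays of equal length")
        if c.size < 6:
            raise ValueError("titration curve needs at least 6 points")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class TitrationParams:
    """Hyperbolic binding parameters: Kd (mM), F0 and dFmax (a.u.)."""

    Kd: float
    F0: float
    dFmax: float
    stderr: tuple[float, ...] | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.F0 + self.dFmax * c / (self.Kd + c)


def fraction_unfolded(
    params: DenaturationParams, D: float | np.ndarray, T: float = DENATURATION_T
) -> float | np.ndarray:
    """Unfolded fraction at denaturant D under the two-state LEM.

    fU = 1 / (1 + exp(dG_fold(D) / RT)) with
    dG_fold(D) = m * (midpoint - D); exactly 0.5 at D = midpoint and
    strictly increasing in D.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("denaturant concentration must be >= 0")
    dg = params.m_value * (params.midpoint - D)
    out = 1.0 / (1.0 + np.exp(dg / (GAS_CONSTANT_KCAL * T)))
    return float(out) if out.ndim == 0 else out


def _denaturation_signal(params: DenaturationParams, D: np.ndarray, T: float) -> np.ndarray:
    fu = fraction_unfolded(params, D, T)
    fb = params.folded_baseline[0] + params.folded_baseline[1] * D
    ub = params.unfolded_baseline[0] + params.unfolded_baseline[1] * D
    return (1.0 - fu) * fb + fu * ub


def fit_denaturation(curve: DenaturationCurve) -> DenaturationParams:
    """Least-squares fit of the two-state LEM with linear baselines.

    Parameters: midpoint, m-value, folded/unfolded baseline intercepts
    and slopes. A curve with no resolvable transition (flat signal or
    midpoint outside the data) is returned with ``converged=False``
    rather than raising.
    """
    D = curve.denaturant
    y = curve.signal
    T = curve.temperature
    span = float(np.ptp(y))
    n_edge = max(2, D.size // 5)
    f0, u0 = float(np.mean(y[:n_edge])), float(np.mean(y[-n_edge:]))
    # midpoint guess: crossing of the half-signal level
    half = 0.5 * (f0 + u0)
    idx = int(np.argmin(np.abs(y - half)))
    x0 = np.array([max(D[idx], 1e-3), 2.0, f0, 0.0, u0, 0.0])

    def resid(p: np.ndarray) -> np.ndarray:
        mid, m, fb0, fb1, ub0, ub1 = p
        params = DenaturationParams(
            midpoint=max(mid, 1e-9),
            m_value=max(m, 1e-9),
            folded_baseline=(fb0, fb1),
            unfolded_baseline=(ub0, ub1),
        )
        return _denaturation_signal(params, D, T) - y

    lo = np.array([1e-6, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf])
    hi = np.full(6, np.inf)
    sol = optimize.least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf")
    mid, m, fb0, fb1, ub0, ub1 = sol.x
    rss = float(2.0 * sol.cost)
    dof = D.size - 6
    se = _stderr(sol.jac, rss, dof)

    converged = bool(sol.success)
    # no transition: amplitude indistinguishable from baseline noise or
    # midpoint escaping the sampled range
    amp = abs((fb0 + fb1 * mid) - (ub0 + ub1 * mid))
    if span < 1e-12 or amp < 1e-6 * max(span, 1e-12) or not (D[0] <= mid <= D[-1]):
        converged = False
    return DenaturationParams(
        midpoint=float(max(mid, 1e-9)),
        m_value=float(max(m, 1e-9)),
        folded_baseline=(float(fb0), float(fb1)),
        unfolded_baseline=(float(ub0), float(ub1)),
        stderr=tuple(se),
        converged=converged,
    )


def stabilization_shift(apo: DenaturationParams, bound: DenaturationParams) -> float:
    """Midpoint shift on ligand binding, midpoint(bound) - midpoint(apo).

    Sign is preserved: destabilization on binding yields a negative shift.
    """
    if not (apo.converged and bound.converged):
        raise ValueError("both denaturation fits must have converged")
    return bound.midpoint - apo.midpoint


def fit_titration(curve: TitrationCurve) -> TitrationParams:
    """Fit F = F0 + dFmax * [X] / (Kd + [X]) by least squares.

    A curve with no curvature (constant signal) leaves Kd unidentifiable
    and is returned with ``converged=False``.
    """
    c = curve.concentration
    y = curve.signal
    span = float(np.ptp(y))
    f0_guess = float(y[np.argmin(c)])
    df_guess = float(y[np.argmax(c)] - f0_guess)
    kd_guess = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0

    def resid(p: np.ndarray) -> np.ndarray:
        kd, f0, df = p
        return f0 + df * c / (max(kd, 1e-12) + c) - y

    lo = np.array([1e-12, -np.inf, -np.inf])
    hi = np.full(3, np.inf)
    x0 = np.clip([kd_guess, f0_guess, df_guess], lo, hi)
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
    kd, f0, df = sol.x
    rss = float(2.0 * sol.cost)
    dof = c.size - 3
    se = _stderr(sol.jac, rss, dof)
    converged = bool(sol.success)
    if span < 1e-12 or abs(df) < 1e-6 * max(span, 1e-12) or not np.isfinite(se[0]):
        converged = False
    return TitrationParams(
        Kd=float(max(kd, 1e-12)),
        F0=float(f0),
        dFmax=float(df),
        stderr=tuple(se),
        converged=converged,
    )


def affinity_fold_change(kd_variant: float, kd_reference: float) -> float:
    """Ratio kd_variant / kd_reference (dimensionless, > 1 means weaker)."""
    if kd_variant <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_variant / kd_reference


def _stderr(jac: np.ndarray, rss: float, dof: int) -> np.ndarray:
    try:
        jtj = jac.T @ jac
        if np.linalg.cond(jtj) > 1e12:
            return np.full(jac.shape[1], np.inf)
        cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        return np.sqrt(np.abs(np.diag(cov)))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.inf)
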