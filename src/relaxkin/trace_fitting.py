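"""Exponential fitting of individual transients and model-count selection.

Each transient is fit by unweighted least squares to

    signal(t) = baseline + sum_i A_i * exp(-alpha_i * t),   i = 1..n

with n = 1 or 2. The choice between one and two exponentials follows a
nested F-test on the residual sum of squares plus identifiability guards
(both rates positive and separated, finite standard errors) — a concrete,
reproducible stand-in for instrument-software residual analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from relaxkin.kinetics_core import RelaxationSpectrum, Trace

__all__ = [
    "ExponentialFit",
    "fit_exponentials",
    "choose_exponential_count",
    "extract_relaxation_profile",
    "PROFILE_COLUMNS",
]

PROFILE_COLUMNS = ["ligand_uM", "temp_K", "alpha1_s", "alpha2_s", "a1", "a2", "n_exp"]


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a 1- or 2-exponential least-squares fit."""

    spectrum: RelaxationSpectrum
    rss: float
    dof: int
    stderr: tuple[float, ...]  # same ordering as (baseline, A1, alpha1[, A2, alpha2])
    converged: bool

    @property
    def n_exponentials(self) -> int:
        return len(self.spectrum.rates)


def _model(t: np.ndarray, params: np.ndarray, n: int) -> np.ndarray:
    out = np.full_like(t, params[0])
    for i in range(n):
        out = out + params[1 + 2 * i] * np.exp(-params[2 + 2 * i] * t)
    return out


def _initial_guess(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Baseline from the tail, rate from the 1-1/e crossing time."""
    n_tail = max(3, t.size // 20)
    baseline = float(np.mean(y[-n_tail:]))
    a_total = float(y[0] - baseline)
    span = t[-1] - t[0]
    if abs(a_total) < 1e-12 * max(1.0, abs(baseline)):
        rate = 1.0 / max(span, 1e-12)
        a_total = 0.0
    else:
        # time at which 1 - 1/e of the total change has occurred
        frac = np.abs(y - baseline) <= abs(a_total) / np.e
        idx = np.argmax(frac) if frac.any() else t.size - 1
        t_e = max(t[idx] - t[0], span / t.size)
        rate = 1.0 / t_e
    if n == 1:
        return np.array([baseline, a_total, rate])
    return np.array([baseline, 0.5 * a_total, 5.0 * rate, 0.5 * a_total, rate])


def fit_exponentials(trace: Trace, n: int = 1) -> ExponentialFit:
    """Fit ``baseline + sum A_i exp(-alpha_i t)`` to a transient.

    Rates are constrained positive and returned sorted descending.
    Non-convergence (including unidentifiable rates on degenerate input)
    is reported through the ``converged`` flag, never as an exception;
    only a trace too short for the parameter count raises.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    n_params = 1 + 2 * n
    t = trace.time
    y = trace.signal
    if t.size <= n_params + 1:
        raise ValueError(f"need more than {n_params + 1} points for a {n}-exponential fit")
    # shift time origin so amplitudes refer to the first recorded point
    t0 = t[0]
    ts = t - t0
    x0 = _initial_guess(ts, y, n)
    lo = np.full(n_params, -np.inf)
    hi = np.full(n_params, np.inf)
    for i in range(n):
        lo[2 + 2 * i] = 1e-12
    x0 = np.clip(x0, lo, hi)

    def resid(p: np.ndarray) -> np.ndarray:
        return _model(ts, p, n) - y

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
    rss = float(2.0 * sol.cost)
    dof = t.size - n_params
    stderr = _stderr_from_jacobian(sol.jac, rss, dof)

    converged = bool(sol.success)
    scale = max(float(np.ptp(y)), 1e-30)
    rates = [float(sol.x[2 + 2 * i]) for i in range(n)]
    amps = [float(sol.x[1 + 2 * i]) for i in range(n)]
    # unidentifiable: negligible amplitude or rate pinned at a bound
    for a, r, se_r in zip(amps, rates, stderr[2::2]):
        if abs(a) < 1e-9 * scale or not np.isfinite(se_r) or r <= 2e-12:
            converged = False

    order = np.argsort(rates)[::-1]
    rates_sorted = [max(rates[i], 1e-12) for i in order]
    amps_sorted = [amps[i] for i in order]
    degenerate = n == 2 and np.isclose(rates_sorted[0], rates_sorted[1])
    if n == 2 and rates_sorted[0] <= rates_sorted[1] and not degenerate:
        degenerate = True
    # amplitudes were fitted against t - t0; refer them back to t = 0
    # (clamped: a runaway rate would overflow the extrapolation factor)
    amps_t0 = [
        a * np.exp(min(r * t0, 700.0)) for a, r in zip(amps_sorted, rates_sorted)
    ]
    spectrum = RelaxationSpectrum(
        rates=tuple(rates_sorted),
        amplitudes=tuple(amps_t0),
        baseline=float(sol.x[0]),
        degenerate=degenerate,
    )
    return ExponentialFit(
        spectrum=spectrum, rss=rss, dof=dof, stderr=tuple(stderr), converged=converged
    )


def _stderr_from_jacobian(jac: np.ndarray, rss: float, dof: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    n_params = jac.shape[1]
    try:
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else np.nan)
        se = np.sqrt(np.abs(np.diag(cov)))
        # singular directions show up as huge variances; mark them infinite
        if np.linalg.cond(jtj) > 1e12:
            se[:] = np.inf
        return se
    except np.linalg.LinAlgError:
        return np.full(n_params, np.inf)


def choose_exponential_count(
    trace: Trace, alpha_level: float = 0.01
) -> tuple[int, ExponentialFit, ExponentialFit | None]:
    """Decide between 1 and 2 exponentials by residual analysis.

    Returns ``(count, fit1, fit2)``; ``fit2`` is ``None`` when the trace
    is too short to attempt it. Two exponentials are accepted only when
    the nested F-test rejects the single-exponential model at
    ``alpha_level`` *and* the second phase is identifiable: both rates
    positive and distinct (ratio > 1.5) with finite standard errors.
    """
    fit1 = fit_exponentials(trace, 1)
    try:
        fit2 = fit_exponentials(trace, 2)
    except ValueError:
        return 1, fit1, None
    if not fit1.converged:
        warnings.warn("single-exponential fit did not converge; returning count 1")
        return 1, fit1, fit2
    if not fit2.converged or fit2.spectrum.degenerate:
        return 1, fit1, fit2

    extra = fit1.dof - fit2.dof
    if fit2.rss <= 0 or fit2.dof <= 0 or extra <= 0:
        return 1, fit1, fit2
    f_stat = ((fit1.rss - fit2.rss) / extra) / (fit2.rss / fit2.dof)
    if f_stat <= 0:
        return 1, fit1, fit2
    p_value = float(stats.f.sf(f_stat, extra, fit2.dof))

    r_fast, r_slow = fit2.spectrum.rates
    ratio_ok = r_slow > 0 and (r_fast / r_slow) > 1.5
    se_ok = all(np.isfinite(se) for se in fit2.stderr)
    if p_value < alpha_level and ratio_ok and se_ok:
        return 2, fit1, fit2
    return 1, fit1, fit2


def extract_relaxation_profile(
    traces: list[Trace], alpha_level: float = 0.01
) -> pd.DataFrame:
    """Fit every transient and tabulate rates vs ligand and temperature.

    One row per trace (replicates retained), columns
    ``ligand_uM, temp_K, alpha1_s, alpha2_s, a1, a2, n_exp``, sorted by
    temperature then ligand concentration. ``alpha2_s``/``a2`` are NaN
    for single-relaxation rows.
    """
    rows = []
    for trace in traces:
        count, fit1, fit2 = choose_exponential_count(trace, alpha_level=alpha_level)
        fit = fit2 if count == 2 else fit1
        spec = fit.spectrum
        rows.append(
            {
                "ligand_uM": trace.ligand_conc,
                "temp_K": trace.temperature,
                "alpha1_s": spec.rates[0],
                "alpha2_s": spec.rates[1] if count == 2 else np.nan,
                "a1": spec.amplitudes[0],
                "a2": spec.amplitudes[1] if count == 2 else np.nan,
                "n_exp": count,
            }
        )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    if not df.empty:
        df = df.sort_values(["temp_K", "ligand_uM"], kind="stable").reset_index(drop=True)
    return df
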