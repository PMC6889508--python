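"""Global Arrhenius fitting of relaxation profiles and derived thermodynamics.

Every rate constant of the chosen binding scheme is written as

    k(T) = k0 * exp{-(E/R) * (1/T - 1/T0)}

with k0 the value at the reference temperature T0 and E the activation
energy, and all relaxation rates in a (ligand, temperature) profile are
fit simultaneously by unweighted least squares. Binding thermodynamics
follow from the fitted laws: Kd = koff/kon, dG = RT ln Kd (1 M standard
state), dH = Eon - Eoff, dS = (dH - dG)/T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from relaxkin.kinetics_core import MechanismCS, MechanismLK, cs_relaxations

__all__ = [
    "GAS_CONSTANT_KCAL",
    "T0_DEFAULT",
    "ArrheniusLaw",
    "GlobalKineticModel",
    "ThermoSummary",
    "arrhenius_eval",
    "fit_global",
    "derive_thermo",
    "discriminate_mechanism",
    "MechanismCall",
]

#: gas constant, kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.9872e-3
#: reference temperature, K (15 C)
T0_DEFAULT = 288.15

_RATE_NAMES = {"cs": ("k12", "k21", "kon", "koff"), "lk": ("kon", "koff")}


@dataclass(frozen=True)
class ArrheniusLaw:
    """Temperature law of one rate constant.

    ``k0`` is the rate at the reference temperature ``T0`` (units of the
    rate constant it parameterizes); ``E`` is the activation energy in
    kcal/mol, unrestricted in sign.
    """

    k0: float
    E: float
    T0: float = T0_DEFAULT

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be > 0, got {self.T0}")

    def __call__(self, T: float) -> float:
        return arrhenius_eval(self, T)


def arrhenius_eval(law: ArrheniusLaw, T: float | np.ndarray) -> float | np.ndarray:
    """k(T) = k0 exp{-(E/R)(1/T - 1/T0)}."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0 K")
    out = law.k0 * np.exp(-(law.E / GAS_CONSTANT_KCAL) * (1.0 / T - 1.0 / law.T0))
    return float(out) if out.ndim == 0 else out


@dataclass
class GlobalKineticModel:
    """Arrhenius laws for every rate constant of a binding scheme.

    ``kind`` is ``"cs"`` (conformational selection: k12, k21, kon, koff)
    or ``"lk"`` (lock-and-key: kon, koff). Fit diagnostics are attached
    by :func:`fit_global`.
    """

    kind: str
    laws: dict[str, ArrheniusLaw]
    rss: float | None = None
    dof: int | None = None
    stderr: dict[str, tuple[float, float]] = field(default_factory=dict)
    covariance: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _RATE_NAMES:
            raise ValueError(f"kind must be 'cs' or 'lk', got {self.kind!r}")
        expected = set(_RATE_NAMES[self.kind])
        if set(self.laws) != expected:
            raise ValueError(f"laws must cover exactly {sorted(expected)}")
        t0s = {law.T0 for law in self.laws.values()}
        if len(t0s) != 1:
            raise ValueError("all laws must share the same reference temperature")

    @property
    def T0(self) -> float:
        return next(iter(self.laws.values())).T0

    def mechanism_at(self, T: float) -> MechanismCS | MechanismLK:
        """Rate constants evaluated at temperature T."""
        k = {name: arrhenius_eval(law, T) for name, law in self.laws.items()}
        if self.kind == "cs":
            return MechanismCS(**k)
        return MechanismLK(**k)

    def predicted_relaxations(self, L: float, T: float) -> tuple[float, ...]:
        m = self.mechanism_at(T)
        if self.kind == "cs":
            return cs_relaxations(m, L)
        return (m.koff + m.kon * L,)


@dataclass(frozen=True)
class ThermoSummary:
    """Binding thermodynamics at one evaluation temperature.

    Kd in uM; dG and dH in kcal/mol; dS in cal/mol/K. The identity
    dG = dH - T*dS holds by construction.
    """

    Kd: float
    dG: float
    dH: float
    dS: float
    T: float

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be > 0")
        if abs(self.dG - (self.dH - self.T * self.dS / 1000.0)) > 1e-9:
            raise ValueError("dG = dH - T*dS identity violated")


def derive_thermo(model: GlobalKineticModel, T: float = T0_DEFAULT) -> ThermoSummary:
    """Kd, dG, dH, dS of binding from the fitted kon/koff laws.

    Kd = koff/kon evaluated at T (uM); dG = RT ln(Kd in M) against the
    1 M standard state; dH = Eon - Eoff; dS = (dH - dG)/T in cal/mol/K.
    """
    kon = arrhenius_eval(model.laws["kon"], T)
    koff = arrhenius_eval(model.laws["koff"], T)
    kd_um = koff / kon
    dG = GAS_CONSTANT_KCAL * T * np.log(kd_um * 1e-6)
    dH = model.laws["kon"].E - model.laws["koff"].E
    dS = (dH - dG) / T * 1000.0
    return ThermoSummary(Kd=kd_um, dG=dG, dH=dH, dS=dS, T=T)


def _pack(model_kind: str, laws: dict[str, ArrheniusLaw]) -> np.ndarray:
    names = _RATE_NAMES[model_kind]
    return np.concatenate([[np.log(laws[n].k0), laws[n].E] for n in names])


def _unpack(model_kind: str, theta: np.ndarray, T0: float) -> dict[str, ArrheniusLaw]:
    names = _RATE_NAMES[model_kind]
    laws = {}
    for i, n in enumerate(names):
        laws[n] = ArrheniusLaw(k0=float(np.exp(theta[2 * i])), E=float(theta[2 * i + 1]), T0=T0)
    return laws


def _profile_arrays(profile: pd.DataFrame) -> tuple[np.ndarray, ...]:
    L = profile["ligand_uM"].to_numpy(float)
    T = profile["temp_K"].to_numpy(float)
    a1 = profile["alpha1_s"].to_numpy(float)
    a2 = profile["alpha2_s"].to_numpy(float) if "alpha2_s" in profile else np.full_like(a1, np.nan)
    return L, T, a1, a2


def _initial_laws(kind: str, profile: pd.DataFrame, T0: float) -> dict[str, ArrheniusLaw]:
    """Crude per-temperature linear fits of alpha1 vs L seed kon/koff."""
    L, T, a1, _ = _profile_arrays(profile)
    slopes, intercepts = [], []
    for t in np.unique(T):
        sel = T == t
        if sel.sum() >= 2 and np.ptp(L[sel]) > 0:
            b, a = np.polyfit(L[sel], a1[sel], 1)
            slopes.append(max(b, 1e-6))
            intercepts.append(max(a, 1e-6))
    kon0 = float(np.median(slopes)) if slopes else 1.0
    koff0 = float(np.median(intercepts)) if intercepts else 1.0
    laws = {
        "kon": ArrheniusLaw(k0=kon0, E=5.0, T0=T0),
        "koff": ArrheniusLaw(k0=koff0, E=10.0, T0=T0),
    }
    if kind == "cs":
        a2_med = float(np.nanmedian(profile["alpha2_s"].to_numpy(float)))
        if not np.isfinite(a2_med) or a2_med <= 0:
            a2_med = 0.1 * koff0
        laws["k12"] = ArrheniusLaw(k0=0.5 * a2_med, E=5.0, T0=T0)
        laws["k21"] = ArrheniusLaw(k0=0.5 * a2_med, E=5.0, T0=T0)
    return laws


def _cs_candidate_laws(profile: pd.DataFrame, T0: float) -> list[dict[str, ArrheniusLaw]]:
    """Moment-based starting points for the conformational-selection fit.

    The sum and product of the two relaxations are both linear in [L]:
    sum = (k12+k21+koff) + kon*L and product = (k12+k21)*koff + k12*kon*L,
    which pins kon and k12 but leaves koff and k12+k21 as the two roots
    of one quadratic — an assignment ambiguity that the two returned
    candidates resolve by trying both branches.
    """
    rows = profile[profile["n_exp"] == 2] if "n_exp" in profile else profile
    if rows.empty:
        return []
    # moments are linear in L only at fixed temperature: seed from the
    # temperature closest to T0
    temps = rows["temp_K"].to_numpy(float)
    t_seed = temps[np.argmin(np.abs(temps - T0))]
    rows = rows[rows["temp_K"] == t_seed]
    L = rows["ligand_uM"].to_numpy(float)
    a1 = rows["alpha1_s"].to_numpy(float)
    a2 = rows["alpha2_s"].to_numpy(float)
    ok = np.isfinite(a1) & np.isfinite(a2)
    L, a1, a2 = L[ok], a1[ok], a2[ok]
    if L.size < 4 or np.unique(L).size < 2:
        return []
    s_slope, s_int = np.polyfit(L, a1 + a2, 1)
    p_slope, p_int = np.polyfit(L, a1 * a2, 1)
    kon = max(s_slope, 1e-9)
    k12 = max(p_slope / kon, 1e-9)
    # koff + (k12+k21) = s_int and koff * (k12+k21) = p_int, so the two
    # are roots of x^2 - s_int*x + p_int with an unresolved assignment
    disc = s_int * s_int - 4.0 * p_int
    if disc < 0:
        roots = (0.5 * s_int, 0.5 * s_int)
    else:
        r = np.sqrt(disc)
        roots = (0.5 * (s_int - r), 0.5 * (s_int + r))
    candidates = []
    for koff in roots:
        other = s_int - koff  # = k12 + k21
        k21 = other - k12
        if koff <= 0 or k21 <= 0:
            continue
        candidates.append(
            {
                "k12": ArrheniusLaw(k0=k12, E=5.0, T0=T0),
                "k21": ArrheniusLaw(k0=max(k21, 1e-9), E=5.0, T0=T0),
                "kon": ArrheniusLaw(k0=kon, E=5.0, T0=T0),
                "koff": ArrheniusLaw(k0=koff, E=5.0, T0=T0),
            }
        )
    return candidates


def fit_global(
    profile: pd.DataFrame,
    kind: str = "lk",
    T0: float = T0_DEFAULT,
    initial: dict[str, ArrheniusLaw] | None = None,
) -> GlobalKineticModel:
    """Fit all relaxations over (L, T) with Arrhenius-parameterized rates.

    Every observed rate in ``profile`` (columns as produced by
    :func:`relaxkin.trace_fitting.extract_relaxation_profile`) enters one
    unweighted residual; rows with two rates contribute both under a
    conformational-selection fit. Requires at least two distinct ligand
    concentrations and two distinct temperatures, otherwise the
    activation energies are unidentifiable.
    """
    if kind not in _RATE_NAMES:
        raise ValueError(f"kind must be 'cs' or 'lk', got {kind!r}")
    if profile.empty:
        raise ValueError("empty relaxation profile")
    L, T, a1, a2 = _profile_arrays(profile)
    if np.unique(L).size < 2:
        raise ValueError("profile must span at least 2 ligand concentrations")
    if np.unique(T).size < 2:
        raise ValueError("profile must span at least 2 temperatures (E unidentifiable)")

    laws0 = dict(_initial_laws(kind, profile, T0))
    if initial:
        laws0.update(initial)
    starts = [laws0]
    if kind == "cs" and not initial:
        # both branches of the koff <-> k12+k21 assignment ambiguity
        starts = _cs_candidate_laws(profile, T0) or starts
    has_a2 = np.isfinite(a2)

    def residuals(theta: np.ndarray) -> np.ndarray:
        laws = _unpack(kind, theta, T0)
        model = GlobalKineticModel(kind=kind, laws=laws)
        res = []
        # optimizer excursions can overflow the discriminant; inf residuals
        # just push the step back
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(L.size):
                pred = model.predicted_relaxations(L[i], T[i])
                res.append(pred[0] - a1[i])
                if has_a2[i]:
                    res.append((pred[1] if len(pred) > 1 else pred[0]) - a2[i])
        return np.nan_to_num(np.asarray(res), nan=1e12, posinf=1e12, neginf=-1e12)

    sol = None
    for cand in starts:
        theta0 = _pack(kind, cand)
        trial = optimize.least_squares(residuals, theta0, method="lm", max_nfev=20000)
        if not trial.success:
            trial = optimize.least_squares(residuals, theta0, method="trf", max_nfev=20000)
        if sol is None or trial.cost < sol.cost:
            sol = trial
    laws = _unpack(kind, sol.x, T0)
    rss = float(2.0 * sol.cost)
    n_obs = int(L.size + has_a2.sum())
    dof = n_obs - sol.x.size
    cov, stderr = _covariance(sol.jac, sol.x, rss, dof, kind)
    return GlobalKineticModel(
        kind=kind,
        laws=laws,
        rss=rss,
        dof=dof,
        stderr=stderr,
        covariance=cov,
        converged=bool(sol.success),
    )


def _covariance(
    jac: np.ndarray, theta: np.ndarray, rss: float, dof: int, kind: str
) -> tuple[np.ndarray | None, dict[str, tuple[float, float]]]:
    names = _RATE_NAMES[kind]
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof if dof > 0 else np.nan)
    except np.linalg.LinAlgError:
        return None, {n: (np.inf, np.inf) for n in names}
    stderr = {}
    for i, n in enumerate(names):
        se_log_k0 = np.sqrt(abs(cov[2 * i, 2 * i]))
        se_k0 = float(np.exp(theta[2 * i]) * se_log_k0)  # delta method
        se_E = float(np.sqrt(abs(cov[2 * i + 1, 2 * i + 1])))
        stderr[n] = (se_k0, se_E)
    return cov, stderr


@dataclass(frozen=True)
class MechanismCall:
    """Outcome of mechanism discrimination with its evidence."""

    kind: str  # "cs" or "lk"
    confident: bool
    fraction_double: float
    evidence: dict


def discriminate_mechanism(profile: pd.DataFrame, alpha_level: float = 0.01) -> MechanismCall:
    """Classify a relaxation profile as conformational selection or lock-and-key.

    Conformational selection is called only when (a) a majority of rows
    carry a second relaxation and (b) that slow relaxation, as a function
    of ligand at fixed temperature, is fit significantly better by the
    saturating two-state expression than by a straight line (nested-style
    F comparison pooled over temperatures). A profile whose relaxations
    stay linear in [L] with no second phase is called lock-and-key. A
    single-row profile cannot resolve saturation and returns lock-and-key
    with ``confident=False``.
    """
    if profile.empty:
        raise ValueError("empty relaxation profile")
    n_rows = len(profile)
    frac2 = float((profile["n_exp"] == 2).mean()) if "n_exp" in profile else 0.0
    if n_rows < 2:
        return MechanismCall(
            kind="lk", confident=False, fraction_double=frac2,
            evidence={"reason": "single row: saturation unresolvable"},
        )
    if frac2 <= 0.5:
        return MechanismCall(
            kind="lk", confident=True, fraction_double=frac2,
            evidence={"reason": "majority of traces single-exponential"},
        )

    # saturation check on the slow relaxation: line vs saturating curve per T
    rows2 = profile[profile["n_exp"] == 2]
    rss_line = 0.0
    rss_sat = 0.0
    n_pts = 0
    n_temps = 0
    for t, grp in rows2.groupby("temp_K"):
        L = grp["ligand_uM"].to_numpy(float)
        a2 = grp["alpha2_s"].to_numpy(float)
        if L.size < 4 or np.unique(L).size < 3:
            continue
        coef = np.polyfit(L, a2, 1)
        rss_line += float(np.sum((np.polyval(coef, L) - a2) ** 2))
        rss_sat += _saturating_rss(L, a2)
        n_pts += L.size
        n_temps += 1
    if n_temps == 0:
        return MechanismCall(
            kind="lk", confident=False, fraction_double=frac2,
            evidence={"reason": "too few ligand levels to test saturation"},
        )
    # line: 2 params/T; saturating plateau form: 3 params/T
    df_line = n_pts - 2 * n_temps
    df_sat = n_pts - 3 * n_temps
    if df_sat <= 0 or rss_sat <= 0:
        better = rss_sat < rss_line
        p_value = 0.0 if better else 1.0
    else:
        f_stat = ((rss_line - rss_sat) / (df_line - df_sat)) / (rss_sat / df_sat)
        p_value = float(stats.f.sf(max(f_stat, 0.0), df_line - df_sat, df_sat))
    is_cs = p_value < alpha_level
    return MechanismCall(
        kind="cs" if is_cs else "lk",
        confident=True,
        fraction_double=frac2,
        evidence={
            "rss_linear": rss_line,
            "rss_saturating": rss_sat,
            "p_value": p_value,
            "n_temperatures": n_temps,
        },
    )


def _saturating_rss(L: np.ndarray, a2: np.ndarray) -> float:
    """Best RSS of the slow-relaxation plateau form a2(L) = lo + (hi-lo)*L/(K+L)."""
    lo0, hi0 = float(np.min(a2)), float(np.max(a2))
    k0 = float(np.median(L))

    def resid(p: np.ndarray) -> np.ndarray:
        lo, hi, k = p
        return lo + (hi - lo) * L / (abs(k) + L) - a2

    best = np.inf
    for kscale in (0.3, 1.0, 3.0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = optimize.least_squares(resid, [lo0, hi0, k0 * kscale], method="lm")
        best = min(best, float(2.0 * sol.cost))
    return best
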