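"""Closed-form relaxation rates and exact trace simulation.

Two linear binding schemes are supported, both linearized under
pseudo-first-order conditions (ligand in large excess over the
macromolecule, so [L] is treated as constant during the transient):

* conformational selection ``E* <-> E <-> E:L`` — the ligand binds only
  the open conformer E of a pre-equilibrating E*/E pair, producing two
  relaxations;
* lock-and-key ``E <-> E:L`` — rigid-body association, producing a
  single relaxation linear in [L].

Units package-wide: time s, rates s^-1, second-order ``kon`` uM^-1 s^-1,
ligand concentration uM, temperature K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MechanismCS",
    "MechanismLK",
    "RelaxationSpectrum",
    "Trace",
    "ObservableModel",
    "cs_relaxations",
    "lk_relaxation",
    "rate_matrix",
    "equilibrium_populations",
    "simulate_trace",
]

#: species ordering used by every matrix/vector in this module
CS_SPECIES = ("E*", "E", "E:L")
LK_SPECIES = ("E", "E:L")


@dataclass(frozen=True)
class MechanismCS:
    """Conformational-selection scheme E* <-> E <-> E:L.

    Parameters
    ----------
    k12 : float
        First-order rate E* -> E, s^-1.
    k21 : float
        First-order rate E -> E*, s^-1.
    kon : float
        Second-order association rate, uM^-1 s^-1.
    koff : float
        First-order dissociation rate, s^-1.

    Notes
    -----
    The ratio ``k21/k12`` gives the E*:E partitioning at equilibrium in
    the absence of ligand (defined only when ``k12 > 0``).
    """

    k12: float
    k21: float
    kon: float
    koff: float

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "kon", "koff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be > 0 for a binding-competent scheme")

    @property
    def partition_ratio(self) -> float:
        """E*:E population ratio at zero ligand, k21/k12."""
        if self.k12 <= 0:
            raise ValueError("partition ratio undefined for k12 = 0")
        return self.k21 / self.k12


@dataclass(frozen=True)
class MechanismLK:
    """Lock-and-key scheme E <-> E:L (``kon`` uM^-1 s^-1, ``koff`` s^-1)."""

    kon: float
    koff: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.kon) or self.kon <= 0:
            raise ValueError(f"kon must be finite and > 0, got {self.kon}")
        if not np.isfinite(self.koff) or self.koff < 0:
            raise ValueError(f"koff must be finite and >= 0, got {self.koff}")


@dataclass(frozen=True)
class RelaxationSpectrum:
    """Exponential relaxation rates/amplitudes of a transient.

    ``rates`` are positive and strictly descending; ``amplitudes`` are
    the signed pre-exponential factors in
    ``signal(t) = baseline + sum_i amplitudes[i] * exp(-rates[i] * t)``.
    ``degenerate`` flags a coalesced pair (equal roots of the secular
    equation), in which case the two rates are reported equal.
    """

    rates: tuple[float, ...]
    amplitudes: tuple[float, ...]
    baseline: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.rates) not in (1, 2):
            raise ValueError("spectrum must carry 1 or 2 relaxations")
        if len(self.rates) != len(self.amplitudes):
            raise ValueError("rates and amplitudes must have equal length")
        if any(r <= 0 for r in self.rates):
            raise ValueError("all relaxation rates must be > 0")
        if len(self.rates) == 2 and not self.degenerate and not self.rates[0] > self.rates[1]:
            raise ValueError("rates must be strictly descending")


@dataclass(frozen=True)
class Trace:
    """A single stopped-flow transient with its acquisition metadata."""

    time: np.ndarray
    signal: np.ndarray
    ligand_conc: float
    temperature: float
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size < 10:
            raise ValueError("trace must contain at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if t[0] < self.dead_time:
            raise ValueError("time grid must start at or after the dead time")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class ObservableModel:
    """Maps species populations to the observed fluorescence signal.

    ``coefficients`` are per-species fluorescence yields (a.u. per unit
    population) in the species order of the mechanism; ``initial`` is the
    population distribution over the *unliganded* species {E*, E} (or
    {E} for lock-and-key) at the instant of mixing. Defaults mimic
    quenching on binding: free species fully fluorescent, complex at 0.7.
    """

    coefficients: tuple[float, ...] = (1.0, 1.0, 0.7)
    initial: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) not in (2, 3):
            raise ValueError("need 2 (LK) or 3 (CS) fluorescence coefficients")
        if len(set(self.coefficients)) < 2:
            raise ValueError("at least two species must have distinct coefficients")
        if self.initial is not None:
            p = np.asarray(self.initial, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("initial populations must be >= 0 and sum to 1")

    def for_mechanism(self, m: MechanismCS | MechanismLK) -> "ObservableModel":
        """Return a copy with coefficient length matching the scheme."""
        n = 3 if isinstance(m, MechanismCS) else 2
        if len(self.coefficients) == n:
            return self
        if n == 2:
            # collapse E*/E onto a single free-species coefficient
            return ObservableModel(
                coefficients=self.coefficients[1:], initial=(1.0,)
            )
        raise ValueError("cannot expand a 2-species observable to a CS scheme")


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")


def cs_relaxations(m: MechanismCS, L: float) -> tuple[float, float]:
    """Both relaxation rates of the conformational-selection scheme.

    Returns ``(alpha1, alpha2)`` with ``alpha1 >= alpha2 >= 0``:

        2*alpha_{1,2} = k12 + k21 + kon*L + koff
                        +/- sqrt((kon*L + koff - k12 - k21)^2 + 4*k21*kon*L)

    The fast relaxation alpha1 (+ sign) reflects binding and grows
    linearly with [L] at high ligand; the slow relaxation alpha2 (- sign)
    saturates at ``k12`` for high [L] and reflects the conformational
    transition linked to binding.
    """
    _check_nonneg(L=L)
    s = m.k12 + m.k21 + m.kon * L + m.koff
    d = m.kon * L + m.koff - m.k12 - m.k21
    disc = d * d + 4.0 * m.k21 * m.kon * L
    root = np.sqrt(disc)
    return (0.5 * (s + root), 0.5 * (s - root))


def lk_relaxation(m: MechanismLK, L: float) -> float:
    """Single relaxation rate of the lock-and-key scheme, koff + kon*[L]."""
    _check_nonneg(L=L)
    return m.koff + m.kon * L


def rate_matrix(m: MechanismCS | MechanismLK, L: float) -> np.ndarray:
    """Column-generator matrix of the linearized scheme at ligand level L.

    ``dp/dt = M @ p`` over species ``("E*", "E", "E:L")`` for
    conformational selection or ``("E", "E:L")`` for lock-and-key.
    Columns sum to zero (probability conservation) and off-diagonal
    entries are nonnegative; the nonzero eigenvalue magnitudes are the
    relaxation rates.
    """
    _check_nonneg(L=L)
    if isinstance(m, MechanismCS):
        kb = m.kon * L
        return np.array(
            [
                [-m.k12, m.k21, 0.0],
                [m.k12, -(m.k21 + kb), m.koff],
                [0.0, kb, -m.koff],
            ]
        )
    if isinstance(m, MechanismLK):
        kb = m.kon * L
        return np.array([[-kb, m.koff], [kb, -m.koff]])
    raise TypeError(f"unsupported mechanism type {type(m).__name__}")


def equilibrium_populations(m: MechanismCS | MechanismLK, L: float) -> np.ndarray:
    """Stationary species fractions (null vector of the rate matrix).

    For the conformational-selection scheme the closed form follows from
    detailed balance on the linear chain:
    ``pE*/pE = k21/k12`` and ``pEL/pE = kon*L/koff``.
    """
    _check_nonneg(L=L)
    if isinstance(m, MechanismCS):
        if m.k12 <= 0 and m.k21 <= 0:
            # disconnected E*: the stationary distribution is not unique
            raise ValueError("all-zero exchange rates: stationary state degenerate")
        if m.k12 <= 0:
            # E* absorbs everything when it cannot relax back to E
            return np.array([1.0, 0.0, 0.0])
        # detailed balance along the chain, unnormalized weights wrt E
        w_estar = m.k21 / m.k12
        w_el = m.kon * L / m.koff
        w = np.array([w_estar, 1.0, w_el])
        return w / w.sum()
    if isinstance(m, MechanismLK):
        pe = m.koff / (m.koff + m.kon * L) if (m.koff + m.kon * L) > 0 else 1.0
        return np.array([pe, 1.0 - pe])
    raise TypeError(f"unsupported mechanism type {type(m).__name__}")


def _initial_populations(
    m: MechanismCS | MechanismLK, obs: ObservableModel
) -> np.ndarray:
    if obs.initial is not None:
        p0 = np.asarray(obs.initial, dtype=float)
        n_free = 2 if isinstance(m, MechanismCS) else 1
        if p0.size != n_free:
            raise ValueError(
                f"initial distribution must cover the {n_free} unliganded species"
            )
        return np.concatenate([p0, [0.0]])
    # default: the unliganded pre-equilibrium an instrument mixes from
    if isinstance(m, MechanismCS):
        eq0 = equilibrium_populations(m, 0.0)
        return eq0
    return np.array([1.0, 0.0])


def simulate_trace(
    m: MechanismCS | MechanismLK,
    obs: ObservableModel,
    L: float,
    time_grid: np.ndarray,
    dead_time: float = 0.0,
    temperature: float = 288.15,
) -> Trace:
    """Exact noiseless transient after a ligand-concentration jump.

    Populations are propagated from the initial distribution by the
    matrix exponential of the generator, ``p(t) = expm(M t) p0``, and the
    signal is the population-weighted sum of the fluorescence
    coefficients. Points earlier than ``dead_time`` are censored
    (dropped), mirroring the blind window of a stopped-flow mixer.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a nonempty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be nonnegative and strictly increasing")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    obs = obs.for_mechanism(m)
    keep = t >= dead_time
    t = t[keep]
    if t.size < 10:
        raise ValueError("fewer than 10 points remain after dead-time censoring")

    M = rate_matrix(m, L)
    p0 = _initial_populations(m, obs)
    c = np.asarray(obs.coefficients, dtype=float)

    # eigen-propagation when well-conditioned, expm fallback otherwise
    populations = _propagate(M, p0, t)
    signal = populations @ c
    return Trace(
        time=t,
        signal=signal,
        ligand_conc=L,
        temperature=temperature,
        dead_time=dead_time,
    )


def _propagate(M: np.ndarray, p0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Populations at each time, shape (len(t), n_species)."""
    try:
        lam, V = np.linalg.eig(M)
        cond = np.linalg.cond(V)
        if cond > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        coef = np.linalg.solve(V, p0)
        out = np.real((V * coef) @ np.exp(np.outer(lam, t)))
        return out.T
    except np.linalg.LinAlgError:
        return np.array([expm(M * ti) @ p0 for ti in t])


def analytic_spectrum(
    m: MechanismCS | MechanismLK, obs: ObservableModel, L: float
) -> RelaxationSpectrum:
    """Exact relaxation spectrum of the noiseless transient.

    Amplitudes come from projecting the initial deviation from the
    stationary distribution onto the eigenmodes of the generator; zero
    (or numerically negligible) amplitude modes are dropped.
    """
    obs = obs.for_mechanism(m)
    M = rate_matrix(m, L)
    p0 = _initial_populations(m, obs)
    c = np.asarray(obs.coefficients, dtype=float)
    lam, V = np.linalg.eig(M)
    coef = np.linalg.solve(V, p0)
    contrib = coef * (c @ V)  # signal contribution of each mode
    order = np.argsort(np.abs(np.real(lam)))
    baseline = 0.0
    rates: list[float] = []
    amps: list[float] = []
    scale = max(float(np.max(np.abs(contrib))), 1e-30)
    for i in order:
        r = -float(np.real(lam[i]))
        a = float(np.real(contrib[i]))
        if r < 1e-12 * max(1.0, float(np.max(np.abs(lam)))):
            baseline += a
        elif abs(a) > 1e-12 * scale:
            rates.append(r)
            amps.append(a)
    idx = np.argsort(rates)[::-1]
    rates_arr = [rates[i] for i in idx]
    amps_arr = [amps[i] for i in idx]
    if not rates_arr:
        raise ValueError("signal carries no relaxation (stationary start)")
    degenerate = bool(len(rates_arr) == 2 and np.isclose(rates_arr[0], rates_arr[1]))
    return RelaxationSpectrum(
        rates=tuple(rates_arr),
        amplitudes=tuple(amps_arr),
        baseline=float(baseline),
        degenerate=degenerate,
    )
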