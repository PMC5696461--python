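"""Allosteric voltage/Ca2+ gating model: state space, rate matrices,
equilibria, relaxation spectra and pulse simulation.

Two complementary representations are implemented and tested against
each other:

* the microscopic generator over all ``1 + 3(m+1)`` states (open state
  O plus three closed tiers C1, C2, C3 each carrying 0..m bound Ca2+),
  with finite fast rates for the O<->C1 equilibrium and
  diffusion-limited binding;
* the rapid-equilibrium reduction: a closed-form partition-sum open
  probability and a 3-aggregate chain {O u C1} <-> {C2} <-> {C3} with
  occupancy-weighted effective rates, whose two nonzero eigenvalues
  give the observable relaxation time constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space
from scipy.optimize import brentq

from .errors import DegenerateSolutionError, InvalidArgumentError, NoRootError
from .params import AllostericParams
from .thermo import DEFAULT_CTX, ThermoContext

TIERS = ("O", "C1", "C2", "C3")

#: Default per-site Ca2+ on-rate, mM^-1 s^-1 (diffusion-limited regime).
DEFAULT_KON0 = 1e4

#: O<->C1 rates exceed the largest slow gating rate by this factor.
FAST_FACTOR = 100.0


@dataclass(frozen=True)
class MicroState:
    """One microscopic state: gating tier and number of bound Ca2+."""

    tier: str
    n_bound: int

    def __post_init__(self):
        if self.tier not in TIERS:
            raise InvalidArgumentError(f"unknown tier {self.tier!r}")
        if self.tier == "O" and self.n_bound != 0:
            raise InvalidArgumentError("the open tier carries no bound Ca2+")
        if self.n_bound < 0:
            raise InvalidArgumentError("n_bound must be >= 0")


def build_state_space(m: int) -> list[MicroState]:
    """Ordered state list: O first, then C1_0..C1_m, C2_0.., C3_0..

    The length is ``1 + 3(m+1)`` (22 states for the hexamer-symmetric
    six-site model).
    """
    if isinstance(m, bool) or not isinstance(m, (int, np.integer)):
        raise InvalidArgumentError(f"m must be an integer, got {m!r}")
    if m < 1:
        raise InvalidArgumentError(f"m must be >= 1, got {m}")
    states = [MicroState("O", 0)]
    for tier in ("C1", "C2", "C3"):
        states += [MicroState(tier, n) for n in range(m + 1)]
    return states


@dataclass(frozen=True)
class GatingRates:
    """Slow gating rates per Ca2+ occupancy and tier binding constants.

    ``alpha``/``chi`` are the closing rates C1->C2 and C2->C3;
    ``beta``/``delta`` the opening rates C2->C1 and C3->C2; each an
    array over n = 0..m bound ions. ``Ka1..Ka3`` are the per-site
    association constants (mM^-1) of the three closed tiers.
    """

    alpha: np.ndarray
    beta: np.ndarray
    chi: np.ndarray
    delta: np.ndarray
    Ka1: float
    Ka2: float
    Ka3: float


def tier_transition_rates(
    params: AllostericParams, V: float, ctx: ThermoContext = DEFAULT_CTX
) -> GatingRates:
    """Voltage- and occupancy-dependent slow gating rates.

    Closing rates carry exp(-z V / Vt) and one factor ``c_b`` per bound
    Ca2+; opening rates carry exp(+z V / Vt) and ``c_f`` per bound ion.
    Detailed balance then forces tier affinities Ka1, C*Ka1, C^2*Ka1
    with C = c_b/c_f.
    """
    vt = ctx.thermal_voltage
    n = np.arange(params.m + 1)
    cb_n = params.c_b**n
    cf_n = params.c_f**n
    alpha = params.A0 * np.exp(-params.za * V / vt) * cb_n
    beta = params.B0 * np.exp(+params.zb * V / vt) * cf_n
    chi = params.C0 * np.exp(-params.zc * V / vt) * cb_n
    delta = params.D0 * np.exp(+params.zd * V / vt) * cf_n
    Ka1 = 1.0 / params.Kd
    C = params.coupling
    return GatingRates(alpha, beta, chi, delta, Ka1, C * Ka1, C * C * Ka1)


def fast_equilibrium_constant(
    params: AllostericParams, V, ctx: ThermoContext = DEFAULT_CTX
):
    """L1(V) = [C1]/[O] = exp(-z1 (V - V1) / Vt) of the fast O<->C1 step."""
    return np.exp(-params.z1 * (np.asarray(V, float) - params.V1) / ctx.thermal_voltage)


def build_generator(
    params: AllostericParams,
    V: float,
    Ca: float,
    kon0: float = DEFAULT_KON0,
    ctx: ThermoContext = DEFAULT_CTX,
    fast_factor: float = FAST_FACTOR,
) -> tuple[np.ndarray, list[MicroState]]:
    """Microscopic generator matrix (rows sum to zero) and its state list.

    Binding within tier i: n -> n+1 at (m-n)*kon0*Ca and n+1 -> n at
    (n+1)*kon0/Ka_i (m independent identical sites, binomial
    multiplicities). The fast O<->C1_0 edge uses finite rates whose
    ratio is L1(V) and whose magnitude exceeds ``fast_factor`` times
    the largest slow gating rate.
    """
    if Ca < 0:
        raise InvalidArgumentError(f"Ca must be >= 0, got {Ca}")
    if not (kon0 > 0):
        raise InvalidArgumentError(f"kon0 must be > 0, got {kon0}")
    m = params.m
    states = build_state_space(m)
    idx = {(s.tier, s.n_bound): i for i, s in enumerate(states)}
    g = tier_transition_rates(params, V, ctx)
    Q = np.zeros((len(states), len(states)))

    def add(a, b, rate):
        Q[idx[a], idx[b]] += rate

    # slow gating edges, tier-to-tier at fixed occupancy
    for n in range(m + 1):
        add(("C1", n), ("C2", n), g.alpha[n])
        add(("C2", n), ("C1", n), g.beta[n])
        add(("C2", n), ("C3", n), g.chi[n])
        add(("C3", n), ("C2", n), g.delta[n])
    # binding ladders within each closed tier
    for tier, Ka in (("C1", g.Ka1), ("C2", g.Ka2), ("C3", g.Ka3)):
        for n in range(m):
            add((tier, n), (tier, n + 1), (m - n) * kon0 * Ca)
            add((tier, n + 1), (tier, n), (n + 1) * kon0 / Ka)
    # fast O <-> C1_0 equilibrium with ratio L1(V)
    L1 = float(fast_equilibrium_constant(params, V, ctx))
    slow_max = max(g.alpha.max(), g.beta.max(), g.chi.max(), g.delta.max())
    scale = fast_factor * slow_max * max(1.0, 1.0 / L1)
    add(("O", 0), ("C1", 0), scale * L1)
    add(("C1", 0), ("O", 0), scale)

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, states


def stationary_occupancy(Q: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Stationary distribution p with p Q = 0 (null space of Q^T).

    Raises DegenerateSolutionError if the null space is not
    one-dimensional (disconnected chain).
    """
    ns = null_space(Q.T, rcond=tol)
    if ns.shape[1] != 1:
        raise DegenerateSolutionError(
            f"stationary distribution is not unique (null space dim {ns.shape[1]})"
        )
    p = ns[:, 0]
    p = p * np.sign(p.sum())
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def open_probability(
    params: AllostericParams, V, Ca, ctx: ThermoContext = DEFAULT_CTX
):
    """Closed-form stationary open probability (partition sum).

    With x = Ca/Kd and C = c_b/c_f,

        Po = 1 / (1 + L1 [ (1+x)^m + K12 (1+Cx)^m + K12 K23 (1+C^2 x)^m ])

    where L1 = exp(-z1 (V-V1)/Vt), K12 = (A0/B0) exp(-(za+zb) V/Vt) and
    K23 = (C0/D0) exp(-(zc+zd) V/Vt). Broadcasts over V and Ca.
    """
    V = np.asarray(V, float)
    Ca = np.asarray(Ca, float)
    if np.any(Ca < 0):
        raise InvalidArgumentError("Ca must be >= 0")
    vt = ctx.thermal_voltage
    x = Ca / params.Kd
    C = params.coupling
    m = params.m
    L1 = np.exp(-params.z1 * (V - params.V1) / vt)
    K12 = (params.A0 / params.B0) * np.exp(-(params.za + params.zb) * V / vt)
    K23 = (params.C0 / params.D0) * np.exp(-(params.zc + params.zd) * V / vt)
    closed = L1 * ((1 + x) ** m + K12 * (1 + C * x) ** m + K12 * K23 * (1 + C * C * x) ** m)
    out = 1.0 / (1.0 + closed)
    return out if out.ndim else float(out)


def half_activation_voltage(
    params: AllostericParams,
    Ca: float = 0.0,
    ctx: ThermoContext = DEFAULT_CTX,
    bracket: tuple[float, float] = (-150.0, 150.0),
) -> float:
    """Voltage at which Po reaches half its depolarized-limit value."""
    lim = open_probability(params, bracket[1], Ca, ctx)
    f = lambda v: open_probability(params, v, Ca, ctx) - 0.5 * lim
    if f(bracket[0]) * f(bracket[1]) > 0:
        raise NoRootError("Po never crosses half-maximum on the bracket")
    return brentq(f, *bracket, xtol=1e-10)


def reduced_rates(
    params: AllostericParams, V, Ca, ctx: ThermoContext = DEFAULT_CTX
):
    """Effective rates (f1, b1, f2, b2) of the 3-aggregate chain.

    Aggregates are {O u C1}, {C2}, {C3}; each rate is the slow gating
    rate averaged over the within-aggregate fast binding (and O<->C1)
    equilibrium. Because c_f * C = c_b, the aggregate equilibrium
    ratios exactly reproduce the partition-sum open probability.
    """
    V = np.asarray(V, float)
    Ca = np.asarray(Ca, float)
    if np.any(Ca < 0):
        raise InvalidArgumentError("Ca must be >= 0")
    vt = ctx.thermal_voltage
    m = params.m
    x = Ca / params.Kd
    C = params.coupling
    L1 = np.exp(-params.z1 * (V - params.V1) / vt)
    a0 = params.A0 * np.exp(-params.za * V / vt)
    b0 = params.B0 * np.exp(+params.zb * V / vt)
    x0 = params.C0 * np.exp(-params.zc * V / vt)
    d0 = params.D0 * np.exp(+params.zd * V / vt)
    cb, cf = params.c_b, params.c_f
    # sum_n binom(m,n) (K x)^n r^n = (1 + r K x)^m
    f1 = a0 * L1 * (1 + cb * x) ** m / (1 + L1 * (1 + x) ** m)
    b1 = b0 * (1 + cb * x) ** m / (1 + C * x) ** m
    f2 = x0 * (1 + cb * C * x) ** m / (1 + C * x) ** m
    b2 = d0 * (1 + cb * C * x) ** m / (1 + C * C * x) ** m
    return f1, b1, f2, b2


def reduced_generator(
    params: AllostericParams, V, Ca, ctx: ThermoContext = DEFAULT_CTX
) -> np.ndarray:
    """3x3 generator of the aggregate chain (batched over broadcast V, Ca)."""
    f1, b1, f2, b2 = reduced_rates(params, V, Ca, ctx)
    f1, b1, f2, b2 = np.broadcast_arrays(f1, b1, f2, b2)
    shape = np.shape(f1)
    G = np.zeros(shape + (3, 3))
    G[..., 0, 0], G[..., 0, 1] = -f1, f1
    G[..., 1, 0], G[..., 1, 1], G[..., 1, 2] = b1, -(b1 + f2), f2
    G[..., 2, 1], G[..., 2, 2] = b2, -b2
    return G


def slow_time_constants(
    params: AllostericParams, V, Ca, ctx: ThermoContext = DEFAULT_CTX
):
    """(tau_fast, tau_slow): negative reciprocals of the two nonzero
    eigenvalues of the reduced 3-aggregate chain. Broadcasts over V, Ca."""
    G = reduced_generator(params, V, Ca, ctx)
    ev = np.linalg.eigvals(G)
    ev = np.sort(np.real(ev), axis=-1)  # reversible chain: real spectrum
    # eigenvalues sorted ascending: [most negative, middle, ~0]
    tau_fast = -1.0 / ev[..., 0]
    tau_slow = -1.0 / ev[..., 1]
    if tau_fast.ndim == 0:
        return float(tau_fast), float(tau_slow)
    return tau_fast, tau_slow


def generator_time_constants(Q: np.ndarray, n: int = 2) -> np.ndarray:
    """The n slowest nonzero relaxation times of a generator, ascending."""
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    nonzero = ev[ev < -1e-12 * max(1.0, float(np.abs(ev).max()))]
    taus = np.sort(-1.0 / nonzero)  # ascending; slowest are the largest
    return taus[-n:]


@dataclass(frozen=True)
class PulseProtocol:
    """Voltage-step protocol: hold, test pulse, tail pulse."""

    holding_V: float
    test_V: float
    tail_V: float
    durations: tuple[float, float]  # (test, tail) in seconds
    sample_interval: float = 1e-3

    def __post_init__(self):
        if any(d <= 0 for d in self.durations):
            raise InvalidArgumentError("durations must be > 0")
        if not (self.sample_interval > 0):
            raise InvalidArgumentError("sample_interval must be > 0")


@dataclass
class SimTrace:
    """Simulated open-probability trace of a pulse protocol."""

    time: np.ndarray
    open_probability: np.ndarray
    voltage: np.ndarray

    def current(self, reversal: float = 0.0, conductance: float = 1.0) -> np.ndarray:
        return self.open_probability * (self.voltage - reversal) * conductance

    def segment(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.time >= t0) & (self.time < t1)
        return self.time[mask] - t0, self.open_probability[mask]


def simulate_pulse(
    params: AllostericParams,
    protocol: PulseProtocol,
    Ca: float = 0.0,
    kon0: float = DEFAULT_KON0,
    ctx: ThermoContext = DEFAULT_CTX,
) -> SimTrace:
    """Propagate the full microscopic generator through a pulse protocol.

    Starts from the stationary distribution at the holding potential and
    advances segment-by-segment with the exact matrix exponential at the
    sampling interval.
    """
    Q_hold, _ = build_generator(params, protocol.holding_V, Ca, kon0, ctx)
    p = stationary_occupancy(Q_hold)
    segments = [
        (protocol.test_V, protocol.durations[0]),
        (protocol.tail_V, protocol.durations[1]),
    ]
    times, pos, volts = [0.0], [p[0]], [protocol.holding_V]
    t0 = 0.0
    for V, dur in segments:
        Q, _ = build_generator(params, V, Ca, kon0, ctx)
        step = expm(Q * protocol.sample_interval)
        nsteps = int(round(dur / protocol.sample_interval))
        for k in range(1, nsteps + 1):
            p = p @ step
            times.append(t0 + k * protocol.sample_interval)
            pos.append(p[0])
            volts.append(V)
        t0 += nsteps * protocol.sample_interval
    return SimTrace(np.array(times), np.array(pos), np.array(volts))


def model_inhibition(
    params: AllostericParams,
    V_test: float,
    ca_grid: Sequence[float],
    ctx: ThermoContext = DEFAULT_CTX,
) -> np.ndarray:
    """Equilibrium relative current Po(V, Ca)/Po(V, 0) over a Ca grid."""
    ca = np.asarray(ca_grid, float)
    if np.any(ca < 0):
        raise InvalidArgumentError("ca_grid must be >= 0")
    return open_probability(params, V_test, ca, ctx) / open_probability(
        params, V_test, 0.0, ctx
    )


def model_ic50(
    params: AllostericParams,
    V_test: float,
    ctx: ThermoContext = DEFAULT_CTX,
    log_bracket: tuple[float, float] = (-6.0, 3.0),
) -> float:
    """Ca2+ concentration (mM) halving the equilibrium current at V_test.

    Bisection on log10 Ca; raises NoRootError if the relative current
    never crosses one half on the bracket.
    """
    po0 = open_probability(params, V_test, 0.0, ctx)
    f = lambda lc: open_probability(params, V_test, 10.0**lc, ctx) / po0 - 0.5
    lo, hi = log_bracket
    if f(lo) * f(hi) > 0:
        raise NoRootError("relative current does not cross 0.5 on the bracket")
    return 10.0 ** brentq(f, lo, hi, xtol=1e-9)
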