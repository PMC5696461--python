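"""Seeded synthetic-data generators for every dataset class.

Each generator draws from the allosteric model (default ground truth:
the published six-site most-likely values) under the standard recording
protocols — tail-current G-V activation from +20 to -60 mV, Ca2+
inhibition at test voltages {+20, +10, 0, -20, -30, -50} mV,
bi-exponential relaxations over -100..+20 mV and over a Ca2+ ladder at
-100 mV, and oocyte swelling area series — then adds configurable
noise: Gaussian on relative currents, log-normal on time constants,
Gaussian on traces and areas. Everything is reproducible bit-for-bit
from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .bayes import Dataset, TauData
from .equilibrium import GVCurve, InhibitionCurve
from .errors import InvalidArgumentError
from .model import PulseProtocol, open_probability, simulate_pulse, slow_time_constants
from .params import AllostericParams
from .thermo import DEFAULT_CTX, ThermoContext


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes of the synthetic observables."""

    rel_current_sd: float = 0.02  # additive Gaussian on relative currents
    tau_log_sd: float = 0.1  # log-normal sigma on time constants
    trace_sd: float = 0.01  # additive Gaussian, fraction of trace amplitude
    # area noise calibrated so the late-window rate estimate of one
    # oocyte is precise relative to the +/-Ca2+ group difference, as in
    # the published four-oocyte comparison
    area_sd: float = 5e-4  # additive Gaussian, fraction of initial area

    def __post_init__(self):
        for name in ("rel_current_sd", "tau_log_sd", "trace_sd", "area_sd"):
            if not (getattr(self, name) > 0):
                raise InvalidArgumentError(f"{name} must be > 0")


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters and protocol grids of a synthetic study."""

    params: AllostericParams = reference.CX46_MLV
    gv_voltages: tuple = tuple(np.arange(20.0, -61.0, -10.0))
    test_voltages: tuple = (20.0, 10.0, 0.0, -20.0, -30.0, -50.0)
    ca_grid: tuple = tuple(np.logspace(-3, 1, 9))
    tau_v_grid: tuple = tuple(np.arange(-100.0, 21.0, 10.0))
    tau_ca_grid: tuple = tuple(np.logspace(-3, 1, 8))
    tau_ca_voltage: float = -100.0
    nominal_ca: float = 0.0

    def __post_init__(self):
        for name in ("gv_voltages", "test_voltages", "ca_grid", "tau_v_grid", "tau_ca_grid"):
            if len(getattr(self, name)) == 0:
                raise InvalidArgumentError(f"{name} must be non-empty")


def gen_gv_dataset(
    truth: TruthConfig,
    noise: NoiseSpec,
    seed: int,
    ctx: ThermoContext = DEFAULT_CTX,
) -> GVCurve:
    """Noisy normalized tail-current activation curve."""
    rng = np.random.default_rng(seed)
    V = np.asarray(truth.gv_voltages)
    po = open_probability(truth.params, V, truth.nominal_ca, ctx)
    rel = po / po.max() + rng.normal(0.0, noise.rel_current_sd, V.size)
    rel = np.clip(rel, 0.0, 1.05)
    return GVCurve(V, rel, np.full(V.size, noise.rel_current_sd))


def gen_inhibition_datasets(
    truth: TruthConfig,
    noise: NoiseSpec,
    seed: int,
    ctx: ThermoContext = DEFAULT_CTX,
) -> list[InhibitionCurve]:
    """Noisy equilibrium Ca2+ inhibition curves, one per test voltage."""
    rng = np.random.default_rng(seed)
    ca = np.asarray(truth.ca_grid)
    out = []
    for V in truth.test_voltages:
        rel = open_probability(truth.params, V, ca, ctx) / open_probability(
            truth.params, V, 0.0, ctx
        )
        # no clipping: normalized tail currents can scatter below zero,
        # and truncating them would bias the apparent IC50 upward
        rel = rel + rng.normal(0.0, noise.rel_current_sd, ca.size)
        out.append(InhibitionCurve(V, ca, rel, np.full(ca.size, noise.rel_current_sd)))
    return out


def gen_tau_datasets(
    truth: TruthConfig,
    noise: NoiseSpec,
    seed: int,
    fidelity: str = "eigen",
    ctx: ThermoContext = DEFAULT_CTX,
    sample_interval: float = 5e-3,
):
    """Relaxation time-constant data at two fidelities.

    ``eigen``: time constants from the reduced-chain spectrum with
    log-normal noise, returned as two TauData tables (tau-V at nominal
    Ca, tau-Ca at the deactivation voltage).
    ``trace``: full pulse simulations with additive trace noise,
    returned as two dicts of condition -> (time, signal) for refitting.
    """
    rng = np.random.default_rng(seed)
    if fidelity == "eigen":
        vgrid = np.asarray(truth.tau_v_grid)
        tf0, ts0 = slow_time_constants(truth.params, vgrid, truth.nominal_ca, ctx)
        tf = tf0 * rng.lognormal(0.0, noise.tau_log_sd, vgrid.size)
        ts = ts0 * rng.lognormal(0.0, noise.tau_log_sd, vgrid.size)
        # per-point SDs reflect the generating noise scale, not the
        # noisy draw, so the likelihood weights are undistorted
        tau_v = TauData(
            "V", truth.nominal_ca, vgrid, tf, ts,
            noise.tau_log_sd * tf0, noise.tau_log_sd * ts0,
        )
        cagrid = np.asarray(truth.tau_ca_grid)
        tf0, ts0 = slow_time_constants(truth.params, truth.tau_ca_voltage, cagrid, ctx)
        tf = tf0 * rng.lognormal(0.0, noise.tau_log_sd, cagrid.size)
        ts = ts0 * rng.lognormal(0.0, noise.tau_log_sd, cagrid.size)
        tau_ca = TauData(
            "Ca", truth.tau_ca_voltage, cagrid, tf, ts,
            noise.tau_log_sd * tf0, noise.tau_log_sd * ts0,
        )
        return tau_v, tau_ca
    if fidelity != "trace":
        raise InvalidArgumentError("fidelity must be 'eigen' or 'trace'")
    traces_v = {}
    for V in truth.tau_v_grid:
        _, ts = slow_time_constants(truth.params, V, truth.nominal_ca, ctx)
        # deactivation pulses from a depolarized holding; activation
        # pulses from -40 mV, where the deeper closed tiers carry
        # enough occupancy to excite both kinetic modes
        proto = PulseProtocol(0.0 if V < -10 else -40.0, V, -70.0,
                              (max(6.0 * ts, 0.5), 0.1), sample_interval)
        tr = simulate_pulse(truth.params, proto, truth.nominal_ca, ctx=ctx)
        t, y = tr.segment(0.0, proto.durations[0])
        amp = max(np.abs(y - y[-1]).max(), 1e-6)
        traces_v[float(V)] = (t, y + rng.normal(0.0, noise.trace_sd * amp, y.size))
    traces_ca = {}
    for ca in truth.tau_ca_grid:
        _, ts = slow_time_constants(truth.params, truth.tau_ca_voltage, ca, ctx)
        proto = PulseProtocol(0.0, truth.tau_ca_voltage, -70.0,
                              (max(6.0 * ts, 0.5), 0.1), sample_interval)
        tr = simulate_pulse(truth.params, proto, float(ca), ctx=ctx)
        t, y = tr.segment(0.0, proto.durations[0])
        amp = max(np.abs(y - y[-1]).max(), 1e-6)
        traces_ca[float(ca)] = (t, y + rng.normal(0.0, noise.trace_sd * amp, y.size))
    return traces_v, traces_ca


def gen_swelling_series(
    rate_no_ca: float = 0.08 / 900.0,
    rate_ca: float = 0.03 / 900.0,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    duration_s: float = 900.0,
    initial_radius: float = 200.0,
):
    """Paired hypotonic-swelling area series (without and with Ca2+).

    Relative volume grows linearly at the configured rate (defaults
    reach about 1.08 without Ca2+ and 1.03 with 5 mM Ca2+ at 900 s);
    the emitted observable is the focal-plane area at 1 Hz with
    additive Gaussian noise.
    """
    from .swelling import AreaSeries

    if rate_no_ca < 0 or rate_ca < 0:
        raise InvalidArgumentError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 1.0)
    v0 = 4.0 / 3.0 * np.pi * initial_radius**3
    out = []
    for rate, label in ((rate_no_ca, "no_ca"), (rate_ca, "ca")):
        vol = v0 * (1.0 + rate * t)
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        area = np.pi * r**2
        area = area + rng.normal(0.0, noise.area_sd * area[0], t.size)
        out.append(AreaSeries(t, area, label))
    return tuple(out)


@dataclass
class SyntheticStudy:
    """A complete seeded study: dataset plus the truth that generated it."""

    data: Dataset
    truth: TruthConfig
    noise: NoiseSpec
    seed: int
    seeds: dict = field(default_factory=dict)


def make_study(
    truth: TruthConfig = TruthConfig(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    ctx: ThermoContext = DEFAULT_CTX,
) -> SyntheticStudy:
    """Generate the full combined dataset used by the global fit."""
    ss = np.random.SeedSequence(seed)
    s_gv, s_inh, s_tau = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    gv = gen_gv_dataset(truth, noise, s_gv, ctx)
    inh = gen_inhibition_datasets(truth, noise, s_inh, ctx)
    tau_v, tau_ca = gen_tau_datasets(truth, noise, s_tau, "eigen", ctx)
    data = Dataset(gv, inh, [tau_v, tau_ca], gv_ca=truth.nominal_ca)
    return SyntheticStudy(data, truth, noise, seed, {"gv": s_gv, "inh": s_inh, "tau": s_tau})
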