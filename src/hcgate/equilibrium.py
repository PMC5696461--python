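"""Equilibrium curve fitting and closed-state-stabilization analysis.

Covers the Boltzmann fit of tail-current G-V curves, Hill fits of Ca2+
inhibition curves (performed on log concentration), the linear
closed-state binding models (Hill, two-site and three-site sequential
schemes fitted globally across test voltages), the IC50-voltage
relation of the linear Hill model, and extrapolation of the
closed-state dissociation constant K_D.

The linear Hill model has states O <-> C <-> C.Ca_n with only the
O <-> C step voltage dependent, [C]/[O] = exp(-z_delta (V - V1/2)/Vt),
and Hill binding [C.Ca_n]/[C] = Ca^n / K_D. Its IC50 obeys

    log10 IC50 = (1/n) [ log10 K_D + log10(1 + exp(+z_delta (V - V1/2)/Vt)) ]

which saturates at (1/n) log10 K_D for V << V1/2 and grows linearly in
V above V1/2. K_D follows the Hill convention and carries units of
mM^n; following common practice it is quoted directly in mM-based
units (micromolar in reports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import FitFailureError, InvalidArgumentError
from .thermo import DEFAULT_CTX, ThermoContext


@dataclass(frozen=True)
class BoltzmannParams:
    """Half-activation voltage (mV) and apparent gating charge (e0)."""

    v_half: float
    z_delta: float
    se_v_half: float = float("nan")
    se_z_delta: float = float("nan")
    rss: float = float("nan")

    def __post_init__(self):
        if not (self.z_delta > 0):
            raise InvalidArgumentError("z_delta must be > 0")


@dataclass(frozen=True)
class HillParams:
    """log10 IC50 (mM) and Hill slope of an inhibition curve.

    The slope is stored as a magnitude; the inhibition sign convention
    is implicit in the model form.
    """

    log_ic50: float
    n: float
    se_log_ic50: float = float("nan")
    se_n: float = float("nan")
    rss: float = float("nan")

    @property
    def ic50(self) -> float:
        return 10.0**self.log_ic50


@dataclass(frozen=True)
class LinearHillParams:
    """Global linear Hill model: log10 K_D (mM^n convention) and slope n."""

    log_kd: float
    n: float
    se_log_kd: float = float("nan")
    se_n: float = float("nan")
    rss: float = float("nan")


@dataclass(frozen=True)
class SequentialSiteParams:
    """Sequential 2- or 3-site scheme: per-step log10 Kd (mM) values."""

    log_kds: tuple
    se_log_kds: tuple
    rss: float = float("nan")

    def __post_init__(self):
        if len(self.log_kds) not in (2, 3):
            raise InvalidArgumentError("sequential schemes have 2 or 3 sites")

    @property
    def ill_constrained(self) -> tuple:
        """Flags per step: standard error at least as large as |estimate|."""
        return tuple(
            se >= abs(est) or not np.isfinite(se)
            for est, se in zip(self.log_kds, self.se_log_kds)
        )


@dataclass
class GVCurve:
    """Relative tail current vs voltage, with optional SEMs."""

    V_mV: np.ndarray
    rel_tail: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.V_mV = np.asarray(self.V_mV, float)
        self.rel_tail = np.asarray(self.rel_tail, float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, float)


@dataclass
class InhibitionCurve:
    """Relative current vs Ca2+ at one test voltage, with optional SEMs."""

    V_test: float
    Ca_mM: np.ndarray
    rel_current: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self):
        self.Ca_mM = np.asarray(self.Ca_mM, float)
        self.rel_current = np.asarray(self.rel_current, float)
        if np.any(self.Ca_mM < 0):
            raise InvalidArgumentError("Ca must be >= 0")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, float)


def _weights(sem, n):
    if sem is None:
        return np.ones(n)
    return np.asarray(sem, float)


def fit_boltzmann(curve: GVCurve, ctx: ThermoContext = DEFAULT_CTX) -> BoltzmannParams:
    """Weighted least-squares Boltzmann fit of a G-V curve.

    Multi-start over gating-charge initializations; raises
    FitFailureError on non-convergence or a degenerate (flat) curve.
    """
    V, y = curve.V_mV, curve.rel_tail
    if V.size < 4:
        raise InvalidArgumentError("need at least 4 points spanning the transition")
    vt = ctx.thermal_voltage
    sigma = _weights(curve.sem, V.size)

    def f(v, v_half, z):
        return 1.0 / (1.0 + np.exp(-z * (v - v_half) / vt))

    best = None
    v0 = V[np.argmin(np.abs(y - 0.5))]
    for z0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    f, V, y, p0=(v0, z0), sigma=sigma,
                    absolute_sigma=curve.sem is not None, maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        if popt[1] <= 0:
            continue
        rss = float(np.sum(((y - f(V, *popt)) / sigma) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitFailureError("Boltzmann fit did not converge from any start")
    popt, pcov, rss = best
    ses = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(ses)) or ses[1] >= 50 * abs(popt[1]):
        raise FitFailureError(
            "Boltzmann fit is unbounded (flat or non-sigmoid curve)",
            fallback={"v_half": popt[0], "z_delta": popt[1]},
        )
    return BoltzmannParams(popt[0], popt[1], ses[0], ses[1], rss)


def fit_hill(curve: InhibitionCurve) -> HillParams:
    """Hill inhibition fit on log10 Ca (zero-Ca points are excluded).

    The fitted relation is 1 / (1 + 10^{n (log Ca - log IC50)}).
    """
    mask = curve.Ca_mM > 0
    lc = np.log10(curve.Ca_mM[mask])
    y = curve.rel_current[mask]
    if lc.size < 4:
        raise InvalidArgumentError("need at least 4 concentrations bracketing the midpoint")
    sigma = _weights(None if curve.sem is None else curve.sem[mask], lc.size)

    def f(logca, log_ic50, n):
        return 1.0 / (1.0 + 10.0 ** (n * (logca - log_ic50)))

    if np.polyfit(lc, y, 1)[0] > 0.05:
        raise FitFailureError("curve increases with Ca; inhibition model inapplicable")
    best = None
    mid = lc[np.argmin(np.abs(y - 0.5))]
    for n0 in (0.5, 1.0, 2.0, 4.0):
        try:
            popt, pcov = curve_fit(
                f, lc, y, p0=(mid, n0), sigma=sigma,
                absolute_sigma=curve.sem is not None, maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        if popt[1] <= 0:
            continue
        rss = float(np.sum(((y - f(lc, *popt)) / sigma) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitFailureError("Hill fit did not converge from any start")
    popt, pcov, rss = best
    ses = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(ses)):
        raise FitFailureError("Hill fit covariance is singular")
    return HillParams(popt[0], popt[1], ses[0], ses[1], rss)


def predict_log_ic50(
    lin: LinearHillParams,
    boltz: BoltzmannParams,
    V,
    ctx: ThermoContext = DEFAULT_CTX,
):
    """log10 IC50 (mM) of the linear Hill model at voltage V (broadcasts)."""
    V = np.asarray(V, float)
    vt = ctx.thermal_voltage
    term = np.log10(1.0 + np.exp(boltz.z_delta * (V - boltz.v_half) / vt))
    out = (lin.log_kd + term) / lin.n
    return out if out.ndim else float(out)


def closed_state_kd(
    hill: HillParams,
    boltz: BoltzmannParams,
    V: float,
    ctx: ThermoContext = DEFAULT_CTX,
) -> float:
    """Closed-state dissociation constant in micromolar (mM^n convention).

    K_D = IC50^n / (1 + exp(z_delta (V - V1/2)/Vt)); at strongly
    negative V this reduces to IC50^n, the saturated-limit estimate.
    """
    n = abs(hill.n)
    vt = ctx.thermal_voltage
    kd_mm = hill.ic50**n / (1.0 + np.exp(boltz.z_delta * (V - boltz.v_half) / vt))
    return float(kd_mm * 1e3)


def global_kd_fit(
    voltages,
    log_ic50s,
    boltz: BoltzmannParams,
    n: float = 2.0,
    ctx: ThermoContext = DEFAULT_CTX,
) -> dict:
    """Least-squares K_D from pooled (V, log IC50) pairs, n fixed.

    Fits log10 IC50 = (1/n)[log K_D + log10(1 + e^{z_delta(V-V1/2)/Vt})]
    for the single parameter log K_D; the 95% CI comes from the
    t-distribution on the residuals. Returns K_D in micromolar.
    """
    V = np.asarray(voltages, float)
    y = np.asarray(log_ic50s, float)
    if V.size < 1:
        raise InvalidArgumentError("need at least one (V, log IC50) pair")
    vt = ctx.thermal_voltage
    g = np.log10(1.0 + np.exp(boltz.z_delta * (V - boltz.v_half) / vt))
    w = n * y - g  # per-point implied log K_D
    log_kd = float(np.mean(w))
    if V.size > 1:
        se = float(np.std(w, ddof=1) / np.sqrt(V.size))
        from scipy.stats import t as tdist

        half = tdist.ppf(0.975, V.size - 1) * se
    else:
        se, half = float("nan"), 0.0
    return {
        "log_kd": log_kd,
        "se_log_kd": se,
        "kd_uM": 10.0**log_kd * 1e3,
        "ci95_uM": (10.0 ** (log_kd - half) * 1e3, 10.0 ** (log_kd + half) * 1e3),
        "n": n,
    }


# -- global linear binding models -----------------------------------------


def _linear_model_prediction(kind, theta, V, Ca, boltz, vt):
    """Relative current (1+Kv)/(1+Kv(1+b(Ca))) for a linear scheme.

    Kv = [C]/[O] = exp(-z_delta (V-V1/2)/Vt); b(Ca) is the closed-state
    binding polynomial of the scheme.
    """
    Kv = np.exp(-boltz.z_delta * (V - boltz.v_half) / vt)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if kind == "hill":
            log_kd, n = theta
            b = Ca**n / 10.0**log_kd
        else:
            b = np.zeros_like(Ca)
            log_prod = np.zeros_like(Ca)
            for log_k in theta:
                log_prod = log_prod + np.log10(Ca) - log_k
                b = b + 10.0**log_prod
        out = (1.0 + Kv) / (1.0 + Kv * (1.0 + b))
    return np.nan_to_num(out, nan=0.0, posinf=1.0)


def _fit_one_linear(kind, p0s, pooled, boltz, vt):
    V, Ca, y, sigma = pooled
    best = None
    for p0 in p0s:
        res = least_squares(
            lambda th: (_linear_model_prediction(kind, th, V, Ca, boltz, vt) - y) / sigma,
            p0,
            method="lm",
            max_nfev=20000,
        )
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2 * best.cost)
    dof = max(V.size - best.x.size, 1)
    JtJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JtJ) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ) * rss / dof
        cov[np.diag(cov) <= 0] = np.inf
    ses = np.sqrt(np.abs(np.diag(cov)))
    return best.x, ses, rss


def fit_linear_models(
    curves: list[InhibitionCurve],
    boltz: BoltzmannParams,
    ctx: ThermoContext = DEFAULT_CTX,
) -> dict:
    """Global fits of the Hill, 2-site and 3-site linear schemes.

    All curves are pooled with shared, fixed Boltzmann parameters;
    each scheme is fitted by multi-start least squares. Singular
    designs are flagged via per-parameter ``ill_constrained`` rather
    than raised: a sequential scheme over-parameterized for the data
    shows standard errors that dwarf the estimates.
    """
    if len(curves) < 3:
        raise InvalidArgumentError("need inhibition curves at >= 3 voltages")
    V = np.concatenate([np.full(c.Ca_mM[c.Ca_mM > 0].size, c.V_test) for c in curves])
    Ca = np.concatenate([c.Ca_mM[c.Ca_mM > 0] for c in curves])
    y = np.concatenate([c.rel_current[c.Ca_mM > 0] for c in curves])
    sems = [
        (np.ones(c.Ca_mM[c.Ca_mM > 0].size) if c.sem is None else c.sem[c.Ca_mM > 0])
        for c in curves
    ]
    sigma = np.concatenate(sems)
    pooled = (V, Ca, y, sigma)
    vt = ctx.thermal_voltage

    x, se, rss = _fit_one_linear(
        "hill", [(-2.0, 2.0), (-1.0, 1.0), (-3.0, 3.0)], pooled, boltz, vt
    )
    hill = LinearHillParams(x[0], x[1], se[0], se[1], rss)

    x, se, rss = _fit_one_linear(
        "sites", [(0.0, -2.0), (-1.0, -1.0), (2.0, -3.0)], pooled, boltz, vt
    )
    two = SequentialSiteParams(tuple(x), tuple(se), rss)

    x, se, rss = _fit_one_linear(
        "sites",
        [(0.0, -2.0, 7.0), (-1.0, -1.0, 3.0), (0.0, -2.0, 2.0)],
        pooled,
        boltz,
        vt,
    )
    three = SequentialSiteParams(tuple(x), tuple(se), rss)
    return {"hill": hill, "two_site": two, "three_site": three}
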