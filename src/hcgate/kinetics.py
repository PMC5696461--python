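"""Exponential relaxation fitting, model-order selection and tau tables.

Current (or open-probability) relaxations following a voltage step are
fitted with one or two exponentials plus an offset. Initialization uses
exponential peeling: a log-linear fit of the tail gives the slow
component, a refit of the residual the fast one. Order selection uses
an extra-sum-of-squares F-test at the 5% level. Because the voltage
electrode needs a few milliseconds to settle after a step, the first
5 ms of each trace are excluded by default when assembling tau tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .errors import FitFailureError, InvalidArgumentError

#: Merge threshold: a 2-exponential fit whose taus differ by less than
#: this relative amount is degenerate.
TAU_MERGE_RTOL = 0.01


@dataclass(frozen=True)
class ExpFit:
    """Result of a k-exponential fit y = offset + sum_i a_i exp(-t/tau_i)."""

    k: int
    amplitudes: tuple
    taus: tuple  # seconds, ascending
    offset: float
    rss: float
    n_points: int
    se_taus: tuple = ()
    degenerate: bool = False

    def __post_init__(self):
        if self.k not in (1, 2):
            raise InvalidArgumentError("k must be 1 or 2")
        if any(t <= 0 for t in self.taus):
            raise InvalidArgumentError("taus must be positive")

    @property
    def n_params(self) -> int:
        return 2 * self.k + 1


def _decay(t, tau):
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return np.exp(np.minimum(-t / tau, 700.0))


def _exp_model(k):
    if k == 1:
        return lambda t, a1, tau1, c: c + a1 * _decay(t, tau1)
    return lambda t, a1, tau1, a2, tau2, c: (
        c + a1 * _decay(t, tau1) + a2 * _decay(t, tau2)
    )


def _peel(t, y):
    """Exponential-peeling initial estimates (slow from the tail)."""
    c = float(y[-1])
    r = y - c
    sgn = np.sign(r[np.argmax(np.abs(r))]) or 1.0
    r = r * sgn
    tail = slice(t.size // 2, None)
    pos = r[tail] > max(1e-12, 1e-4 * np.abs(r).max())
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(t[tail][pos], np.log(r[tail][pos]), 1)
        tau_slow = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        a_slow = np.exp(intercept)
    else:
        tau_slow = (t[-1] - t[0]) / 3.0
        a_slow = float(np.abs(r).max())
    resid = r - a_slow * np.exp(-t / tau_slow)
    head = slice(0, max(3, t.size // 4))
    pos = resid[head] > max(1e-12, 1e-4 * np.abs(r).max())
    if pos.sum() >= 3:
        slope, intercept = np.polyfit(t[head][pos], np.log(resid[head][pos]), 1)
        tau_fast = -1.0 / slope if slope < 0 else tau_slow / 5.0
        a_fast = np.exp(intercept)
    else:
        tau_fast = tau_slow / 5.0
        a_fast = a_slow / 2.0
    return sgn, c, a_slow, max(tau_slow, 1e-9), a_fast, max(tau_fast, 1e-9)


def fit_exponentials(t, y, k: int) -> ExpFit:
    """Nonlinear least-squares fit of k exponentials to a relaxation.

    Deterministic given the trace; peeling estimates seed the
    optimiser. Raises FitFailureError (with peeling fallback) on
    non-convergence. A two-exponential fit with merged taus or a
    vanishing amplitude is returned with ``degenerate=True``.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if k not in (1, 2):
        raise InvalidArgumentError("k must be 1 or 2")
    if t.size < 10 * k:
        raise InvalidArgumentError(f"need at least {10 * k} samples for k={k}")
    t0 = t - t[0]
    sgn, c, a_s, tau_s, a_f, tau_f = _peel(t0, y)
    model = _exp_model(k)
    span = t0[-1] - t0[0]
    scale = max(np.ptp(y), 1e-12)
    # taus bounded by the observable window, amplitudes/offset by the
    # data range: keeps noise drift from producing runaway components
    tau_lo, tau_hi = span / (5 * t0.size), 5.0 * span
    amp = 10.0 * scale
    clip = lambda tau: float(np.clip(tau, tau_lo, tau_hi))
    if k == 1:
        p0s = [(sgn * (a_s + a_f), clip(tau_s), c)]
        lb = (-amp, tau_lo, y.min() - scale)
        ub = (amp, tau_hi, y.max() + scale)
    else:
        # multi-start over fast/slow tau ratios: the peeling estimate
        # can land both components on the slow tail, where a
        # near-merged pair with canceling amplitudes is a local optimum
        p0s = [
            (sgn * a_f, clip(tau_f), sgn * a_s, clip(tau_s), c),
            (sgn * a_f, clip(tau_s / 5), sgn * a_s, clip(tau_s), c),
            (sgn * a_f, clip(tau_s / 20), sgn * a_s, clip(tau_s), c),
            (sgn * (a_s + a_f) / 2, clip(tau_s / 2), sgn * (a_s + a_f) / 2, clip(2 * tau_s), c),
        ]
        lb = (-amp, tau_lo, -amp, tau_lo, y.min() - scale)
        ub = (amp, tau_hi, amp, tau_hi, y.max() + scale)
    lb_a, ub_a = np.asarray(lb), np.asarray(ub)
    margin = 1e-9 * (ub_a - lb_a)
    p0s = [tuple(np.clip(p0, lb_a + margin, ub_a - margin)) for p0 in p0s]
    best = None
    import warnings

    for p0 in p0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt_i, pcov_i = curve_fit(
                    model, t0, y, p0=p0, bounds=(lb, ub), maxfev=40000
                )
        except (RuntimeError, ValueError):
            continue
        rss_i = float(np.sum((y - model(t0, *popt_i)) ** 2))
        if best is None or rss_i < best[2]:
            best = (popt_i, pcov_i, rss_i)
    if best is None:
        raise FitFailureError(f"{k}-exponential fit failed from every start", fallback=p0s[0])
    popt, pcov, _ = best
    rss = float(np.sum((y - model(t0, *popt)) ** 2))
    ses = np.sqrt(np.abs(np.diag(pcov)))
    if k == 1:
        taus, amps, se_taus = (abs(popt[1]),), (popt[0],), (ses[1],)
        degen = False
    else:
        pairs = sorted(
            [(abs(popt[1]), popt[0], ses[1]), (abs(popt[3]), popt[2], ses[3])]
        )
        taus = (pairs[0][0], pairs[1][0])
        amps = (pairs[0][1], pairs[1][1])
        se_taus = (pairs[0][2], pairs[1][2])
        scale = max(np.abs(y - y[-1]).max(), 1e-12)
        degen = (
            abs(taus[1] - taus[0]) < TAU_MERGE_RTOL * taus[1]
            or min(abs(a) for a in amps) < 1e-6 * scale
        )
    return ExpFit(k, tuple(amps), tuple(taus), float(popt[-1]), rss, t.size, tuple(se_taus), degen)


def select_order(t, y, alpha: float = 0.05) -> tuple[int, float, float]:
    """Extra-sum-of-squares F-test choosing 1 vs 2 exponentials.

    Returns (k, F, p). k=2 is selected when the two-exponential fit is
    non-degenerate and significantly better at level alpha.
    """
    fit1 = fit_exponentials(t, y, 1)
    try:
        fit2 = fit_exponentials(t, y, 2)
    except FitFailureError:
        return 1, 0.0, 1.0
    if fit2.degenerate or fit2.rss <= 0 or fit2.rss >= fit1.rss:
        return 1, 0.0, 1.0
    df2 = fit2.n_points - fit2.n_params
    dfd = fit2.n_params - fit1.n_params
    F = ((fit1.rss - fit2.rss) / dfd) / (fit2.rss / df2)
    p = float(f_dist.sf(F, dfd, df2))
    return (2 if p < alpha else 1), float(F), p


def extract_tau_curves(
    traces: Mapping[float, tuple[Sequence[float], Sequence[float]]],
    skip_initial: float = 0.005,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit each trace and assemble a tau table over the condition axis.

    ``traces`` maps a condition value (voltage in mV or Ca in mM) to a
    (time, signal) pair starting at the voltage step. The first
    ``skip_initial`` seconds are excluded (electrode settling). Failed
    fits are recorded as NaN rows rather than raised.
    """
    if len(traces) == 0:
        raise InvalidArgumentError("no traces supplied")
    rows = []
    for cond in sorted(traces):
        t, y = (np.asarray(a, float) for a in traces[cond])
        mask = t - t[0] >= skip_initial
        t, y = t[mask], y[mask]
        try:
            k, F, p = select_order(t, y, alpha)
            fit = fit_exponentials(t, y, 2)
            if fit.degenerate:
                raise FitFailureError("degenerate two-exponential fit")
            rows.append(
                {
                    "condition": cond,
                    "tau_fast_s": fit.taus[0],
                    "tau_fast_se": fit.se_taus[0],
                    "tau_slow_s": fit.taus[1],
                    "tau_slow_se": fit.se_taus[1],
                    "k": k,
                }
            )
        except FitFailureError:
            rows.append(
                {
                    "condition": cond,
                    "tau_fast_s": np.nan,
                    "tau_fast_se": np.nan,
                    "tau_slow_s": np.nan,
                    "tau_slow_se": np.nan,
                    "k": 0,
                }
            )
    return pd.DataFrame(rows)
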