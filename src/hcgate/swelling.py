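"""Osmotic-swelling volume analysis.

Oocyte volume is recovered from the cross-sectional area at the focal
plane assuming spherical symmetry (r = sqrt(A/pi), V = 4/3 pi r^3),
expressed relative to the initial volume, and the late-time swelling
rate is the least-squares slope of V/Vi over the final window of the
recording (50 s by default). Groups of per-oocyte rates are compared
with a two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError


@dataclass
class AreaSeries:
    """Focal-plane cross-sectional area sampled at 1 Hz (arbitrary units^2)."""

    time: np.ndarray
    area: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.area = np.asarray(self.area, float)
        if self.time.size != self.area.size:
            raise InvalidArgumentError("time and area must have equal length")


@dataclass
class VolumeSeries:
    """Absolute volume and volume relative to the first sample."""

    time: np.ndarray
    volume: np.ndarray
    label: str = ""

    @property
    def relative(self) -> np.ndarray:
        return self.volume / self.volume[0]


def volume_from_area(series: AreaSeries) -> VolumeSeries:
    """Spherical-symmetry volume from focal-plane area."""
    if np.any(series.area <= 0):
        raise InvalidArgumentError("areas must be positive")
    r = np.sqrt(series.area / np.pi)
    return VolumeSeries(series.time, 4.0 / 3.0 * np.pi * r**3, series.label)


def swelling_rate(series: VolumeSeries, window_s: float = 50.0) -> float:
    """Least-squares slope of relative volume over the final window (1/s)."""
    t, v = series.time, series.relative
    span = t[-1] - t[0]
    if span <= window_s:
        raise InvalidArgumentError(
            f"series spans {span:.0f} s, shorter than the {window_s:.0f} s window"
        )
    mask = t >= t[-1] - window_s
    return float(np.polyfit(t[mask], v[mask], 1)[0])


def compare_rates(rates_a, rates_b, alpha: float = 0.05) -> dict:
    """Two-sample t-test on per-oocyte swelling rates."""
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need at least 2 rates per group")
    t, p = stats.ttest_ind(a, b)
    return {
        "t": float(t),
        "p": float(p),
        "significant": bool(p < alpha),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
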