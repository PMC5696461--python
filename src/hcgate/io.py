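"""CSV/JSON schemas shared by the library and the command line.

All tabular files are plain CSV with a header row:

* ``gv.csv`` — V_mV, rel_tail, sem
* ``inhibition_<V>.csv`` — Ca_mM, rel_current, sem (voltage in the name
  and repeated in a V_mV column)
* ``trace_<id>.csv`` — time_s, open_prob
* ``taus.csv`` — condition, tau_fast_s, tau_fast_se, tau_slow_s,
  tau_slow_se, k
* ``areas_<id>.csv`` — time_s, area
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import GVCurve, InhibitionCurve
from .errors import InvalidArgumentError
from .swelling import AreaSeries


def _read(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"input file not found: {path}")
    return pd.read_csv(path)


def write_gv(curve: GVCurve, path) -> None:
    sem = np.full(curve.V_mV.size, np.nan) if curve.sem is None else curve.sem
    pd.DataFrame({"V_mV": curve.V_mV, "rel_tail": curve.rel_tail, "sem": sem}).to_csv(
        path, index=False
    )


def read_gv(path) -> GVCurve:
    df = _read(path)
    sem = df["sem"].to_numpy() if "sem" in df and df["sem"].notna().all() else None
    return GVCurve(df["V_mV"].to_numpy(), df["rel_tail"].to_numpy(), sem)


def write_inhibition(curve: InhibitionCurve, path) -> None:
    sem = np.full(curve.Ca_mM.size, np.nan) if curve.sem is None else curve.sem
    pd.DataFrame(
        {
            "V_mV": np.full(curve.Ca_mM.size, curve.V_test),
            "Ca_mM": curve.Ca_mM,
            "rel_current": curve.rel_current,
            "sem": sem,
        }
    ).to_csv(path, index=False)


def read_inhibition(path) -> InhibitionCurve:
    df = _read(path)
    sem = df["sem"].to_numpy() if "sem" in df and df["sem"].notna().all() else None
    return InhibitionCurve(
        float(df["V_mV"].iloc[0]), df["Ca_mM"].to_numpy(), df["rel_current"].to_numpy(), sem
    )


def write_trace(time, signal, path, column: str = "open_prob") -> None:
    pd.DataFrame({"time_s": time, column: signal}).to_csv(path, index=False)


def read_trace(path, column: str = "open_prob"):
    df = _read(path)
    return df["time_s"].to_numpy(), df[column].to_numpy()


def write_taus(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_taus(path) -> pd.DataFrame:
    return _read(path)


def write_areas(series: AreaSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "area": series.area}).to_csv(path, index=False)


def read_areas(path, label: str = "") -> AreaSeries:
    df = _read(path)
    return AreaSeries(df["time_s"].to_numpy(), df["area"].to_numpy(), label)


def write_taudata(tab, path) -> None:
    """Serialize a bayes.TauData table (axis/fixed repeated per row)."""
    pd.DataFrame(
        {
            "axis": [tab.axis] * tab.conditions.size,
            "fixed": np.full(tab.conditions.size, tab.fixed),
            "condition": tab.conditions,
            "tau_fast_s": tab.tau_fast,
            "tau_fast_sd": tab.sd_fast,
            "tau_slow_s": tab.tau_slow,
            "tau_slow_sd": tab.sd_slow,
        }
    ).to_csv(path, index=False)


def read_taudata(path):
    from .bayes import TauData

    df = _read(path)
    return TauData(
        str(df["axis"].iloc[0]),
        float(df["fixed"].iloc[0]),
        df["condition"].to_numpy(),
        df["tau_fast_s"].to_numpy(),
        df["tau_slow_s"].to_numpy(),
        df["tau_fast_sd"].to_numpy(),
        df["tau_slow_sd"].to_numpy(),
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=float))


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"input file not found: {path}")
    return json.loads(path.read_text())
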