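"""Published reference estimates for rat Cx46 hemichannels.

Literature values from two-electrode voltage-clamp recordings of Cx46
expressed in *Xenopus laevis* oocytes. These serve as ground truth for
the synthetic-data generators and as worked-example inputs: the
Boltzmann activation parameters of the tail-current G-V curve, the
Hill inhibition parameters of the depolarizing-pulse protocol, the
apparent Ca2+ affinity at each test voltage, the linear
closed-state-stabilization (Hill) fit pooled across voltages, and the
most-likely values of the six-site allosteric gating model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import AllostericParams

#: Boltzmann activation of the tail-current G-V curve: (V1/2 mV, z-delta e0).
GV_BOLTZMANN = {"v_half": -18.0, "z_delta": 2.8}

#: Hill inhibition of the 0 mV depolarizing-pulse protocol.
HILL_INHIBITION = {"ic50_mM": 0.17, "n": 2.0}

#: Apparent Ca2+ affinity (log10 IC50 in mM) and Hill slope at each test
#: voltage; Hill slopes quoted as magnitudes. Values are mean +/- SEM.
INHIBITION_BY_VOLTAGE = pd.DataFrame(
    {
        "V_mV": [-50.0, -30.0, -20.0, 0.0, 10.0, 20.0],
        "log_ic50": [-1.09, -1.1, -1.09, -0.8, -0.5, -0.2],
        "log_ic50_sem": [0.06, 0.1, 0.06, 0.1, 0.1, 0.1],
        "hill_slope": [1.9, 2.5, 2.4, 2.0, 2.3, 2.0],
        "hill_slope_sem": [0.2, 0.7, 0.2, 0.2, 0.2, 0.6],
    }
)

#: Linear closed-state-stabilization model with Hill binding, fitted
#: globally to the inhibition curves at all test voltages.
LINEAR_HILL = {"log_kd": -2.31, "log_kd_se": 0.07, "n": 1.99, "n_se": 0.07}

#: Most-likely values of the six-binding-site allosteric model.
CX46_MLV = AllostericParams(
    A0=7.12,
    B0=0.92,
    C0=0.74,
    D0=1.22,
    za=0.0015e-6,
    zb=0.22,
    zc=0.18,
    zd=1.99,
    z1=0.85,
    V1=-126.0,
    Kd=0.96,
    c_b=1.11,
    c_f=0.87,
    m=6,
)

#: 95% credible intervals of the six-site model (per-parameter lo, hi).
CX46_MLV_CI = {
    "za": (0.0, 0.072),
    "zb": (0.13, 0.31),
    "zc": (0.12, 0.25),
    "zd": (1.66, 2.44),
    "A0": (5.23, 8.14),
    "B0": (0.77, 1.18),
    "C0": (0.57, 0.95),
    "D0": (0.91, 1.52),
    "z1": (0.69, 0.96),
    "V1": (-141.0, -113.0),
    "Kd": (0.85, 1.13),
    "c_b": (1.07, 1.15),
    "c_f": (0.76, 1.00),
}

#: Relative oocyte volume after 900 s in hypotonic solution.
SWELLING_RELATIVE_VOLUME = {"no_ca": 1.08, "ca_5mM": 1.03}


def table1_pairs() -> tuple[np.ndarray, np.ndarray]:
    """(voltages mV, log10 IC50 mM) pairs of the per-voltage Hill fits."""
    t = INHIBITION_BY_VOLTAGE
    return t["V_mV"].to_numpy(), t["log_ic50"].to_numpy()
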