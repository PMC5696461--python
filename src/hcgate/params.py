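"""Parameter vector of the allosteric voltage/Ca2+ gating model.

The model has one open state O and three closed tiers C1, C2, C3. The
O<->C1 step is a fast voltage-dependent equilibrium (charge ``z1``,
half-point ``V1``); the two slow voltage-dependent steps C1<->C2 and
C2<->C3 carry rate prefactors ``A0``..``D0`` (the rates at 0 mV) and
partial charges ``za``..``zd``. Ca2+ binds only to the closed tiers at
``m`` identical independent sites with per-site dissociation constant
``Kd`` in tier C1; the per-bound-ion kinetic factors ``c_b`` (closing)
and ``c_f`` (opening) couple occupancy to gating, and their ratio
``C = c_b/c_f`` scales the binding constant of each deeper tier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .errors import InvalidArgumentError
from .thermo import ThermoContext

_POSITIVE = ("A0", "B0", "C0", "D0", "Kd", "c_b", "c_f")
_CHARGES = ("za", "zb", "zc", "zd", "z1")


@dataclass(frozen=True)
class AllostericParams:
    """Rates, charges and binding constants of the allosteric model.

    Units: prefactors in s^-1, charges in elementary charges, ``V1`` in
    mV, ``Kd`` in mM, ``c_b``/``c_f`` dimensionless, ``m`` a positive
    integer count of Ca2+ binding sites.
    """

    A0: float
    B0: float
    C0: float
    D0: float
    za: float
    zb: float
    zc: float
    zd: float
    z1: float
    V1: float
    Kd: float
    c_b: float
    c_f: float
    m: int

    def __post_init__(self):
        for name in _POSITIVE:
            if not (getattr(self, name) > 0):
                raise InvalidArgumentError(f"{name} must be > 0")
        for name in _CHARGES:
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not (isinstance(self.m, (int,)) and not isinstance(self.m, bool)):
            raise InvalidArgumentError(f"m must be an integer, got {self.m!r}")
        if self.m < 1:
            raise InvalidArgumentError(f"m must be >= 1, got {self.m}")

    @property
    def coupling(self) -> float:
        """Coupling constant C = c_b / c_f (never stored independently)."""
        return self.c_b / self.c_f

    def replace(self, **kwargs) -> "AllostericParams":
        return replace(self, **kwargs)

    # -- JSON serialization -------------------------------------------------

    def to_dict(self, ctx: ThermoContext | None = None) -> dict:
        d = asdict(self)
        d["temperature_K"] = (ctx or ThermoContext()).temperature
        return d

    def to_json(self, path, ctx: ThermoContext | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(ctx), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> tuple["AllostericParams", ThermoContext]:
        d = dict(d)
        temp = d.pop("temperature_K", 295.0)
        d["m"] = int(d["m"])
        return cls(**d), ThermoContext(temp)

    @classmethod
    def from_json(cls, path) -> tuple["AllostericParams", ThermoContext]:
        return cls.from_dict(json.loads(Path(path).read_text()))
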