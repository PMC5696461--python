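"""Thermodynamic context: temperature and the thermal voltage RT/F.

All voltage dependences in the gating model enter through dimensionless
ratios z*V / (RT/F), so the only thermodynamic quantity the rest of the
package needs is the thermal voltage in millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1


@dataclass(frozen=True)
class ThermoContext:
    """Temperature of the preparation.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Defaults to 295 K (room
        temperature for a two-electrode voltage-clamp rig).
    """

    temperature: float = 295.0

    def __post_init__(self):
        if not (self.temperature > 0):
            raise InvalidArgumentError(
                f"temperature must be positive, got {self.temperature}"
            )

    @property
    def thermal_voltage(self) -> float:
        """RT/F in millivolts (≈ 25.42 mV at 295 K)."""
        return 1e3 * GAS_CONSTANT * self.temperature / FARADAY


DEFAULT_CTX = ThermoContext()
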