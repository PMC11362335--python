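"""Counts-to-concentration conversion and calibration.

The number concentration of particles in the sample flow is

    C = R / (A * U)                                        (per channel)

with R the particle detection rate corrected for the recording duty cycle,
A the effective detection area perpendicular to the flow, and U the mean
flow velocity in the cell.  A is calibrated from suspensions of PSL spheres
whose absolute concentration is fixed independently by a transmission
(Lambert–Beer) measurement.

Internally concentrations are carried in m^-3; the conventional reporting
unit is mL^-1 (1 m^-3 = 1e-6 mL^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "A_S_CHANNEL_M2",
    "A_L_CHANNEL_M2",
    "ChannelCalibration",
    "CountSummary",
    "detection_rate",
    "number_concentration",
    "effective_area",
    "lambert_beer_concentration",
    "per_ml",
]

#: calibrated effective detection areas (m²); plateau values from the
#: 0.510–1.036 µm (s) and 2.020–5.010 µm (l) PSL runs.  Using the plateau
#: for all sizes underestimates concentrations of the smallest particles
#: (< ~0.5 µm in s, < ~1 µm in l), whose lower signal-to-noise reduces the
#: effective area.
A_S_CHANNEL_M2 = 4.52e-11
A_L_CHANNEL_M2 = 2.38e-10


def per_ml(concentration_m3: float) -> float:
    """Convert a concentration from m^-3 to mL^-1."""
    return concentration_m3 * 1e-6


@dataclass(frozen=True)
class ChannelCalibration:
    """Per-channel geometry/flow calibration entering C = R/(A U).

    ``flow_velocity`` (U, m/s) has no published default and must be supplied;
    if the flow cell's cross-section area is known, U = flow_rate / area.
    ``flow_rate_ml_min`` is metadata only (nominal 1.9 mL/min).
    """

    effective_area: float          # A, m²
    flow_velocity: float           # U, m/s
    duty_cycle: float = 1.0        # fraction of wall time available for logging
    flow_rate_ml_min: float = 1.9

    def __post_init__(self) -> None:
        if not (self.effective_area > 0 and math.isfinite(self.effective_area)):
            raise ValueError("effective_area must be positive")
        if not (self.flow_velocity > 0 and math.isfinite(self.flow_velocity)):
            raise ValueError("flow_velocity must be positive")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must be in (0, 1]")

    def sampled_volume_m3(self, wall_time_s: float) -> float:
        """Effective sampled volume A*U*duty*t (m³) for a measurement."""
        return self.effective_area * self.flow_velocity * self.duty_cycle * wall_time_s


@dataclass(frozen=True)
class CountSummary:
    """Raw count over a wall-time interval and its duty-corrected rate."""

    raw_count: int
    wall_time: float
    duty_cycle: float = 1.0

    def __post_init__(self) -> None:
        if self.raw_count < 0:
            raise ValueError("raw_count must be >= 0")
        if self.wall_time <= 0:
            raise ValueError("wall_time must be positive")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must be in (0, 1]")

    @property
    def corrected_rate(self) -> float:
        return detection_rate(self.raw_count, self.wall_time, self.duty_cycle)


def detection_rate(raw_count: int, wall_time: float, duty_cycle: float = 1.0) -> float:
    """Duty-cycle-corrected detection rate R = n / (t * duty), in s^-1."""
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    if wall_time <= 0:
        raise ValueError("wall_time must be positive")
    if not (0.0 < duty_cycle <= 1.0):
        raise ValueError("duty_cycle must be in (0, 1]")
    return raw_count / (wall_time * duty_cycle)


def number_concentration(rate: float, cal: ChannelCalibration) -> float:
    """C = R/(A U), in m^-3."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rate / (cal.effective_area * cal.flow_velocity)


def effective_area(rate: float, concentration_known: float, flow_velocity: float) -> float:
    """A = R/(C U) — the calibration inverse, from a known-concentration run."""
    if rate <= 0 or concentration_known <= 0 or flow_velocity <= 0:
        raise ValueError("rate, concentration and velocity must be positive")
    return rate / (concentration_known * flow_velocity)


def lambert_beer_concentration(
    transmittance: float, path_length: float, c_ext: float
) -> float:
    """N = -ln(T)/(C_ext * L): suspension number concentration (m^-3) from
    transmitted intensity fraction T over path L (m), extinction
    cross-section C_ext (m²) per particle."""
    if not (0.0 < transmittance <= 1.0):
        raise ValueError("transmittance must be in (0, 1]")
    if path_length <= 0 or c_ext <= 0:
        raise ValueError("path_length and c_ext must be positive")
    return -math.log(transmittance) / (c_ext * path_length)
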