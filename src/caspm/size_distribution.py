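"""Channel merging and size-resolved concentrations dN/dlogD, dV/dlogD.

The two channels overlap in amplitude space; to avoid double counting,
s-channel events are used inside the rectangle 0 < ReS < 1.5 µm,
0 < ImS < 0.5 µm and l-channel events inside the larger window
0 < ReS < 10 µm, 0 < ImS < 5 µm minus that rectangle.  l-channel events
above the outer window are discarded (the plane-wave approximation behind
the amplitude retrieval fails for them).

Sized, typed events are histogrammed on a log10-spaced diameter grid:

    dN/dlogD[bin] = count[bin] / (sampled_volume_of_channel * dlogD)
    dV/dlogD[bin] = dN/dlogD[bin] * pi * D_mid^3 / 6

with sampled volume A*U*duty*t per channel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import Channel, L_WINDOW, S_WINDOW, ParticleType

__all__ = [
    "RegionAssignment",
    "ChannelRegion",
    "SizeGrid",
    "SizeResolvedConcentration",
    "assign_channel_region",
    "build_size_distribution",
    "volume_distribution",
    "integrate",
]


class RegionAssignment(str, enum.Enum):
    USE_S = "use_s"
    USE_L = "use_l"
    DISCARD = "discard"


@dataclass(frozen=True)
class ChannelRegion:
    """Disjoint amplitude-plane acceptance regions for the two channels."""

    s_rect: tuple[float, float] = S_WINDOW   # (re_max, im_max) µm
    l_outer: tuple[float, float] = L_WINDOW

    def assign(
        self, channel: np.ndarray, re_s: np.ndarray, im_s: np.ndarray
    ) -> np.ndarray:
        """Vectorized region rule; returns an object array of region values.

        Values are the strings of :class:`RegionAssignment` (a str enum, so
        comparisons against the enum members work either way).
        """
        channel = np.asarray(channel)
        re_s = np.asarray(re_s, dtype=float)
        im_s = np.asarray(im_s, dtype=float)
        in_s_rect = (
            (re_s > 0) & (re_s < self.s_rect[0]) & (im_s > 0) & (im_s < self.s_rect[1])
        )
        in_outer = (
            (re_s > 0) & (re_s < self.l_outer[0]) & (im_s > 0) & (im_s < self.l_outer[1])
        )
        is_s = channel == Channel.S_CHANNEL.value
        out = np.full(re_s.size, RegionAssignment.DISCARD.value, dtype=object)
        out[is_s & in_s_rect] = RegionAssignment.USE_S.value
        out[~is_s & in_outer & ~in_s_rect] = RegionAssignment.USE_L.value
        return out


def assign_channel_region(
    channel: Channel | str, re_s: float, im_s: float,
    region: ChannelRegion | None = None,
) -> RegionAssignment:
    """Region rule for a single event."""
    region = region or ChannelRegion()
    ch = channel.value if isinstance(channel, Channel) else channel
    return RegionAssignment(
        region.assign(np.array([ch]), np.array([re_s]), np.array([im_s]))[0]
    )


@dataclass(frozen=True)
class SizeGrid:
    """Log10-uniform diameter bin edges (µm)."""

    edges: np.ndarray
    bins_per_decade: int = 16

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing, >= 2 values")
        dlog = np.diff(np.log10(e))
        if not np.allclose(dlog, dlog[0], rtol=1e-9):
            raise ValueError("edges must be log-uniform")

    @classmethod
    def from_range(
        cls, d_min: float = 0.1, d_max: float = 10.0, bins_per_decade: int = 16
    ) -> "SizeGrid":
        n_bins = int(round(math.log10(d_max / d_min) * bins_per_decade))
        edges = 10.0 ** (
            math.log10(d_min)
            + np.arange(n_bins + 1) * (math.log10(d_max / d_min) / n_bins)
        )
        return cls(edges=edges, bins_per_decade=bins_per_decade)

    @property
    def dlog(self) -> float:
        return float(np.log10(self.edges[1] / self.edges[0]))

    @property
    def mids(self) -> np.ndarray:
        """Geometric bin midpoints."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


# Type labels that carry a size distribution
_SIZED_TYPES = tuple(ParticleType(i) for i in range(5))


@dataclass(frozen=True, eq=False)
class SizeResolvedConcentration:
    """Per-Type dN/dlogD (mL^-1) and dV/dlogD (µm³ mL^-1) on a SizeGrid."""

    grid: SizeGrid
    dn_dlogd: dict            # ParticleType -> array over bins, mL^-1
    dv_dlogd: dict | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, arr in self.dn_dlogd.items():
            if np.asarray(arr).shape != (self.grid.n_bins,):
                raise ValueError(f"dN/dlogD for {t} has wrong shape")
            if np.any(np.asarray(arr) < 0):
                raise ValueError("concentrations must be non-negative")

    def types(self):
        return list(self.dn_dlogd)

    def total_dn(self) -> np.ndarray:
        return np.sum([self.dn_dlogd[t] for t in self.dn_dlogd], axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (type, D_mid_um, dN_dlogD_per_mL[, dV_dlogD_um3_per_mL])."""
        rows = []
        dv = self.dv_dlogd or {}
        for t, arr in self.dn_dlogd.items():
            name = t.name if isinstance(t, ParticleType) else str(t)
            for i, mid in enumerate(self.grid.mids):
                row = {"type": name, "D_mid_um": mid, "dN_dlogD_per_mL": arr[i]}
                if t in dv:
                    row["dV_dlogD_um3_per_mL"] = dv[t][i]
                rows.append(row)
        return pd.DataFrame(rows)


def build_size_distribution(
    diameters: np.ndarray,
    type_codes: np.ndarray,
    regions: np.ndarray,
    grid: SizeGrid,
    sampled_volume_ml: dict,
    metadata: dict | None = None,
) -> SizeResolvedConcentration:
    """Histogram sized, typed, region-assigned events into dN/dlogD.

    ``sampled_volume_ml`` maps 's'/'l' to the channel's effective sampled
    volume in mL (A*U*duty*t); each event divides by its own channel's
    volume, and the two channels' disjoint contributions add.
    """
    for key in ("s", "l"):
        if key in sampled_volume_ml and sampled_volume_ml[key] <= 0:
            raise ValueError("sampled volume must be positive")
    diameters = np.asarray(diameters, dtype=float)
    type_codes = np.asarray(type_codes)
    regions = np.asarray(regions, dtype=object)

    dn = {t: np.zeros(grid.n_bins) for t in _SIZED_TYPES}
    for region_key, vol_key in (
        (RegionAssignment.USE_S, "s"),
        (RegionAssignment.USE_L, "l"),
    ):
        sel = regions == region_key.value
        if not sel.any():
            continue
        if vol_key not in sampled_volume_ml:
            raise ValueError(f"no sampled volume given for the {vol_key}-channel")
        vol = sampled_volume_ml[vol_key]
        for t in _SIZED_TYPES:
            mask = sel & (type_codes == int(t)) & np.isfinite(diameters)
            if not mask.any():
                continue
            counts, _ = np.histogram(diameters[mask], bins=grid.edges)
            dn[t] += counts / (vol * grid.dlog)
    return SizeResolvedConcentration(
        grid=grid, dn_dlogd=dn, metadata=dict(metadata or {})
    )


def volume_distribution(dist: SizeResolvedConcentration) -> SizeResolvedConcentration:
    """Attach dV/dlogD = dN/dlogD * pi D_mid^3/6 (µm³ mL^-1) per bin."""
    mult = math.pi * dist.grid.mids**3 / 6.0
    dv = {t: arr * mult for t, arr in dist.dn_dlogd.items()}
    return SizeResolvedConcentration(
        grid=dist.grid, dn_dlogd=dist.dn_dlogd, dv_dlogd=dv, metadata=dist.metadata
    )


def integrate(
    dist: SizeResolvedConcentration,
    d_lo: float,
    d_hi: float,
    which: str = "number",
    particle_type: ParticleType | None = None,
) -> float | dict:
    """Integral of dX/dlogD over [d_lo, d_hi] (partial bins pro-rated in logD).

    ``which`` is "number" (mL^-1) or "volume" (µm³ mL^-1).  With
    ``particle_type=None`` a dict over Types is returned.
    """
    edges = dist.grid.edges
    if not (edges[0] <= d_lo < d_hi <= edges[-1]):
        raise ValueError("integration range must be non-empty and inside the grid")
    if which == "number":
        source = dist.dn_dlogd
    elif which == "volume":
        if dist.dv_dlogd is None:
            dist = volume_distribution(dist)
        source = dist.dv_dlogd
    else:
        raise ValueError("which must be 'number' or 'volume'")
    log_e = np.log10(edges)
    lo, hi = math.log10(d_lo), math.log10(d_hi)
    # overlap of [lo, hi] with each bin, in logD
    overlap = np.clip(
        np.minimum(hi, log_e[1:]) - np.maximum(lo, log_e[:-1]), 0.0, None
    )

    def _one(arr):
        return float(np.sum(arr * overlap))

    if particle_type is not None:
        return _one(source[particle_type])
    return {t: _one(arr) for t, arr in source.items()}
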