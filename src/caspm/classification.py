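"""Complex-plane particle-type classification.

Each detected particle is a point (ReS, ImS) on the amplitude plane.  The
plane is partitioned by three theoretical S curves for non-absorbing spheres
(m = 1.38, 1.43, 1.60 by default), two straight lines, and a small exclusion
ellipse around the origin:

* Type 0 — right of the m=1.38 curve (diatom fragments, carbonaceous),
* Type 1 — between the 1.38 and 1.43 curves (carbonaceous),
* Type 2 — between the 1.43 and 1.60 curves (mineral dust),
* left of the 1.60 curve, s-channel only:
  Type 3 — right of y = -5.5x + 0.6 or of y = 0.72x - 0.0072 (iron oxides),
  Type 4 — left of both lines (black carbon);
* l-channel points left of the 1.60 curve are UNCLASSIFIED (Types 3/4 are
  not defined there);
* s-channel points inside (x/0.2)^2 + (y/0.025)^2 <= 1 are EXCLUDED (too
  concentrated near the origin to separate).

"Right" always means the greater-ReS side of a boundary.  Curves are used
on their initial monotone branch clipped to the channel window, and the
side of a point is the sign of the cross product between the nearest curve
segment (directed toward increasing D) and the segment-to-point vector.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .mie_optics import ComplexAmplitude, OpticalConfig, SCurve, theoretical_curve

__all__ = [
    "Channel",
    "ParticleType",
    "Side",
    "TypeBoundaries",
    "ellipse_excluded",
    "side_of_curve",
    "classify_point",
    "classify_arrays",
    "S_WINDOW",
    "L_WINDOW",
]

#: s-channel accepted amplitude window (re_s < 1.5 µm, im_s < 0.5 µm)
S_WINDOW = (1.5, 0.5)
#: outer amplitude window for the l-channel (re_s < 10 µm, im_s < 5 µm)
L_WINDOW = (10.0, 5.0)


class Channel(str, enum.Enum):
    """Detection channel; s targets 0.2–1.0 µm particles, l targets 1.0–5.0 µm."""

    S_CHANNEL = "s"
    L_CHANNEL = "l"

    @property
    def nominal_size_range(self) -> tuple[float, float]:
        return (0.2, 1.0) if self is Channel.S_CHANNEL else (1.0, 5.0)

    @property
    def window(self) -> tuple[float, float]:
        return S_WINDOW if self is Channel.S_CHANNEL else L_WINDOW


class ParticleType(enum.IntEnum):
    TYPE0 = 0
    TYPE1 = 1
    TYPE2 = 2
    TYPE3 = 3
    TYPE4 = 4
    EXCLUDED = 5
    UNCLASSIFIED = 6


class Side(enum.Enum):
    RIGHT = "right"
    LEFT = "left"
    ON = "on"


def ellipse_excluded(
    point: ComplexAmplitude, a: float = 0.2, b: float = 0.025
) -> bool:
    """True iff the point lies inside or on (x/a)^2 + (y/b)^2 = 1.

    Applied by the classifier to s-channel events only.
    """
    return (point.re_s / a) ** 2 + (point.im_s / b) ** 2 <= 1.0


def _clip_to_window(curve: SCurve, window: tuple[float, float]) -> SCurve:
    """Initial monotone branch of the curve, stopped at the first window exit."""
    branch = curve.initial_monotone_branch()
    inside = (
        (branch.re_s > 0)
        & (branch.re_s < window[0])
        & (branch.im_s > 0)
        & (branch.im_s < window[1])
    )
    stop = int(np.argmin(inside)) if not inside.all() else len(branch)
    stop = max(stop, 2)
    return SCurve(
        m_real=branch.m_real,
        diameters=branch.diameters[:stop],
        re_s=branch.re_s[:stop],
        im_s=branch.im_s[:stop],
        optics=branch.optics,
    )


def signed_distance_to_curve(
    re_s: np.ndarray, im_s: np.ndarray, curve: SCurve, chunk: int = 20000
) -> np.ndarray:
    """Signed perpendicular distance from points to the curve polyline, in µm.

    Positive on the LEFT (smaller-ReS) side, negative on the RIGHT.  The
    sign comes from the cross product of the nearest segment's direction
    (increasing D) with the segment-to-point vector; among equidistant
    segments the more decisive (larger |cross|) one wins.
    """
    re_s = np.atleast_1d(np.asarray(re_s, dtype=float))
    im_s = np.atleast_1d(np.asarray(im_s, dtype=float))
    ax, ay = curve.re_s[:-1], curve.im_s[:-1]
    tx, ty = np.diff(curve.re_s), np.diff(curve.im_s)
    seg_len2 = tx * tx + ty * ty
    out = np.empty(re_s.size)
    for lo in range(0, re_s.size, chunk):
        px = re_s[lo : lo + chunk, None]
        py = im_s[lo : lo + chunk, None]
        t = ((px - ax) * tx + (py - ay) * ty) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dx = px - (ax + t * tx)
        dy = py - (ay + t * ty)
        dist2 = dx * dx + dy * dy
        cross = tx * (py - ay) - ty * (px - ax)
        # nearest segment; break exact distance ties toward larger |cross|
        best = np.argmin(dist2, axis=1)
        rows = np.arange(px.shape[0])
        d_best = np.sqrt(dist2[rows, best])
        # check the neighboring segment sharing the nearest vertex
        alt = np.clip(best + np.where(t[rows, best] < 0.5, -1, 1), 0, tx.size - 1)
        tie = np.isclose(np.sqrt(dist2[rows, alt]), d_best, rtol=0, atol=1e-15)
        use_alt = tie & (np.abs(cross[rows, alt]) > np.abs(cross[rows, best]))
        pick = np.where(use_alt, alt, best)
        sign = np.sign(cross[rows, pick])
        sign[sign == 0] = 1.0  # exactly on the segment line -> distance 0 anyway
        out[lo : lo + chunk] = sign * d_best
    return out


@dataclass(frozen=True, eq=False)
class TypeBoundaries:
    """All geometric boundaries of the Type 0–4 partition.

    Curves are stored over the full diameter range; clipping to the channel
    window happens lazily per channel.  ``line_a``/``line_b`` are (slope,
    intercept) pairs on the (ReS, ImS) plane; the ellipse semi-axes are in
    µm on ReS and ImS respectively.
    """

    curve_138: SCurve
    curve_143: SCurve
    curve_160: SCurve
    line_a: tuple[float, float] = (-5.5, 0.6)
    line_b: tuple[float, float] = (0.72, -0.0072)
    ellipse_a: float = 0.2
    ellipse_b: float = 0.025
    on_tolerance: float = 1e-9
    #: max polyline points per clipped boundary; the chord error of these
    #: gently curved boundaries at 300 points is ~1e-5 µm, far below the
    #: measurement noise scale
    max_boundary_points: int = 300
    _clipped: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (self.ellipse_a > 0 and self.ellipse_b > 0):
            raise ValueError("ellipse semi-axes must be positive")
        optics = {c.optics for c in (self.curve_138, self.curve_143, self.curve_160)}
        if len(optics) != 1:
            raise ValueError("boundary curves must share one OpticalConfig")

    @classmethod
    def from_optics(
        cls,
        optics: OpticalConfig,
        curve_m: tuple[float, float, float] = (1.38, 1.43, 1.60),
        n_points: int = 2000,
        **kwargs,
    ) -> "TypeBoundaries":
        c = [theoretical_curve(m, optics, 0.1, 10.0, n_points) for m in curve_m]
        return cls(curve_138=c[0], curve_143=c[1], curve_160=c[2], **kwargs)

    def clipped(self, curve: SCurve, channel: Channel) -> SCurve:
        key = (id(curve), channel)
        if key not in self._clipped:
            c = _clip_to_window(curve, channel.window)
            if len(c) > self.max_boundary_points:
                keep = np.unique(
                    np.linspace(0, len(c) - 1, self.max_boundary_points).round()
                ).astype(int)
                c = SCurve(
                    m_real=c.m_real,
                    diameters=c.diameters[keep],
                    re_s=c.re_s[keep],
                    im_s=c.im_s[keep],
                    optics=c.optics,
                )
            self._clipped[key] = c
        return self._clipped[key]


def side_of_curve(
    point: ComplexAmplitude, curve: SCurve, tolerance: float = 1e-9
) -> Side:
    """Which side of the curve's initial monotone branch the point lies on."""
    if len(curve) < 2:
        raise ValueError("curve must have at least 2 points")
    d = signed_distance_to_curve(point.re_s, point.im_s, curve)[0]
    if abs(d) <= tolerance:
        return Side.ON
    return Side.LEFT if d > 0 else Side.RIGHT


def _right_of_line(x: np.ndarray, y: np.ndarray, line: tuple[float, float]) -> np.ndarray:
    """True iff the point is on the greater-ReS side of y = slope*x + intercept.

    Boundary points (x exactly at the line) count as right.
    """
    slope, intercept = line
    if slope == 0:
        raise ValueError("horizontal boundary line has no ReS side")
    return x >= (y - intercept) / slope if slope > 0 else x >= (intercept - y) / (-slope)


def classify_arrays(
    re_s: np.ndarray,
    im_s: np.ndarray,
    channel: Channel,
    boundaries: TypeBoundaries,
) -> np.ndarray:
    """Vectorized Type assignment; returns an int array of ParticleType values.

    Points are assumed to be inside the channel's accepted S-region; the
    region filter itself lives in :mod:`caspm.size_distribution`.
    """
    re_s = np.atleast_1d(np.asarray(re_s, dtype=float))
    im_s = np.atleast_1d(np.asarray(im_s, dtype=float))
    tol = boundaries.on_tolerance
    out = np.full(re_s.size, int(ParticleType.UNCLASSIFIED), dtype=int)

    undecided = np.ones(re_s.size, dtype=bool)
    if channel is Channel.S_CHANNEL:
        excl = (re_s / boundaries.ellipse_a) ** 2 + (im_s / boundaries.ellipse_b) ** 2 <= 1.0
        out[excl] = int(ParticleType.EXCLUDED)
        undecided &= ~excl

    for curve, label in (
        (boundaries.curve_138, ParticleType.TYPE0),
        (boundaries.curve_143, ParticleType.TYPE1),
        (boundaries.curve_160, ParticleType.TYPE2),
    ):
        if not undecided.any():
            break
        clipped = boundaries.clipped(curve, channel)
        d = signed_distance_to_curve(re_s[undecided], im_s[undecided], clipped)
        hit = d <= tol  # RIGHT of (or ON) the curve; ON -> lower Type index
        idx = np.flatnonzero(undecided)[hit]
        out[idx] = int(label)
        undecided[idx] = False

    if undecided.any():  # left of the m=1.60 curve
        if channel is Channel.S_CHANNEL:
            x, y = re_s[undecided], im_s[undecided]
            type3 = _right_of_line(x, y, boundaries.line_a) | _right_of_line(
                x, y, boundaries.line_b
            )
            idx = np.flatnonzero(undecided)
            out[idx[type3]] = int(ParticleType.TYPE3)
            out[idx[~type3]] = int(ParticleType.TYPE4)
        # l-channel: stays UNCLASSIFIED (Types 3/4 not defined there)
    return out


def classify_point(
    point: ComplexAmplitude, channel: Channel, boundaries: TypeBoundaries
) -> ParticleType:
    """Assign a single amplitude point to a ParticleType."""
    code = classify_arrays(
        np.array([point.re_s]), np.array([point.im_s]), channel, boundaries
    )[0]
    return ParticleType(code)


@lru_cache(maxsize=4)
def default_boundaries(medium_index: float, wavelength: float = 0.6328) -> TypeBoundaries:
    """Cached standard boundaries for a given suspension medium."""
    return TypeBoundaries.from_optics(
        OpticalConfig(wavelength_vacuum=wavelength, medium_index=medium_index)
    )
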