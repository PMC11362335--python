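"""Amplitude-to-size inversion.

Three routes, dispatched on the particle Type:

* ``invert_nonabsorbing`` — nearest-cell lookup in a dense (m, D) table of
  theoretical S values for non-absorbing spheres (Types 0–3); returns the
  most-likely refractive index ``m_ml`` and diameter minimizing the
  Euclidean distance in the (ReS, ImS) plane.
* ``project_onto_curve`` — projection onto a single-m S curve (used for
  PSL calibration runs where the refractive index is known).
* ``size_bc`` — monotone interpolation of an externally supplied
  amplitude-to-volume-equivalent-diameter calibration (Type 4 / black
  carbon, whose irregular fractal morphology invalidates the sphere model).

Type 3 (iron oxides) is sized with the non-absorbing sphere table even
though the particles absorb; this mirrors the measurement chain's own
acknowledged approximation and carries the corresponding size uncertainty.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .classification import ParticleType
from .mie_optics import (
    ComplexAmplitude,
    OpticalConfig,
    SCurve,
    SLookupTable,
    forward_amplitude_batch,
)

__all__ = [
    "SizingMethod",
    "SizingResult",
    "BCCalibration",
    "LookupInverter",
    "invert_nonabsorbing",
    "invert_nonabsorbing_exhaustive",
    "project_onto_curve",
    "size_bc",
    "size_events",
    "synthetic_bc_calibration",
]


class SizingMethod(str, enum.Enum):
    LOOKUP = "lookup"
    PSL_PROJECTION = "psl_projection"
    BC_CALIBRATION = "bc_calibration"


@dataclass(frozen=True)
class SizingResult:
    """Outcome of one amplitude-to-size inversion.

    ``residual`` is the remaining distance in the S plane (µm); ``m_ml`` is
    None for BC-calibrated sizing; ``clamped`` flags an out-of-range BC
    amplitude whose diameter was clamped to the calibration endpoint.
    """

    diameter: float
    m_ml: float | None
    residual: float
    method: SizingMethod
    clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("diameter must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def _tie_order_flat(table: SLookupTable) -> np.ndarray:
    # flat index layout (m-major); kept for clarity of the tie rule below
    return np.arange(table.m_grid.size * table.d_grid.size)


class LookupInverter:
    """Accelerated nearest-cell search over an S lookup table.

    A k-d tree over all grid amplitudes; near-ties (within 1e-12 µm) are
    re-resolved toward smaller D, then smaller m, matching the exhaustive
    scan's deterministic tie-break.
    """

    def __init__(self, table: SLookupTable):
        self.table = table
        pts = np.column_stack([table.re_s.ravel(), table.im_s.ravel()])
        self._tree = cKDTree(pts)
        self._n_d = table.d_grid.size

    def invert(self, re_s: np.ndarray, im_s: np.ndarray):
        """Vectorized inversion; returns (diameter, m_ml, residual) arrays."""
        q = np.column_stack(
            [np.atleast_1d(re_s).astype(float), np.atleast_1d(im_s).astype(float)]
        )
        dist, idx = self._tree.query(q, k=2)
        near_tie = dist[:, 1] - dist[:, 0] < 1e-12
        choice = idx[:, 0].copy()
        if near_tie.any():
            # prefer smaller D, then smaller m
            cand = idx[near_tie]
            i_m = cand // self._n_d
            i_d = cand % self._n_d
            first_wins = (i_d[:, 0] < i_d[:, 1]) | (
                (i_d[:, 0] == i_d[:, 1]) & (i_m[:, 0] <= i_m[:, 1])
            )
            choice[near_tie] = np.where(first_wins, cand[:, 0], cand[:, 1])
        i_m, i_d = np.divmod(choice, self._n_d)
        resid = np.hypot(
            q[:, 0] - self.table.re_s[i_m, i_d], q[:, 1] - self.table.im_s[i_m, i_d]
        )
        return self.table.d_grid[i_d], self.table.m_grid[i_m], resid


_inverter_cache: dict[int, LookupInverter] = {}


def _inverter(table: SLookupTable) -> LookupInverter:
    inv = _inverter_cache.get(id(table))
    if inv is None or inv.table is not table:
        inv = LookupInverter(table)
        _inverter_cache.clear()
        _inverter_cache[id(table)] = inv
    return inv


def invert_nonabsorbing(point: ComplexAmplitude, table: SLookupTable) -> SizingResult:
    """Most-likely (m, D) for a measured amplitude, by nearest table cell."""
    d, m, r = _inverter(table).invert(point.re_s, point.im_s)
    return SizingResult(
        diameter=float(d[0]), m_ml=float(m[0]), residual=float(r[0]),
        method=SizingMethod.LOOKUP,
    )


def invert_nonabsorbing_exhaustive(
    point: ComplexAmplitude, table: SLookupTable
) -> SizingResult:
    """Brute-force scan over the entire grid; the reference the k-d tree must match.

    Ties broken toward smaller D, then smaller m.
    """
    dist2 = (table.re_s - point.re_s) ** 2 + (table.im_s - point.im_s) ** 2
    # transpose so that the first flat minimum has smallest D, then smallest m
    flat = int(np.argmin(dist2.T))
    i_d, i_m = divmod(flat, table.m_grid.size)
    return SizingResult(
        diameter=float(table.d_grid[i_d]),
        m_ml=float(table.m_grid[i_m]),
        residual=float(math.sqrt(dist2[i_m, i_d])),
        method=SizingMethod.LOOKUP,
    )


def project_onto_curve(point: ComplexAmplitude, curve: SCurve) -> SizingResult:
    """Diameter of the nearest point on a single-m S curve (PSL sizing)."""
    if len(curve) < 2:
        raise ValueError("curve must have at least 2 points")
    ax, ay = curve.re_s[:-1], curve.im_s[:-1]
    tx, ty = np.diff(curve.re_s), np.diff(curve.im_s)
    seg2 = tx * tx + ty * ty
    t = np.clip(((point.re_s - ax) * tx + (point.im_s - ay) * ty) / seg2, 0.0, 1.0)
    dx = point.re_s - (ax + t * tx)
    dy = point.im_s - (ay + t * ty)
    dist2 = dx * dx + dy * dy
    i = int(np.argmin(dist2))
    d_a, d_b = curve.diameters[i], curve.diameters[i + 1]
    return SizingResult(
        diameter=float(d_a + t[i] * (d_b - d_a)),
        m_ml=float(curve.m_real),
        residual=float(math.sqrt(dist2[i])),
        method=SizingMethod.PSL_PROJECTION,
    )


@dataclass(frozen=True, eq=False)
class BCCalibration:
    """Monotone map from an amplitude scalar (default |S|, µm) to BC
    volume-equivalent diameter (µm), with provenance."""

    amplitude_um: np.ndarray
    diameter_um: np.ndarray
    provenance: str = "unspecified"
    scalar: str = "magnitude"  # or "im_s"

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude_um, dtype=float)
        d = np.asarray(self.diameter_um, dtype=float)
        if a.size != d.size or a.size < 2:
            raise ValueError("calibration needs >= 2 matched knots")
        if not (np.all(np.diff(a) > 0) and np.all(np.diff(d) > 0)):
            raise ValueError("calibration must be strictly increasing")

    def amplitude_scalar(self, point: ComplexAmplitude) -> float:
        return point.im_s if self.scalar == "im_s" else point.magnitude

    def to_file(self, path) -> None:
        with open(path, "w") as f:
            f.write(f"# provenance: {self.provenance}\n")
            f.write(f"# scalar: {self.scalar}\n")
            f.write("amplitude_um,diameter_um\n")
            for a, d in zip(self.amplitude_um, self.diameter_um):
                f.write(f"{float(a)!r},{float(d)!r}\n")

    @classmethod
    def from_file(cls, path) -> "BCCalibration":
        provenance, scalar = "unspecified", "magnitude"
        rows = []
        with open(path) as f:
            for line in f:
                line = line.strip()
                if line.startswith("# provenance:"):
                    provenance = line.split(":", 1)[1].strip()
                elif line.startswith("# scalar:"):
                    scalar = line.split(":", 1)[1].strip()
                elif line and not line.startswith("#") and not line[0].isalpha():
                    a, d = line.split(",")
                    rows.append((float(a), float(d)))
        arr = np.array(rows)
        return cls(
            amplitude_um=arr[:, 0], diameter_um=arr[:, 1],
            provenance=provenance, scalar=scalar,
        )


def size_bc(point: ComplexAmplitude, cal: BCCalibration) -> SizingResult:
    """BC volume-equivalent diameter by monotone interpolation of the calibration."""
    s = cal.amplitude_scalar(point)
    clamped = bool(s < cal.amplitude_um[0] or s > cal.amplitude_um[-1])
    if clamped:
        warnings.warn(
            f"BC amplitude scalar {s:.4g} µm outside calibration range "
            f"[{cal.amplitude_um[0]:.4g}, {cal.amplitude_um[-1]:.4g}]; diameter clamped",
            stacklevel=2,
        )
    d = float(np.interp(s, cal.amplitude_um, cal.diameter_um))
    return SizingResult(
        diameter=d, m_ml=None, residual=0.0,
        method=SizingMethod.BC_CALIBRATION, clamped=clamped,
    )


def synthetic_bc_calibration(
    optics: OpticalConfig | None = None,
    m_bc: complex = 2.26 + 1.26j,
    d_range: tuple[float, float] = (0.03, 1.2),
    n_points: int = 200,
) -> BCCalibration:
    """SYNTHETIC stand-in BC calibration built from the absorbing-sphere model.

    This is NOT the externally inferred shape-model relation used for real
    measurements (which is supplied by the user as a two-column file); it
    maps |S| of a compact absorbing sphere at a typical BC refractive index
    to its diameter, which is sufficient for closed-loop synthetic tests.
    """
    optics = optics or OpticalConfig()
    d = np.logspace(math.log10(d_range[0]), math.log10(d_range[1]), n_points)
    re, im = forward_amplitude_batch(d, m_bc, optics)
    mag = np.hypot(re, im)
    # keep the strictly increasing prefix (the map must be invertible)
    stop = int(np.argmin(np.diff(mag) > 0)) + 1 if not (np.diff(mag) > 0).all() else d.size
    return BCCalibration(
        amplitude_um=mag[:stop],
        diameter_um=d[:stop],
        provenance=f"synthetic absorbing-sphere stand-in, m_bc={m_bc}",
    )


def size_events(
    type_codes: np.ndarray,
    re_s: np.ndarray,
    im_s: np.ndarray,
    table: SLookupTable,
    bc_cal: BCCalibration | None = None,
):
    """Type-dispatched sizing for event arrays.

    Types 0–3 go through the non-absorbing lookup table, Type 4 through the
    BC calibration; EXCLUDED/UNCLASSIFIED events get NaN diameters.
    Returns (diameter, m_ml, residual) arrays (NaN where not applicable).
    """
    type_codes = np.asarray(type_codes)
    re_s = np.asarray(re_s, dtype=float)
    im_s = np.asarray(im_s, dtype=float)
    n = type_codes.size
    diam = np.full(n, np.nan)
    m_ml = np.full(n, np.nan)
    resid = np.full(n, np.nan)
    spheres = (type_codes >= int(ParticleType.TYPE0)) & (
        type_codes <= int(ParticleType.TYPE3)
    )
    if spheres.any():
        d, m, r = _inverter(table).invert(re_s[spheres], im_s[spheres])
        diam[spheres], m_ml[spheres], resid[spheres] = d, m, r
    bc = type_codes == int(ParticleType.TYPE4)
    if bc.any():
        if bc_cal is None:
            raise ValueError(
                "Type 4 (black carbon) events present but no BC calibration supplied"
            )
        mag = np.hypot(re_s[bc], im_s[bc])
        scal = im_s[bc] if bc_cal.scalar == "im_s" else mag
        out_of_range = (scal < bc_cal.amplitude_um[0]) | (scal > bc_cal.amplitude_um[-1])
        if out_of_range.any():
            warnings.warn(
                f"{int(out_of_range.sum())} BC events outside calibration range; clamped",
                stacklevel=2,
            )
        diam[bc] = np.interp(scal, bc_cal.amplitude_um, bc_cal.diameter_um)
        resid[bc] = 0.0
    return diam, m_ml, resid
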