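"""Mie forward model for the complex forward-scattering amplitude S(0°).

The sensor reports, for each particle, a point (ReS, ImS) on the complex
plane in length units (µm).  For a homogeneous sphere of diameter ``D`` and
vacuum refractive index ``m`` suspended in a non-absorbing medium of index
``m_med``, the dimensionless forward amplitude is the Mie series

    S0 = 1/2 * sum_n (2n+1) (a_n + b_n),

evaluated at relative index ``m_rel = m/m_med`` and size parameter
``x = pi * D * m_med / lambda_vac``.  The length-valued amplitude used
throughout the package is

    re_s = Im(S0) / k,   im_s = Re(S0) / k,   k = 2*pi*m_med/lambda_vac,

a convention under which non-absorbing spheres map into the first quadrant
(Rayleigh limit: re_s ~ k^2 (D/2)^3 (m_rel^2-1)/(m_rel^2+2)) and the optical
theorem takes the clean form C_ext = 2 * lambda_med * im_s.

Coefficients are computed BHMIE-style: the logarithmic derivative
D_n(m_rel*x) by downward recurrence, Riccati–Bessel psi/chi of the real
argument by upward recurrence, truncated at the Wiscombe order
n_max = ceil(x + 4 x^{1/3} + 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PURE_WATER_INDEX",
    "SEAWATER_INDEX",
    "PSL_REFRACTIVE_INDEX",
    "PSL_DIAMETERS_UM",
    "OpticalConfig",
    "SphereSpec",
    "ComplexAmplitude",
    "SCurve",
    "SLookupTable",
    "forward_amplitude",
    "forward_amplitude_batch",
    "extinction_cross_section",
    "theoretical_curve",
    "build_lookup_table",
    "size_parameter",
]

#: refractive index of pure water at 632.8 nm
PURE_WATER_INDEX = 1.33154
#: refractive index of seawater (640 nm, 20 degC, salinity 34 permil)
SEAWATER_INDEX = 1.3373
#: vacuum refractive index of polystyrene latex calibration spheres at 632.8 nm
PSL_REFRACTIVE_INDEX = 1.5854 + 6.1764e-7j
#: certified diameters (µm) of the PSL calibration set
PSL_DIAMETERS_UM = (0.303, 0.510, 0.803, 1.036, 2.020, 2.994, 5.010)


class MieRangeError(ValueError):
    """Size parameter outside the validated range of the series."""


@dataclass(frozen=True)
class OpticalConfig:
    """Wavelength and suspension-medium index defining the optical geometry.

    Parameters
    ----------
    wavelength_vacuum : float
        Vacuum wavelength in µm (default 0.6328, the HeNe line).
    medium_index : float
        Real refractive index of the suspension medium (pure water or
        seawater presets are module constants).
    x_max : float
        Guard on the size parameter; the default 150 is far above the
        x ~ 66 reached by a 10 µm sphere at 632.8 nm in water.
    """

    wavelength_vacuum: float = 0.6328
    medium_index: float = PURE_WATER_INDEX
    x_max: float = 150.0

    def __post_init__(self) -> None:
        if not (self.wavelength_vacuum > 0 and math.isfinite(self.wavelength_vacuum)):
            raise ValueError("wavelength_vacuum must be positive and finite")
        if not (self.medium_index >= 1 and math.isfinite(self.medium_index)):
            raise ValueError("medium_index must be >= 1 and finite")

    @property
    def wavenumber(self) -> float:
        """k = 2*pi*m_med/lambda_vac in µm^-1."""
        return 2.0 * math.pi * self.medium_index / self.wavelength_vacuum

    @property
    def wavelength_medium(self) -> float:
        """In-medium wavelength lambda_vac/m_med in µm."""
        return self.wavelength_vacuum / self.medium_index


@dataclass(frozen=True)
class SphereSpec:
    """A homogeneous sphere: diameter in µm and vacuum complex index."""

    diameter: float
    refractive_index: complex

    def __post_init__(self) -> None:
        m = complex(self.refractive_index)
        if not (self.diameter > 0 and math.isfinite(self.diameter)):
            raise ValueError("diameter must be positive and finite")
        if not (math.isfinite(m.real) and math.isfinite(m.imag)):
            raise ValueError("refractive index must be finite")
        if m.real < 1.0 or m.imag < 0.0:
            raise ValueError("require Re(m) >= 1 and Im(m) >= 0")


@dataclass(frozen=True)
class ComplexAmplitude:
    """A point (ReS, ImS) on the complex amplitude plane, in µm."""

    re_s: float
    im_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.re_s) and math.isfinite(self.im_s)):
            raise ValueError("amplitude must be finite")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.re_s, self.im_s)

    @property
    def phase(self) -> float:
        """Phase shift Delta = atan2(ImS, ReS)."""
        return math.atan2(self.im_s, self.re_s)


def size_parameter(diameter: float, optics: OpticalConfig) -> float:
    """x = pi * D * m_med / lambda_vac."""
    return math.pi * diameter * optics.medium_index / optics.wavelength_vacuum


def _wiscombe_nmax(x: np.ndarray) -> np.ndarray:
    return np.ceil(x + 4.0 * np.cbrt(x) + 2.0).astype(int)


def _mie_sums_chunk(m_rel: complex, x: np.ndarray):
    """S0 sum and extinction sum for a chunk of size parameters, common m_rel.

    Returns (s0_sum, qext_sum) where s0_sum = sum (2n+1)(a_n+b_n) evaluated
    with the e^{-iwt} sign and qext_sum = sum (2n+1) Re(a_n+b_n); the caller
    applies the 1/2 and conjugation.  Terms beyond each element's own
    Wiscombe order are masked out, so a chunk shares recurrences but not the
    truncation point.
    """
    nmax_each = _wiscombe_nmax(x)
    n_top = int(nmax_each.max())
    z = m_rel * x
    # The downward recurrences only contract above both the truncation order
    # and the turning point |z|; the generous margin keeps near-resonance
    # coefficients accurate to ~1e-10.
    n_start = max(n_top, int(np.ceil(max(np.abs(z).max(), x.max())))) + 50
    # logarithmic derivative D_n(z), downward
    dn = np.zeros_like(z)
    d_table = np.empty((n_top + 1, x.size), dtype=complex)
    for n in range(n_start, 0, -1):
        rn = n / z
        dn = rn - 1.0 / (dn + rn)  # now holds D_{n-1}
        if n - 1 <= n_top:
            d_table[n - 1] = dn
    # psi_n(x): downward ratios rho_n = psi_n/psi_{n-1} (psi is the minimal
    # solution, so upward recursion of psi itself is unstable past n ~ x),
    # then an upward product anchored at psi_0 = sin x
    rho = np.zeros_like(x)
    rho_table = np.empty((n_top + 1, x.size))
    for n in range(n_start, 0, -1):
        rho = 1.0 / ((2 * n + 1) / x - rho)  # now holds rho_n
        if n <= n_top:
            rho_table[n] = rho
    # chi_n(x) (dominant solution): plain upward recurrence is stable
    psi_nm1 = np.cos(x)   # psi_{n-1} at n=1 start -> psi_0 handled below
    psi_n = np.sin(x)
    chi_nm1 = -np.sin(x)
    chi_n = np.cos(x)
    s0_sum = np.zeros(x.size, dtype=complex)
    q_sum = np.zeros(x.size)
    for n in range(1, n_top + 1):
        # advance: psi_n holds psi_{n-1}(x) values of order n-1 at loop top
        psi = rho_table[n] * psi_n
        chi = (2 * n - 1) / x * chi_n - chi_nm1
        psi_nm1, psi_n = psi_n, psi
        chi_nm1, chi_n = chi_n, chi
        xi = psi - 1j * chi
        xi_prev = psi_nm1 - 1j * chi_nm1
        d_n = d_table[n]
        fa = d_n / m_rel + n / x
        fb = d_n * m_rel + n / x
        a_n = (fa * psi - psi_nm1) / (fa * xi - xi_prev)
        b_n = (fb * psi - psi_nm1) / (fb * xi - xi_prev)
        active = n <= nmax_each
        term = (2 * n + 1) * (a_n + b_n)
        s0_sum += np.where(active, term, 0.0)
        q_sum += np.where(active, (2 * n + 1) * (a_n + b_n).real, 0.0)
    return s0_sum, q_sum


def _mie_s0_qext(m_rel: complex, x: np.ndarray):
    """Vectorized S0 (length convention applied by caller) and Qext sums.

    Sorts the size parameters and processes chunks whose Wiscombe orders
    span <= 20, so the chi recurrence never runs far past an element's own
    truncation order (where it would overflow for very small x).
    """
    x = np.asarray(x, dtype=float)
    flat = x.ravel()
    order = np.argsort(flat)
    s0 = np.empty(flat.size, dtype=complex)
    q = np.empty(flat.size)
    nmax_sorted = _wiscombe_nmax(flat[order])
    i = 0
    while i < flat.size:
        j = i + 1
        while j < flat.size and nmax_sorted[j] <= nmax_sorted[i] + 20:
            j += 1
        idx = order[i:j]
        s0[idx], q[idx] = _mie_sums_chunk(m_rel, flat[idx])
        i = j
    # e^{+iwt} (van de Hulst) convention: conjugate of the summed series
    s0 = np.conj(s0 / 2.0)
    return s0.reshape(x.shape), q.reshape(x.shape)


def _validate_relative_index(m_rel: complex) -> None:
    if not (math.isfinite(m_rel.real) and math.isfinite(m_rel.imag)):
        raise ValueError("relative refractive index must be finite")
    if m_rel.real < 1.0 / 1.5:
        raise ValueError(f"relative index Re(m_rel)={m_rel.real:.4f} below validated range")


def forward_amplitude(sphere: SphereSpec, optics: OpticalConfig) -> ComplexAmplitude:
    """Length-valued complex forward-scattering amplitude of a sphere, in µm."""
    m_rel = complex(sphere.refractive_index) / optics.medium_index
    _validate_relative_index(m_rel)
    x = size_parameter(sphere.diameter, optics)
    if x > optics.x_max:
        raise MieRangeError(f"size parameter x={x:.1f} exceeds x_max={optics.x_max}")
    s0, _ = _mie_s0_qext(m_rel, np.array([x]))
    k = optics.wavenumber
    return ComplexAmplitude(re_s=float(s0[0].imag) / k, im_s=float(s0[0].real) / k)


def forward_amplitude_batch(
    diameters: np.ndarray, refractive_index: complex, optics: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(re_s, im_s) arrays for many diameters sharing one refractive index."""
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size and (not np.all(np.isfinite(diameters)) or np.any(diameters <= 0)):
        raise ValueError("diameters must be positive and finite")
    m_rel = complex(refractive_index) / optics.medium_index
    _validate_relative_index(m_rel)
    x = np.pi * diameters * optics.medium_index / optics.wavelength_vacuum
    if diameters.size and x.max() > optics.x_max:
        raise MieRangeError("size parameter exceeds x_max")
    s0, _ = _mie_s0_qext(m_rel, x)
    k = optics.wavenumber
    return s0.imag / k, s0.real / k


def extinction_cross_section(sphere: SphereSpec, optics: OpticalConfig) -> float:
    """C_ext = (2*pi/k^2) * sum (2n+1) Re(a_n + b_n), in µm²."""
    m_rel = complex(sphere.refractive_index) / optics.medium_index
    _validate_relative_index(m_rel)
    x = size_parameter(sphere.diameter, optics)
    if x > optics.x_max:
        raise MieRangeError(f"size parameter x={x:.1f} exceeds x_max={optics.x_max}")
    _, q = _mie_s0_qext(m_rel, np.array([x]))
    k = optics.wavenumber
    return float(2.0 * math.pi / k**2 * q[0])


@dataclass(frozen=True)
class SCurve:
    """Theoretical S locus for one real refractive index, D as the parameter.

    ``diameters`` is strictly increasing; ``re_s``/``im_s`` give the locus
    on the amplitude plane in µm.
    """

    m_real: float
    diameters: np.ndarray
    re_s: np.ndarray
    im_s: np.ndarray
    optics: OpticalConfig = field(repr=False, default=OpticalConfig())

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.size < 2:
            raise ValueError("an S curve needs at least 2 points")
        if not np.all(np.diff(d) > 0):
            raise ValueError("diameters must be strictly increasing")

    def __len__(self) -> int:
        return int(self.diameters.size)

    def points(self) -> np.ndarray:
        """(n, 2) array of (re_s, im_s)."""
        return np.column_stack([self.re_s, self.im_s])

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.re_s, self.im_s)

    def initial_monotone_branch(self) -> "SCurve":
        """Truncate to the first branch where |S| strictly increases with D.

        At large phase shift the S locus loops back on itself; the inversion
        and the classification boundaries only ever use the initial branch,
        where the map D -> S is injective.
        """
        mag = self.magnitude()
        inc = np.diff(mag) > 0
        stop = int(np.argmin(inc)) + 1 if not inc.all() else len(mag)
        if stop < 2:
            stop = 2
        return SCurve(
            m_real=self.m_real,
            diameters=self.diameters[:stop],
            re_s=self.re_s[:stop],
            im_s=self.im_s[:stop],
            optics=self.optics,
        )


def theoretical_curve(
    m_real: float,
    optics: OpticalConfig,
    d_min: float = 0.1,
    d_max: float = 10.0,
    n_points: int = 2000,
) -> SCurve:
    """S curve for a non-absorbing sphere of index ``m_real``.

    Points are sampled log-uniformly in diameter between ``d_min`` and
    ``d_max`` (µm).
    """
    if not (0 < d_min < d_max):
        raise ValueError("require 0 < d_min < d_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    d = np.logspace(math.log10(d_min), math.log10(d_max), n_points)
    # endpoints exactly as requested despite logspace rounding
    d[0], d[-1] = d_min, d_max
    re_s, im_s = forward_amplitude_batch(d, complex(m_real), optics)
    return SCurve(m_real=float(m_real), diameters=d, re_s=re_s, im_s=im_s, optics=optics)


@dataclass(frozen=True)
class SLookupTable:
    """Theoretical S on a dense (m, D) grid for non-absorbing spheres.

    ``re_s``/``im_s`` have shape (len(m_grid), len(d_grid)).
    """

    m_grid: np.ndarray
    d_grid: np.ndarray
    re_s: np.ndarray
    im_s: np.ndarray
    optics: OpticalConfig = field(repr=False, default=OpticalConfig())

    def __post_init__(self) -> None:
        m = np.asarray(self.m_grid, dtype=float)
        d = np.asarray(self.d_grid, dtype=float)
        if m.size == 0 or d.size == 0:
            raise ValueError("lookup grid must be non-empty")
        if not (np.all(np.diff(m) > 0) and np.all(np.diff(d) > 0)):
            raise ValueError("grids must be strictly increasing")
        if not (np.all(np.isfinite(self.re_s)) and np.all(np.isfinite(self.im_s))):
            raise ValueError("amplitudes must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.m_grid.size), int(self.d_grid.size))

    def save(self, path) -> None:
        """Serialize to an .npz archive with optics metadata; bit-exact."""
        np.savez(
            path,
            m_grid=self.m_grid,
            d_grid=self.d_grid,
            re_s=self.re_s,
            im_s=self.im_s,
            wavelength_vacuum=self.optics.wavelength_vacuum,
            medium_index=self.optics.medium_index,
            x_max=self.optics.x_max,
            convention=np.array("vdH-S0/k", dtype=object),
        )

    @classmethod
    def load(cls, path) -> "SLookupTable":
        with np.load(path, allow_pickle=True) as f:
            optics = OpticalConfig(
                wavelength_vacuum=float(f["wavelength_vacuum"]),
                medium_index=float(f["medium_index"]),
                x_max=float(f["x_max"]),
            )
            return cls(
                m_grid=f["m_grid"],
                d_grid=f["d_grid"],
                re_s=f["re_s"],
                im_s=f["im_s"],
                optics=optics,
            )


def build_lookup_table(
    optics: OpticalConfig,
    m_range: tuple[float, float] = (1.34, 2.40),
    d_range: tuple[float, float] = (0.1, 10.0),
    m_step: float = 0.005,
    n_diameters: int = 2000,
) -> SLookupTable:
    """Dense grid of theoretical S values for non-absorbing spheres.

    Defaults cover 1.34 < m < 2.40 and 0.1 µm < D < 10 µm with m spacing
    0.005 and 2000 log-spaced diameters.
    """
    m_lo, m_hi = m_range
    d_lo, d_hi = d_range
    if not (m_lo < m_hi and 0 < d_lo < d_hi):
        raise ValueError("invalid grid ranges")
    n_m = int(round((m_hi - m_lo) / m_step)) + 1
    m_grid = m_lo + m_step * np.arange(n_m)
    m_grid = m_grid[m_grid <= m_hi + 1e-12]
    d_grid = np.logspace(math.log10(d_lo), math.log10(d_hi), n_diameters)
    re = np.empty((m_grid.size, d_grid.size))
    im = np.empty_like(re)
    for i, m in enumerate(m_grid):
        re[i], im[i] = forward_amplitude_batch(d_grid, complex(m), optics)
    return SLookupTable(m_grid=m_grid, d_grid=d_grid, re_s=re, im_s=im, optics=optics)
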