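"""Arbitrary-precision brute-force Mie forward amplitude, independent of caspm.

This module deliberately avoids the production code path: Riccati–Bessel
functions psi_n and chi_n are computed directly (normalized downward
recurrence for psi, upward for chi) in mpmath arbitrary precision, and the
Mie coefficients use the derivative (Bohren–Huffman) form rather than the
logarithmic-derivative form used in ``caspm.mie_optics``.
"""

from __future__ import annotations

import mpmath as mp


def _n_max(x: float) -> int:
    return int(mp.ceil(x + 4 * mp.cbrt(x) + 2))


def _riccati_psi(z, n_top: int):
    """psi_n(z) = z*j_n(z) for n=0..n_top via normalized downward recurrence."""
    start = max(n_top, int(mp.ceil(abs(z)))) + 30
    f_hi = mp.mpc(0)
    f = mp.mpc("1e-40")
    vals = [None] * (start + 1)
    vals[start] = f
    for n in range(start, 0, -1):
        f_lo = (2 * n + 1) / z * f - f_hi
        f_hi, f = f, f_lo
        vals[n - 1] = f
    # normalize against whichever closed form is better conditioned
    psi0, psi1 = mp.sin(z), mp.sin(z) / z - mp.cos(z)
    if abs(psi0) >= abs(psi1):
        scale = psi0 / vals[0]
    else:
        scale = psi1 / vals[1]
    return [v * scale for v in vals[: n_top + 1]]


def _riccati_chi(z, n_top: int):
    """chi_n(z) = -z*y_n(z) for n=0..n_top via (stable) upward recurrence."""
    vals = [mp.cos(z), mp.cos(z) / z + mp.sin(z)]
    for n in range(1, n_top):
        vals.append((2 * n + 1) / z * vals[n] - vals[n - 1])
    return vals[: n_top + 1]


def s0_and_cross_sections(m_rel, x, dps: int = 50):
    """Return (S0, Qext_sum) for relative index m_rel and size parameter x.

    S0 follows the convention with Re S0 = extinction-positive part and
    Im S0 > 0 in the Rayleigh limit (conjugate of the e^{-iwt} sum);
    Qext_sum = sum (2n+1) Re(a_n + b_n).
    """
    with mp.workdps(dps):
        m = mp.mpc(m_rel)
        x = mp.mpf(x)
        z = m * x
        nmax = _n_max(float(x))
        psi_x = _riccati_psi(mp.mpc(x), nmax)
        psi_z = _riccati_psi(z, nmax)
        chi_x = _riccati_chi(mp.mpc(x), nmax)
        xi_x = [psi_x[n] - 1j * chi_x[n] for n in range(nmax + 1)]

        def d(seq, n, z_):
            return seq[n - 1] - n * seq[n] / z_

        s0 = mp.mpc(0)
        qsum = mp.mpf(0)
        for n in range(1, nmax + 1):
            psix, psixp = psi_x[n], d(psi_x, n, x)
            psiz, psizp = psi_z[n], d(psi_z, n, z)
            xix, xixp = xi_x[n], d(xi_x, n, x)
            a_n = (m * psiz * psixp - psix * psizp) / (m * psiz * xixp - xix * psizp)
            b_n = (psiz * psixp - m * psix * psizp) / (psiz * xixp - m * xix * psizp)
            s0 += (2 * n + 1) * (a_n + b_n)
            qsum += (2 * n + 1) * mp.re(a_n + b_n)
        s0 = mp.conj(s0 / 2)
        return complex(s0), float(qsum)


def forward_amplitude_oracle(diameter_um, m_vacuum, wavelength_um=0.6328,
                             m_medium=1.33154, dps: int = 50):
    """(re_s, im_s) in µm for a sphere, via the oracle series."""
    with mp.workdps(dps):
        k = 2 * mp.pi * mp.mpf(m_medium) / mp.mpf(wavelength_um)
        x = mp.pi * mp.mpf(diameter_um) * mp.mpf(m_medium) / mp.mpf(wavelength_um)
        m_rel = mp.mpc(m_vacuum) / mp.mpf(m_medium)
        s0, _ = s0_and_cross_sections(m_rel, x, dps=dps)
        return float(s0.imag / float(k)), float(s0.real / float(k))
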