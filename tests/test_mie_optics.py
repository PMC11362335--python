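"""Forward-model correctness: oracle agreement, limits, identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caspm import (
    ComplexAmplitude,
    OpticalConfig,
    PSL_REFRACTIVE_INDEX,
    SEAWATER_INDEX,
    SLookupTable,
    SphereSpec,
    build_lookup_table,
    extinction_cross_section,
    forward_amplitude,
    forward_amplitude_batch,
    theoretical_curve,
)
from caspm.mie_optics import MieRangeError, _mie_s0_qext, size_parameter

from _mie_oracle import forward_amplitude_oracle, s0_and_cross_sections

# frozen with the arbitrary-precision oracle: PSL 0.303 µm,
# m = 1.5854 + 6.1764e-7i, pure water (1.33154), 632.8 nm
PSL_0303_RE_S = 0.08133963774834968
PSL_0303_IM_S = 0.016596274071506264


def test_psl_amplitude_matches_frozen_oracle_value(pw_optics):
    amp = forward_amplitude(SphereSpec(0.303, PSL_REFRACTIVE_INDEX), pw_optics)
    assert amp.re_s == pytest.approx(PSL_0303_RE_S, rel=1e-10)
    assert amp.im_s == pytest.approx(PSL_0303_IM_S, rel=1e-10)


def test_forward_amplitude_matches_bruteforce_series(rng):
    """Production series vs the arbitrary-precision oracle, random cases."""
    worst = 0.0
    for _ in range(60):
        m_rel = complex(rng.uniform(1.0, 1.9), rng.uniform(0, 0.5) * rng.integers(0, 2))
        x = rng.uniform(0.01, 50.0)
        s0_prod = _mie_s0_qext(m_rel, np.array([x]))[0][0]
        s0_ref, _ = s0_and_cross_sections(m_rel, x)
        worst = max(worst, abs(s0_prod - s0_ref) / abs(s0_ref))
    assert worst <= 1e-8


def test_vanishing_scatterer(pw_optics):
    amp = forward_amplitude(SphereSpec(1e-6, 1.5 + 0j), pw_optics)
    assert abs(amp.re_s) < 1e-12 and abs(amp.im_s) < 1e-12


@pytest.mark.parametrize("m", [1.36, 1.45, 1.9])
def test_rayleigh_closed_form(m, pw_optics):
    """re_s -> k^2 (D/2)^3 (m_rel^2-1)/(m_rel^2+2) for x <= 0.05."""
    D = 0.05 * pw_optics.wavelength_vacuum / (np.pi * pw_optics.medium_index) * 0.9
    assert size_parameter(D, pw_optics) <= 0.05
    amp = forward_amplitude(SphereSpec(D, m + 0j), pw_optics)
    m_rel = m / pw_optics.medium_index
    k = pw_optics.wavenumber
    closed = k**2 * (D / 2) ** 3 * (m_rel**2 - 1) / (m_rel**2 + 2)
    assert amp.re_s == pytest.approx(closed, rel=0.01)
    assert amp.im_s >= 0


def test_optical_theorem_identity(rng, sw_optics):
    """C_ext = 2 * lambda_med * im_s for arbitrary spheres."""
    for _ in range(40):
        sphere = SphereSpec(
            rng.uniform(0.1, 8.0),
            complex(rng.uniform(1.34, 2.4), rng.uniform(0.0, 0.6)),
        )
        c_ext = extinction_cross_section(sphere, sw_optics)
        amp = forward_amplitude(sphere, sw_optics)
        assert c_ext == pytest.approx(2 * sw_optics.wavelength_medium * amp.im_s, rel=1e-10)


def test_extinction_paradox_limit():
    """Q_ext -> 2 within 10% at x = 100, m_rel = 1.1."""
    optics = OpticalConfig(x_max=200.0)
    D = 100.0 * optics.wavelength_vacuum / (np.pi * optics.medium_index)
    sphere = SphereSpec(D, 1.1 * optics.medium_index + 0j)
    q = extinction_cross_section(sphere, optics) / (np.pi * (D / 2) ** 2)
    assert q == pytest.approx(2.0, rel=0.10)


def test_medium_scaling_invariance():
    """Amplitude depends only on m_rel and x (and the k normalization)."""
    a = OpticalConfig(wavelength_vacuum=0.6328, medium_index=1.33154)
    b = OpticalConfig(wavelength_vacuum=0.5000, medium_index=1.40)
    m_rel, x = 1.12, 7.3
    d_a = x * a.wavelength_vacuum / (np.pi * a.medium_index)
    d_b = x * b.wavelength_vacuum / (np.pi * b.medium_index)
    amp_a = forward_amplitude(SphereSpec(d_a, m_rel * a.medium_index + 0j), a)
    amp_b = forward_amplitude(SphereSpec(d_b, m_rel * b.medium_index + 0j), b)
    assert amp_a.re_s * a.wavenumber == pytest.approx(amp_b.re_s * b.wavenumber, rel=1e-10)
    assert amp_a.im_s * a.wavenumber == pytest.approx(amp_b.im_s * b.wavenumber, rel=1e-10)


def test_batch_matches_scalar(rng, sw_optics):
    d = np.sort(rng.uniform(0.1, 9.0, 50))
    re_b, im_b = forward_amplitude_batch(d, 1.45 + 0j, sw_optics)
    for i in [0, 13, 27, 49]:
        amp = forward_amplitude(SphereSpec(float(d[i]), 1.45 + 0j), sw_optics)
        assert re_b[i] == pytest.approx(amp.re_s, rel=1e-11)
        assert im_b[i] == pytest.approx(amp.im_s, rel=1e-11)


class TestTheoreticalCurve:
    def test_endpoints_and_log_spacing(self, sw_optics):
        c = theoretical_curve(1.43, sw_optics, 0.2, 5.0, n_points=2)
        assert len(c) == 2
        assert c.diameters[0] == 0.2 and c.diameters[-1] == 5.0

    def test_points_are_forward_amplitudes(self, sw_optics):
        c = theoretical_curve(1.43, sw_optics, 0.2, 5.0, 50)
        for i in [0, 10, 49]:
            amp = forward_amplitude(SphereSpec(float(c.diameters[i]), 1.43 + 0j), sw_optics)
            assert c.re_s[i] == pytest.approx(amp.re_s, rel=1e-11)

    def test_invalid_range_raises(self, sw_optics):
        with pytest.raises(ValueError):
            theoretical_curve(1.43, sw_optics, 1.0, 0.5, 10)
        with pytest.raises(ValueError):
            theoretical_curve(1.43, sw_optics, 0.5, 1.0, 1)

    def test_curve_ordering_in_window(self, sw_optics):
        """At equal re_s inside the s window, im_s is non-decreasing in m."""
        curves = {
            m: theoretical_curve(m, sw_optics, 0.1, 10.0, 1500).initial_monotone_branch()
            for m in (1.38, 1.43, 1.50, 1.60)
        }
        interp = {}
        for m, c in curves.items():
            inside = (c.re_s < 1.5) & (c.im_s < 0.5)
            stop = int(np.argmin(inside)) if not inside.all() else len(c.re_s)
            re, im = c.re_s[:stop], c.im_s[:stop]
            mono = np.diff(re) > 0  # use the re-monotone prefix for interpolation
            stop2 = int(np.argmin(mono)) + 1 if not mono.all() else re.size
            interp[m] = (re[:stop2], im[:stop2])
        for re_q in (0.1, 0.3, 0.5, 0.7):
            ims = [
                np.interp(re_q, *interp[m])
                for m in (1.38, 1.43, 1.50, 1.60)
                if re_q <= interp[m][0][-1]
            ]
            assert all(lo <= hi + 1e-12 for lo, hi in zip(ims, ims[1:]))


class TestLookupTable:
    def test_default_ranges(self, lookup_sw):
        assert lookup_sw.m_grid[0] == pytest.approx(1.34)
        assert lookup_sw.m_grid[-1] == pytest.approx(2.40)
        assert lookup_sw.d_grid[0] == pytest.approx(0.1)
        assert lookup_sw.d_grid[-1] == pytest.approx(10.0)
        assert np.isfinite(lookup_sw.re_s).all() and np.isfinite(lookup_sw.im_s).all()

    def test_cells_are_forward_amplitudes(self, lookup_sw, sw_optics, rng):
        for _ in range(5):
            i = int(rng.integers(0, lookup_sw.m_grid.size))
            j = int(rng.integers(0, lookup_sw.d_grid.size))
            amp = forward_amplitude(
                SphereSpec(float(lookup_sw.d_grid[j]), float(lookup_sw.m_grid[i]) + 0j),
                sw_optics,
            )
            assert lookup_sw.re_s[i, j] == pytest.approx(amp.re_s, rel=1e-11)

    def test_save_load_roundtrip_is_bit_identical(self, lookup_sw, tmp_path):
        path = tmp_path / "table.npz"
        lookup_sw.save(path)
        loaded = SLookupTable.load(path)
        assert np.array_equal(loaded.re_s, lookup_sw.re_s)
        assert np.array_equal(loaded.im_s, lookup_sw.im_s)
        assert loaded.optics == lookup_sw.optics

    def test_empty_grid_rejected(self, sw_optics):
        with pytest.raises(ValueError):
            build_lookup_table(sw_optics, m_range=(1.5, 1.4))


class TestValidation:
    def test_nonpositive_diameter(self):
        with pytest.raises(ValueError):
            SphereSpec(0.0, 1.5 + 0j)

    def test_nonfinite_index(self):
        with pytest.raises(ValueError):
            SphereSpec(1.0, complex("nan"))

    def test_absorbing_medium_index_below_one(self):
        with pytest.raises(ValueError):
            OpticalConfig(medium_index=0.9)

    def test_size_parameter_guard(self, pw_optics):
        with pytest.raises(MieRangeError):
            forward_amplitude(SphereSpec(40.0, 1.5 + 0j), pw_optics)

    def test_nonfinite_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ComplexAmplitude(float("inf"), 0.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    m=st.floats(1.34, 1.60),
    d=st.floats(0.1, 0.6),
)
def test_first_quadrant_for_small_nonabsorbing_spheres(m, d):
    """In the sub-micron working range, non-absorbing spheres map into the
    first quadrant of the amplitude plane (im_s > 0 strictly: extinction)."""
    optics = OpticalConfig(medium_index=SEAWATER_INDEX)
    amp = forward_amplitude(SphereSpec(d, m + 0j), optics)
    assert amp.im_s > 0
    assert amp.re_s > 0
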