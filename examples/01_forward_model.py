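"""Forward model: where do spheres land on the complex amplitude plane?

Computes the length-valued forward-scattering amplitude (ReS, ImS) for the
seven certified PSL calibration spheres in pure water, and samples the
theoretical S curve for an m = 1.43 sphere in seawater.
"""

from caspm import (
    OpticalConfig,
    PSL_DIAMETERS_UM,
    PSL_REFRACTIVE_INDEX,
    PURE_WATER_INDEX,
    SEAWATER_INDEX,
    SphereSpec,
    extinction_cross_section,
    forward_amplitude,
    theoretical_curve,
)

pw = OpticalConfig(medium_index=PURE_WATER_INDEX)

print("PSL calibration spheres (m = 1.5854 + 6.2e-7i, pure water, 632.8 nm):")
print(f"{'D (µm)':>8} {'ReS (µm)':>10} {'ImS (µm)':>10} {'C_ext (µm²)':>12}")
for d in PSL_DIAMETERS_UM:
    sphere = SphereSpec(d, PSL_REFRACTIVE_INDEX)
    amp = forward_amplitude(sphere, pw)
    c_ext = extinction_cross_section(sphere, pw)
    print(f"{d:8.3f} {amp.re_s:10.4f} {amp.im_s:10.4f} {c_ext:12.4f}")
print(
    "\nImS is proportional to the extinction cross-section (optical theorem:"
    " C_ext = 2 λ_med ImS), so absorbing or large particles sit higher on"
    " the plane; ReS grows with the scattered amplitude itself."
)

sw = OpticalConfig(medium_index=SEAWATER_INDEX)
curve = theoretical_curve(1.43, sw, 0.2, 1.2, 6)
print("\nTheoretical S curve for a non-absorbing m = 1.43 sphere in seawater")
print("(this curve is the Type 1 / Type 2 boundary of the classifier):")
for d, re, im in zip(curve.diameters, curve.re_s, curve.im_s):
    print(f"  D = {d:5.3f} µm -> (ReS, ImS) = ({re:7.4f}, {im:7.4f}) µm")
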