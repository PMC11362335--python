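"""Counts to concentrations: C = R/(A U) and its calibration.

Shows the duty-cycle-corrected detection rate, the conversion to number
concentration with the calibrated effective detection areas, the inverse
(calibrating A from a known suspension), and the Lambert-Beer determination
of that known suspension's concentration.
"""

from caspm import (
    ChannelCalibration,
    OpticalConfig,
    PSL_REFRACTIVE_INDEX,
    PURE_WATER_INDEX,
    SphereSpec,
    detection_rate,
    effective_area,
    extinction_cross_section,
    lambert_beer_concentration,
    number_concentration,
)
from caspm.concentration import A_S_CHANNEL_M2, per_ml

# 1) raw counts -> corrected rate
n, t, duty = 540, 600.0, 0.9
rate = detection_rate(n, t, duty)
print(f"{n} counts in {t:.0f} s at duty cycle {duty} -> R = {rate:.3f} s^-1")

# 2) rate -> concentration with the s-channel calibration
cal = ChannelCalibration(effective_area=A_S_CHANNEL_M2, flow_velocity=0.5)
c = number_concentration(rate, cal)
print(
    f"C = R/(A U) = {c:.3e} m^-3 = {per_ml(c):.3e} mL^-1"
    f"   (A = {cal.effective_area:.2e} m², U = {cal.flow_velocity} m/s)"
)

# 3) Lambert-Beer: absolute concentration of a PSL stock suspension
pw = OpticalConfig(medium_index=PURE_WATER_INDEX)
c_ext_um2 = extinction_cross_section(SphereSpec(1.036, PSL_REFRACTIVE_INDEX), pw)
c_ext_m2 = c_ext_um2 * 1e-12
transmittance, path = 0.82, 0.01  # 1 cm cuvette
n_psl = lambert_beer_concentration(transmittance, path, c_ext_m2)
print(
    f"\nLambert-Beer: T = {transmittance} over {path*100:.0f} cm with"
    f" C_ext = {c_ext_um2:.3f} µm² -> N = {per_ml(n_psl):.3e} mL^-1"
)

# 4) calibrating the effective area from that known suspension
r_measured = n_psl * 4.3e-11 * cal.flow_velocity  # a hypothetical observed rate
a_hat = effective_area(r_measured, n_psl, cal.flow_velocity)
print(
    f"Effective-area calibration: R = {r_measured:.3f} s^-1 at known N"
    f" -> A = {a_hat:.2e} m² (the inverse of C = R/(A U))"
)
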