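"""A synthetic cruise end to end: depth profiles and chl-a regressions.

Simulates ten stations (six depths each) with the five-component preset —
carbonaceous volume coupled to chlorophyll-a at correlation 0.8, iron
oxides and black carbon surface-enhanced and uncoupled — then runs the
whole pipeline and prints the per-Type regression table and a surface
enrichment ratio.
"""

import warnings

import caspm
from caspm import surface_enrichment

warnings.filterwarnings("ignore")

cfg = {
    "seed": 23,
    "medium": "seawater",
    "simulate": {"stations": 10, "duration_s": 120.0, "chl_coupling": 0.8},
}
result = caspm.run_pipeline(cfg)
print(f"{len(result.sample_table)} samples processed; log excerpt:")
for line in result.log[:3]:
    print("  " + line)

reg = result.regressions
chl = reg[reg.covariate == "chl_a_ug_L"]
print("\nper-Type volume concentration vs chlorophyll-a (OLS):")
print(f"{'type':>7} {'R^2':>7} {'p':>10} {'n':>4}")
for _, row in chl.iterrows():
    print(f"{row['type']:>7} {row.r_squared:7.3f} {row.p_value:10.2e} {int(row.n):4d}")
print(
    "  Types 0-2 (biogenic/mixed) correlate with chl-a; Types 3-4"
    " (atmospherically deposited) do not — the generated structure the"
    " pipeline should and does recover."
)

import numpy as np

ratios = []
for station, prof in result.station_profiles.items():
    prof = prof.assign(
        V_deposited=prof["V_TYPE3_um3_per_mL"] + prof["V_TYPE4_um3_per_mL"]
    )
    r = surface_enrichment(prof, "V_deposited")
    if np.isfinite(r):
        ratios.append(r)
print(
    f"\nsurface enrichment of deposited particles (Types 3+4), median over"
    f" {len(ratios)} stations: V(0 m)/V(10 m) = {np.median(ratios):.1f}"
    f" (values > 1 indicate surface accumulation, as generated)"
)
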