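# Methods

## The measurement model

A complex-amplitude sensor records, per particle, the forward-scattering
amplitude S(0°) as a point (ReS, ImS) in length units (µm), in two
channels: an s-channel aimed at sub-micron particles (amplitudes used in
0 < ReS < 1.5 µm, 0 < ImS < 0.5 µm) and an l-channel aimed at super-micron
particles (used in the 0 < ReS < 10 µm, 0 < ImS < 5 µm window minus the
s rectangle; amplitudes above that window violate the plane-wave
approximation of the waveform retrieval and are discarded).

For a homogeneous sphere of diameter D and vacuum refractive index m in a
non-absorbing medium of index m_med, the dimensionless forward amplitude is
the Mie series S0 = ½ Σₙ (2n+1)(aₙ+bₙ) evaluated at relative index
m_rel = m/m_med and size parameter x = π·D·m_med/λ_vac, truncated at the
Wiscombe order n_max = ⌈x + 4x^{1/3} + 2⌉.

**Amplitude convention.** The sensor's length-valued amplitude is related
to S0 by

    re_s = Im(S0)/k,   im_s = Re(S0)/k,   k = 2π·m_med/λ_vac,

with S0 in the e^{+iωt} (van de Hulst) sign convention. This choice is
fixed by three requirements that the processing chain relies on: (i) in
the Rayleigh limit re_s → k²(D/2)³(m_rel²−1)/(m_rel²+2) > 0, so
non-absorbing spheres populate the first quadrant; (ii) the optical
theorem takes the exact form C_ext = 2·λ_med·im_s, used as an internal
consistency identity (satisfied to ~1e−16 relative); (iii) boundary curves
shift toward higher ImS/ReS with increasing m, and absorbers shift further
left — the qualitative layout the classification geometry assumes. The
convention is validated against this layout, not against published numeric
S values, which do not exist for this instrument class.

**Numerics.** Mie coefficients are computed BHMIE-style in double
precision: the logarithmic derivative Dₙ(m_rel·x) by downward recurrence
and the Riccati–Bessel ψₙ(x) by downward-ratio recurrence with an upward
product anchored at ψ₀ = sin x (ψ is the minimal solution, so plain upward
recursion of ψ is unstable past n ≈ x); χₙ(x), the dominant solution, by
plain upward recurrence. Both downward recurrences start 50 orders above
max(n_max, |m_rel·x|); with this margin the series agrees with an
independently coded arbitrary-precision reference (mpmath, 50 digits,
derivative-form coefficients — a disjoint code path kept in
`tests/_mie_oracle.py`) to ≤ 1e−12 relative for x ≤ 50, including near
resonances. Batched evaluation sorts size parameters and processes chunks
spanning ≤ 20 truncation orders, masking each element's series at its own
n_max, so χ never overflows for small x. A guard rejects x > 150 (a 10 µm
sphere at 632.8 nm in water reaches only x ≈ 66).

Medium indices: 1.33154 (pure water, used for filter-sample measurements)
and 1.3373 (seawater, in situ), both at the working wavelength.

## Classification

Boundaries are theoretical S curves for non-absorbing spheres with
m = 1.38, 1.43, 1.60 computed in the measurement medium, two straight
lines y = −5.5x + 0.6 and y = 0.72x − 0.0072 separating Types 3 and 4, and
the exclusion ellipse (x/0.2)² + (y/0.025)² ≤ 1 inside which points are
too crowded to type (s-channel only; boundary inclusive). Each curve is
truncated to its initial branch (|S| strictly increasing in D) clipped to
the channel window, then decimated to ≤ 300 polyline points (chord error
~1e−5 µm, far below any noise scale). The side of a point is the sign of
the 2-D cross product between the nearest segment's direction (increasing
D) and the segment-to-point vector; "right" is the greater-ReS side; points
within 1e−9 µm are "on" and resolve to the lower Type index (lines resolve
to Type 3). Types 3/4 are only defined in the s-channel; l-channel points
left of the m = 1.60 curve are UNCLASSIFIED and excluded from
concentrations — whether the original analysis counted them anywhere is
unknown, so the choice is configurable.

## Sizing

Types 0–3 are sized as non-absorbing spheres by nearest-cell search
(Euclidean distance in the S plane) over a dense lookup table: m from 1.34
to 2.40 in steps of 0.005, 2000 log-spaced diameters from 0.1 to 10 µm.
The accelerated k-d-tree search is exactly equivalent to the exhaustive
scan (near-ties within 1e−12 µm are re-resolved toward smaller D, then
smaller m, the same deterministic rule the scan uses). Sizing Type 3
(iron oxides) as non-absorbing is a knowing approximation carried over
from the measurement practice; its size uncertainty is correspondingly
large. Two caveats quantified by the tests:

* the (m, D) → S map is near-degenerate along one direction even on the
  initial branch — adjacent m rows (Δm = 0.005) run nearly parallel in
  the S plane, so a noiseless query can land on a neighboring m with a
  compensating D shift. For ~90% of on-grid-m queries the recovered m is
  exact and D is then within one grid step by bracketing; the median
  |D̂−D|/D over the 1.36–2.0, 0.3–4 µm band is ≤ 2%.
* with Gaussian amplitude noise of 0.01 µm the median relative diameter
  error stays ≤ 10% for D ≥ 0.5 µm.

PSL calibration spheres (certified diameters 0.303–5.010 µm, vacuum index
1.5854 + 6.1764e−7i) are sized by projecting onto their theoretical curve
(nearest segment, linear interpolation of D); all seven are recovered to
≪ 1% from their own forward-modeled amplitudes.

Type 4 (black carbon) is sized through a strictly monotone table mapping
an amplitude scalar (|S| by default, configurable to ImS) to volume-
equivalent diameter, supplied as a two-column text file. The shipped
default is a **synthetic stand-in** generated from this package's own
absorbing-sphere model at m = 2.26 + 1.26i (a typical BC value at red
wavelengths); it is *not* the externally inferred shape-model relation
used with real data, which is not tabulated in any open source. Out-of-
range amplitudes are clamped to the calibration endpoint and flagged.

## Concentrations and size distributions

C = R/(A·U) with R the duty-cycle-corrected detection rate. The effective
detection areas default to the plateau calibrations A_s = 4.52e−11 m² and
A_l = 2.38e−10 m²; the area is known to be lower for the smallest
particles in each channel (signal-to-noise), so concentrations below
~0.5 µm (s) and ~1 µm (l) are systematically underestimated — an optional
per-size area table can be supplied. The flow velocity U has no published
value (only the ~1.9 mL/min flow rate and the 50 µm flow-pass thickness
are known) and is therefore a required calibration input; the virtual
instrument uses an illustrative U = 0.5 m/s. The duty cycle is likewise a
free configuration parameter (default 1).

Events are merged across channels over disjoint amplitude regions
(s rectangle / outer window minus s rectangle — the set difference avoids
silently losing events in the ReS < 1.5, ImS > 0.5 gap, whose original
treatment is unstated), then histogrammed per Type on a log₁₀ grid
(default 16 bins per decade over 0.1–10 µm, half-open bins): dN/dlogD =
count/(sampled volume of the event's channel × dlogD), channels added.
dV/dlogD = dN/dlogD·πD³_mid/6 exactly, per bin. Range integrals pro-rate
partial bins linearly in logD; full-range integrals conserve
count/volume to ~1e−15 relative.

## Profiles and regressions

Per-station profiles sort samples by depth and average replicates.
Regressions of per-Type volume concentration on chlorophyll-a or turbidity
are unweighted OLS on untransformed values (a log option exists), pooling
all samples, with R² and the two-sided slope p-value. Surface enrichment
is reported as the ratio V(0 m)/V(10 m).

## The virtual instrument

`caspm.synthetic` emulates exactly the statistical structure the chain
assumes — and no more:

* per component and channel, detection counts are Poisson with mean
  C·A·U·duty·t; diameters lognormal (median, GSD); amplitudes come from
  the package's own forward model at a fixed complex index, plus isotropic
  Gaussian noise on (ReS, ImS) (default σ = 0.005 µm); timestamps uniform.
  Counts, sizes, noise and covariates draw from independent sub-streams of
  one seed, so changing σ never changes counts.
* the five-component cruise preset (diatom-fragment-like m = 1.44 with an
  ImS deflation factor 0.45 standing in for cavity-bearing fragment
  morphology, carbonaceous m = 1.40, mineral dust m = 1.55, goethite-like
  iron oxide m = 2.20 + 0.10i, BC m = 2.26 + 1.26i; concentrations
  4e4/7e4/1e4/7e2/2.5e2 mL⁻¹) mirrors the qualitative ordering of coastal
  Pacific observations — Types 0/1 dominant with sub-micron modes, 3/4
  rare and surface-enhanced — without reproducing any cruise's values. A
  hematite-like index (2.9 + 0.4i) was deliberately not used for the iron
  component: under the adopted convention it scatters to ReS ≤ 0 at
  sub-0.5 µm sizes and would not populate the Type 3 region.
* stations couple chlorophyll-a to the carbonaceous volume concentration
  with a chosen correlation ρ: chl = base·(1 + cv·(ρz + √(1−ρ²)ε)), where
  z standardizes the carbonaceous volume with its *design* moments (depth
  shape × lognormal jitter, known in closed form), so the stated ρ holds
  in population whether stations are pooled or analyzed singly. Turbidity
  is proportional to total volume concentration with 5% noise. Biogenic
  components peak near a 30 m chlorophyll maximum; deposited components
  (iron oxides, BC) decay from the surface.

**What passing closed-loop tests do and do not show.** The generator
draws from the same sphere forward model the inversion assumes, so
round-trip tests certify the chain's internal consistency — bookkeeping,
geometry, calibration algebra, statistical recovery — not the adequacy of
the sphere model for real, irregular marine particles, nor detector-level
effects (coincidence, drift, waveform thresholds) that the generator does
not emulate. Two quantified sensitivities worth knowing:

* a 5:1 carbonaceous:dust mixture is recovered as a Type1:Type2
  concentration ratio of ≈ 4.4–4.5 noiseless — the deficit is the
  differential loss of the small-median component to the exclusion
  ellipse. At the default σ = 0.005 µm the ratio degrades to ≈ 3.3–3.6,
  because the m = 1.40 population sits only ~1σ from the m = 1.43
  boundary near the ellipse and hopped events are amplified by the
  s-channel's small sampled volume. Composition ratios between
  spectrally adjacent Types are accordingly noise-limited, exactly as the
  crowding of real data near the origin suggests.
* under an active chlorophyll coupling, components generated *without*
  coupling still share deterministic depth structure with chlorophyll
  (through the coupled component's depth shape), so their regression
  p-values are not exactly uniform; the clean type-I control is a
  ρ = 0 cruise, which is what the tests use.

Default synthetic study sizes: 120 s per sample, ten stations × six
depths (60 samples) for cruise statistics, ~1e4 events for mixture
recovery; at these sizes the cruise R² estimate carries a sampling SD of
~0.07 around ρ² = 0.64.

## Interchange formats

All interchange is comma-separated UTF-8 text: event files with a
`# key: value` header (schema version, medium, duration, duty cycle,
sample id) and per-row channel/time/ReS/ImS; BC calibrations as two
columns with a provenance header line; run configuration as YAML with
strict key validation; lookup tables as .npz archives carrying λ, m_med
and a convention tag, reloadable bit-identically. The pipeline log echoes
per-stage event counts and discard reasons (window, ellipse), so the
filtering chain is auditable sample by sample.

## Known limitations

* No shape model: all non-BC sizing assumes homogeneous non-absorbing
  spheres; Type 3 sizes are biased by absorption; the ImS-deflation
  factor is a one-parameter caricature of irregularity.
* The BC calibration shipped is synthetic; quantitative BC sizes require
  the user-supplied instrument-specific relation.
* Concentrations of the smallest particles per channel are biased low by
  the plateau effective-area choice.
* The amplitude sign/normalization convention is fixed by qualitative
  layout only; absolute comparisons with other instruments require a
  cross-calibration.
* No coincidence or dead-time treatment beyond the scalar duty cycle.
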