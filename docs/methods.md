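# Methods

## Dose model

Foetal absorbed dose is estimated through normalized uterus dose (NUD)
coefficients: Monte Carlo–derived uterus doses per unit of a measurable
exposure quantity, tabulated by projection/view, beam-quality (kVp) band
and mean foetal depth. The package consumes such tables; it never
regenerates them (radiation-transport calculation is out of scope).

Four pathways produce a per-record dose contribution:

- **Radiographic** — `NUD_ESD(d) · ESD · SF` per film, summed over the
  series. ESD is the free-in-air entrance surface dose in mGy.
- **Fluoroscopic** — the radiographic sum over spot films plus
  `NUD_ESD(d) · ESD_screening · SF` per screening run.
- **DAP** — `DAP · NUD_DAP(d) · SF` per examination, DAP in Gy·cm²,
  NUD_DAP in mGy/(Gy·cm²).
- **CT** — `NUD_V · (1.07 · CTDI_air) · (mAs/100) / pitch`. `NUD_V` sums
  per-slab uterus coefficients over the scanned range of a 208-slab
  (5 mm, 1040 mm) reference phantom. The slab tables are normalized per
  100 mAs, hence the mAs/100 factor. Division by pitch reflects helical
  geometry: larger table travel per rotation spreads the same tube output
  over more anatomy. The stacked-fraction notation this expression is
  sometimes written in is ambiguous between multiplying and dividing by
  pitch; division is the physically consistent reading and is what is
  implemented. No size factor enters the CT pathway: the slab
  coefficients already give the dose to the uterus region, and the
  published per-examination CT products use them directly.

ESD reconstruction from QA tube output applies an inverse-square
distance correction and a quadratic kVp correction,
`[(FSD_QA/FSD_EX)·(kVp_EX/kVp_QA)]²`. The quadratic kVp rule is an
approximation that degrades over wide potential gaps; a warning is
emitted when |kVp_EX − kVp_QA| > 30 kV, but the rule is still applied as
stated. Output and output-rate are interpreted as measured at the QA
geometry (FSD_QA, kVp_QA), with output in mGy/mAs and output-rate in
mGy/(min·mA), screening time in minutes. When a record carries both a
measured ESD and reconstructable QA data, the measurement wins and the
redundancy is logged.

The size factor SF (uterus→foetus conversion) is evaluated once per
foetus from the gestational age, not per film: records carry a single GA
per patient, so per-film SFs would be identical anyway. With no SF table
loaded, SF = 1.0 is used with a warning (foetal dose taken equal to
uterus dose — conservative in late gestation).

## Interpolation and lookup rules

- Depth and gestational-age interpolation is piecewise linear, exact at
  grid points, clamped to the nearest endpoint outside the grid (with a
  warning). Linear interpolation cannot overshoot the neighbouring grid
  values and keeps the depth-monotonicity of the tables.
- Beam-quality matching selects the band whose kVp interval contains the
  record's kVp; a shared edge resolves to the lower band; a kVp outside
  every band falls back to the nearest band with a warning. (The table
  dialect could be extended with a half-value-layer column if tables
  indexed by HVL are available; only kVp bands are implemented.)
- A CT slab belongs to the scan volume iff its midpoint lies in the
  half-open interval [start, end), in a frame with the origin at slab 0's
  lower edge, millimetres increasing toward the head. The midpoint rule
  makes the slab sum additive over abutting ranges and order-independent;
  fractional-overlap weighting was deliberately rejected to keep NUD_V a
  pure sum of tabulated slab values. A range containing no midpoint
  yields 0 with a warning.
- CT scanner models must match exactly; there is no interpolation
  between scanner models.
- Patient defaults: foetal depth 9 cm and maternal AP thickness 25 cm
  when not supplied — the population averages used in foetal-dose
  practice.

## Risk model

All stochastic endpoints use linear no-threshold conversion
`R = D_f · RC` with defaults (per mGy): childhood cancer 8.0×10⁻⁵,
hereditary effects 0.5×10⁻⁵, severe mental retardation 43×10⁻⁵, and IQ
decline 25×10⁻³ IQ points (a magnitude, not a probability). All are
overridable via YAML config. No gestational-age gating is applied to the
mental-retardation/IQ endpoints by default; their radiobiological windows
(roughly weeks 8–15/16–25) can be imposed by the caller through a zero
coefficient if desired.

Deterministic effects (death, malformation, growth and mental
retardation) have a practical threshold around 100 mGy of foetal dose;
reports set an advisory flag at ≥ 100 mGy rather than computing a
deterministic risk.

### The "1 in N" rendering

Risk strings follow the counselling convention: round the probability to
one significant figure `d × 10^e` (decimal half-up), then print
`N = m(d) × 10⁻ᵉ` with the reciprocal mantissa map

    d    1    2    3     4     5    6     7     8      9
    m    1    0.5  0.33  0.25  0.2  0.17  0.14  0.125  0.11

This is the map that yields the denominators used in published
foetal-risk tables (12500 for 8×10⁻⁵, 3300 for 3×10⁻⁴, 14000 for 7×10⁻⁵);
generic two-significant-figure reciprocal rounding would print 13000,
3333, 14286. Half-up rounding acts on the shortest decimal representation
of the float, so exact halves (2.5×10⁻⁷ → 3×10⁻⁷) round up reliably.
Zero or sub-10⁻⁹ risks render as a "negligible" sentinel instead of an
unbounded denominator. The rendering is designed for small probabilities;
above ~0.05 the integer denominator is too coarse to round-trip within
the map's ~2% precision.

Comparative presentations use two configurable references: the mean
foetal dose of one AP chest radiograph (default 0.001 mGy) and the
annual natural background dose (default 2.4 mGy/year; the background
period is rendered in days, weeks or years as magnitude dictates).

## Cohort layer

Per-foetus totals are arithmetic sums over all of a patient's records
(multiple and repeat examinations accumulate). Dose histograms use the
survey bins <0.1 / 0.1–<1 / 1–<10 / 10–<50 mGy, half-open on the right
(exactly 1.0 mGy falls in 1–<10), plus an overflow bin at 50 mGy that
warns when populated. Risk-band strings render each bin as
"1 in N(lo)–<1 in N(hi)". Range/mean tables (ESD and foetal dose by
projection) aggregate per examination record; histograms and headline
percentages aggregate per foetus, matching how such surveys mix the two.
Means are unrounded internally and rendered to 2 decimals; headline
shares round to the nearest integer percent. Rows whose dose pathway
cannot be resolved are rejected with a logged reason, not fatal.

## Synthetic data

Two generators make the package testable without the licensed coefficient
publications and without patient data; both are deterministic under a
seed.

**Coefficient tables.** Radiographic/DAP NUD curves are exponential
decays in depth (attenuation-like, decay constant 0.15–0.30 cm⁻¹) on a
4–12 cm grid covering the clinical 4.9–9.3 cm depth range, scaled up
slightly with beam quality, and bounded to [10⁻⁵, 1] per mGy ESD;
chest-type projections get 10⁻³-scale magnitudes since the uterus is far
outside the beam. CT slab profiles are Gaussians centred on a
configurable uterus position (default 320 mm) with per-slab values sized
so the whole-profile sum is ~0.2–1 mGy/mGy — giving uterus doses of a few
to ~20 mGy for typical abdominal helical technique. Size factors drift
smoothly near 1 over 2–40 weeks. These tables have the correct structure,
monotonicity and magnitudes but synthetic values: tests against them
verify the machinery (lookup, interpolation, summation, formatting), not
the clinical accuracy of any particular coefficient.

**Cohort.** 367 patients by default, gestational age ~N(19.2, 8²)
clipped to [2, 38] weeks, foetal depth ~N(7.1, 1²) clipped to
[4.9, 9.3] cm, maternal AP thickness ~N(23.7, 3²) clipped to
[16.5, 31] cm; an exam mix weighted toward plain radiography with DAP,
screening and CT minorities; ~10% of patients receive 2–4 distinct
examinations and ~5% repeat one 2–3 times. The generated cohort exercises
every pathway end-to-end with zero schema rejects. It does not emulate
inter-hospital technique differences, censored ("<0.001") dose recording,
or the real survey's exam-frequency correlations.

## Numerical choices and limitations

- Doses are never rounded internally; all rounding is presentational.
- Dose totals are plain floating-point sums; contributions are
  non-negative, so cancellation is not a concern at survey scale.
- Validation is strict at load time (monotone depth grids, positive NUD,
  exactly 208 slabs, SF table spanning 2–38 weeks); the CT profile
  unimodality check is a warning, not an error, since a genuinely bimodal
  profile could arise from unusual scanner geometry.
- Test and acceptance runs use desk-scale problem sizes (cohorts of
  50–150, full property suites on one fixture store); the pipeline is
  linear in record count.
- The package estimates uterus-region foetal dose only; organ doses,
  shielding, automatic exposure control and dose-response curvature
  (DDREF, BEIR-style lifetime risk) are out of scope.
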