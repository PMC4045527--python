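# fetaldose

Foetal absorbed dose and radiation-risk estimation for diagnostic
radiology exposures of pregnant patients.

When a radiological examination is performed on a patient who is (or
turns out to have been) pregnant, a medical physicist is asked to
estimate the absorbed dose to the foetus and the associated risks. This
package implements that desk calculation for the four common exposure
situations — plain radiographs, fluoroscopic examinations (spot films +
screening), dose-area-product (DAP) records, and helical CT — and
converts the dose to stochastic-risk estimates with the risk-communication
conventions used in counselling reports.

## The model

Foetal dose is built from **normalized uterus dose (NUD)** coefficients —
uterus dose per unit entrance surface dose (ESD) or per unit DAP,
tabulated by projection, beam-quality band and mean foetal depth *d* —
and a gestational-age-dependent **size factor** SF converting uterus dose
to foetal dose:

```
radiographs:   D_f = Σᵢ NUD_d,ESD,i · ESD_i · SF
fluoroscopy:   D_f = Σ spot films  +  Σⱼ NUD_d,ESD,j · ESD_screening,j · SF
DAP records:   D_f = Σᵢ DAP_i · NUD_d,DAP,i · SF
CT:            D_f = NUD_V · CTDI_soft · (mAs/100) / pitch
```

When no measured ESD is supplied it is reconstructed from QA tube-output
data with inverse-square distance and quadratic kVp corrections:

```
ESD = [(FSD_QA/FSD_EX) · (kVp_EX/kVp_QA)]² · output · mAs
```

(`output_rate · mA · time` for screening runs). For CT, `NUD_V` is the sum
of per-slab normalized uterus doses over all 5 mm phantom slabs whose
midpoint lies in the scanned range (208 slabs per scanner model), and
`CTDI_soft = 1.07 · CTDI_air`.

Risk is linear in dose with no threshold: `R = D_f · RC`, with default
coefficients 8.0×10⁻⁵ /mGy (childhood cancer), 0.5×10⁻⁵ /mGy (hereditary
effects), 43×10⁻⁵ /mGy (severe mental retardation) and 25×10⁻³ IQ
points/mGy. Probabilities are rendered in the counselling "1 in N" style:
the risk is rounded to one significant figure `d × 10^e` and
`N = m(d) × 10⁻ᵉ` with the reciprocal mantissa map
`m = {1:1, 2:0.5, 3:0.33, 4:0.25, 5:0.2, 6:0.17, 7:0.14, 8:0.125, 9:0.11}` —
so 21.9 mGy of childhood-cancer risk prints "1 in 500", and 8×10⁻⁵ prints
"1 in 12500" (not the 13000 that generic two-figure rounding would give).

The real NUD compilations are licensed publications, so the package ships
a deterministic generator of synthetic coefficient tables (correct
structure and magnitudes, synthetic values) in an open CSV dialect;
supply your own tables in the same dialect for clinical-grade numbers.

## Worked example

```python
import fetaldose as fd

store = fd.loads_tables(fd.generate_fixture_tables(seed=20260930, n_projections=8))
ctx = fd.PatientContext(ga_weeks=20.0, fetal_depth_cm=7.0, maternal_ap_cm=24.0)
cal = fd.QACalibration(kvp_qa=80.0, fsd_qa_cm=100.0, output_mgy_per_mas=0.05)
series = [
    fd.RadiographRecord(projection="abdomen", view="ap", kvp=75.0,
                        fsd_cm=90.0, mas=40.0, calibration=cal),
    fd.RadiographRecord(projection="abdomen", view="ap", kvp=80.0,
                        fsd_cm=90.0, mas=32.0, calibration=cal),
]
result = fd.dose_radiographic(series, ctx, store)
report = fd.consequence_report(result.dose_mgy)
```

Running `python examples/single_examination_dose.py` prints:

```
foetal dose: 0.289 mGy over 2 films
  abdomen/ap: ESD 2.17 mGy x NUD 0.0666 x SF 0.99 = 0.1431 mGy
  abdomen/ap: ESD 1.98 mGy x NUD 0.0746 x SF 0.99 = 0.1458 mGy
childhood cancer risk: 2.31e-05 -> 1 in 50000 (safety 0.999977)
equivalent chest radiographs: 289
equivalent natural background: 6.3 weeks
deterministic-effect advisory (>=100 mGy): False
```

Each audit row shows the reconstructed entrance surface dose, the
normalized-uterus-dose coefficient interpolated at the 7 cm foetal depth,
and the size factor at 20 weeks; the total of 0.289 mGy carries a
childhood-cancer risk of about 1 in 50000 — far below the ~100 mGy
deterministic-effect threshold, and equivalent to about six weeks of
natural background exposure.

Other examples: `examples/ct_examination.py` (CT slab-sum pathway) and
`examples/cohort_survey.py` (survey-style cohort report with dose-band
risk strings).

## Command line

```
fetaldose risk --dose-mgy 21.9
fetaldose dose --records exams.csv --coefficients coeff.csv --patient P0001
fetaldose cohort simulate --seed 1 --n 367 --out exams.csv
fetaldose cohort summarize --records exams.csv --coefficients coeff.csv --out-dir report/
fetaldose coefficients simulate --seed 1 --out coeff.csv
```

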