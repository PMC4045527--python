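"""Foetal dose from a helical CT acquisition.

The CT pathway sums per-slab normalized uterus doses over the scanned
longitudinal range, scales by soft-tissue CTDI (1.07 x CTDI free-in-air),
mAs/100 and 1/pitch.
"""

import fetaldose as fd

store = fd.loads_tables(fd.generate_fixture_tables(seed=20260930, n_scanners=2))
ctx = fd.PatientContext(ga_weeks=24.0)  # depth not known -> 9 cm default used

rec = fd.CTRecord(
    scanner_model="scanner-a",
    ctdi_air=14.0,        # mGy per 100 mAs, free-in-air
    mas=180.0,            # mAs per rotation
    pitch=1.2,
    scan_start_mm=200.0,  # phantom frame, origin at the feet-end slab edge
    scan_end_mm=520.0,
)

result = fd.dose_ct(rec, ctx, store)
c = result.contributions[0]
print(f"NUD_V (slab sum over scan volume): {c.nud:.4f} mGy/mGy per 100 mAs")
print(f"CTDI_soft x mAs/100 / pitch:        {c.quantity:.3f} mGy")
print(f"foetal dose:                        {result.dose_mgy:.2f} mGy")

for ep in ("childhood_cancer", "hereditary"):
    r = fd.consequence_report(result.dose_mgy).endpoints[ep]
    print(f"{ep}: {r.one_in_n}")
# Pitch > 1 stretches the helix, lowering dose; halving pitch would double it.
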