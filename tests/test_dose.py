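"""Dose-engine pathways: sums, linearity, monotonicity, audit totals."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fetaldose as fd
from fetaldose.coefficients import N_SLABS, CTScannerSlabTable
from fetaldose.errors import InputError, UnknownKeyError

# a minimal hand-written store with known coefficients
_STORE_TEXT = (
    "table_type,projection,view,kvp_min,kvp_max,depth_cm,nud,scanner_model,slab_index,ga_weeks,sf\n"
    "nud_esd,abdomen,ap,60,100,5,0.1,,,,\n"
    "nud_esd,abdomen,ap,60,100,9,0.1,,,,\n"
    "nud_dap,abdomen,ap,60,100,5,0.5,,,,\n"
    "nud_dap,abdomen,ap,60,100,9,0.5,,,,\n"
    + "".join(f"size_factor,,,,,,,,,{ga},1.0\n" for ga in (2, 20, 38))
)


@pytest.fixture(scope="module")
def flat_store():
    return fd.loads_tables(_STORE_TEXT)


@pytest.fixture
def flat_ctx():
    return fd.PatientContext(ga_weeks=20.0, fetal_depth_cm=7.0)


def _esd_record(esd=2.0, kvp=80.0):
    return fd.RadiographRecord(projection="abdomen", view="ap", kvp=kvp, esd_mgy=esd)


class TestRadiographic:
    def test_single_record_product(self, flat_store, flat_ctx):
        # NUD 0.1 × ESD 2.0 × SF 1.0
        res = fd.dose_radiographic([_esd_record(2.0)], flat_ctx, flat_store)
        assert res.dose_mgy == pytest.approx(0.2)

    def test_duplicated_record_doubles_dose(self, flat_store, flat_ctx):
        one = fd.dose_radiographic([_esd_record()], flat_ctx, flat_store)
        two = fd.dose_radiographic([_esd_record()] * 2, flat_ctx, flat_store)
        assert two.dose_mgy == pytest.approx(2 * one.dose_mgy)

    def test_unknown_projection_names_the_key(self, flat_store, flat_ctx):
        bad = fd.RadiographRecord(projection="skull", view="lat", esd_mgy=1.0)
        with pytest.raises(UnknownKeyError, match="skull"):
            fd.dose_radiographic([bad], flat_ctx, flat_store)

    @given(esds=st.lists(st.floats(min_value=0.01, max_value=50), min_size=1, max_size=5))
    def test_matches_term_by_term_oracle(self, store, ctx, esds):
        """Series dose equals a hand sum of NUD·ESD·SF over records."""
        records = [
            fd.RadiographRecord(projection="abdomen", view="ap", kvp=70.0, esd_mgy=e)
            for e in esds
        ]
        res = fd.dose_radiographic(records, ctx, store)
        nud = store.nud_esd_table("abdomen", "ap").nud_at_depth(ctx.resolved_depth_cm, 70.0)
        sf = store.size_factor(ctx.ga_weeks)
        assert res.dose_mgy == pytest.approx(sum(nud * e * sf for e in esds), rel=1e-12)

    def test_total_equals_sum_of_contributions(self, store, ctx):
        records = [_esd_record(e) for e in (0.5, 1.5, 3.0)]
        res = fd.dose_radiographic(records, ctx, store)
        assert res.dose_mgy == pytest.approx(
            sum(c.dose_mgy for c in res.contributions), rel=1e-9
        )
        assert all(c.dose_mgy >= 0 for c in res.contributions)

    @given(k=st.floats(min_value=0.1, max_value=20))
    def test_linearity_in_esd(self, flat_store, flat_ctx, k):
        base = fd.dose_radiographic([_esd_record(2.0)], flat_ctx, flat_store).dose_mgy
        scaled = fd.dose_radiographic([_esd_record(2.0 * k)], flat_ctx, flat_store).dose_mgy
        assert scaled == pytest.approx(k * base, rel=1e-12)

    @given(
        d1=st.floats(min_value=4.9, max_value=9.3),
        d2=st.floats(min_value=4.9, max_value=9.3),
    )
    def test_monotone_in_fetal_depth(self, store, d1, d2):
        """A deeper foetus never receives more dose from the same series."""
        lo, hi = sorted((d1, d2))
        rec = fd.RadiographRecord(projection="abdomen", view="ap", kvp=70.0, esd_mgy=3.0)
        doses = [
            fd.dose_radiographic(
                [rec], fd.PatientContext(ga_weeks=20.0, fetal_depth_cm=d), store
            ).dose_mgy
            for d in (lo, hi)
        ]
        assert doses[0] >= doses[1] - 1e-15


class TestFluoroscopic:
    def _screening(self, time_min=1.5):
        cal = fd.QACalibration(kvp_qa=80.0, fsd_qa_cm=100.0,
                               output_rate_mgy_per_min_ma=10.0)
        return fd.ScreeningRecord("abdomen", "ap", kvp=80.0, fsd_cm=100.0,
                                  ma=2.0, time_min=time_min, calibration=cal)

    def test_empty_screening_list_degenerates_to_radiographic(self, flat_store, flat_ctx):
        spots = [_esd_record(2.0)]
        assert fd.dose_fluoroscopic(spots, [], flat_ctx, flat_store).dose_mgy == (
            fd.dose_radiographic(spots, flat_ctx, flat_store).dose_mgy
        )

    def test_empty_spots_is_pure_screening_sum(self, flat_store, flat_ctx):
        res = fd.dose_fluoroscopic([], [self._screening()], flat_ctx, flat_store)
        # ESD_screening = 10 × 2 × 1.5 = 30 mGy; NUD 0.1, SF 1
        assert res.dose_mgy == pytest.approx(3.0)

    def test_mixed_series_matches_oracle_sum(self, flat_store, flat_ctx):
        spots = [_esd_record(e) for e in (1.0, 2.0)]
        screenings = [self._screening(1.0), self._screening(2.0)]
        res = fd.dose_fluoroscopic(spots, screenings, flat_ctx, flat_store)
        expected = 0.1 * (1.0 + 2.0) + 0.1 * (10 * 2 * 1.0 + 10 * 2 * 2.0)
        assert res.dose_mgy == pytest.approx(expected, rel=1e-12)

    @given(k=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_screening_time(self, flat_store, flat_ctx, k):
        base = fd.dose_fluoroscopic([], [self._screening(1.0)], flat_ctx, flat_store).dose_mgy
        scaled = fd.dose_fluoroscopic([], [self._screening(k)], flat_ctx, flat_store).dose_mgy
        assert scaled == pytest.approx(k * base, rel=1e-12)


class TestDAP:
    def test_one_term_product(self, flat_store, flat_ctx):
        rec = fd.RadiographRecord(projection="abdomen", view="ap", kvp=80.0, dap_gycm2=2.0)
        # DAP 2.0 Gy·cm² × NUD_DAP 0.5 mGy/(Gy·cm²) × SF 1
        assert fd.dose_dap([rec], flat_ctx, flat_store).dose_mgy == pytest.approx(1.0)

    def test_zero_dap_gives_zero(self, flat_store, flat_ctx):
        rec = fd.RadiographRecord(projection="abdomen", view="ap", kvp=80.0, dap_gycm2=0.0)
        assert fd.dose_dap([rec], flat_ctx, flat_store).dose_mgy == 0.0

    @given(daps=st.lists(st.floats(min_value=0, max_value=30), min_size=1, max_size=5))
    def test_matches_oracle_sum(self, store, ctx, daps):
        records = [
            fd.RadiographRecord(projection="pelvis", view="ap", kvp=75.0, dap_gycm2=d)
            for d in daps
        ]
        res = fd.dose_dap(records, ctx, store)
        nud = store.nud_dap_table("pelvis", "ap").nud_at_depth(ctx.resolved_depth_cm, 75.0)
        sf = store.size_factor(ctx.ga_weeks)
        assert res.dose_mgy == pytest.approx(sum(d * nud * sf for d in daps), rel=1e-12)


class TestCT:
    def test_worked_value(self, flat_ctx):
        """NUD_V 0.5 × CTDI_soft 10.7 × (200/100) / 1.0 = 10.7 mGy."""
        slabs = np.zeros(N_SLABS)
        slabs[60:65] = 0.1  # midpoints 302.5..322.5 → NUD_V = 0.5 over the range
        store = fd.CoefficientStore(ct_slab={"scanner-a": CTScannerSlabTable("scanner-a", slabs)})
        rec = fd.CTRecord("scanner-a", ctdi_air=10.0, mas=200.0, pitch=1.0,
                          scan_start_mm=300.0, scan_end_mm=325.0)
        assert fd.dose_ct(rec, flat_ctx, store).dose_mgy == pytest.approx(10.7)

    def test_pitch_two_halves_the_dose(self, store, ctx):
        kw = dict(scanner_model=list(store.ct_slab)[0], ctdi_air=12.0, mas=150.0,
                  scan_start_mm=200.0, scan_end_mm=500.0)
        d1 = fd.dose_ct(fd.CTRecord(pitch=1.0, **kw), ctx, store).dose_mgy
        d2 = fd.dose_ct(fd.CTRecord(pitch=2.0, **kw), ctx, store).dose_mgy
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_scan_without_slab_midpoints_gives_zero_with_warning(self, store, ctx):
        rec = fd.CTRecord(list(store.ct_slab)[0], ctdi_air=10.0, mas=100.0,
                          pitch=1.0, scan_start_mm=501.0, scan_end_mm=502.0)
        with pytest.warns(UserWarning, match="no slab midpoint"):
            assert fd.dose_ct(rec, ctx, store).dose_mgy == 0.0

    def test_unknown_scanner_rejected(self, ctx, store):
        rec = fd.CTRecord("mystery-scanner", ctdi_air=10.0, mas=100.0, pitch=1.0,
                          scan_start_mm=100.0, scan_end_mm=400.0)
        with pytest.raises(UnknownKeyError, match="mystery-scanner"):
            fd.dose_ct(rec, ctx, store)

    @given(k=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_mas(self, store, ctx, k):
        kw = dict(scanner_model=list(store.ct_slab)[0], ctdi_air=12.0, pitch=1.0,
                  scan_start_mm=200.0, scan_end_mm=500.0)
        base = fd.dose_ct(fd.CTRecord(mas=100.0, **kw), ctx, store).dose_mgy
        scaled = fd.dose_ct(fd.CTRecord(mas=100.0 * k, **kw), ctx, store).dose_mgy
        assert scaled == pytest.approx(k * base, rel=1e-12)


class TestTotals:
    def _results(self, flat_store, flat_ctx):
        return [
            fd.dose_radiographic([_esd_record(e)], flat_ctx, flat_store, patient_id="P1")
            for e in (0.5, 1.5, 4.0)
        ]

    def test_single_exam_is_identity(self, flat_store, flat_ctx):
        (res,) = self._results(flat_store, flat_ctx)[:1]
        assert fd.total_per_foetus([res]).dose_mgy == pytest.approx(res.dose_mgy)

    def test_permutation_invariant(self, flat_store, flat_ctx):
        results = self._results(flat_store, flat_ctx)
        fwd = fd.total_per_foetus(results).dose_mgy
        rev = fd.total_per_foetus(results[::-1]).dose_mgy
        assert fwd == pytest.approx(rev)

    def test_equals_oracle_sum(self, flat_store, flat_ctx):
        results = self._results(flat_store, flat_ctx)
        assert fd.total_per_foetus(results).dose_mgy == pytest.approx(
            sum(r.dose_mgy for r in results), rel=1e-12
        )

    def test_mixed_patients_rejected(self, flat_store, flat_ctx):
        a = fd.dose_radiographic([_esd_record()], flat_ctx, flat_store, patient_id="P1")
        b = fd.dose_radiographic([_esd_record()], flat_ctx, flat_store, patient_id="P2")
        with pytest.raises(InputError):
            fd.total_per_foetus([a, b])
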