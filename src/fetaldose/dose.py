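"""Foetal absorbed dose per exposure and per foetus.

Each pathway combines the exposure quantity with a normalized-uterus-dose
lookup and the foetal size factor SF (uterus→foetus conversion):

    radiographic:  D_f = Σ_i NUD_ESD(d)_i · ESD_i · SF
    fluoroscopic:  D_f = Σ spot films + Σ_j NUD_ESD(d)_j · ESD_screening_j · SF
    DAP:           D_f = Σ_i DAP_i · NUD_DAP(d)_i · SF
    CT:            D_f = NUD_V · CTDI_soft · (mAs/100) / pitch

with d the mean foetal depth, NUD_V the slab sum over the scan volume and
CTDI_soft = 1.07 · CTDI_air.  Doses are never rounded here; presentation
rounding lives in the risk and cohort layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coefficients import CoefficientStore, PatientContext
from .errors import InputError
from .exposures import (
    CTRecord,
    RadiographRecord,
    ScreeningRecord,
    ctdi_soft_tissue,
    esd_screening,
)

__all__ = ["DoseContribution", "DoseResult", "dose_radiographic",
           "dose_fluoroscopic", "dose_dap", "dose_ct", "total_per_foetus"]


@dataclass(frozen=True)
class DoseContribution:
    """Audit row for one exposure's contribution to the foetal dose."""

    label: str  # projection/view or scanner model
    pathway: str  # esd | qa | dap | screening | ct
    quantity: float  # ESD (mGy), DAP (Gy·cm²) or CTDI_soft·mAs/100/pitch (mGy)
    nud: float  # NUD at depth, or NUD_V for CT
    sf: float
    dose_mgy: float


@dataclass
class DoseResult:
    """Per-record contributions and their total for one foetus."""

    contributions: list[DoseContribution] = field(default_factory=list)
    patient_id: str | None = None

    @property
    def dose_mgy(self) -> float:
        return sum(c.dose_mgy for c in self.contributions)

    def __add__(self, other: "DoseResult") -> "DoseResult":
        pid = self.patient_id if self.patient_id == other.patient_id else None
        return DoseResult(self.contributions + other.contributions, pid)


def _sf(ctx: PatientContext, store: CoefficientStore) -> float:
    # evaluated once per foetus from the gestational age at examination
    return store.size_factor(ctx.ga_weeks)


def dose_radiographic(
    records: list[RadiographRecord],
    ctx: PatientContext,
    store: CoefficientStore,
    patient_id: str | None = None,
) -> DoseResult:
    """Foetal dose from a series of radiographs via the ESD pathway."""
    sf = _sf(ctx, store)
    depth = ctx.resolved_depth_cm
    result = DoseResult(patient_id=patient_id)
    for rec in records:
        esd = rec.resolve_esd()
        if esd < 0:
            raise InputError(f"negative ESD {esd} mGy for {rec.projection}/{rec.view}")
        nud = store.nud_esd_table(rec.projection, rec.view).nud_at_depth(depth, rec.kvp)
        result.contributions.append(
            DoseContribution(
                label=f"{rec.projection}/{rec.view}",
                pathway=rec.pathway,
                quantity=esd,
                nud=nud,
                sf=sf,
                dose_mgy=nud * esd * sf,
            )
        )
    return result


def dose_fluoroscopic(
    spots: list[RadiographRecord],
    screenings: list[ScreeningRecord],
    ctx: PatientContext,
    store: CoefficientStore,
    patient_id: str | None = None,
) -> DoseResult:
    """Foetal dose from a complete fluoroscopic examination: spot films
    plus screening runs.  With no screenings this degenerates to the plain
    radiographic sum."""
    result = dose_radiographic(spots, ctx, store, patient_id)
    sf = _sf(ctx, store)
    depth = ctx.resolved_depth_cm
    for rec in screenings:
        if rec.calibration is None:
            raise InputError(
                f"screening {rec.projection}/{rec.view} has no QA calibration"
            )
        esd = esd_screening(rec.calibration, rec)
        nud = store.nud_esd_table(rec.projection, rec.view).nud_at_depth(depth, rec.kvp)
        result.contributions.append(
            DoseContribution(
                label=f"{rec.projection}/{rec.view}",
                pathway="screening",
                quantity=esd,
                nud=nud,
                sf=sf,
                dose_mgy=nud * esd * sf,
            )
        )
    return result


def dose_dap(
    records: list[RadiographRecord],
    ctx: PatientContext,
    store: CoefficientStore,
    patient_id: str | None = None,
) -> DoseResult:
    """Foetal dose from dose-area-product records."""
    sf = _sf(ctx, store)
    depth = ctx.resolved_depth_cm
    result = DoseResult(patient_id=patient_id)
    for rec in records:
        if rec.dap_gycm2 is None:
            raise InputError(
                f"record {rec.projection}/{rec.view} carries no DAP value"
            )
        if rec.dap_gycm2 < 0:
            raise InputError(f"negative DAP {rec.dap_gycm2} Gy·cm²")
        nud = store.nud_dap_table(rec.projection, rec.view).nud_at_depth(depth, rec.kvp)
        result.contributions.append(
            DoseContribution(
                label=f"{rec.projection}/{rec.view}",
                pathway="dap",
                quantity=float(rec.dap_gycm2),
                nud=nud,
                sf=sf,
                dose_mgy=float(rec.dap_gycm2) * nud * sf,
            )
        )
    return result


def dose_ct(
    rec: CTRecord,
    ctx: PatientContext,
    store: CoefficientStore,
    patient_id: str | None = None,
) -> DoseResult:
    """Foetal dose from one CT acquisition.

    The per-100-mAs slab normalization gives the mAs/100 factor; helical
    table travel spreads the dose, hence division by pitch.  No foetal
    size factor enters this pathway: the CT slab coefficients already give
    the dose to the uterus region directly.
    """
    table = store.ct_table(rec.scanner_model)
    nud_v = table.slab_sum(rec.scan_start_mm, rec.scan_end_mm)
    quantity = ctdi_soft_tissue(rec.ctdi_air) * (rec.mas / 100.0) / rec.pitch
    result = DoseResult(patient_id=patient_id)
    result.contributions.append(
        DoseContribution(
            label=rec.scanner_model,
            pathway="ct",
            quantity=quantity,
            nud=nud_v,
            sf=1.0,
            dose_mgy=nud_v * quantity,
        )
    )
    return result


def total_per_foetus(results: list[DoseResult]) -> DoseResult:
    """Total dose for one foetus across multiple and repeat examinations."""
    total = DoseResult()
    ids = {r.patient_id for r in results if r.patient_id is not None}
    if len(ids) > 1:
        raise InputError(f"results belong to different patients: {sorted(ids)}")
    for r in results:
        total.contributions.extend(r.contributions)
    total.patient_id = next(iter(ids)) if ids else None
    return total
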