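"""Exposure records and entrance-surface-dose reconstruction.

Four record kinds cover the collection forms a foetal-dose service works
from: plain radiographs, fluoroscopic screening runs, dose-area-product
entries and CT acquisitions.  When no measured ESD or DAP is supplied, the
free-in-air entrance surface dose is reconstructed from quality-assurance
tube-output data by inverse-square distance correction and a quadratic kVp
correction:

    ESD_rad       = [(FSD_QA/FSD_EX) · (kVp_EX/kVp_QA)]² · output · mAs
    ESD_screening = [(FSD_QA/FSD_EX) · (kVp_EX/kVp_QA)]² · output_rate · mA · time

with ``output`` in mGy/mAs and ``output_rate`` in mGy/(min·mA), both
referred to the QA geometry (FSD_QA, kVp_QA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, InputError, SchemaError

__all__ = [
    "CTDI_SOFT_TISSUE_FACTOR",
    "QACalibration",
    "RadiographRecord",
    "ScreeningRecord",
    "CTRecord",
    "esd_radiograph",
    "esd_screening",
    "ctdi_soft_tissue",
    "read_exposure_csv",
    "rows_to_records",
    "EXPOSURE_COLUMNS",
]

log = logging.getLogger(__name__)

#: Free-in-air CTDI to ICRU soft tissue conversion.
CTDI_SOFT_TISSUE_FACTOR = 1.07

#: kVp gap beyond which the quadratic output-scaling rule is flagged as a
#: long extrapolation.
_KVP_WARN_GAP = 30.0


def _positive(name: str, value: float | None, required: bool = True) -> None:
    if value is None:
        if required:
            raise InputError(f"{name} is required")
        return
    if not value > 0:
        raise InputError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class QACalibration:
    """Tube output measured at QA conditions.

    ``output_mgy_per_mas`` applies to radiographic exposures;
    ``output_rate_mgy_per_min_ma`` to fluoroscopic screening.  Both are
    referred to ``fsd_qa_cm`` and ``kvp_qa``.
    """

    kvp_qa: float
    fsd_qa_cm: float
    output_mgy_per_mas: float | None = None
    output_rate_mgy_per_min_ma: float | None = None

    def __post_init__(self) -> None:
        _positive("kvp_qa", self.kvp_qa)
        _positive("fsd_qa_cm", self.fsd_qa_cm)
        _positive("output_mgy_per_mas", self.output_mgy_per_mas, required=False)
        _positive("output_rate_mgy_per_min_ma", self.output_rate_mgy_per_min_ma, required=False)


@dataclass(frozen=True)
class RadiographRecord:
    """One radiograph (or one DAP entry, when only ``dap_gycm2`` is set).

    The dose pathway is resolved in priority order: measured ESD, then
    DAP, then QA reconstruction from (calibration, kVp, FSD, mAs).  At
    least one pathway must be resolvable.
    """

    projection: str
    view: str
    kvp: float | None = None
    fsd_cm: float | None = None
    mas: float | None = None
    esd_mgy: float | None = None
    dap_gycm2: float | None = None
    calibration: QACalibration | None = None

    def __post_init__(self) -> None:
        if self.pathway is None:
            raise InputError(
                f"radiograph {self.projection}/{self.view}: no resolvable dose "
                "pathway (need esd_mgy, dap_gycm2, or calibration+kvp+fsd_cm+mas)"
            )
        if self.esd_mgy is not None and self._qa_resolvable:
            log.warning(
                "radiograph %s/%s supplies both a measured ESD and QA data; "
                "the measured ESD takes precedence",
                self.projection, self.view,
            )

    @property
    def _qa_resolvable(self) -> bool:
        return (
            self.calibration is not None
            and self.calibration.output_mgy_per_mas is not None
            and self.kvp is not None
            and self.fsd_cm is not None
            and self.mas is not None
        )

    @property
    def pathway(self) -> str | None:
        if self.esd_mgy is not None:
            return "esd"
        if self.dap_gycm2 is not None:
            return "dap"
        if self._qa_resolvable:
            return "qa"
        return None

    def resolve_esd(self) -> float:
        """Measured ESD if present, else Eq.-style QA reconstruction."""
        if self.esd_mgy is not None:
            return float(self.esd_mgy)
        if self._qa_resolvable:
            return esd_radiograph(self.calibration, self)
        raise InputError(
            f"radiograph {self.projection}/{self.view}: no ESD pathway "
            "(record is DAP-only)"
        )


@dataclass(frozen=True)
class ScreeningRecord:
    """One fluoroscopic screening run."""

    projection: str
    view: str
    kvp: float
    fsd_cm: float
    ma: float
    time_min: float
    calibration: QACalibration | None = None

    def __post_init__(self) -> None:
        _positive("kvp", self.kvp)
        _positive("fsd_cm", self.fsd_cm)
        _positive("ma", self.ma)
        _positive("time_min", self.time_min)


@dataclass(frozen=True)
class CTRecord:
    """One CT acquisition in the phantom longitudinal frame (mm)."""

    scanner_model: str
    ctdi_air: float  # mGy per 100 mAs, free-in-air
    mas: float  # mAs per rotation
    pitch: float
    scan_start_mm: float
    scan_end_mm: float

    def __post_init__(self) -> None:
        _positive("ctdi_air", self.ctdi_air)
        _positive("mas", self.mas)
        _positive("pitch", self.pitch)
        if not self.scan_start_mm < self.scan_end_mm:
            raise InputError(
                f"scan_start_mm ({self.scan_start_mm}) must be < scan_end_mm "
                f"({self.scan_end_mm})"
            )


def _geometry_factor(cal: QACalibration, kvp_ex: float, fsd_ex_cm: float) -> float:
    if not fsd_ex_cm > 0:
        raise InputError(f"FSD_EX must be > 0 cm, got {fsd_ex_cm}")
    if not kvp_ex > 0:
        raise InputError(f"kVp_EX must be > 0, got {kvp_ex}")
    if abs(kvp_ex - cal.kvp_qa) > _KVP_WARN_GAP:
        warnings.warn(
            f"kVp_EX {kvp_ex:g} is more than {_KVP_WARN_GAP:g} kV from the QA "
            f"potential {cal.kvp_qa:g}; the quadratic output-scaling rule is a "
            "long extrapolation here",
            stacklevel=3,
        )
    return ((cal.fsd_qa_cm / fsd_ex_cm) * (kvp_ex / cal.kvp_qa)) ** 2


def esd_radiograph(cal: QACalibration, rec: RadiographRecord) -> float:
    """Entrance surface dose (mGy) of a radiograph from QA output data."""
    if cal.output_mgy_per_mas is None:
        raise ConfigurationError("QA calibration has no radiographic output (mGy/mAs)")
    if rec.kvp is None or rec.fsd_cm is None or rec.mas is None:
        raise InputError("radiograph record lacks kvp/fsd_cm/mas for QA reconstruction")
    return _geometry_factor(cal, rec.kvp, rec.fsd_cm) * cal.output_mgy_per_mas * rec.mas


def esd_screening(cal: QACalibration, rec: ScreeningRecord) -> float:
    """Entrance surface dose (mGy) of a screening run from QA output-rate data."""
    if cal.output_rate_mgy_per_min_ma is None:
        raise ConfigurationError(
            "QA calibration has no fluoroscopic output rate (mGy/(min·mA))"
        )
    return (
        _geometry_factor(cal, rec.kvp, rec.fsd_cm)
        * cal.output_rate_mgy_per_min_ma
        * rec.ma
        * rec.time_min
    )


def ctdi_soft_tissue(ctdi_air: float) -> float:
    """Convert free-in-air CTDI to soft-tissue CTDI (× 1.07)."""
    if ctdi_air < 0:
        raise InputError(f"CTDI_air must be >= 0, got {ctdi_air}")
    return ctdi_air * CTDI_SOFT_TISSUE_FACTOR


# ---------------------------------------------------------------------------
# CSV interface

#: Canonical columns of the exposure-record CSV.  The four QA columns are
#: optional and only needed for records resolved through the QA pathway.
EXPOSURE_COLUMNS = [
    "record_type", "projection", "view", "kvp", "fsd_cm", "mas", "ma",
    "time_min", "esd_mgy", "dap_gycm2", "scanner_model", "ctdi_air", "pitch",
    "scan_start_mm", "scan_end_mm", "patient_id", "ga_weeks",
    "fetal_depth_cm", "maternal_ap_cm",
    "kvp_qa", "fsd_qa_cm", "output_mgy_per_mas", "output_rate_mgy_per_min_ma",
]

_RECORD_TYPES = {"radiograph", "screening", "dap", "ct"}


def read_exposure_csv(path) -> pd.DataFrame:
    """Read an exposure-record CSV, checking the schema (not row validity)."""
    df = pd.read_csv(path)
    required = ["record_type", "patient_id", "ga_weeks"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"exposure CSV is missing column(s) {missing}")
    bad = set(df["record_type"].astype(str).str.strip().str.lower()) - _RECORD_TYPES
    if bad:
        raise SchemaError(f"unknown record_type value(s): {sorted(bad)}")
    for col in EXPOSURE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df


def _get(row, col):
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)) or pd.isna(val):
        return None
    return val


def _getf(row, col) -> float | None:
    val = _get(row, col)
    return None if val is None else float(val)


def _row_calibration(row) -> QACalibration | None:
    kvp_qa = _getf(row, "kvp_qa")
    fsd_qa = _getf(row, "fsd_qa_cm")
    if kvp_qa is None or fsd_qa is None:
        return None
    return QACalibration(
        kvp_qa=kvp_qa,
        fsd_qa_cm=fsd_qa,
        output_mgy_per_mas=_getf(row, "output_mgy_per_mas"),
        output_rate_mgy_per_min_ma=_getf(row, "output_rate_mgy_per_min_ma"),
    )


def rows_to_records(df: pd.DataFrame):
    """Yield ``(index, patient_id, context_fields, record)`` per CSV row.

    ``context_fields`` is a dict of ga_weeks / fetal_depth_cm /
    maternal_ap_cm.  Rows that fail their record invariants raise from the
    record constructors; callers wanting reject handling catch per row.
    """
    for index, row in df.iterrows():
        row = row.to_dict()
        rtype = str(row["record_type"]).strip().lower()
        ctx = {
            "ga_weeks": _getf(row, "ga_weeks"),
            "fetal_depth_cm": _getf(row, "fetal_depth_cm"),
            "maternal_ap_cm": _getf(row, "maternal_ap_cm"),
        }
        cal = _row_calibration(row)
        if rtype in ("radiograph", "dap"):
            rec = RadiographRecord(
                projection=str(row["projection"]),
                view=str(row["view"]),
                kvp=_getf(row, "kvp"),
                fsd_cm=_getf(row, "fsd_cm"),
                mas=_getf(row, "mas"),
                esd_mgy=_getf(row, "esd_mgy"),
                dap_gycm2=_getf(row, "dap_gycm2"),
                calibration=cal,
            )
        elif rtype == "screening":
            rec = ScreeningRecord(
                projection=str(row["projection"]),
                view=str(row["view"]),
                kvp=_getf(row, "kvp"),
                fsd_cm=_getf(row, "fsd_cm"),
                ma=_getf(row, "ma"),
                time_min=_getf(row, "time_min"),
                calibration=cal,
            )
        else:  # ct
            rec = CTRecord(
                scanner_model=str(row["scanner_model"]),
                ctdi_air=_getf(row, "ctdi_air"),
                mas=_getf(row, "mas"),
                pitch=_getf(row, "pitch"),
                scan_start_mm=_getf(row, "scan_start_mm"),
                scan_end_mm=_getf(row, "scan_end_mm"),
            )
        yield index, str(row["patient_id"]), ctx, rec
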