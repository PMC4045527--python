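"""Coefficient tables for foetal dosimetry.

Normalized uterus dose (NUD) tables give the uterus dose per unit
free-in-air entrance surface dose (mGy/mGy) or per unit dose-area product
(mGy per Gy·cm²), indexed by projection, beam-quality (kVp) band and mean
foetal depth.  CT tables give the normalized uterus dose contribution of
each contiguous 5 mm slab of a reference adult phantom (208 slabs,
1040 mm), per mGy of soft-tissue CTDI per 100 mAs.  A foetal size-factor
table converts uterus dose to foetal dose as a function of gestational age.

The real NUD compilations are licensed publications distributed in print
or inside closed software, so this module also ships a deterministic
synthetic-table generator producing physically plausible tables in the
package's open CSV dialect; every downstream module is testable against
those fixtures.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RangeError, SchemaError, TableValidationError, UnknownKeyError

__all__ = [
    "N_SLABS",
    "SLAB_THICKNESS_MM",
    "PHANTOM_LENGTH_MM",
    "DEFAULT_FETAL_DEPTH_CM",
    "DEFAULT_MATERNAL_AP_CM",
    "BeamQualityBand",
    "NUDTable",
    "CTScannerSlabTable",
    "SizeFactorTable",
    "PatientContext",
    "CoefficientStore",
    "load_tables",
    "loads_tables",
    "nud_at_depth",
    "slab_sum",
    "size_factor",
    "generate_fixture_tables",
]

N_SLABS = 208
SLAB_THICKNESS_MM = 5.0
PHANTOM_LENGTH_MM = N_SLABS * SLAB_THICKNESS_MM  # 1040 mm

# Population averages used when the patient record does not supply them.
DEFAULT_FETAL_DEPTH_CM = 9.0
DEFAULT_MATERNAL_AP_CM = 25.0

#: Required columns of the coefficient CSV dialect, by table_type.
_SECTION_COLUMNS = {
    "nud_esd": ["projection", "view", "kvp_min", "kvp_max", "depth_cm", "nud"],
    "nud_dap": ["projection", "view", "kvp_min", "kvp_max", "depth_cm", "nud"],
    "ct_slab": ["scanner_model", "slab_index", "nud"],
    "size_factor": ["ga_weeks", "sf"],
}


def _interp_clamped(x: float, xp: np.ndarray, fp: np.ndarray, what: str) -> float:
    """Piecewise-linear interpolation, clamping (with a warning) outside the grid."""
    if xp.size == 0:
        raise UnknownKeyError(f"empty {what} table")
    if x < xp[0] or x > xp[-1]:
        warnings.warn(
            f"{what} {x:g} outside tabulated grid [{xp[0]:g}, {xp[-1]:g}]; "
            "clamping to the nearest endpoint",
            stacklevel=3,
        )
        x = min(max(x, xp[0]), xp[-1])
    return float(np.interp(x, xp, fp))


@dataclass(frozen=True)
class BeamQualityBand:
    """One beam-quality band of a NUD table: a depth→NUD polyline valid for
    tube potentials in [kvp_min, kvp_max]."""

    kvp_min: float
    kvp_max: float
    depths_cm: np.ndarray
    nud: np.ndarray

    def nud_at_depth(self, depth_cm: float) -> float:
        return _interp_clamped(depth_cm, self.depths_cm, self.nud, "foetal depth (cm)")


@dataclass(frozen=True)
class NUDTable:
    """Normalized uterus dose for one projection key.

    ``quantity`` is ``"esd"`` (mGy uterus dose per mGy entrance surface
    dose) or ``"dap"`` (mGy per Gy·cm²).
    """

    projection: str
    view: str
    quantity: str  # "esd" | "dap"
    bands: tuple[BeamQualityBand, ...]

    @property
    def key(self) -> tuple[str, str]:
        return (self.projection, self.view)

    def band_for(self, kvp: float | None) -> BeamQualityBand:
        """Select the beam-quality band whose kVp interval contains ``kvp``.

        Ties on a shared band edge resolve to the lower band.  With no kVp
        given (or a kVp outside every band) the nearest band is used with a
        warning.
        """
        if not self.bands:
            raise UnknownKeyError(f"NUD table {self.projection}/{self.view} has no bands")
        if kvp is None:
            if len(self.bands) > 1:
                warnings.warn(
                    f"no kVp given for {self.projection}/{self.view}; "
                    "using the lowest beam-quality band",
                    stacklevel=2,
                )
            return self.bands[0]
        for band in self.bands:  # bands sorted ascending; lower band wins ties
            if band.kvp_min <= kvp <= band.kvp_max:
                return band
        nearest = min(
            self.bands,
            key=lambda b: min(abs(kvp - b.kvp_min), abs(kvp - b.kvp_max)),
        )
        warnings.warn(
            f"kVp {kvp:g} outside every beam-quality band of "
            f"{self.projection}/{self.view}; using band "
            f"[{nearest.kvp_min:g}, {nearest.kvp_max:g}]",
            stacklevel=2,
        )
        return nearest

    def nud_at_depth(self, depth_cm: float, kvp: float | None = None) -> float:
        return self.band_for(kvp).nud_at_depth(depth_cm)


@dataclass(frozen=True)
class CTScannerSlabTable:
    """Per-slab normalized uterus dose for one scanner model.

    Exactly 208 entries; slab ``i`` spans [5i, 5(i+1)) mm from the phantom
    origin (slab 0's lower edge, increasing toward the head).  Units:
    mGy uterus dose per mGy soft-tissue CTDI per 100 mAs.
    """

    scanner_model: str
    slab_nud: np.ndarray

    def slab_midpoints_mm(self) -> np.ndarray:
        return (np.arange(N_SLABS) + 0.5) * SLAB_THICKNESS_MM

    def slab_sum(self, scan_start_mm: float, scan_end_mm: float) -> float:
        """Sum of per-slab NUD over slabs whose midpoint lies in
        [scan_start_mm, scan_end_mm)."""
        if not scan_start_mm < scan_end_mm:
            raise RangeError(
                f"inverted scan range [{scan_start_mm:g}, {scan_end_mm:g}] mm"
            )
        if scan_start_mm < 0 or scan_end_mm > PHANTOM_LENGTH_MM:
            raise RangeError(
                f"scan range [{scan_start_mm:g}, {scan_end_mm:g}] mm outside "
                f"the phantom [0, {PHANTOM_LENGTH_MM:g}] mm"
            )
        mid = self.slab_midpoints_mm()
        mask = (mid >= scan_start_mm) & (mid < scan_end_mm)
        if not mask.any():
            warnings.warn(
                f"scan range [{scan_start_mm:g}, {scan_end_mm:g}] mm contains "
                "no slab midpoint; NUD_V = 0",
                stacklevel=2,
            )
            return 0.0
        return float(self.slab_nud[mask].sum())


@dataclass(frozen=True)
class SizeFactorTable:
    """Uterus-to-foetus dose conversion factor vs gestational age (weeks)."""

    ga_weeks: np.ndarray
    sf: np.ndarray

    def size_factor(self, ga_weeks: float) -> float:
        return _interp_clamped(ga_weeks, self.ga_weeks, self.sf, "gestational age (weeks)")


@dataclass(frozen=True)
class PatientContext:
    """Gestational age plus optional foetal depth and maternal AP thickness.

    Missing depth/thickness fall back to the documented population
    averages (9 cm and 25 cm)."""

    ga_weeks: float
    fetal_depth_cm: float | None = None
    maternal_ap_cm: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ga_weeks <= 45:
            raise TableValidationError(
                f"gestational age {self.ga_weeks} weeks outside (0, 45]"
            )
        ap = self.maternal_ap_cm if self.maternal_ap_cm is not None else DEFAULT_MATERNAL_AP_CM
        if self.fetal_depth_cm is not None and not 0 < self.fetal_depth_cm < ap:
            raise TableValidationError(
                f"foetal depth {self.fetal_depth_cm} cm not in (0, {ap} cm)"
            )

    @property
    def resolved_depth_cm(self) -> float:
        if self.fetal_depth_cm is None:
            return DEFAULT_FETAL_DEPTH_CM
        return self.fetal_depth_cm


@dataclass
class CoefficientStore:
    """All coefficient tables needed by the dose engine."""

    nud_esd: dict[tuple[str, str], NUDTable] = field(default_factory=dict)
    nud_dap: dict[tuple[str, str], NUDTable] = field(default_factory=dict)
    ct_slab: dict[str, CTScannerSlabTable] = field(default_factory=dict)
    size_factors: SizeFactorTable | None = None

    def _nud(self, kind: str, projection: str, view: str) -> NUDTable:
        tables = self.nud_esd if kind == "esd" else self.nud_dap
        key = (_norm(projection), _norm(view))
        try:
            return tables[key]
        except KeyError:
            raise UnknownKeyError(
                f"no {kind.upper()}-normalized uterus dose table for "
                f"projection {projection!r}/{view!r}"
            ) from None

    def nud_esd_table(self, projection: str, view: str) -> NUDTable:
        return self._nud("esd", projection, view)

    def nud_dap_table(self, projection: str, view: str) -> NUDTable:
        return self._nud("dap", projection, view)

    def ct_table(self, scanner_model: str) -> CTScannerSlabTable:
        try:
            return self.ct_slab[_norm(scanner_model)]
        except KeyError:
            raise UnknownKeyError(f"no CT slab table for scanner model {scanner_model!r}") from None

    def size_factor(self, ga_weeks: float) -> float:
        """SF for a gestational age; 1.0 with a warning when no table is loaded."""
        if self.size_factors is None:
            warnings.warn(
                "no foetal size-factor table loaded; using SF = 1.0 "
                "(foetal dose taken equal to uterus dose)",
                stacklevel=2,
            )
            return 1.0
        return self.size_factors.size_factor(ga_weeks)


def _norm(s: str) -> str:
    return str(s).strip().lower()


# ---------------------------------------------------------------------------
# Loading and validation


def _require_columns(df: pd.DataFrame, cols: list[str], table_type: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"coefficient file is missing column(s) {missing} required for "
            f"table_type={table_type!r}"
        )


def _validate_nud_group(
    projection: str, view: str, band_df: pd.DataFrame, quantity: str
) -> BeamQualityBand:
    rows = band_df["__row__"].tolist()
    depths = band_df["depth_cm"].to_numpy(dtype=float)
    nud = band_df["nud"].to_numpy(dtype=float)
    key = f"{projection}/{view}"
    if np.any(~np.isfinite(depths)) or np.any(~np.isfinite(nud)):
        raise TableValidationError(
            f"non-numeric depth/NUD for projection {key} (rows {rows})"
        )
    if not np.all(np.diff(depths) > 0):
        raise TableValidationError(
            f"foetal depths not strictly increasing for projection {key} (rows {rows})"
        )
    if not np.all(nud > 0):
        raise TableValidationError(
            f"non-positive NUD value for projection {key} (rows {rows})"
        )
    if not np.all(np.diff(nud) <= 0):
        raise TableValidationError(
            f"NUD must be non-increasing with foetal depth for projection {key} "
            f"(rows {rows})"
        )
    kvp_min = float(band_df["kvp_min"].iloc[0])
    kvp_max = float(band_df["kvp_max"].iloc[0])
    if not kvp_min < kvp_max:
        raise TableValidationError(
            f"empty kVp band [{kvp_min}, {kvp_max}] for projection {key} (rows {rows})"
        )
    return BeamQualityBand(kvp_min, kvp_max, depths, nud)


def _load_nud_section(df: pd.DataFrame, quantity: str) -> dict[tuple[str, str], NUDTable]:
    table_type = f"nud_{quantity}"
    _require_columns(df, _SECTION_COLUMNS[table_type], table_type)
    out: dict[tuple[str, str], NUDTable] = {}
    for (projection, view), proj_df in df.groupby(
        [df["projection"].map(_norm), df["view"].map(_norm)], sort=True
    ):
        bands = []
        # validate in file order: a grid stored out of order is an error,
        # not something to silently re-sort
        for _band_key, band_df in proj_df.groupby(["kvp_min", "kvp_max"], sort=True):
            bands.append(_validate_nud_group(projection, view, band_df, quantity))
        bands.sort(key=lambda b: (b.kvp_min, b.kvp_max))
        out[(projection, view)] = NUDTable(projection, view, quantity, tuple(bands))
    return out


def _load_ct_section(df: pd.DataFrame) -> dict[str, CTScannerSlabTable]:
    _require_columns(df, _SECTION_COLUMNS["ct_slab"], "ct_slab")
    out: dict[str, CTScannerSlabTable] = {}
    for model, model_df in df.groupby(df["scanner_model"].map(_norm), sort=True):
        rows = model_df["__row__"].tolist()
        idx = model_df["slab_index"].to_numpy(dtype=float)
        nud = model_df["nud"].to_numpy(dtype=float)
        if len(model_df) != N_SLABS:
            raise TableValidationError(
                f"scanner {model!r}: expected {N_SLABS} slabs, got {len(model_df)} "
                f"(rows {rows[0]}..{rows[-1]})"
            )
        order = np.argsort(idx, kind="stable")
        idx, nud = idx[order], nud[order]
        if not np.array_equal(idx, np.arange(N_SLABS)):
            raise TableValidationError(
                f"scanner {model!r}: slab_index must be exactly 0..{N_SLABS - 1}"
            )
        if np.any(nud < 0) or np.any(~np.isfinite(nud)):
            raise TableValidationError(
                f"scanner {model!r}: slab NUD values must be finite and >= 0"
            )
        if not _is_unimodal_or_flat(nud):
            warnings.warn(
                f"scanner {model!r}: slab profile is not unimodal; check the table",
                stacklevel=4,
            )
        out[str(model)] = CTScannerSlabTable(str(model), nud)
    return out


def _is_unimodal_or_flat(values: np.ndarray, rtol: float = 1e-9) -> bool:
    d = np.diff(values)
    tol = rtol * max(float(np.abs(values).max()), 1.0)
    signs = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    signs = signs[signs != 0]
    if signs.size == 0:
        return True
    # at most one rise→fall transition and no fall→rise
    transitions = np.diff(signs)
    return not np.any(transitions > 0)


def _load_sf_section(df: pd.DataFrame) -> SizeFactorTable:
    _require_columns(df, _SECTION_COLUMNS["size_factor"], "size_factor")
    rows = df["__row__"].tolist()
    ga = df["ga_weeks"].to_numpy(dtype=float)
    sf = df["sf"].to_numpy(dtype=float)
    if not np.all(np.diff(ga) > 0):
        raise TableValidationError(
            f"size-factor gestational ages not strictly increasing (rows {rows})"
        )
    if not np.all(sf > 0):
        raise TableValidationError(f"size factors must be > 0 (rows {rows})")
    if ga[0] > 2 or ga[-1] < 38:
        raise TableValidationError(
            f"size-factor table spans [{ga[0]:g}, {ga[-1]:g}] weeks; must cover "
            "at least 2–38 weeks"
        )
    return SizeFactorTable(ga, sf)


def loads_tables(text: str) -> CoefficientStore:
    """Parse a coefficient file from a string; see :func:`load_tables`."""
    return _build_store(pd.read_csv(io.StringIO(text)))


def load_tables(path) -> CoefficientStore:
    """Read and validate a coefficient CSV file.

    The file carries all four table kinds distinguished by the
    ``table_type`` column (``nud_esd``, ``nud_dap``, ``ct_slab``,
    ``size_factor``).  Invariant violations raise
    :class:`TableValidationError` naming the offending projection/scanner
    and 1-based data row numbers; missing columns raise
    :class:`SchemaError`.
    """
    return _build_store(pd.read_csv(path))


def _build_store(df: pd.DataFrame) -> CoefficientStore:
    if "table_type" not in df.columns:
        raise SchemaError("coefficient file has no 'table_type' column")
    df = df.copy()
    df["__row__"] = np.arange(1, len(df) + 1)  # 1-based data row numbers
    unknown = set(df["table_type"].map(_norm)) - set(_SECTION_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown table_type value(s): {sorted(unknown)}")
    store = CoefficientStore()
    by_type = dict(tuple(df.groupby(df["table_type"].map(_norm))))
    if "nud_esd" in by_type:
        store.nud_esd = _load_nud_section(by_type["nud_esd"], "esd")
    if "nud_dap" in by_type:
        store.nud_dap = _load_nud_section(by_type["nud_dap"], "dap")
    if "ct_slab" in by_type:
        store.ct_slab = _load_ct_section(by_type["ct_slab"])
    if "size_factor" in by_type:
        store.size_factors = _load_sf_section(by_type["size_factor"])
    return store


# ---------------------------------------------------------------------------
# Functional wrappers (operation surface)


def nud_at_depth(table: NUDTable, depth_cm: float, kvp: float | None = None) -> float:
    """Normalized uterus dose at a mean foetal depth.

    Exact at grid depths, piecewise-linear between them; depths outside the
    grid clamp to the nearest endpoint with a warning.
    """
    return table.nud_at_depth(depth_cm, kvp)


def slab_sum(table: CTScannerSlabTable, scan_start_mm: float, scan_end_mm: float) -> float:
    """NUD_V: sum of per-slab normalized doses over the scan volume.

    A slab belongs to the scan volume iff its midpoint lies in
    [scan_start_mm, scan_end_mm), which makes the sum additive over
    abutting ranges.
    """
    return table.slab_sum(scan_start_mm, scan_end_mm)


def size_factor(table: SizeFactorTable, ga_weeks: float) -> float:
    """Foetal size factor at a gestational age (piecewise-linear, clamped)."""
    return table.size_factor(ga_weeks)


# ---------------------------------------------------------------------------
# Synthetic fixture tables

#: Projection keys the fixture generator draws from, roughly the common
#: abdominal/pelvic/chest examinations a foetal-dose service sees.
CANONICAL_PROJECTIONS: tuple[tuple[str, str], ...] = (
    ("abdomen", "ap"),
    ("pelvis", "ap"),
    ("lumbar spine", "ap"),
    ("lumbar spine", "lat"),
    ("chest", "pa"),
    ("chest", "ap"),
    ("thoracic spine", "ap"),
    ("stomach", "ap"),
    ("colon", "pa"),
    ("hip joint", "ap"),
    ("urinary bladder", "ap"),
    ("kub", "ap"),
)

CANONICAL_SCANNERS: tuple[str, ...] = (
    "scanner-a", "scanner-b", "scanner-c", "scanner-d", "scanner-e",
)

_FIXTURE_DEPTH_GRID = np.arange(4.0, 13.0, 1.0)  # cm, covers clinical 4.9–9.3
_FIXTURE_KVP_BANDS = ((55.0, 75.0), (75.0, 95.0), (95.0, 125.0))


def generate_fixture_tables(
    seed: int,
    n_projections: int = 6,
    n_scanners: int = 2,
    uterus_center_mm: float = 320.0,
    path=None,
) -> str:
    """Emit a synthetic coefficient CSV (deterministic for a given seed).

    The tables are synthetic stand-ins with realistic magnitudes and the
    correct qualitative structure: NUD decays roughly exponentially with
    foetal depth, grows with beam quality, and stays within [1e-5, 1] per
    mGy ESD; CT slab profiles are non-negative and unimodal, peaking at
    ``uterus_center_mm``.  Returns the CSV text; also writes it to ``path``
    when given.
    """
    if n_projections < 1 or n_scanners < 1:
        raise ValueError("n_projections and n_scanners must be >= 1")
    if n_projections > len(CANONICAL_PROJECTIONS):
        raise ValueError(f"at most {len(CANONICAL_PROJECTIONS)} projections available")
    if n_scanners > len(CANONICAL_SCANNERS):
        raise ValueError(f"at most {len(CANONICAL_SCANNERS)} scanner models available")
    rng = np.random.default_rng(seed)
    lines = [
        "table_type,projection,view,kvp_min,kvp_max,depth_cm,nud,"
        "scanner_model,slab_index,ga_weeks,sf"
    ]

    def num(x: float) -> str:
        return format(float(x), ".6g")

    for projection, view in CANONICAL_PROJECTIONS[:n_projections]:
        # deeper-lying beams attenuate; chest-type projections barely reach
        # the uterus at all
        remote = projection in ("chest", "thoracic spine")
        base = rng.uniform(1e-4, 1e-3) if remote else rng.uniform(0.05, 0.6)
        mu = rng.uniform(0.15, 0.30)  # per cm
        dap_base = base * rng.uniform(0.5, 5.0)  # mGy per Gy·cm²
        for kvp_min, kvp_max in _FIXTURE_KVP_BANDS:
            quality = 1.0 + 0.006 * (0.5 * (kvp_min + kvp_max) - 65.0)
            esd_vals = np.clip(base * quality * np.exp(-mu * _FIXTURE_DEPTH_GRID), 1e-5, 1.0)
            dap_vals = dap_base * quality * np.exp(-mu * _FIXTURE_DEPTH_GRID)
            for kind, vals in (("nud_esd", esd_vals), ("nud_dap", dap_vals)):
                for d, v in zip(_FIXTURE_DEPTH_GRID, vals):
                    lines.append(
                        f"{kind},{projection},{view},{num(kvp_min)},{num(kvp_max)},"
                        f"{num(d)},{num(v)},,,,"
                    )

    mid = (np.arange(N_SLABS) + 0.5) * SLAB_THICKNESS_MM
    for model in CANONICAL_SCANNERS[:n_scanners]:
        # per-slab values sized so the whole-profile sum is ~0.2–1
        # mGy/mGy, matching uterus doses of a few to ~20 mGy for typical
        # abdominal helical technique
        peak = rng.uniform(0.005, 0.02)  # mGy per mGy CTDI_soft per 100 mAs
        sigma = rng.uniform(60.0, 110.0)  # mm
        profile = peak * np.exp(-0.5 * ((mid - uterus_center_mm) / sigma) ** 2)
        for i, v in enumerate(profile):
            lines.append(f"ct_slab,,,,,,{num(v)},{model},{i},,")

    ga_grid = np.arange(2.0, 42.0, 2.0)
    # uterus-to-foetus conversion drifts smoothly away from 1 as the foetus
    # grows and fills the uterus
    slope = rng.uniform(-0.008, -0.002)
    sf_vals = np.clip(1.05 + slope * (ga_grid - 2.0) + rng.normal(0, 0.005, ga_grid.size), 0.5, 1.5)
    for ga, sf in zip(ga_grid, sf_vals):
        lines.append(f"size_factor,,,,,,,,,{num(ga)},{num(sf)}")

    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    return text
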