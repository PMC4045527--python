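"""Stochastic-risk conversion and risk communication.

Risk is linear in dose with no threshold (LNT): R = D_f · RC, with default
coefficients per mGy of foetal absorbed dose

    childhood cancer            8.0 × 10⁻⁵
    hereditary effects          0.5 × 10⁻⁵
    IQ decline                  25 × 10⁻³ IQ points (not a probability)
    severe mental retardation   43 × 10⁻⁵

Risks are communicated four ways: as a probability, as the complementary
"safety" probability, as an equivalent number of chest radiographs, and as
an equivalent period of natural background exposure.  Probabilities are
rendered as "1 in N" strings: the risk is rounded to one significant
figure d × 10^e (decimal half-up) and N is the reciprocal rounded to the
conventional communication values, i.e. N = m(d) × 10⁻ᵉ with

    m = {1: 1, 2: 0.5, 3: 0.33, 4: 0.25, 5: 0.2,
         6: 0.17, 7: 0.14, 8: 0.125, 9: 0.11}

so 2 × 10⁻³ → "1 in 500" and 8 × 10⁻⁵ → "1 in 12500" (generic two-figure
rounding would give 13000 instead).

Deterministic effects (death, malformation, growth/mental retardation)
have a dose threshold of about 100 mGy for the foetus; reports carry an
advisory flag once the total dose reaches it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import yaml

from .errors import InputError

__all__ = [
    "ENDPOINTS",
    "PROBABILITY_ENDPOINTS",
    "DETERMINISTIC_THRESHOLD_MGY",
    "RiskCoefficients",
    "ReferenceValues",
    "EndpointRisk",
    "RiskReport",
    "risk",
    "round_risk_one_sig_fig",
    "format_one_in_n",
    "parse_one_in_n",
    "risk_range",
    "consequence_report",
    "load_config",
]

#: Endpoints whose R = D·RC is a probability.
PROBABILITY_ENDPOINTS = ("childhood_cancer", "hereditary", "severe_mental_retardation")
#: All endpoints; iq_decline yields IQ points lost, not a probability.
ENDPOINTS = PROBABILITY_ENDPOINTS + ("iq_decline",)

#: Foetal dose threshold (mGy) below which no deterministic effect of
#: practical significance is expected.
DETERMINISTIC_THRESHOLD_MGY = 100.0

_ALIASES = {
    "cancer": "childhood_cancer",
    "childhood_cancer": "childhood_cancer",
    "hereditary": "hereditary",
    "smr": "severe_mental_retardation",
    "severe_mental_retardation": "severe_mental_retardation",
    "iq": "iq_decline",
    "iq_decline": "iq_decline",
}


@dataclass(frozen=True)
class RiskCoefficients:
    """Per-mGy risk coefficients; override any field via config."""

    childhood_cancer: float = 8.0e-5
    hereditary: float = 0.5e-5
    iq_decline: float = 25e-3  # IQ points per mGy
    severe_mental_retardation: float = 43e-5

    def __post_init__(self) -> None:
        for name in ENDPOINTS:
            if getattr(self, name) < 0:
                raise InputError(f"risk coefficient {name} must be >= 0")

    def for_endpoint(self, endpoint: str) -> float:
        return getattr(self, canonical_endpoint(endpoint))


@dataclass(frozen=True)
class ReferenceValues:
    """Reference doses used by the comparative presentations.

    ``chest_dose_mgy``: mean foetal dose of one AP chest radiograph.
    ``background_mgy_per_year``: annual natural background dose.
    """

    chest_dose_mgy: float = 0.001
    background_mgy_per_year: float = 2.4


def canonical_endpoint(endpoint: str) -> str:
    try:
        return _ALIASES[endpoint.strip().lower()]
    except KeyError:
        raise InputError(
            f"unknown endpoint {endpoint!r}; expected one of {sorted(set(_ALIASES))}"
        ) from None


def risk(dose_mgy: float, endpoint: str, coeffs: RiskCoefficients | None = None) -> float:
    """R = D_f · RC.  For ``iq_decline`` the value is IQ points lost."""
    if dose_mgy < 0:
        raise InputError(f"dose must be >= 0 mGy, got {dose_mgy}")
    coeffs = coeffs or RiskCoefficients()
    return dose_mgy * coeffs.for_endpoint(endpoint)


def round_risk_one_sig_fig(value: float) -> tuple[int, int]:
    """Round to one significant figure, returning (digit, exponent).

    Decimal half-up on the shortest round-trip representation, so
    2.5 × 10⁻⁷ rounds to (3, -7) even when the float sits a hair off the
    exact half.
    """
    if value <= 0:
        raise InputError(f"need a positive value, got {value}")
    d = Decimal(repr(float(value)))
    exp = d.adjusted()
    digit = int(d.scaleb(-exp).quantize(Decimal(1), rounding=ROUND_HALF_UP))
    if digit == 10:
        digit, exp = 1, exp + 1
    return digit, exp

# reciprocal of each leading digit at communication precision; this map —
# not generic rounding of 1/risk — is what yields denominators like 12500
_RECIPROCAL_MANTISSA = {
    1: Decimal("1"), 2: Decimal("0.5"), 3: Decimal("0.33"),
    4: Decimal("0.25"), 5: Decimal("0.2"), 6: Decimal("0.17"),
    7: Decimal("0.14"), 8: Decimal("0.125"), 9: Decimal("0.11"),
}

#: Risks below this render as a negligible-risk sentinel.
NEGLIGIBLE_RISK = 1e-9


def one_in_n_denominator(risk_value: float) -> int:
    """Denominator N of the "1 in N" rendering of a probability."""
    digit, exp = round_risk_one_sig_fig(risk_value)
    n = _RECIPROCAL_MANTISSA[digit].scaleb(-exp)
    return int(n.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def format_one_in_n(risk_value: float, negligible_below: float = NEGLIGIBLE_RISK) -> str:
    """Render a probability as a "1 in N" string.

    Zero (or sub-threshold) risks return a negligible-risk sentinel rather
    than an unbounded denominator.
    """
    if risk_value < 0 or risk_value > 1:
        raise InputError(f"risk must lie in [0, 1], got {risk_value}")
    if risk_value < negligible_below:
        return f"negligible (< 1 in {int(round(1 / negligible_below))})"
    return f"1 in {one_in_n_denominator(risk_value)}"


_ONE_IN_N = re.compile(r"^\s*<?\s*1\s+in\s+([0-9]+)\s*$")


def parse_one_in_n(text: str) -> float:
    """Parse "1 in N" back to the probability 1/N."""
    m = _ONE_IN_N.match(text)
    if not m:
        raise InputError(f"cannot parse {text!r} as a '1 in N' risk string")
    return 1.0 / int(m.group(1))


def risk_range(
    dose_lo_mgy: float,
    dose_hi_mgy: float,
    endpoint: str,
    coeffs: RiskCoefficients | None = None,
) -> str:
    """Format the risk range of a dose interval as "1 in N_lo–1 in N_hi"."""
    if dose_lo_mgy > dose_hi_mgy:
        raise InputError("dose_lo_mgy must be <= dose_hi_mgy")
    lo = format_one_in_n(risk(dose_lo_mgy, endpoint, coeffs))
    hi = format_one_in_n(risk(dose_hi_mgy, endpoint, coeffs))
    if lo == hi:
        return lo
    return f"{lo}–{hi}"


@dataclass(frozen=True)
class EndpointRisk:
    """One endpoint's risk in all its presentations."""

    endpoint: str
    raw: float
    rounded: float | None  # 1-sf probability (None for zero risk)
    one_in_n: str | None  # None for the non-probability IQ endpoint
    safety: float | None  # 1 - risk


@dataclass(frozen=True)
class RiskReport:
    """The consequence report for one foetal absorbed dose."""

    dose_mgy: float
    endpoints: dict[str, EndpointRisk]
    chest_xray_equivalents: float
    background_period_years: float
    background_period: str
    deterministic_advisory: bool
    references: ReferenceValues = field(default_factory=ReferenceValues)


def _format_period(years: float) -> str:
    if years >= 1.0:
        return f"{years:.1f} years"
    weeks = years * 52.18
    if weeks >= 1.0:
        return f"{weeks:.1f} weeks"
    return f"{years * 365.25:.1f} days"


def consequence_report(
    dose_mgy: float,
    coeffs: RiskCoefficients | None = None,
    refs: ReferenceValues | None = None,
) -> RiskReport:
    """Full consequence report: risk, safety, chest-radiograph and
    natural-background equivalents, plus the deterministic advisory flag
    (set when the dose reaches 100 mGy)."""
    if dose_mgy < 0:
        raise InputError(f"dose must be >= 0 mGy, got {dose_mgy}")
    coeffs = coeffs or RiskCoefficients()
    refs = refs or ReferenceValues()
    endpoints: dict[str, EndpointRisk] = {}
    for ep in ENDPOINTS:
        raw = risk(dose_mgy, ep, coeffs)
        if ep == "iq_decline":
            endpoints[ep] = EndpointRisk(ep, raw, None, None, None)
            continue
        if raw == 0:
            endpoints[ep] = EndpointRisk(ep, 0.0, None, format_one_in_n(0.0), 1.0)
            continue
        digit, exp = round_risk_one_sig_fig(raw)
        endpoints[ep] = EndpointRisk(
            ep, raw, digit * 10.0 ** exp, format_one_in_n(raw), 1.0 - raw
        )
    years = dose_mgy / refs.background_mgy_per_year
    return RiskReport(
        dose_mgy=dose_mgy,
        endpoints=endpoints,
        chest_xray_equivalents=dose_mgy / refs.chest_dose_mgy,
        background_period_years=years,
        background_period=_format_period(years),
        deterministic_advisory=dose_mgy >= DETERMINISTIC_THRESHOLD_MGY,
        references=refs,
    )


def load_config(path) -> tuple[RiskCoefficients, ReferenceValues]:
    """Read risk coefficients and reference values from a YAML file.

    Keys: ``risk_coefficients.<endpoint>`` and
    ``references.chest_dose_mgy`` / ``references.background_mgy_per_year``;
    anything omitted keeps its default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    coeffs = RiskCoefficients()
    for key, val in (data.get("risk_coefficients") or {}).items():
        coeffs = replace(coeffs, **{canonical_endpoint(key): float(val)})
    refs = ReferenceValues()
    ref_data = data.get("references") or {}
    refs = replace(
        refs,
        chest_dose_mgy=float(ref_data.get("chest_dose_mgy", refs.chest_dose_mgy)),
        background_mgy_per_year=float(
            ref_data.get("background_mgy_per_year", refs.background_mgy_per_year)
        ),
    )
    return coeffs, refs
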