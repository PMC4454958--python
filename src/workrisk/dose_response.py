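"""Worker-adjusted toxicity reference values.

Two derivation chains, both starting from a published point of departure
(POD) of an animal study:

**Carcinogenic.** An oral cancer slope factor SF (per mg/kg-day, from
benchmark-dose modelling) is converted to an inhalation unit risk
``IUR = SF * IR / BW`` using the general-population reference profile
(inhalation rate IR = 20 m3/day, body weight BW = 70 kg), then rescaled to
worker exposure conditions by the correction factor

    CF = (IR_ref / IR_worker) * (days_ref / days_worker)
         * (years_ref / years_worker)

giving the workplace unit risk ``UR_work = IUR / CF``. With the default
profiles (worker: 10 m3 per working day, 260 days/year, 40 years) the
factor is (20/10) * (365/260) * (70/40) = 4.9.

**Non-carcinogenic.** For each endpoint, the POD (BMDL, NOAEL or LOAEL) is
expressed as an air concentration (route-to-route extrapolation for oral
PODs), multiplied by the quantitative corrections (duration adjustment
NOAEL_ADJ, human-equivalent-concentration adjustment NOAEL_HEC) and
divided by the chain of uncertainty factors — interspecies, intraspecies,
study duration, effect severity, data quality — prescribed by the selected
agency schema (KOSHA, EPA, ECHA, MHLW), yielding the workplace reference
concentration RfC_work in mg/m3.

**Staged rounding.** Published derivations round each intermediate (IUR,
CF, UR_work, RfC_work) to its printed precision before using it
downstream; this module reproduces that convention (round-half-up; 2
significant figures for risks, 2 decimals for reference concentrations)
so reported chains agree digit-for-digit with the published tables, while
every result object also retains the unrounded value for auditing.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import floor, log10

__all__ = [
    "WorkerProfile",
    "ReferenceProfile",
    "PodType",
    "Route",
    "Endpoint",
    "PointOfDeparture",
    "CorrectionSchema",
    "UnitRiskResult",
    "RfCResult",
    "AGENCY_SCHEMAS",
    "DEFAULT_DURATION_BANDS",
    "round_half_up",
    "round_sig",
    "worker_correction_factor",
    "iur_from_slope_factor",
    "unit_risk_work",
    "derive_unit_risk",
    "duration_factor",
    "severity_factor",
    "route_to_route",
    "rfc_work",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# rounding helpers (round-half-up, matching published-table conventions)

def round_half_up(x: float, decimals: int = 0) -> float:
    """Round to ``decimals`` decimal places with ties away from zero
    (0.005 -> 0.01), the convention of published reference-value tables,
    unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half up."""
    if x == 0:
        return 0.0
    if sig < 1:
        raise ValueError("sig must be >= 1")
    exponent = floor(log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


# --------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class WorkerProfile:
    """Exposure pattern of the worker population being protected.

    Defaults: 10 m3 inhaled per working day (light work, 8 h), 260 working
    days/year, a 40-year working life, 60 kg body weight.
    """

    inhalation_volume: float = 10.0   # m3 per working day
    exposure_days: float = 260.0      # days/year
    exposure_years: float = 40.0      # years
    body_weight: float = 60.0         # kg

    def __post_init__(self) -> None:
        _check_profile(self)


@dataclass(frozen=True)
class ReferenceProfile:
    """General-population profile under which published unit risks are
    expressed: 20 m3/day inhalation (IR), continuous 365 days/year,
    70-year lifetime, 70 kg body weight (BW)."""

    inhalation_volume: float = 20.0
    exposure_days: float = 365.0
    exposure_years: float = 70.0
    body_weight: float = 70.0

    def __post_init__(self) -> None:
        _check_profile(self)


def _check_profile(p) -> None:
    for f in ("inhalation_volume", "exposure_days", "exposure_years",
              "body_weight"):
        if getattr(p, f) <= 0:
            raise ValueError(f"{f} must be positive, got {getattr(p, f)}")
    if p.exposure_days > 365:
        raise ValueError(f"exposure_days must be <= 365, got {p.exposure_days}")


# --------------------------------------------------------------------------
# points of departure

class PodType(enum.Enum):
    BMDL = "BMDL"     # lower 95% confidence limit of the benchmark dose
    NOAEL = "NOAEL"   # no observed adverse effect level
    LOAEL = "LOAEL"   # lowest observed adverse effect level


class Route(enum.Enum):
    ORAL = "oral"             # POD in mg/kg-day
    INHALATION = "inhalation"  # POD in mg/m3


class Endpoint(enum.Enum):
    CARCINOGENIC = "carcinogenic"
    ORAL_STO = "oral_sto"               # specific target organ, oral
    INHALATION_STO = "inhalation_sto"   # specific target organ, inhalation
    REPRODUCTIVE = "reproductive"


@dataclass(frozen=True)
class PointOfDeparture:
    """A published POD: value (mg/kg-day for oral, mg/m3 for inhalation),
    its type, route, study species and study duration."""

    value: float
    pod_type: PodType
    route: Route
    endpoint: Endpoint
    species: str = ""
    study_duration_weeks: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("POD value must be positive")
        if self.study_duration_weeks <= 0:
            raise ValueError("study_duration_weeks must be positive")


# --------------------------------------------------------------------------
# agency correction schemas

#: Study-duration bands -> duration uncertainty factor, longest band wins.
#: Chronic (>= 6 months = 26 weeks): 1; subchronic (>= 13 weeks): 2;
#: short-term (>= 4 weeks): 6. Studies under 4 weeks are unsupported.
DEFAULT_DURATION_BANDS: tuple[tuple[float, float], ...] = (
    (26.0, 1.0),
    (13.0, 2.0),
    (4.0, 6.0),
)

#: Effect-severity factor by POD type: benchmark-dose and no-effect PODs
#: need no adjustment; a LOAEL is divided by 5 to approximate a NOAEL.
SEVERITY_BY_POD_TYPE = {PodType.BMDL: 1.0, PodType.NOAEL: 1.0,
                        PodType.LOAEL: 5.0}


@dataclass(frozen=True)
class CorrectionSchema:
    """One agency's correction-factor column for deriving RfC_work.

    ``noael_adj`` (exposure-duration adjustment of the POD, a multiplier
    <= 1) and ``noael_hec`` (human-equivalent-concentration adjustment)
    are quantitative corrections; the ``uf_*`` entries are uncertainty
    divisors. ``uf_duration_default`` / ``uf_severity_default`` are the
    agency's generic values, superseded by the study-specific
    ``duration_rule`` bands and ``severity_rule`` whenever the study
    duration and POD type are known. ``route_scaling_divisor`` documents
    the allometric animal-to-human dose-scaling entry; the numerically
    effective oral-to-air conversion is supplied per derivation (see
    :func:`route_to_route`).
    """

    agency: str
    noael_adj: float
    noael_hec: float
    uf_interspecies: float
    uf_intraspecies: float
    uf_duration_default: float
    uf_severity_default: float
    uf_quality: float
    duration_rule: tuple[tuple[float, float], ...] = DEFAULT_DURATION_BANDS
    route_scaling_divisor: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.noael_adj <= 1:
            raise ValueError("noael_adj must be a multiplier in (0, 1]")
        if self.noael_hec <= 0:
            raise ValueError("noael_hec must be positive")
        for f in ("uf_interspecies", "uf_intraspecies", "uf_duration_default",
                  "uf_severity_default", "uf_quality"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be a divisor >= 1")

    def severity_rule(self, pod_type: PodType) -> float:
        return SEVERITY_BY_POD_TYPE[pod_type]


#: Built-in agency columns: Korea Occupational Safety & Health Agency,
#: US Environmental Protection Agency, European Chemicals Agency, and
#: Japan's Ministry of Health, Labour and Welfare.
AGENCY_SCHEMAS: dict[str, CorrectionSchema] = {
    "KOSHA": CorrectionSchema("KOSHA", 0.5, 1.0, 3.0, 5.0, 2.0, 1.0, 1.0),
    "EPA": CorrectionSchema("EPA", 0.17, 1.0, 3.0, 10.0, 3.0, 1.0, 1.0),
    "ECHA": CorrectionSchema("ECHA", 0.5, 1.0, 2.5, 5.0, 2.0, 1.0, 1.0),
    "MHLW": CorrectionSchema("MHLW", 0.5, 1.0, 10.0, 1.0, 1.0, 1.0, 1.0),
}


# --------------------------------------------------------------------------
# carcinogenic chain

@dataclass(frozen=True)
class UnitRiskResult:
    """The carcinogenic derivation chain with staged-rounded intermediates.

    ``slope_factor`` -> ``iur`` (= SF * IR / BW, 2 significant figures) ->
    ``ur_work`` (= IUR / CF, 2 significant figures). The ``*_unrounded``
    fields keep full precision for the audit trail.
    """

    iur: float
    cf: float
    ur_work: float
    slope_factor: float | None = None
    iur_unrounded: float = 0.0
    cf_unrounded: float = 0.0
    ur_work_unrounded: float = 0.0

    def __post_init__(self) -> None:
        for f in ("iur", "cf", "ur_work"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.slope_factor is not None and self.slope_factor <= 0:
            raise ValueError("slope_factor must be positive")


def worker_correction_factor(ref: ReferenceProfile,
                             worker: WorkerProfile) -> float:
    """Exposure-pattern correction factor CF (dimensionless, unrounded).

    CF = (IR_ref/IR_worker) * (days_ref/days_worker) * (years_ref/years_worker).
    Report at 2 significant figures (defaults give 4.91... -> 4.9).
    """
    return (
        (ref.inhalation_volume / worker.inhalation_volume)
        * (ref.exposure_days / worker.exposure_days)
        * (ref.exposure_years / worker.exposure_years)
    )


def iur_from_slope_factor(sf: float, ref: ReferenceProfile) -> float:
    """Inhalation unit risk IUR = SF * IR / BW (unrounded).

    Converts an oral slope factor (per mg/kg-day) to an inhalation unit
    risk under the reference profile's inhalation rate and body weight.
    """
    if sf <= 0:
        raise ValueError("slope factor must be positive")
    return sf * ref.inhalation_volume / ref.body_weight


def unit_risk_work(iur: float, cf: float, slope_factor: float | None = None
                   ) -> UnitRiskResult:
    """Workplace unit risk UR_work = IUR / CF under staged rounding.

    ``iur`` and ``cf`` are rounded to their reporting precision (2
    significant figures) before the division, matching how published
    chains propagate printed intermediates; unrounded values are retained.
    """
    if iur <= 0 or cf <= 0:
        raise ValueError("iur and cf must be positive")
    iur_r = round_sig(iur, 2)
    cf_r = round_sig(cf, 2)
    ur_unrounded = iur / cf
    ur = round_sig(iur_r / cf_r, 2)
    logger.info("UR_work: IUR %.6g -> %.2g, CF %.6g -> %.2g, UR_work %.2g",
                iur, iur_r, cf, cf_r, ur)
    return UnitRiskResult(
        slope_factor=slope_factor,
        iur=iur_r,
        cf=cf_r,
        ur_work=ur,
        iur_unrounded=iur,
        cf_unrounded=cf,
        ur_work_unrounded=ur_unrounded,
    )


def derive_unit_risk(
    sf: float,
    ref: ReferenceProfile | None = None,
    worker: WorkerProfile | None = None,
) -> UnitRiskResult:
    """Full carcinogenic chain from slope factor to UR_work."""
    ref = ref if ref is not None else ReferenceProfile()
    worker = worker if worker is not None else WorkerProfile()
    iur = iur_from_slope_factor(sf, ref)
    cf = worker_correction_factor(ref, worker)
    result = unit_risk_work(iur, cf, slope_factor=sf)
    return result


# --------------------------------------------------------------------------
# non-carcinogenic chain

class UnsupportedStudyError(ValueError):
    """Study duration below the shortest supported band (< 4 weeks)."""


def duration_factor(study_duration_weeks: float,
                    schema: CorrectionSchema) -> float:
    """Duration uncertainty factor from the schema's bands; the longest
    matching band wins (chronic 1, subchronic 2, short-term 6 by
    default)."""
    if study_duration_weeks <= 0:
        raise ValueError("study duration must be positive")
    for threshold, factor in sorted(schema.duration_rule, reverse=True):
        if study_duration_weeks >= threshold:
            return factor
    raise UnsupportedStudyError(
        f"study duration {study_duration_weeks} weeks is below the shortest "
        f"supported band ({min(t for t, _ in schema.duration_rule)} weeks)"
    )


def severity_factor(pod_type: PodType) -> float:
    """Effect-severity factor: BMDL/NOAEL -> 1, LOAEL -> 5."""
    return SEVERITY_BY_POD_TYPE[pod_type]


class RouteConversionError(ValueError):
    """An oral POD was supplied without an oral-to-air conversion value."""


def route_to_route(
    pod: PointOfDeparture,
    conversion: float | None = None,
    scaling_divisor: float = 4.0,
) -> float:
    """Express a POD as an equivalent air concentration (mg/m3).

    Inhalation PODs pass through unchanged. Oral PODs (mg/kg-day) are
    multiplied by ``conversion`` — the composite oral-to-air multiplier in
    (mg/m3) per (mg/kg-day), a substance-assessment configuration value
    that must be supplied explicitly. ``scaling_divisor`` records the
    allometric animal-to-human dose-scaling entry of the derivation table
    for the audit trail; it is not applied separately because the
    composite multiplier already absorbs it.
    """
    if pod.route is Route.INHALATION:
        return pod.value
    if conversion is None:
        raise RouteConversionError(
            "oral POD requires an explicit oral-to-air conversion multiplier"
        )
    if conversion <= 0:
        raise ValueError("conversion must be positive")
    return pod.value * conversion


@dataclass(frozen=True)
class RfCResult:
    """A workplace reference concentration with its full audit trail.

    ``applied_factors`` lists every (name, value, operation) applied in
    order, ``operation`` being "multiply" or "divide"; re-applying them to
    the POD value reconstructs ``rfc_work_unrounded`` exactly.
    ``rfc_work`` is the reported value, rounded half-up to 2 decimals.
    """

    pod: PointOfDeparture
    schema_agency: str
    applied_factors: tuple[tuple[str, float, str], ...]
    rfc_work: float
    rfc_work_unrounded: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.rfc_work <= 0:
            raise ValueError("rfc_work must be positive")

    def reconstruct(self) -> float:
        """Re-apply the audit trail to the POD value."""
        x = self.pod.value
        for _, value, op in self.applied_factors:
            x = x * value if op == "multiply" else x / value
        return x


def rfc_work(
    pod: PointOfDeparture,
    schema: CorrectionSchema,
    oral_to_air: float | None = None,
) -> RfCResult:
    """Derive RfC_work for one endpoint under one agency schema.

    Order of operations: route-to-route extrapolation (oral PODs only),
    quantitative corrections (x noael_adj x noael_hec), then division by
    uf_interspecies x uf_intraspecies x duration x severity x uf_quality,
    with the duration and severity factors resolved from the study
    duration and POD type. The reported value is rounded half-up to 2
    decimal places; the unrounded value and the ordered factor trail are
    retained.
    """
    trail: list[tuple[str, float, str]] = []
    if pod.route is Route.ORAL:
        air = route_to_route(pod, oral_to_air, schema.route_scaling_divisor)
        trail.append(("oral_to_air_conversion", air / pod.value, "multiply"))
    else:
        air = pod.value

    trail.append(("noael_adj", schema.noael_adj, "multiply"))
    trail.append(("noael_hec", schema.noael_hec, "multiply"))
    dur = duration_factor(pod.study_duration_weeks, schema)
    sev = schema.severity_rule(pod.pod_type)
    for name, value in (
        ("uf_interspecies", schema.uf_interspecies),
        ("uf_intraspecies", schema.uf_intraspecies),
        ("uf_duration", dur),
        ("uf_severity", sev),
        ("uf_quality", schema.uf_quality),
    ):
        trail.append((name, value, "divide"))

    value = air * schema.noael_adj * schema.noael_hec
    value /= (schema.uf_interspecies * schema.uf_intraspecies * dur * sev
              * schema.uf_quality)
    reported = round_half_up(value, 2)
    logger.info(
        "RfC_work[%s/%s]: POD %.6g -> %.6g mg/m3 (reported %.2f)",
        pod.endpoint.value, schema.agency, pod.value, value, reported,
    )
    return RfCResult(
        pod=pod,
        schema_agency=schema.agency,
        applied_factors=tuple(trail),
        rfc_work=reported,
        rfc_work_unrounded=value,
    )
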