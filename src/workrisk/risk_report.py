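"""Risk characterization: excess cancer risk, hazard quotients, reporting.

For each exposure scenario (a named air concentration C in mg/m3, usually
the CTE, RME and OEL):

* excess cancer risk  ECR = C * UR_work, screened against 1e-4;
* hazard quotient     HQ  = C / RfC_work per endpoint, screened against 1.0.

Acceptability uses the unrounded values with a <=-inclusive boundary (a
value exactly at the limit is acceptable). Reported numbers follow the
published-table precision conventions: ECR to 2 decimals on the 1e-4
scale, HQ to 2 decimals below 1 and 1 decimal at or above 1, each rounded
half-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from workrisk.dose_response import (
    RfCResult,
    UnitRiskResult,
    round_half_up,
)

__all__ = [
    "ECR_LIMIT",
    "HQ_LIMIT",
    "ExposureScenario",
    "RiskReport",
    "excess_cancer_risk",
    "hazard_quotient",
    "round_ecr",
    "round_hq",
    "classify",
    "assess",
    "build_report",
    "report_to_frame",
]

logger = logging.getLogger(__name__)

#: Conventional acceptability limit for excess cancer risk in the workplace.
ECR_LIMIT = 1e-4
#: Conventional acceptability limit for a hazard quotient.
HQ_LIMIT = 1.0


@dataclass(frozen=True)
class ExposureScenario:
    """A named exposure concentration (mg/m3) to characterize."""

    name: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class RiskReport:
    """ECR and per-endpoint HQs for one scenario, with acceptability flags.

    ``ecr``/``hq_by_endpoint`` carry unrounded values (used for the
    flags); rounding to reporting precision happens at formatting time.
    """

    scenario: ExposureScenario
    ecr: float
    hq_by_endpoint: dict[str, float]
    ecr_acceptable: bool | None = None
    hq_acceptable: dict[str, bool] | None = None


def excess_cancer_risk(conc: float, ur: UnitRiskResult) -> float:
    """ECR = concentration (mg/m3) * UR_work.

    Uses the staged-rounded (printed) UR_work, so chains reproduce
    published risk tables digit-for-digit.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return conc * ur.ur_work


def hazard_quotient(conc: float, rfc: RfCResult) -> float:
    """HQ = concentration (mg/m3) / RfC_work (rounded published value)."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if rfc.rfc_work <= 0:
        raise ValueError("rfc_work must be positive")
    return conc / rfc.rfc_work


def round_ecr(ecr: float) -> float:
    """ECR at reporting precision: 2 decimals on the 1e-4 scale
    (7.0499e-4 -> 7.05e-4)."""
    return round_half_up(ecr * 1e4, 2) / 1e4


def round_hq(hq: float) -> float:
    """HQ at reporting precision: 2 decimals below 1, 1 decimal above."""
    return round_half_up(hq, 2 if hq < 1 else 1)


def classify(
    report: RiskReport,
    ecr_limit: float = ECR_LIMIT,
    hq_limit: float = HQ_LIMIT,
) -> RiskReport:
    """Attach acceptability flags; comparisons use unrounded values,
    boundary inclusive (value == limit is acceptable)."""
    if ecr_limit <= 0 or hq_limit <= 0:
        raise ValueError("limits must be positive")
    return RiskReport(
        scenario=report.scenario,
        ecr=report.ecr,
        hq_by_endpoint=dict(report.hq_by_endpoint),
        ecr_acceptable=report.ecr <= ecr_limit,
        hq_acceptable={k: v <= hq_limit for k, v in report.hq_by_endpoint.items()},
    )


def assess(
    scenarios,
    ur: UnitRiskResult,
    rfcs: dict[str, RfCResult],
    ecr_limit: float = ECR_LIMIT,
    hq_limit: float = HQ_LIMIT,
) -> list[RiskReport]:
    """Characterize every scenario against one unit risk and a set of
    endpoint reference concentrations; returns classified reports in
    scenario order."""
    reports = []
    for sc in scenarios:
        ecr = excess_cancer_risk(sc.concentration, ur)
        hqs = {name: hazard_quotient(sc.concentration, rfc)
               for name, rfc in rfcs.items()}
        reports.append(classify(RiskReport(sc, ecr, hqs), ecr_limit, hq_limit))
        logger.info("scenario %s (%.4g mg/m3): ECR %.3g, HQ %s",
                    sc.name, sc.concentration, ecr,
                    {k: f"{v:.3g}" for k, v in hqs.items()})
    return reports


def report_to_frame(reports: list[RiskReport]) -> pd.DataFrame:
    """Numeric report table, one row per scenario, values at reporting
    precision (ECR additionally as a raw column for screening)."""
    endpoints: list[str] = []
    for r in reports:
        for k in r.hq_by_endpoint:
            if k not in endpoints:
                endpoints.append(k)
    rows = []
    for r in reports:
        row: dict[str, object] = {
            "scenario": r.scenario.name,
            "concentration_mgm3": r.scenario.concentration,
            "ecr": round_ecr(r.ecr),
            "ecr_acceptable": r.ecr_acceptable,
        }
        for ep in endpoints:
            if ep in r.hq_by_endpoint:
                row[f"hq_{ep}"] = round_hq(r.hq_by_endpoint[ep])
                row[f"hq_{ep}_acceptable"] = (r.hq_acceptable or {}).get(ep)
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(
    reports: list[RiskReport],
    ur: UnitRiskResult | None = None,
    rfcs: dict[str, RfCResult] | None = None,
    estimates=None,
) -> str:
    """Aligned plain-text risk table with an audit-trail footer.

    One row per scenario: ECR (in units of 1e-4) and each endpoint HQ,
    an asterisk marking values above their acceptability limit. The
    footer records the derivation chain (slope factor, IUR, CF, UR_work,
    every RfC_work factor), the rounding stages, and the simulation seed,
    so a report is reproducible from its own text.
    """
    endpoints: list[str] = []
    for r in reports:
        for k in r.hq_by_endpoint:
            if k not in endpoints:
                endpoints.append(k)

    head = f"{'Scenario':<10}{'C (mg/m3)':>11}{'ECR (1e-4)':>12}"
    for ep in endpoints:
        head += f"{'HQ ' + ep:>18}"
    lines = [head, "-" * len(head)]
    for r in reports:
        ecr_mark = "" if (r.ecr_acceptable in (True, None)) else "*"
        line = (f"{r.scenario.name:<10}{r.scenario.concentration:>11.3f}"
                f"{round_ecr(r.ecr) * 1e4:>11.2f}{ecr_mark:<1}")
        for ep in endpoints:
            if ep not in r.hq_by_endpoint:
                line += f"{'-':>18}"
                continue
            hq = round_hq(r.hq_by_endpoint[ep])
            mark = "" if (r.hq_acceptable or {}).get(ep, True) else "*"
            line += f"{hq:>17.2f}{mark:<1}"
        lines.append(line)
    lines.append(
        f"* exceeds the acceptability limit (ECR {ECR_LIMIT:g}, HQ "
        f"{HQ_LIMIT:g}); values exactly at a limit count as acceptable."
    )

    if ur is not None:
        sf = f"{ur.slope_factor:.3g}" if ur.slope_factor is not None else "n/a"
        lines.append("")
        lines.append("Carcinogenic chain (per mg/kg-day, staged rounding):")
        lines.append(
            f"  SF {sf} -> IUR {ur.iur_unrounded:.6g} (reported {ur.iur:.2g})"
            f" / CF {ur.cf_unrounded:.6g} (reported {ur.cf:.2g})"
            f" -> UR_work {ur.ur_work:.2g}"
        )
    if rfcs:
        lines.append("Non-carcinogenic chains (mg/m3):")
        for name, rfc in rfcs.items():
            factors = ", ".join(
                f"{n} {'x' if op == 'multiply' else '/'} {v:g}"
                for n, v, op in rfc.applied_factors
            )
            lines.append(
                f"  {name}: POD {rfc.pod.pod_type.value} {rfc.pod.value:g} "
                f"({rfc.pod.route.value}); {factors} -> "
                f"{rfc.rfc_work_unrounded:.6g} (reported {rfc.rfc_work:.2f}) "
                f"[{rfc.schema_agency}]"
            )
    if estimates is not None:
        lines.append(
            f"Exposure simulation: n_iter {estimates.n_iter}, seed "
            f"{estimates.seed}; CTE {estimates.cte:.4g}, RME "
            f"{estimates.rme:.4g} mg/m3"
            + (f", raw-data GM {estimates.cte_gm:.4g} mg/m3"
               if estimates.cte_gm is not None else "")
        )
    return "\n".join(lines)
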