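"""Substance dossiers: toxicological inputs for a risk assessment.

A dossier bundles everything the dose-response stage consumes for one
substance: identity (name, molecular weight), the regulatory occupational
exposure limit, the cancer slope factor, the points of departure per
non-carcinogenic endpoint, and the oral-to-air conversion multiplier used
for route-to-route extrapolation.

The built-in biphenyl dossier carries the published assessment inputs:

* slope factor 8.2e-3 per mg/kg-day (hepatic tumours, chronic mouse study);
* oral target-organ BMDL 23 mg/kg-day (2-year rat study, urinary system);
* inhalation LOAEL 157.75 mg/m3 (13-week mouse vapor study);
* reproductive BMDL 20 mg/kg-day (rat gestational study, ~9 weeks);
* OEL 0.2 ppm carried as 1.5 mg/m3 (the regulatory pairing, stored
  verbatim rather than recomputed from the molecular weight);
* oral-to-air conversion 2.78 (mg/m3 per mg/kg-day) — a composite value
  inferred from the published reference-concentration results; it absorbs
  the allometric dose-scaling entry (4) documented in the derivation
  table, whose stand-alone physiological basis is not stated.

Dossiers can also be loaded from a YAML file with the same field names
(see :func:`load_dossier`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from workrisk.dose_response import Endpoint, PodType, PointOfDeparture, Route
from workrisk.exposure_data import SubstanceDossier

__all__ = [
    "AssessmentInputs",
    "biphenyl_dossier",
    "load_dossier",
    "BIPHENYL_ORAL_TO_AIR",
]

#: Composite oral-to-air conversion for biphenyl, (mg/m3)/(mg/kg-day);
#: inferred from the published RfC_work chain (labelled as such).
BIPHENYL_ORAL_TO_AIR = 2.78


@dataclass(frozen=True)
class AssessmentInputs:
    """Everything the dose-response stage needs for one substance."""

    dossier: SubstanceDossier
    slope_factor: float  # per mg/kg-day
    pods: tuple[PointOfDeparture, ...]
    oral_to_air: float | None = None  # (mg/m3)/(mg/kg-day), required if any oral POD

    def __post_init__(self) -> None:
        if self.slope_factor <= 0:
            raise ValueError("slope_factor must be positive")
        if any(p.route is Route.ORAL for p in self.pods) and (
            self.oral_to_air is None or self.oral_to_air <= 0
        ):
            raise ValueError(
                "oral PODs present: oral_to_air must be a positive multiplier"
            )

    def pod(self, endpoint: Endpoint) -> PointOfDeparture:
        for p in self.pods:
            if p.endpoint is endpoint:
                return p
        raise KeyError(f"no POD for endpoint {endpoint.value}")


def biphenyl_dossier() -> AssessmentInputs:
    """The built-in biphenyl assessment inputs (see module docstring)."""
    return AssessmentInputs(
        dossier=SubstanceDossier(
            name="biphenyl",
            molecular_weight=154.21,
            oel_ppm=0.2,
            oel_mgm3=1.5,
        ),
        slope_factor=8.2e-3,
        pods=(
            PointOfDeparture(
                value=23.0,
                pod_type=PodType.BMDL,
                route=Route.ORAL,
                endpoint=Endpoint.ORAL_STO,
                species="rat",
                study_duration_weeks=104.0,
            ),
            PointOfDeparture(
                value=157.75,
                pod_type=PodType.LOAEL,
                route=Route.INHALATION,
                endpoint=Endpoint.INHALATION_STO,
                species="mouse",
                study_duration_weeks=13.0,
            ),
            PointOfDeparture(
                value=20.0,
                pod_type=PodType.BMDL,
                route=Route.ORAL,
                endpoint=Endpoint.REPRODUCTIVE,
                species="rat",
                study_duration_weeks=9.0,
            ),
        ),
        oral_to_air=BIPHENYL_ORAL_TO_AIR,
    )


def load_dossier(path: str | Path) -> AssessmentInputs:
    """Load assessment inputs from a YAML document.

    Expected layout::

        name: biphenyl
        molecular_weight: 154.21
        oel_ppm: 0.2
        oel_mgm3: 1.5
        slope_factor: 8.2e-3
        oral_to_air: 2.78
        pods:
          - value: 23
            pod_type: BMDL        # BMDL | NOAEL | LOAEL
            route: oral           # oral | inhalation
            endpoint: oral_sto    # carcinogenic | oral_sto | inhalation_sto | reproductive
            species: rat
            study_duration_weeks: 104
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        dossier = SubstanceDossier(
            name=str(doc["name"]),
            molecular_weight=float(doc["molecular_weight"]),
            oel_ppm=float(doc["oel_ppm"]),
            oel_mgm3=float(doc["oel_mgm3"]),
        )
        pods = tuple(
            PointOfDeparture(
                value=float(p["value"]),
                pod_type=PodType[str(p["pod_type"]).upper()],
                route=Route(str(p["route"]).lower()),
                endpoint=Endpoint(str(p["endpoint"]).lower()),
                species=str(p.get("species", "")),
                study_duration_weeks=float(p["study_duration_weeks"]),
            )
            for p in doc.get("pods", [])
        )
        oral_to_air = doc.get("oral_to_air")
        return AssessmentInputs(
            dossier=dossier,
            slope_factor=float(doc["slope_factor"]),
            pods=pods,
            oral_to_air=float(oral_to_air) if oral_to_air is not None else None,
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing dossier field {exc}") from None
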