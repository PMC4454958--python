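"""Workplace air-concentration measurements: data model, I/O, units, summaries.

Concentrations are carried internally in mg/m3. Input tables may be in ppm;
they are converted on load using the ideal-gas relation
``c[mg/m3] = c[ppm] * MW / Vm`` with molar volume Vm = 24.45 L/mol at
25 degC and 1 atm by default.

Values at or below the analytical detection limit are flagged
``below_detection`` and carried at face value (simple substitution); the
flag is preserved so censoring-aware policies can be layered on later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MOLAR_VOLUME_25C",
    "ExposureSample",
    "ExposureDataset",
    "WorkplaceSummary",
    "SubstanceDossier",
    "ExposureInputError",
    "convert_ppm_to_mgm3",
    "convert_mgm3_to_ppm",
    "load_exposure_table",
    "summarize",
    "format_summary_table",
    "summary_to_frame",
]

#: Molar volume of an ideal gas at 25 degC and 1 atm, L/mol.
MOLAR_VOLUME_25C = 24.45

SAMPLE_KINDS = ("personal", "area")

#: Label used for the pooled all-workplaces summary row.
TOTAL_LABEL = "Total"


class ExposureInputError(ValueError):
    """Malformed exposure input (missing column, bad unit, negative value)."""


def convert_ppm_to_mgm3(
    c: float, mw: float, molar_volume: float = MOLAR_VOLUME_25C
) -> float:
    """Convert a gas-phase concentration from ppm to mg/m3.

    Parameters
    ----------
    c : float
        Concentration in ppm (parts per million by volume), >= 0.
    mw : float
        Molecular weight, g/mol.
    molar_volume : float
        Molar volume of the gas phase, L/mol. Default 24.45 (25 degC, 1 atm).
    """
    if mw <= 0 or molar_volume <= 0:
        raise ValueError(
            f"mw and molar_volume must be positive, got mw={mw}, "
            f"molar_volume={molar_volume}"
        )
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c * mw / molar_volume


def convert_mgm3_to_ppm(
    c: float, mw: float, molar_volume: float = MOLAR_VOLUME_25C
) -> float:
    """Inverse of :func:`convert_ppm_to_mgm3`."""
    if mw <= 0 or molar_volume <= 0:
        raise ValueError(
            f"mw and molar_volume must be positive, got mw={mw}, "
            f"molar_volume={molar_volume}"
        )
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c * molar_volume / mw


@dataclass(frozen=True)
class ExposureSample:
    """A single air measurement.

    Attributes
    ----------
    workplace_id : str
        Workplace label (e.g. "A").
    sample_kind : str
        "personal" (worn sampler) or "area" (fixed location).
    concentration : float
        Concentration in mg/m3, >= 0.
    below_detection : bool
        True if the analytical result was at or below the detection limit;
        the stored concentration is then the detection-limit surrogate.
    """

    workplace_id: str
    sample_kind: str
    concentration: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(
                f"sample_kind must be one of {SAMPLE_KINDS}, got "
                f"{self.sample_kind!r}"
            )
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"concentration must be finite and >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class ExposureDataset:
    """An ordered collection of exposure samples plus the detection limit."""

    samples: tuple[ExposureSample, ...]
    detection_limit: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if not self.samples:
            raise ValueError("ExposureDataset must contain at least one sample")
        if not (self.detection_limit >= 0 and math.isfinite(self.detection_limit)):
            raise ValueError(f"invalid detection_limit {self.detection_limit}")

    def __len__(self) -> int:
        return len(self.samples)

    def concentrations(self) -> list[float]:
        """All concentrations, in sample order, mg/m3."""
        return [s.concentration for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "workplace_id": [s.workplace_id for s in self.samples],
                "sample_kind": [s.sample_kind for s in self.samples],
                "concentration": [s.concentration for s in self.samples],
                "below_detection": [s.below_detection for s in self.samples],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the dataset in the package CSV dialect (mg/m3)."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# units: mg/m3\n")
            self.to_frame().drop(columns="below_detection").to_csv(fh, index=False)


@dataclass(frozen=True)
class WorkplaceSummary:
    """Descriptive statistics for one workplace (or the pooled total).

    AM is the arithmetic mean and SD the sample standard deviation
    (n-1 denominator), the industrial-hygiene reporting convention.
    """

    workplace_id: str
    n: int
    am: float
    sd: float
    range_lo: float
    range_hi: float
    sd_degenerate: bool = False  # single observation: SD reported as 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        # tolerate float rounding in the mean of near-equal values
        slack = 1e-9 * max(abs(self.range_lo), abs(self.range_hi), 1e-300)
        if not (self.range_lo - slack <= self.am <= self.range_hi + slack):
            raise ValueError(
                f"require range_lo <= am <= range_hi, got "
                f"{self.range_lo}, {self.am}, {self.range_hi}"
            )


@dataclass(frozen=True)
class SubstanceDossier:
    """Identity and regulatory context of the assessed substance.

    The occupational exposure limit (OEL) is stored both in ppm and in
    mg/m3 as published, because regulatory ppm/mg-m3 pairs are set by
    convention and need not agree with the molecular-weight conversion
    (biphenyl: 0.2 ppm is carried as 1.5 mg/m3 although MW-based
    conversion gives ~1.26 mg/m3).
    """

    name: str
    molecular_weight: float
    oel_ppm: float
    oel_mgm3: float

    def __post_init__(self) -> None:
        for f in ("molecular_weight", "oel_ppm", "oel_mgm3"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _read_units_pragma(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip().lower()
                if body.startswith("units:"):
                    return body.split(":", 1)[1].strip()
                continue
            break
    return None


def load_exposure_table(
    path: str | Path,
    detection_limit: float,
    *,
    molecular_weight: float | None = None,
    molar_volume: float = MOLAR_VOLUME_25C,
) -> ExposureDataset:
    """Read a delimited measurement table into an :class:`ExposureDataset`.

    The file is CSV or TSV (autodetected by extension, ``.tsv``/``.tab``
    meaning tab) with columns ``workplace_id, sample_kind, concentration``
    and an optional leading pragma line ``# units: mg/m3`` or
    ``# units: ppm`` (mg/m3 assumed if absent). ppm input requires
    ``molecular_weight``. Rows at or below ``detection_limit`` (after unit
    conversion) are flagged ``below_detection``.
    """
    path = Path(path)
    if not path.exists():
        raise ExposureInputError(f"no such file: {path}")

    units = _read_units_pragma(path) or "mg/m3"
    units_norm = units.replace("^", "").replace("**", "")
    if units_norm in ("mg/m3", "mg/m³"):
        to_mgm3 = lambda c: c  # noqa: E731
    elif units_norm == "ppm":
        if molecular_weight is None:
            raise ExposureInputError(
                f"{path}: units are ppm but no molecular_weight was given"
            )
        to_mgm3 = lambda c: convert_ppm_to_mgm3(  # noqa: E731
            c, molecular_weight, molar_volume
        )
    else:
        raise ExposureInputError(f"{path}: unknown units {units!r}")

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ExposureInputError(f"{path}: no data rows") from None
    df.columns = [str(c).strip() for c in df.columns]

    required = ("workplace_id", "sample_kind", "concentration")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ExposureInputError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ExposureInputError(f"{path}: no data rows")

    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            raw = float(row.concentration)
        except (TypeError, ValueError):
            raise ExposureInputError(
                f"{path} row {i}: non-numeric concentration "
                f"{row.concentration!r}"
            ) from None
        if not math.isfinite(raw) or raw < 0:
            raise ExposureInputError(
                f"{path} row {i}: concentration must be finite and >= 0, got {raw}"
            )
        kind = str(row.sample_kind).strip().lower()
        if kind not in SAMPLE_KINDS:
            raise ExposureInputError(
                f"{path} row {i}: unknown sample_kind {row.sample_kind!r}"
            )
        conc = to_mgm3(raw)
        samples.append(
            ExposureSample(
                workplace_id=str(row.workplace_id).strip(),
                sample_kind=kind,
                concentration=conc,
                below_detection=conc <= detection_limit,
            )
        )
    return ExposureDataset(samples=tuple(samples), detection_limit=detection_limit)


def _summary_of(workplace_id: str, values: Sequence[float]) -> WorkplaceSummary:
    s = pd.Series(list(values), dtype=float)
    degenerate = len(s) == 1
    return WorkplaceSummary(
        workplace_id=workplace_id,
        n=len(s),
        am=float(s.mean()),
        sd=0.0 if degenerate else float(s.std(ddof=1)),
        range_lo=float(s.min()),
        range_hi=float(s.max()),
        sd_degenerate=degenerate,
    )


def summarize(
    dataset: ExposureDataset, by: str = "workplace_id"
) -> list[WorkplaceSummary]:
    """Per-group descriptive statistics plus a pooled ``Total`` row.

    Groups are ordered by first appearance in the dataset. SD uses the
    n-1 denominator; a single-observation group reports SD = 0 with
    ``sd_degenerate`` set.
    """
    df = dataset.to_frame()
    if by not in df.columns:
        raise ValueError(f"unknown grouping key {by!r}")
    out = []
    for key in df[by].drop_duplicates():
        sub = df.loc[df[by] == key, "concentration"]
        out.append(_summary_of(str(key), sub.tolist()))
    out.append(_summary_of(TOTAL_LABEL, df["concentration"].tolist()))
    return out


def summary_to_frame(summaries: Iterable[WorkplaceSummary]) -> pd.DataFrame:
    rows = [
        {
            "workplace": s.workplace_id,
            "n": s.n,
            "am_mgm3": s.am,
            "sd_mgm3": s.sd,
            "range_lo_mgm3": s.range_lo,
            "range_hi_mgm3": s.range_hi,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def format_summary_table(summaries: Iterable[WorkplaceSummary]) -> str:
    """Aligned plain-text summary table (Workplace, N, AM, SD, Range)."""
    header = f"{'Workplace':<10}{'N':>4}  {'AM':>7}  {'SD':>7}  {'Range':>14}"
    lines = [header, "-" * len(header)]
    for s in summaries:
        rng = f"{s.range_lo:.3f}-{s.range_hi:.3f}"
        lines.append(
            f"{s.workplace_id:<10}{s.n:>4}  {s.am:>7.3f}  {s.sd:>7.3f}  {rng:>14}"
        )
    lines.append("AM: arithmetic mean (mg/m3); SD: sample standard deviation.")
    return "\n".join(lines)
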