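"""Per-subject data model, CSV round-trip, evaluability filtering and derived biomarkers.

The trial enrolls patients with mIDH1-R132H nonenhancing glioma and randomizes them
to an IDH inhibitor (vorasidenib 50/10 mg q.d., ivosidenib 500 mg q.d. / 250 mg
b.i.d.) or no treatment before a planned resection.  The resected tumor provides the
pharmacodynamic readout: d-2-hydroxyglutarate (2-HG) concentration in µg per gram of
tissue, plus DNA-hydroxymethylation, proliferation and immune-infiltration markers.

Column schema for the cohort CSV is documented in ``docs/cohort_schema.md``.
Missing numeric cells are a distinct *absent* state (``None``), never imputed and
never silently zero.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Arm",
    "ExclusionReason",
    "SubjectRecord",
    "ExternalControlRecord",
    "AnalysisSet",
    "read_cohort_table",
    "write_cohort_table",
    "read_external_control_table",
    "write_external_control_table",
    "eligibility_filter",
    "compute_5hmc_percent",
    "normalize_2hg",
    "SchemaError",
]


class Arm(str, Enum):
    """Pre-surgery treatment assignment."""

    VOR50 = "VOR50"    # vorasidenib 50 mg q.d.
    VOR10 = "VOR10"    # vorasidenib 10 mg q.d.
    IVO500 = "IVO500"  # ivosidenib 500 mg q.d.
    IVO250 = "IVO250"  # ivosidenib 250 mg b.i.d.
    UNTREATED = "UNTREATED"

    @property
    def treated(self) -> bool:
        return self is not Arm.UNTREATED


TREATED_ARMS = (Arm.VOR50, Arm.VOR10, Arm.IVO500, Arm.IVO250)


class ExclusionReason(str, Enum):
    INSUFFICIENT_TISSUE = "INSUFFICIENT_TISSUE"
    MIDH1_NOT_CONFIRMED = "MIDH1_NOT_CONFIRMED"
    INCORRECT_DOSING = "INCORRECT_DOSING"
    MISSED_DOSES = "MISSED_DOSES"


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass
class SubjectRecord:
    """One enrolled subject.

    ``tumor_2hg`` is µg of 2-HG per gram of tumor tissue; ``cellularity`` the
    tumor-cell fraction in (0, 1]; nucleoside counts are LC–MS/MS signal for
    5hmC, 5mC and unmodified cytosine; densities are cells per mm².
    ``lesion_spd`` is the ordered post-baseline SPD series (cm²) with
    ``lesion_days`` the matching study days; ``baseline_spd`` of ``None`` with
    ``no_residual_disease`` True marks a complete resection.
    """

    subject_id: str
    cohort: int
    arm: Arm
    treated_presurgery: bool
    missed_doses_2wk: int = 0
    midh1_confirmed: bool = True
    tissue_sufficient: bool = True
    dosing_correct: bool = True
    tumor_2hg: float | None = None
    cellularity: float | None = None
    c_5hmc: float | None = None
    c_5mc: float | None = None
    c_c: float | None = None
    ki67_pct: float | None = None
    cd3_density: float | None = None
    cd8_density: float | None = None
    baseline_spd: float | None = None
    no_residual_disease: bool = False
    lesion_days: tuple[int, ...] = field(default_factory=tuple)
    lesion_spd: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.arm = Arm(self.arm)
        if self.tumor_2hg is not None and self.tumor_2hg < 0:
            raise ValueError(f"tumor_2hg must be nonnegative, got {self.tumor_2hg}")
        if self.cellularity is not None and not (0.0 < self.cellularity <= 1.0):
            raise ValueError(f"cellularity must lie in (0, 1], got {self.cellularity}")
        if self.arm is Arm.UNTREATED and self.treated_presurgery:
            raise ValueError("untreated subjects cannot be treated pre-surgery")
        if len(self.lesion_days) != len(self.lesion_spd):
            raise ValueError("lesion_days and lesion_spd lengths differ")


@dataclass
class ExternalControlRecord:
    """Archival (banked) untreated tumor sample used for dynamic borrowing."""

    sample_id: str
    idh_status: str  # "WT" or "mIDH1"
    tumor_2hg: float

    def __post_init__(self) -> None:
        if self.idh_status not in ("WT", "mIDH1"):
            raise ValueError(f"idh_status must be WT or mIDH1, got {self.idh_status}")
        if self.tumor_2hg < 0:
            raise ValueError("tumor_2hg must be nonnegative")


@dataclass
class AnalysisSet:
    """Evaluability-filter outcome: included subjects plus per-subject exclusion reasons."""

    included: list[SubjectRecord]
    exclusions: list[tuple[str, ExclusionReason]]

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


# ---------------------------------------------------------------------------
# CSV round trip

_BOOL_COLS = ("treated_presurgery", "midh1_confirmed", "tissue_sufficient",
              "dosing_correct", "no_residual_disease")
_FLOAT_COLS = ("tumor_2hg", "cellularity", "c_5hmc", "c_5mc", "c_c",
               "ki67_pct", "cd3_density", "cd8_density", "baseline_spd")

_WRITE_ORDER = (
    "subject_id", "cohort", "arm", "treated_presurgery", "missed_doses_2wk",
    "midh1_confirmed", "tissue_sufficient", "dosing_correct",
    "tumor_2hg", "cellularity", "c_5hmc", "c_5mc", "c_c",
    "ki67_pct", "cd3_density", "cd8_density",
    "baseline_spd", "no_residual_disease", "lesion_days", "lesion_spd",
)
COHORT_COLUMNS = _WRITE_ORDER


def _parse_float(cell: str, row: int, col: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise SchemaError(f"row {row}: column '{col}' is not numeric: {cell!r}") from exc
    if not math.isfinite(value):
        raise SchemaError(f"row {row}: column '{col}' is not finite: {cell!r}")
    return value


def _parse_series(cell: str, cast) -> tuple:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(cast(tok) for tok in cell.split(";"))


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read a cohort CSV (UTF-8, header row, '.' decimal) into SubjectRecords.

    Empty numeric cells become ``None`` (absent), not zero.  Raises
    :class:`SchemaError` naming the first missing mandatory column, or the
    offending row for unparseable numeric cells.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _WRITE_ORDER:
            if col not in header:
                raise SchemaError(f"missing mandatory column '{col}'")
        records = []
        for i, row in enumerate(reader, start=1):
            kwargs = {
                "subject_id": row["subject_id"].strip(),
                "cohort": int(row["cohort"]),
                "arm": Arm(row["arm"].strip()),
                "missed_doses_2wk": int(row["missed_doses_2wk"] or 0),
                "lesion_days": _parse_series(row["lesion_days"], int),
                "lesion_spd": _parse_series(row["lesion_spd"], float),
            }
            for col in _BOOL_COLS:
                kwargs[col] = row[col].strip().lower() in ("1", "true", "yes")
            for col in _FLOAT_COLS:
                kwargs[col] = _parse_float(row[col], i, col)
            records.append(SubjectRecord(**kwargs))
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable literal
    return str(value)


def write_cohort_table(records: Sequence[SubjectRecord], path) -> None:
    """Write SubjectRecords so that :func:`read_cohort_table` reproduces them exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_WRITE_ORDER)
        for rec in records:
            row = []
            for col in _WRITE_ORDER:
                value = getattr(rec, col)
                if col == "arm":
                    row.append(value.value)
                elif col in ("lesion_days", "lesion_spd"):
                    row.append(";".join(_fmt(v) for v in value))
                else:
                    row.append(_fmt(value))
            writer.writerow(row)


_EXTERNAL_COLUMNS = ("sample_id", "idh_status", "tumor_2hg")


def read_external_control_table(path) -> list[ExternalControlRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in _EXTERNAL_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"missing mandatory column '{col}'")
        out = []
        for i, row in enumerate(reader, start=1):
            value = _parse_float(row["tumor_2hg"], i, "tumor_2hg")
            if value is None:
                raise SchemaError(f"row {i}: tumor_2hg is required for external controls")
            out.append(ExternalControlRecord(row["sample_id"].strip(),
                                             row["idh_status"].strip(), value))
    return out


def write_external_control_table(records: Sequence[ExternalControlRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXTERNAL_COLUMNS)
        for rec in records:
            writer.writerow([rec.sample_id, rec.idh_status, _fmt(rec.tumor_2hg)])


# ---------------------------------------------------------------------------
# Evaluability filter

def eligibility_filter(records: Iterable[SubjectRecord]) -> AnalysisSet:
    """Apply the tissue-analysis evaluability rules.

    A treated subject is excluded iff tissue is insufficient, mIDH1 is not
    confirmed in the resected tissue, pre-surgery dosing was incorrect, or the
    subject missed two or more doses in the two weeks before surgery.
    Untreated subjects can only be excluded for tissue/confirmation reasons
    (dosing does not apply to them).  When several reasons apply, the recorded
    reason follows the fixed precedence tissue → confirmation → dosing →
    missed doses.  Idempotent: filtering the included list again excludes nobody.
    """
    included: list[SubjectRecord] = []
    exclusions: list[tuple[str, ExclusionReason]] = []
    for rec in records:
        reason = None
        if not rec.tissue_sufficient:
            reason = ExclusionReason.INSUFFICIENT_TISSUE
        elif not rec.midh1_confirmed:
            reason = ExclusionReason.MIDH1_NOT_CONFIRMED
        elif rec.arm.treated and not rec.dosing_correct:
            reason = ExclusionReason.INCORRECT_DOSING
        elif rec.arm.treated and rec.missed_doses_2wk >= 2:
            reason = ExclusionReason.MISSED_DOSES
        if reason is None:
            included.append(rec)
        else:
            exclusions.append((rec.subject_id, reason))
    return AnalysisSet(included=included, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Derived biomarker quantities

def compute_5hmc_percent(c_5hmc: float, c_c: float) -> float:
    """Percent 5-hydroxymethylcytosine relative to unmodified cytosine signal.

    5hmC rises when TET hydroxylases are released from 2-HG inhibition, so this
    ratio is the DNA-demethylation pharmacodynamic readout.  The denominator is
    the unmodified-C nucleoside count.
    """
    if c_c <= 0:
        raise ValueError(f"cytosine count must be positive, got {c_c}")
    if c_5hmc < 0:
        raise ValueError("5hmC count must be nonnegative")
    return 100.0 * c_5hmc / c_c


def normalize_2hg(tumor_2hg: float, cellularity: float) -> float:
    """Cellularity-corrected 2-HG: bulk concentration per unit tumor-cell fraction.

    Bulk 2-HG dilutes with non-tumor tissue; dividing by the H&E tumor-cell
    fraction puts samples of different cellularity on a common scale.
    """
    if cellularity <= 0 or cellularity > 1:
        raise ValueError(f"cellularity must lie in (0, 1], got {cellularity}")
    if tumor_2hg < 0:
        raise ValueError("tumor_2hg must be nonnegative")
    return tumor_2hg / cellularity
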