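"""Subjects, BALF differential cytology and clinical phenotype classification.

A cohort is a collection of :class:`HorseRecord` objects, each carrying the
clinical findings and bronchoalveolar lavage fluid (BALF) differential
cytology used to classify equine asthma phenotypes.  Classification follows
strict inequalities throughout: a horse is asthmatic if at least one
granulocytic population is elevated (neutrophils >5%, eosinophils >1%,
mast cells >2%), and an asthmatic horse is severe if it shows labored
breathing at rest, an abnormal lung auscultation, or BALF neutrophilia >20%.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

GROUP_LABELS = ("healthy", "moderate", "severe", "unknown")

#: thresholds for granulocytic elevation, percent of total nucleated cells
NEUTROPHIL_CUTOFF = 5.0
EOSINOPHIL_CUTOFF = 1.0
MAST_CELL_CUTOFF = 2.0
#: BALF neutrophilia indicative of the severe phenotype
SEVERE_NEUTROPHIL_CUTOFF = 20.0


class CohortValidationError(ValueError):
    """Raised when a record violates a cytology or record invariant."""


class CohortParseError(ValueError):
    """Raised on malformed cohort CSV input; names the offending row/column."""


@dataclass(frozen=True)
class BALFCytology:
    """BALF differential cell count, percentages of total nucleated cells.

    Differential counts are performed on 300 cells and rounded to halves,
    so the five populations are required to sum to 100 +/- 5.
    """

    macrophages_pct: float
    lymphocytes_pct: float
    neutrophils_pct: float
    eosinophils_pct: float
    mast_cells_pct: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not 0.0 <= value <= 100.0:
                raise CohortValidationError(
                    f"{name}={value!r} outside [0, 100]"
                )
        total = sum(self.as_dict().values())
        if not 95.0 <= total <= 105.0:
            raise CohortValidationError(
                f"cytology percentages sum to {total}, outside [95, 105]"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "macrophages_pct": self.macrophages_pct,
            "lymphocytes_pct": self.lymphocytes_pct,
            "neutrophils_pct": self.neutrophils_pct,
            "eosinophils_pct": self.eosinophils_pct,
            "mast_cells_pct": self.mast_cells_pct,
        }


@dataclass(frozen=True)
class HorseRecord:
    """One subject: clinical findings plus BALF cytology.

    ``abnormal_lung_auscultation`` is a curated boolean: crackles, wheezes
    or increased lung sounds count as abnormal; nasal discharge or a cough
    reflex alone do not.  ``wcs`` is the weighted clinical score (0-23).
    Missing tracheal data is represented as ``None``, never imputed.
    """

    subject_id: str
    cytology: BALFCytology
    group_label: str = "unknown"
    labored_breathing_at_rest: bool = False
    abnormal_lung_auscultation: bool = False
    tracheal_mucus_score: Optional[int] = None
    tracheal_neutrophilia_gt20: Optional[bool] = None
    wcs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise CohortValidationError(
                f"group_label {self.group_label!r} not in {GROUP_LABELS}"
            )
        if self.tracheal_mucus_score is not None and (
            self.tracheal_mucus_score not in range(6)
        ):
            raise CohortValidationError(
                f"tracheal_mucus_score {self.tracheal_mucus_score!r} not in 0..5"
            )
        if self.wcs is not None and not 0 <= self.wcs <= 23:
            raise CohortValidationError(f"wcs {self.wcs!r} outside [0, 23]")


@dataclass
class CohortTable:
    """Ordered collection of records with unique subject ids."""

    records: list[HorseRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def is_asthmatic(cyt: BALFCytology) -> bool:
    """True iff at least one granulocytic population is elevated.

    Strict inequalities: neutrophils >5%, eosinophils >1% or mast cells >2%.
    """
    return (
        cyt.neutrophils_pct > NEUTROPHIL_CUTOFF
        or cyt.eosinophils_pct > EOSINOPHIL_CUTOFF
        or cyt.mast_cells_pct > MAST_CELL_CUTOFF
    )


def classify_phenotype(rec: HorseRecord, honor_explicit_label: bool = True) -> str:
    """Classify a record as ``healthy``, ``moderate`` or ``severe``.

    Rule: not asthmatic -> healthy; asthmatic with labored breathing at
    rest, abnormal lung auscultation or BALF neutrophilia >20% -> severe;
    otherwise moderate.

    When ``honor_explicit_label`` is set and the record carries an explicit
    group label that disagrees with the rule, the label wins and the
    discrepancy is logged (cohorts may retain, e.g., a clinically healthy
    horse whose cytology exceeds reference values).
    """
    cyt = rec.cytology
    if not is_asthmatic(cyt):
        rule = "healthy"
    elif (
        rec.labored_breathing_at_rest
        or rec.abnormal_lung_auscultation
        or cyt.neutrophils_pct > SEVERE_NEUTROPHIL_CUTOFF
    ):
        rule = "severe"
    else:
        rule = "moderate"

    if (
        honor_explicit_label
        and rec.group_label != "unknown"
        and rec.group_label != rule
    ):
        logger.warning(
            "subject %s: explicit label %r overrides rule-based %r",
            rec.subject_id,
            rec.group_label,
            rule,
        )
        return rec.group_label
    return rule


def subgroup_moderate(rec: HorseRecord) -> str:
    """Split a moderate record into ``neu_lo`` (<5% BALF neutrophils) or ``neu_hi``.

    A value exactly at 5% goes to ``neu_hi``.  Calling this on a record
    that does not classify as moderate is a contract error.
    """
    if classify_phenotype(rec) != "moderate":
        raise CohortValidationError(
            f"subgroup_moderate called on non-moderate record {rec.subject_id!r}"
        )
    return "neu_lo" if rec.cytology.neutrophils_pct < NEUTROPHIL_CUTOFF else "neu_hi"


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "subject_id",
    "group_label",
    "labored_breathing",
    "abnormal_auscultation",
    "mucus_score",
    "tracheal_neut_gt20",
    "wcs",
    "macrophages",
    "lymphocytes",
    "neutrophils",
    "eosinophils",
    "mast_cells",
]

_BOOL = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: str, row: int, column: str) -> Optional[bool]:
    if raw == "":
        return None
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise CohortParseError(
            f"row {row}, column {column!r}: cannot parse boolean from {raw!r}"
        ) from None


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise CohortParseError(
            f"row {row}, column {column!r}: non-numeric value {raw!r}"
        ) from None


def read_cohort_csv(path: str | Path, provenance: str = "") -> CohortTable:
    """Read a cohort table from CSV (see :data:`CSV_COLUMNS`); empty cell = missing."""
    path = Path(path)
    records: list[HorseRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortParseError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            cyt = BALFCytology(
                macrophages_pct=_parse_float(row["macrophages"], i, "macrophages"),
                lymphocytes_pct=_parse_float(row["lymphocytes"], i, "lymphocytes"),
                neutrophils_pct=_parse_float(row["neutrophils"], i, "neutrophils"),
                eosinophils_pct=_parse_float(row["eosinophils"], i, "eosinophils"),
                mast_cells_pct=_parse_float(row["mast_cells"], i, "mast_cells"),
            )
            records.append(
                HorseRecord(
                    subject_id=row["subject_id"],
                    group_label=row["group_label"] or "unknown",
                    labored_breathing_at_rest=bool(
                        _parse_bool(row["labored_breathing"], i, "labored_breathing")
                    ),
                    abnormal_lung_auscultation=bool(
                        _parse_bool(
                            row["abnormal_auscultation"], i, "abnormal_auscultation"
                        )
                    ),
                    tracheal_mucus_score=(
                        int(row["mucus_score"]) if row["mucus_score"] else None
                    ),
                    tracheal_neutrophilia_gt20=_parse_bool(
                        row["tracheal_neut_gt20"], i, "tracheal_neut_gt20"
                    ),
                    wcs=int(row["wcs"]) if row["wcs"] else None,
                    cytology=cyt,
                )
            )
    return CohortTable(records=records, provenance=provenance or str(path))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table; round-trips with :func:`read_cohort_csv`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in table.records:
            c = r.cytology

            def fmt(v):
                if v is None:
                    return ""
                if isinstance(v, bool):
                    return "yes" if v else "no"
                if isinstance(v, float) and v == int(v):
                    return str(int(v))
                return str(v)

            writer.writerow(
                [
                    r.subject_id,
                    r.group_label,
                    fmt(r.labored_breathing_at_rest),
                    fmt(r.abnormal_lung_auscultation),
                    fmt(r.tracheal_mucus_score),
                    fmt(r.tracheal_neutrophilia_gt20),
                    fmt(r.wcs),
                    fmt(c.macrophages_pct),
                    fmt(c.lymphocytes_pct),
                    fmt(c.neutrophils_pct),
                    fmt(c.eosinophils_pct),
                    fmt(c.mast_cells_pct),
                ]
            )


def load_fixture(name: str) -> CohortTable:
    """Load a packaged cohort fixture by name.

    Available fixtures: ``table1_healthy``, ``table2_asthmatic``.
    """
    ref = resources.files("netscope.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_cohort_csv(path, provenance=f"packaged fixture {name}")


def load_healthy_fixture() -> CohortTable:
    """The 12 healthy control subjects."""
    return load_fixture("table1_healthy")


def load_asthmatic_fixture() -> CohortTable:
    """The 21 asthmatic subjects (14 severe, 7 moderate)."""
    return load_fixture("table2_asthmatic")


def classify_cohort(table: CohortTable | Iterable[HorseRecord]) -> dict[str, str]:
    """Map subject_id -> phenotype for every record in a cohort."""
    return {r.subject_id: classify_phenotype(r) for r in table}
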