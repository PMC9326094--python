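"""Plate-assay quantification: PicoGreen cf-DNA calibration, ELISA OD
processing and DNase titration plateau selection."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class AssayError(ValueError):
    pass


@dataclass
class StandardCurve:
    """Linear calibration fitted by OLS of readout on concentration."""

    points: list[tuple[float, float]]  # (concentration ug/ml, readout a.u.)
    fit_slope: float
    fit_intercept: float
    r_squared: float


@dataclass(frozen=True)
class Well:
    well: str
    role: str  # "standard", "blank" or "sample"
    value: float
    concentration: Optional[float] = None  # standards only
    sample_id: Optional[str] = None


@dataclass
class PlateReadout:
    """Labeled plate: fluorescence (PicoGreen) or OD 450 nm (ELISA) values."""

    wells: list[Well] = field(default_factory=list)

    def by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]


@dataclass
class DnaseTitration:
    """DNase activity (UI/well) vs mean OD, activities strictly increasing."""

    points: list[tuple[float, float]]
    plateau_tolerance: float = 0.05

    def __post_init__(self) -> None:
        acts = [a for a, _ in self.points]
        if any(b <= a for a, b in zip(acts, acts[1:])):
            raise AssayError("DNase activities must be strictly increasing")
        if any(od < 0 for _, od in self.points):
            raise AssayError("ODs must be >= 0")


def serial_dilution_series(
    top: float = 0.4, n_points: int = 8, factor: float = 2.0
) -> list[float]:
    """Concentrations of a serial dilution, highest first.

    Defaults give the 2-fold series 0.4 ... 3.125e-3 ug/ml (8 points).
    """
    return [top / factor**i for i in range(n_points)]


def fit_standard_curve(
    standards: Sequence[tuple[float, float]], r2_warn: float = 0.98
) -> StandardCurve:
    """Least-squares line ``readout = slope * conc + intercept``.

    Warns when r^2 falls below ``r2_warn``; refuses to fit when all
    concentrations coincide.
    """
    if len(standards) < 2:
        raise AssayError("need at least 2 standards")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    readout = np.asarray([r for _, r in standards], dtype=float)
    if np.any(conc <= 0):
        raise AssayError("standard concentrations must be > 0")
    if np.unique(conc).size < 2:
        raise AssayError("standards must span at least 2 distinct concentrations")
    res = stats.linregress(conc, readout)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0
    if r2 < r2_warn:
        logger.warning("standard curve r^2 = %.4f < %.2f", r2, r2_warn)
    return StandardCurve(
        points=[(float(c), float(r)) for c, r in standards],
        fit_slope=float(res.slope),
        fit_intercept=float(res.intercept),
        r_squared=r2,
    )


def interpolate_cfdna(
    curve: StandardCurve, sample_readout: float
) -> tuple[float, str]:
    """Invert the calibration: ``(readout - intercept) / slope``.

    Returns ``(concentration, flag)`` where flag is ``"ok"``,
    ``"below_range"`` or ``"above_range"``; out-of-range values are still
    returned.
    """
    if curve.fit_slope == 0:
        raise AssayError("standard curve slope is zero; cannot interpolate")
    conc = (sample_readout - curve.fit_intercept) / curve.fit_slope
    lo = min(c for c, _ in curve.points)
    hi = max(c for c, _ in curve.points)
    flag = "ok"
    if conc < lo:
        flag = "below_range"
    elif conc > hi:
        flag = "above_range"
    return float(conc), flag


def elisa_blank_correct(plate: PlateReadout) -> dict[str, float]:
    """Subtract the mean blank OD from each sample, flooring at 0."""
    blanks = plate.by_role("blank")
    if not blanks:
        raise AssayError("ELISA blank correction requires at least one blank well")
    blank_mean = float(np.mean([w.value for w in blanks]))
    corrected: dict[str, float] = {}
    for w in plate.by_role("sample"):
        sid = w.sample_id or w.well
        corrected[sid] = max(w.value - blank_mean, 0.0)
    return corrected


def select_dnase_plateau(titration: DnaseTitration) -> float:
    """Lowest DNase activity whose OD is within tolerance of the maximum OD.

    Picks the smallest activity with ``OD >= (1 - tol) * max(OD)`` — the
    plateau onset, chosen to maximize signal while minimizing degradation.
    """
    if len(titration.points) < 3:
        raise AssayError("plateau selection requires at least 3 titration points")
    max_od = max(od for _, od in titration.points)
    cutoff = (1.0 - titration.plateau_tolerance) * max_od
    for activity, od in titration.points:
        if od >= cutoff:
            return activity
    raise AssayError("no titration point reaches the plateau cutoff")  # pragma: no cover


# ---------------------------------------------------------------------------
# Plate CSV I/O: well,role,value[,concentration]
# ---------------------------------------------------------------------------


def read_plate_csv(path: str | Path) -> PlateReadout:
    """Read a plate layout CSV with columns ``well,role,value[,concentration]``.

    ``role`` is ``blank``, ``standard`` (requires a concentration), or a
    sample identifier (any other string; stored as the well's sample_id).
    """
    path = Path(path)
    wells: list[Well] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"well", "role", "value"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise AssayError(f"plate CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            role = row["role"].strip()
            try:
                value = float(row["value"])
            except ValueError:
                raise AssayError(
                    f"row {i}: non-numeric value {row['value']!r}"
                ) from None
            conc = None
            if role == "standard":
                raw = (row.get("concentration") or "").strip()
                if not raw:
                    raise AssayError(f"row {i}: standard well without concentration")
                conc = float(raw)
            sample_id = None
            if role not in ("standard", "blank"):
                sample_id, role = role, "sample"
            wells.append(
                Well(
                    well=row["well"],
                    role=role,
                    value=value,
                    concentration=conc,
                    sample_id=sample_id,
                )
            )
    return PlateReadout(wells=wells)


def quantify_picogreen_plate(
    plate: PlateReadout, blank_correct: bool = True
) -> tuple[StandardCurve, list[dict[str, object]]]:
    """Fit the standard curve from a plate and interpolate every sample.

    When blanks are present the mean blank fluorescence is subtracted from
    standards and samples before fitting (logged); results are long-format
    rows ``sample_id, assay, value, unit, flag``.
    """
    blanks = plate.by_role("blank")
    offset = 0.0
    if blank_correct and blanks:
        offset = float(np.mean([w.value for w in blanks]))
        logger.info("PicoGreen blank subtraction: %.3f a.u.", offset)
    standards = [
        (w.concentration, w.value - offset)
        for w in plate.by_role("standard")
    ]
    curve = fit_standard_curve(standards)
    rows = []
    for w in plate.by_role("sample"):
        conc, flag = interpolate_cfdna(curve, w.value - offset)
        rows.append(
            {
                "sample_id": w.sample_id or w.well,
                "assay": "cfdna_picogreen",
                "value": conc,
                "unit": "ug/ml",
                "flag": flag,
            }
        )
    return curve, rows


def quantify_elisa_plate(plate: PlateReadout) -> list[dict[str, object]]:
    """Blank-corrected MPO-DNA ELISA ODs as long-format rows (OD units)."""
    corrected = elisa_blank_correct(plate)
    return [
        {
            "sample_id": sid,
            "assay": "mpo_dna_elisa",
            "value": od,
            "unit": "OD450",
            "flag": "ok",
        }
        for sid, od in corrected.items()
    ]
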