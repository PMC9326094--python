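"""End-to-end orchestration: classify -> quantify -> assay -> statistics ->
report bundle, plus the printed-table reproduction checks."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .assays import quantify_elisa_plate, quantify_picogreen_plate, read_plate_csv
from .cohort import (
    CohortTable,
    classify_phenotype,
    load_asthmatic_fixture,
    load_healthy_fixture,
    read_cohort_csv,
    subgroup_moderate,
)
from .imaging import (
    ThresholdConfig,
    quantifications_to_rows,
    quantify_field,
    read_field,
    summarize_individual,
)
from .simulate import CohortSimSpec, generate_cohort
from .stats import comparison_to_dict, compare_groups, roc_auc, spearman

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One pipeline run: either real input paths or a simulation spec per
    data stream, never both."""

    output_dir: Path = Path("netscope_out")
    cohort_csv: Optional[Path] = None
    image_manifest: Optional[Path] = None
    picogreen_plate_csv: Optional[Path] = None
    elisa_plate_csv: Optional[Path] = None
    simulate_cohort: bool = False
    cohort_sim_spec: Optional[CohortSimSpec] = None
    thresholds: ThresholdConfig = dc_field(default_factory=ThresholdConfig)
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate_cohort and self.cohort_csv is not None:
            raise ValueError("choose real cohort CSV or simulation, not both")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _stats_on_measurements(df: pd.DataFrame, alpha: float) -> dict:
    """Group comparisons, correlations and ROC on a measurement table.

    The table needs ``group`` plus any of the readout columns; correlations
    pool every subject into a single group, and ROC uses one-vs-rest with
    explicit positive-class orientation.
    """
    readouts = [
        c
        for c in ("cfdna_ug_ml", "mpo_dna_od", "nets_area_per_cell")
        if c in df.columns
    ]
    out: dict = {"comparisons": {}, "correlations": {}, "roc": {}}
    groups_present = df["group"].unique().tolist()
    # clinical covariates double as predictors even without assay readouts
    if {"neutrophils_pct", "wcs"} <= set(df.columns):
        res = spearman(df["neutrophils_pct"], df["wcs"])
        out["correlations"]["neutrophils_pct_vs_wcs"] = {
            "rho": res.rho,
            "p_value": res.p_value,
            "n": res.n,
            "flag": res.flag,
        }
    for covar in ("neutrophils_pct", "wcs"):
        if covar not in df.columns:
            continue
        for positive in ("severe", "moderate"):
            if positive in groups_present and len(groups_present) > 1:
                roc = roc_auc(df[covar], df["group"], positive_class=positive)
                out["roc"][f"{covar}_{positive}"] = {
                    "auc": roc.auc,
                    "positive_class": positive,
                    "n": int(len(df)),
                }
    for col in readouts:
        samples = {
            g: df.loc[df["group"] == g, col].to_numpy()
            for g in ("healthy", "moderate", "severe")
            if g in groups_present
        }
        if len(samples) >= 2 and all(len(v) >= 3 for v in samples.values()):
            out["comparisons"][col] = comparison_to_dict(
                compare_groups(samples, alpha=alpha)
            )
        for covar in ("neutrophils_pct", "wcs"):
            if covar in df.columns:
                res = spearman(df[col], df[covar])
                out["correlations"][f"{col}_vs_{covar}"] = {
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                    "flag": res.flag,
                }
        for positive in ("severe", "moderate"):
            if positive in groups_present and len(groups_present) > 1:
                roc = roc_auc(df[col], df["group"], positive_class=positive)
                out["roc"][f"{col}_{positive}"] = {
                    "auc": roc.auc,
                    "positive_class": positive,
                    "n": int(len(df)),
                }
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Writes classification, per-field/per-individual quantification, assay
    results and statistics tables under ``cfg.output_dir``, plus a run log
    with version, seed and every test-dispatch decision.  Returns the
    report as a dict.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": []}

    # --- cohort stage -----------------------------------------------------
    measurements: Optional[pd.DataFrame] = None
    cohort: Optional[CohortTable] = None
    try:
        if cfg.simulate_cohort:
            spec = cfg.cohort_sim_spec or CohortSimSpec(seed=cfg.seed)
            cohort, measurements = generate_cohort(spec)
        elif cfg.cohort_csv is not None:
            cohort = read_cohort_csv(cfg.cohort_csv)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cohort", str(exc)) from exc

    if cohort is not None:
        rows = []
        for rec in cohort:
            phen = classify_phenotype(rec)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group_label": rec.group_label,
                    "phenotype": phen,
                    "moderate_subgroup": (
                        subgroup_moderate(rec) if phen == "moderate" else ""
                    ),
                    "neutrophils_pct": rec.cytology.neutrophils_pct,
                    "wcs": rec.wcs if rec.wcs is not None else "",
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "classification.csv", index=False)
        report["stages"].append("cohort")
        if measurements is None:
            measurements = pd.DataFrame(
                {
                    "subject_id": [r.subject_id for r in cohort],
                    "group": [classify_phenotype(r) for r in cohort],
                    "neutrophils_pct": [
                        r.cytology.neutrophils_pct for r in cohort
                    ],
                    "wcs": [r.wcs for r in cohort],
                }
            )

    # --- imaging stage ----------------------------------------------------
    if cfg.image_manifest is not None:
        try:
            quants = quantify_manifest(cfg.image_manifest, cfg.thresholds)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("imaging", str(exc)) from exc
        pd.DataFrame(quantifications_to_rows(quants)).to_csv(
            outdir / "field_quantification.csv", index=False
        )
        by_subject: dict[str, list] = {}
        for q in quants:
            by_subject.setdefault(q.subject_id, []).append(q)
        summaries = [summarize_individual(v) for v in by_subject.values()]
        pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "n_fields": s.n_fields,
                    "mean_nets_area_per_cell": s.mean_nets_area_per_cell,
                    "mean_nets_area_per_neutrophil": s.mean_nets_area_per_neutrophil,
                }
                for s in summaries
            ]
        ).to_csv(outdir / "individual_nets.csv", index=False)
        report["stages"].append("imaging")

    # --- assay stage ------------------------------------------------------
    assay_rows: list[dict] = []
    try:
        if cfg.picogreen_plate_csv is not None:
            curve, rows = quantify_picogreen_plate(
                read_plate_csv(cfg.picogreen_plate_csv)
            )
            assay_rows.extend(rows)
            report["picogreen_curve"] = {
                "slope": curve.fit_slope,
                "intercept": curve.fit_intercept,
                "r_squared": curve.r_squared,
            }
        if cfg.elisa_plate_csv is not None:
            assay_rows.extend(quantify_elisa_plate(read_plate_csv(cfg.elisa_plate_csv)))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("assay", str(exc)) from exc
    if assay_rows:
        pd.DataFrame(assay_rows).to_csv(outdir / "assay_results.csv", index=False)
        report["stages"].append("assay")

    # --- statistics stage -------------------------------------------------
    if measurements is not None and "group" in measurements.columns:
        try:
            stats = _stats_on_measurements(measurements.dropna(), cfg.alpha)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("stats", str(exc)) from exc
        report["statistics"] = stats
        _write_json(outdir / "statistics.json", stats)
        measurements.to_csv(outdir / "measurements.csv", index=False)
        report["stages"].append("stats")

    _write_json(outdir / "report.json", report)
    with (outdir / "run.log").open("w", encoding="utf-8") as fh:
        fh.write(f"netscope {__version__} seed={cfg.seed}\n")
        for stage in report["stages"]:
            fh.write(f"stage completed: {stage}\n")
        for name, comp in report.get("statistics", {}).get("comparisons", {}).items():
            fh.write(
                f"dispatch {name}: {comp['test_used']} "
                f"(normality {comp['normality_p']})\n"
            )
    return report


def quantify_manifest(manifest_path: Path, cfg: ThresholdConfig) -> list:
    """Quantify every field listed in a manifest CSV.

    Columns: ``subject_id,field_id,dapi,mpo,cith3`` with per-channel image
    paths relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    quants = []
    with manifest_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "field_id", "dapi", "mpo", "cith3"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            fieldobj = read_field(
                {ch: base / row[ch] for ch in ("dapi", "mpo", "cith3")},
                subject_id=row["subject_id"],
                field_id=row["field_id"],
            )
            quants.append(quantify_field(fieldobj, cfg))
    return quants


def reproduce_paper_counts() -> list[dict]:
    """Recompute the printed-table counts from the packaged fixtures.

    Each check carries the expected printed value, the recomputed value and
    a pass flag.
    """
    asthmatic = load_asthmatic_fixture()
    healthy = load_healthy_fixture()

    phen = {r.subject_id: classify_phenotype(r) for r in asthmatic}
    severe = [r for r in asthmatic if phen[r.subject_id] == "severe"]
    moderate = [r for r in asthmatic if phen[r.subject_id] == "moderate"]
    subgroups = [subgroup_moderate(r) for r in moderate]

    checks = [
        ("severe_count", 14, len(severe)),
        ("moderate_count", 7, len(moderate)),
        (
            "severe_labored_breathing_count",
            8,
            sum(r.labored_breathing_at_rest for r in severe),
        ),
        ("moderate_neu_lo_count", 3, subgroups.count("neu_lo")),
        ("moderate_neu_hi_count", 4, subgroups.count("neu_hi")),
        (
            "healthy_max_neutrophil_pct",
            8.0,
            max(r.cytology.neutrophils_pct for r in healthy),
        ),
        (
            "moderate_mucus_score_3_count",
            1,
            sum(r.tracheal_mucus_score == 3 for r in moderate),
        ),
    ]
    return [
        {"check": name, "expected": exp, "actual": act, "pass": exp == act}
        for name, exp, act in checks
    ]
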