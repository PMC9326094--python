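"""Ground-truthed synthetic data: 3-channel cytospin-like fields and cohort
measurement tables.

The image generator paints nuclei (DAPI), neutrophil cytoplasm annuli (MPO),
filamentous NET structures (identical pixels in MPO and Cit-H3) and
"primed" neutrophils (nuclear Cit-H3), records exact ground truth, then
applies an optional Gaussian PSF and additive Gaussian noise.  The cohort
generator draws per-subject assay readouts with a severe-shifted effect
structure so that the downstream statistics have a known sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk as disk_footprint

from .cohort import BALFCytology, CohortTable, HorseRecord, classify_phenotype
from .imaging import FluorescenceField

FOREGROUND = 200.0  # painted object intensity, all channels


class PlacementError(RuntimeError):
    """Could not place the requested number of non-touching objects."""


@dataclass
class ImageSceneSpec:
    """Parameters of one synthetic field."""

    field_size_px: int = 512
    n_cells: int = 30
    n_neutrophils: int = 10
    n_nets_filaments: int = 3
    n_primed_neutrophils: int = 0
    filament_length_px: tuple[int, int] = (60, 140)
    filament_width_px: tuple[int, int] = (4, 7)
    nucleus_radius_px: tuple[int, int] = (6, 10)
    background_level: float = 10.0
    noise_sigma: float = 5.0
    psf_sigma_px: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neutrophils > self.n_cells:
            raise ValueError("n_neutrophils exceeds n_cells")
        if self.n_primed_neutrophils > self.n_neutrophils:
            raise ValueError("n_primed_neutrophils exceeds n_neutrophils")
        if min(self.n_cells, self.n_nets_filaments, self.n_primed_neutrophils) < 0:
            raise ValueError("object counts must be non-negative")


@dataclass
class ImageGroundTruth:
    """Exact truth recorded before PSF blur and noise."""

    true_cell_count: int
    true_neutrophil_count: int
    true_coloc_area_px: int
    nucleus_labels: np.ndarray
    mpo_mask: np.ndarray
    cith3_mask: np.ndarray
    filament_mask: np.ndarray


def _place_centers(
    rng: np.random.Generator,
    n: int,
    size: int,
    margin: int,
    min_dist: float,
    max_tries: int = 5000,
) -> list[tuple[int, int]]:
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{n} non-touching nuclei in {max_tries} tries"
            )
        r = rng.integers(margin, size - margin)
        c = rng.integers(margin, size - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((int(r), int(c)))
    return centers


def _paint_filament(
    rng: np.random.Generator,
    size: int,
    length: int,
    width: int,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Smoothed random-walk curve of the given length and width, avoiding
    the forbidden zone."""
    mask = np.zeros((size, size), dtype=bool)
    r = float(rng.uniform(width, size - width))
    c = float(rng.uniform(width, size - width))
    angle = float(rng.uniform(0, 2 * math.pi))
    radius = max(1, width // 2)
    for _ in range(length):
        angle += float(rng.normal(0.0, 0.25))
        r = min(max(r + math.sin(angle), radius), size - radius - 1)
        c = min(max(c + math.cos(angle), radius), size - radius - 1)
        rr, cc = draw_disk((r, c), radius, shape=(size, size))
        mask[rr, cc] = True
    mask &= ~forbidden
    return mask


def generate_field(
    spec: ImageSceneSpec,
    subject_id: str = "sim",
    field_id: str = "f0",
    pixel_size_um: Optional[float] = None,
) -> tuple[FluorescenceField, ImageGroundTruth]:
    """Paint one synthetic 3-channel field and its exact ground truth.

    Nuclei are non-touching ellipses; neutrophils add an MPO annulus around
    the nucleus; NET filaments are painted identically in MPO and Cit-H3
    (so the true colocalization area is the filament pixel count); primed
    neutrophils add Cit-H3 inside the nucleus, which by construction never
    contributes to colocalization.  Same seed, same spec => identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.field_size_px
    r_max = spec.nucleus_radius_px[1]
    annulus_w = 3
    clearance = r_max + annulus_w + 5  # annulus + blur margin
    min_dist = 2 * clearance

    centers = _place_centers(rng, spec.n_cells, size, clearance, min_dist)

    nucleus_labels = np.zeros((size, size), dtype=np.int32)
    nucleus_mask = np.zeros((size, size), dtype=bool)
    mpo_mask = np.zeros((size, size), dtype=bool)
    cith3_mask = np.zeros((size, size), dtype=bool)

    nuclei_params = []
    for lbl, (r0, c0) in enumerate(centers, start=1):
        ra = float(rng.uniform(*spec.nucleus_radius_px))
        rb = float(rng.uniform(*spec.nucleus_radius_px))
        rot = float(rng.uniform(0, math.pi))
        rr, cc = draw_ellipse(r0, c0, ra, rb, shape=(size, size), rotation=rot)
        nucleus_labels[rr, cc] = lbl
        nucleus_mask[rr, cc] = True
        nuclei_params.append((r0, c0, ra, rb, rot))

    # neutrophils: first n_neutrophils of a shuffled order get MPO annuli
    order = rng.permutation(spec.n_cells)
    neutrophil_idx = sorted(order[: spec.n_neutrophils].tolist())
    for idx in neutrophil_idx:
        r0, c0, ra, rb, rot = nuclei_params[idx]
        rr, cc = draw_ellipse(
            r0, c0, ra + annulus_w, rb + annulus_w, shape=(size, size), rotation=rot
        )
        ring = np.zeros((size, size), dtype=bool)
        ring[rr, cc] = True
        ring &= ~nucleus_mask
        mpo_mask |= ring

    # NET filaments, kept clear of dilated nuclei so counts stay exact
    forbidden = dilation(nucleus_mask, disk_footprint(clearance - r_max))
    filament_mask = np.zeros((size, size), dtype=bool)
    for _ in range(spec.n_nets_filaments):
        length = int(rng.integers(*spec.filament_length_px))
        width = int(rng.integers(*spec.filament_width_px))
        filament_mask |= _paint_filament(rng, size, length, width, forbidden)
    mpo_mask |= filament_mask
    cith3_mask |= filament_mask

    # primed neutrophils: nuclear Cit-H3 (no MPO there, so no coloc)
    for idx in neutrophil_idx[: spec.n_primed_neutrophils]:
        cith3_mask |= nucleus_labels == (idx + 1)

    truth = ImageGroundTruth(
        true_cell_count=spec.n_cells,
        true_neutrophil_count=spec.n_neutrophils,
        true_coloc_area_px=int(filament_mask.sum()),
        nucleus_labels=nucleus_labels,
        mpo_mask=mpo_mask.copy(),
        cith3_mask=cith3_mask.copy(),
        filament_mask=filament_mask,
    )

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full((size, size), spec.background_level, dtype=np.float64)
        img[mask] = FOREGROUND
        if spec.psf_sigma_px > 0:
            img = gaussian_filter(img, spec.psf_sigma_px)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        return np.clip(img, 0.0, None).astype(np.float32)

    fieldobj = FluorescenceField(
        dapi=render(nucleus_mask),
        mpo=render(mpo_mask),
        cith3=render(cith3_mask),
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        subject_id=subject_id,
    )
    return fieldobj, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class GroupEffect:
    """Lognormal location/scale for one readout in one group."""

    mu: float
    sigma: float


@dataclass
class CohortSimSpec:
    """Effect structure of a simulated cohort.

    Defaults reproduce the qualitative ordering severe > {healthy, moderate}
    for every NETs readout, NETs area near zero outside the severe group,
    and a WCS that increases with severity and neutrophil percentage.
    Magnitudes are calibrated to ordering and significance only.
    """

    n_healthy: int = 12
    n_moderate: int = 7
    n_severe: int = 14
    cfdna: dict[str, GroupEffect] = field(
        default_factory=lambda: {
            "healthy": GroupEffect(math.log(0.05), 0.5),
            "moderate": GroupEffect(math.log(0.07), 0.5),
            "severe": GroupEffect(math.log(0.20), 0.6),
        }
    )
    mpo_dna_od: dict[str, GroupEffect] = field(
        default_factory=lambda: {
            "healthy": GroupEffect(math.log(0.10), 0.4),
            "moderate": GroupEffect(math.log(0.12), 0.4),
            "severe": GroupEffect(math.log(0.60), 0.5),
        }
    )
    od_floor: float = 0.05  # assay background floor added to every OD
    nets_area_severe: GroupEffect = field(
        default_factory=lambda: GroupEffect(math.log(8.0), 0.7)
    )
    nets_area_background: float = 0.02  # half-normal scale outside severe
    wcs_noise_sd: float = 1.5
    severity_effect: float = 1.0  # 0 silences every group difference
    seed: int = 0


def _interpolate_mu(base: GroupEffect, healthy: GroupEffect, effect: float) -> float:
    return healthy.mu + effect * (base.mu - healthy.mu)


def _draw_cytology(rng: np.random.Generator, group: str) -> tuple[float, ...]:
    """Cytology consistent with the classification rules for ``group``.

    Percentages are rounded to halves as in a 300-cell differential count.
    """
    if group == "healthy":
        neut = rng.uniform(0.5, 5.0)
        eos = rng.uniform(0.0, 1.0)
        mast = rng.uniform(0.0, 2.0)
    elif group == "moderate":
        if rng.random() < 3 / 7:  # neu-lo: mast-cell elevation, neutrophils <5
            neut = rng.uniform(0.5, 4.5)
            mast = rng.uniform(2.5, 5.0)
        else:  # neu-hi: 5 < neut <= 20
            neut = rng.uniform(6.0, 19.5)
            mast = rng.uniform(0.0, 2.0)
        eos = rng.uniform(0.0, 1.0)
    elif group == "severe":
        neut = rng.uniform(14.0, 92.0)
        eos = 0.0
        mast = rng.uniform(0.0, 2.0)
    else:  # pragma: no cover
        raise ValueError(group)

    def half(x: float) -> float:
        return round(x * 2) / 2

    neut, eos, mast = half(neut), half(eos), half(mast)
    rest = 100.0 - neut - eos - mast
    macro = half(rest * float(rng.uniform(0.35, 0.65)))
    lymph = rest - macro
    return macro, lymph, neut, eos, mast


def generate_cohort(spec: CohortSimSpec) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a cohort and its per-subject measurement table.

    Returns the clinical table and a DataFrame with columns ``subject_id,
    group, neutrophils_pct, wcs, cfdna_ug_ml, mpo_dna_od,
    nets_area_per_cell``.  Reproducible under the spec seed.
    """
    for name, n in (
        ("n_healthy", spec.n_healthy),
        ("n_moderate", spec.n_moderate),
        ("n_severe", spec.n_severe),
    ):
        if n <= 0:
            raise ValueError(f"{name} must be > 0 for the group contrasts")

    rng = np.random.default_rng(spec.seed)
    records: list[HorseRecord] = []
    rows: list[dict[str, object]] = []
    plan = (
        [("healthy", i) for i in range(spec.n_healthy)]
        + [("moderate", i) for i in range(spec.n_moderate)]
        + [("severe", i) for i in range(spec.n_severe)]
    )
    eff = spec.severity_effect
    for group, i in plan:
        macro, lymph, neut, eos, mast = _draw_cytology(rng, group)
        cyt = BALFCytology(macro, lymph, neut, eos, mast)

        labored = False
        ausc = False
        mucus: Optional[int] = None
        if group == "severe":
            labored = bool(rng.random() < 0.6)
            ausc = bool(rng.random() < 0.5)
            if neut <= 20 and not labored and not ausc:
                labored = True  # keep the record classifiable as severe
            mucus = int(rng.integers(3, 6))
        elif group == "moderate":
            mucus = int(rng.integers(2, 4))
        severity_rank = {"healthy": 0.0, "moderate": 1.0, "severe": 2.0}[group]
        wcs_raw = (
            eff * (4.0 * severity_rank + 0.12 * neut)
            + rng.normal(0.0, spec.wcs_noise_sd)
        )
        wcs = int(np.clip(round(wcs_raw), 0, 23))

        sid = f"{group[0].upper()}{i + 1:02d}"
        records.append(
            HorseRecord(
                subject_id=sid,
                group_label=group,
                labored_breathing_at_rest=labored,
                abnormal_lung_auscultation=ausc,
                tracheal_mucus_score=mucus,
                tracheal_neutrophilia_gt20=(neut > 20) if group != "healthy" else None,
                wcs=wcs,
                cytology=cyt,
            )
        )

        mu_cf = _interpolate_mu(spec.cfdna[group], spec.cfdna["healthy"], eff)
        cfdna = float(rng.lognormal(mu_cf, spec.cfdna[group].sigma))
        mu_od = _interpolate_mu(
            spec.mpo_dna_od[group], spec.mpo_dna_od["healthy"], eff
        )
        od = spec.od_floor + float(rng.lognormal(mu_od, spec.mpo_dna_od[group].sigma))
        if group == "severe" and eff > 0:
            nets = float(
                rng.lognormal(spec.nets_area_severe.mu * eff, spec.nets_area_severe.sigma)
            )
        else:
            nets = abs(float(rng.normal(0.0, spec.nets_area_background)))
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "neutrophils_pct": neut,
                "wcs": wcs,
                "cfdna_ug_ml": cfdna,
                "mpo_dna_od": od,
                "nets_area_per_cell": nets,
            }
        )

    table = CohortTable(records=records, provenance=f"simulated, seed={spec.seed}")
    # generated covariates must classify back to their own label
    for rec in records:
        assert classify_phenotype(rec, honor_explicit_label=False) == rec.group_label
    return table, pd.DataFrame(rows)
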