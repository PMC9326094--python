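"""NETs-area quantification from 3-channel fluorescence fields.

The pipeline mirrors a colocalization script for cytospin images: threshold
the MPO (green) and Cit-H3 (red) channels, intersect the two binary masks,
measure the intersection area, count DAPI nuclei, identify MPO+ neutrophils,
and normalize the colocalization area per cell and per neutrophil.  The DAPI
channel is deliberately excluded from the intersection; only MPO and Cit-H3
define a NET structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from skimage import io as skio
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

logger = logging.getLogger(__name__)

Threshold = Union[float, int, str]  # numeric cutoff or "otsu"


class FieldShapeError(ValueError):
    """Channel arrays of one field do not share a shape."""


@dataclass
class FluorescenceField:
    """One acquired field: DAPI (blue), MPO (green) and Cit-H3 (red) channels."""

    dapi: np.ndarray
    mpo: np.ndarray
    cith3: np.ndarray
    pixel_size_um: Optional[float] = None
    field_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi)
        self.mpo = np.asarray(self.mpo)
        self.cith3 = np.asarray(self.cith3)
        if not (self.dapi.shape == self.mpo.shape == self.cith3.shape):
            raise FieldShapeError(
                f"channel shapes differ: dapi {self.dapi.shape}, "
                f"mpo {self.mpo.shape}, cith3 {self.cith3.shape}"
            )
        for name, ch in (("dapi", self.dapi), ("mpo", self.mpo), ("cith3", self.cith3)):
            if ch.ndim != 2:
                raise FieldShapeError(f"{name} channel is not 2-D")
            if np.any(ch < 0):
                raise ValueError(f"{name} channel has negative intensities")


@dataclass
class ThresholdConfig:
    """Per-channel thresholds and object-size/overlap parameters.

    Thresholds are numeric cutoffs (strict ``intensity > t`` comparison) or
    the string ``"otsu"`` for a per-image Otsu threshold.
    """

    mpo_threshold: Threshold = "otsu"
    cith3_threshold: Threshold = "otsu"
    dapi_threshold: Threshold = "otsu"
    min_nucleus_area_px: int = 30
    min_coloc_object_area_px: int = 0
    neutrophil_overlap_fraction: float = 0.1
    nucleus_dilation_radius_px: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.neutrophil_overlap_fraction <= 1.0:
            raise ValueError("neutrophil_overlap_fraction outside [0, 1]")
        if self.min_nucleus_area_px < 0 or self.min_coloc_object_area_px < 0:
            raise ValueError("minimum object areas must be >= 0")
        if self.nucleus_dilation_radius_px < 0:
            raise ValueError("nucleus_dilation_radius_px must be >= 0")


@dataclass
class FieldQuantification:
    """Per-field readouts; ``nets_area_per_neutrophil`` is None when undefined."""

    subject_id: str
    field_id: str
    coloc_area: float
    cell_count: int
    neutrophil_count: int
    nets_area_per_cell: float
    nets_area_per_neutrophil: Optional[float]


@dataclass
class IndividualNETsSummary:
    """Arithmetic means over the fields acquired for one subject."""

    subject_id: str
    n_fields: int
    mean_nets_area_per_cell: float
    mean_nets_area_per_neutrophil: Optional[float]


def resolve_threshold(channel: np.ndarray, threshold: Threshold) -> float:
    """Resolve ``"otsu"`` to a numeric cutoff; pass numeric cutoffs through."""
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        channel = np.asarray(channel)
        if channel.min() == channel.max():
            logger.warning(
                "otsu threshold on constant image (value %s): empty mask",
                channel.flat[0],
            )
            return float(channel.flat[0])
        return float(threshold_otsu(channel))
    return float(threshold)


def binarize_channel(channel: np.ndarray, threshold: Threshold) -> np.ndarray:
    """Binary mask, true exactly where ``intensity > threshold`` (strict)."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel array")
    cutoff = resolve_threshold(channel, threshold)
    return channel > cutoff


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 0 or not mask.any():
        return mask
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labels]


def coloc_mask(
    mpo_mask: np.ndarray, cith3_mask: np.ndarray, min_object_area_px: int = 0
) -> np.ndarray:
    """Pixelwise AND of the two masks, small objects removed (8-connectivity)."""
    mpo_mask = np.asarray(mpo_mask, dtype=bool)
    cith3_mask = np.asarray(cith3_mask, dtype=bool)
    if mpo_mask.shape != cith3_mask.shape:
        raise FieldShapeError(
            f"mask shapes differ: {mpo_mask.shape} vs {cith3_mask.shape}"
        )
    return _remove_small(mpo_mask & cith3_mask, min_object_area_px)


def coloc_area(mask: np.ndarray, pixel_size_um: Optional[float] = None) -> float:
    """Area of a binary mask: pixel count, or um^2 when a pixel size is given."""
    n = int(np.count_nonzero(np.asarray(mask, dtype=bool)))
    if pixel_size_um is not None:
        return n * pixel_size_um**2
    return float(n)


def count_cells(
    dapi: np.ndarray, cfg: ThresholdConfig
) -> tuple[int, np.ndarray]:
    """Count nuclei as connected DAPI components with area >= min_nucleus_area_px.

    Returns ``(count, label_map)``; the label map is relabeled consecutively
    after the size filter.
    """
    mask = binarize_channel(dapi, cfg.dapi_threshold)
    mask = _remove_small(mask, cfg.min_nucleus_area_px)
    labels = cc_label(mask, connectivity=2)
    return int(labels.max()), labels


def count_neutrophils(
    nucleus_labels: np.ndarray, mpo_mask: np.ndarray, cfg: ThresholdConfig
) -> int:
    """Count nuclei whose dilated footprint is sufficiently MPO positive.

    A nucleus is a neutrophil iff, within its footprint dilated by
    ``nucleus_dilation_radius_px``, the fraction of MPO+ pixels is at least
    ``neutrophil_overlap_fraction``.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    mpo_mask = np.asarray(mpo_mask, dtype=bool)
    if nucleus_labels.shape != mpo_mask.shape:
        raise FieldShapeError("nucleus label map and MPO mask shapes differ")
    n_nuclei = int(nucleus_labels.max())
    if n_nuclei == 0 or not mpo_mask.any():
        return 0
    footprint = disk(cfg.nucleus_dilation_radius_px) if cfg.nucleus_dilation_radius_px else None
    count = 0
    for lbl in range(1, n_nuclei + 1):
        region = nucleus_labels == lbl
        if footprint is not None:
            region = dilation(region, footprint)
        area = int(region.sum())
        if area == 0:
            continue
        frac = int(mpo_mask[region].sum()) / area
        if frac >= cfg.neutrophil_overlap_fraction:
            count += 1
    return count


def quantify_field(
    field: FluorescenceField, cfg: Optional[ThresholdConfig] = None
) -> FieldQuantification:
    """Full per-field quantification: coloc area, cell and neutrophil counts,
    and normalized NETs areas.

    Division policy: a field with no cells reports both normalized areas as 0
    (with a warning); a field with colocalization but no neutrophils reports
    the per-neutrophil value as missing (None) rather than infinite.
    """
    cfg = cfg or ThresholdConfig()
    mpo_mask = binarize_channel(field.mpo, cfg.mpo_threshold)
    cith3_mask = binarize_channel(field.cith3, cfg.cith3_threshold)
    inter = coloc_mask(mpo_mask, cith3_mask, cfg.min_coloc_object_area_px)
    area = coloc_area(inter, field.pixel_size_um)

    cell_count, labels = count_cells(field.dapi, cfg)
    neutrophil_count = count_neutrophils(labels, mpo_mask, cfg)

    if cell_count == 0:
        if area > 0:
            logger.warning(
                "field %s/%s: colocalization area %s but no cells; "
                "normalized areas reported as 0",
                field.subject_id,
                field.field_id,
                area,
            )
        per_cell = 0.0
        per_neutrophil: Optional[float] = 0.0
    else:
        per_cell = area / cell_count
        if neutrophil_count > 0:
            per_neutrophil = area / neutrophil_count
        elif area > 0:
            per_neutrophil = None  # flagged missing, not infinite
        else:
            per_neutrophil = 0.0

    return FieldQuantification(
        subject_id=field.subject_id,
        field_id=field.field_id,
        coloc_area=area,
        cell_count=cell_count,
        neutrophil_count=neutrophil_count,
        nets_area_per_cell=per_cell,
        nets_area_per_neutrophil=per_neutrophil,
    )


def summarize_individual(
    fields: Sequence[FieldQuantification],
) -> IndividualNETsSummary:
    """Arithmetic means over a subject's fields.

    Missing per-neutrophil values are excluded from that mean; if every
    field's per-neutrophil value is missing the summary value is None.
    """
    if not fields:
        raise ValueError("summarize_individual requires at least one field")
    subjects = {f.subject_id for f in fields}
    if len(subjects) > 1:
        raise ValueError(f"fields from mixed subjects: {sorted(subjects)}")
    per_cell = [f.nets_area_per_cell for f in fields]
    per_neu = [
        f.nets_area_per_neutrophil
        for f in fields
        if f.nets_area_per_neutrophil is not None
    ]
    return IndividualNETsSummary(
        subject_id=fields[0].subject_id,
        n_fields=len(fields),
        mean_nets_area_per_cell=float(np.mean(per_cell)),
        mean_nets_area_per_neutrophil=(
            float(np.mean(per_neu)) if per_neu else None
        ),
    )


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

CHANNEL_NAMES = ("dapi", "mpo", "cith3")


def read_field(
    paths: dict[str, str | Path] | str | Path,
    channel_order: Sequence[str] = CHANNEL_NAMES,
    pixel_size_um: Optional[float] = None,
    field_id: str = "",
    subject_id: str = "",
) -> FluorescenceField:
    """Read a field from per-channel grayscale files or one multi-channel TIFF.

    ``paths`` is either a mapping ``{"dapi": path, "mpo": path, "cith3": path}``
    or a single path to a (C, Y, X) stack interpreted via ``channel_order``.
    """
    if isinstance(paths, (str, Path)):
        stack = np.asarray(skio.imread(str(paths)))
        if stack.ndim != 3:
            raise FieldShapeError(
                f"expected a 3-D channel stack, got shape {stack.shape}"
            )
        if stack.shape[0] not in (3,) and stack.shape[-1] == 3:
            stack = np.moveaxis(stack, -1, 0)
        channels = {name: stack[i] for i, name in enumerate(channel_order)}
    else:
        channels = {name: np.asarray(skio.imread(str(p))) for name, p in paths.items()}
    missing = set(CHANNEL_NAMES) - set(channels)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    return FluorescenceField(
        dapi=channels["dapi"],
        mpo=channels["mpo"],
        cith3=channels["cith3"],
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        subject_id=subject_id,
    )


def quantifications_to_rows(
    quants: Sequence[FieldQuantification],
) -> list[dict[str, object]]:
    """Rows for the per-field output CSV."""
    return [
        {
            "subject_id": q.subject_id,
            "field_id": q.field_id,
            "coloc_area": q.coloc_area,
            "cell_count": q.cell_count,
            "neutrophil_count": q.neutrophil_count,
            "nets_area_per_cell": q.nets_area_per_cell,
            "nets_area_per_neutrophil": (
                q.nets_area_per_neutrophil
                if q.nets_area_per_neutrophil is not None
                else math.nan
            ),
        }
        for q in quants
    ]
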