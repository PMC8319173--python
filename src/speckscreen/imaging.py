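"""Speck image-analysis pipeline for two-channel high-content fields.

The pipeline mirrors a high-content screening workflow for counting
ASC-speck-positive macrophages:

1. segment and count all nuclei on the nuclear-stain channel;
2. segment specks (bright ~1 um puncta) on the reporter channel;
3. reject over-bright reporter cells, measured as the mean reporter
   intensity over each nucleus with speck pixels masked out, against a
   fixed intensity threshold;
4. dilate the surviving nuclei into pseudo-cell regions (the cytoplasm
   is unstained, so a collision-aware isotropic expansion stands in for
   the cell boundary);
5. link specks to cells by centroid containment — a cell is
   speck-positive when it contains at least one speck;
6. report 100 * (cells with specks) / (total nuclei) per field, pooled
   over the fields of a well.

The denominator of the final percentage is configurable between the
total nucleus count (default) and the post-rejection selected count;
see :class:`SegmentationParams`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "FieldImagePair",
    "SegmentationParams",
    "FieldResult",
    "WellResult",
    "ImagingError",
    "segment_nuclei",
    "reject_bright_cells",
    "dilate_nuclei",
    "segment_specks",
    "link_targets",
    "percent_cells_with_specks",
    "suggest_bright_threshold",
    "analyze_field",
    "analyze_well",
    "pool_field_results",
]


class ImagingError(ValueError):
    """Raised for undefined results (e.g. zero-nucleus percentage)."""


@dataclass(frozen=True)
class FieldImagePair:
    """Two registered single-plane intensity grids plus the pixel size."""

    nuclear_channel: np.ndarray
    reporter_channel: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.nuclear_channel.shape != self.reporter_channel.shape:
            raise ValueError(
                f"channel shapes differ: {self.nuclear_channel.shape} vs "
                f"{self.reporter_channel.shape}"
            )
        if self.nuclear_channel.ndim != 2:
            raise ValueError("channels must be 2-D single-plane grids")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


class SegmentationParams(BaseModel):
    """Tunable parameters of the six-step pipeline.

    Intensity parameters are in raw reporter-channel units.
    ``bright_intensity_threshold`` is the fixed cut on mean nuclear
    reporter intensity above which a cell is discarded as over-bright;
    ``speck_threshold`` is applied to the background-subtracted
    (top-hat) reporter image.  ``denominator`` selects whether the final
    percentage divides by all counted nuclei or only those surviving
    bright-cell rejection.
    """

    nuclei_threshold_method: Literal["auto", "fixed"] = "auto"
    nuclei_fixed_threshold: float | None = None
    nuclei_min_area_px: int = Field(default=20, gt=0)
    nuclei_smooth_sigma_px: float = Field(default=2.0, ge=0)
    watershed_min_distance_px: int = Field(default=6, gt=0)
    bright_intensity_threshold: float = 1500.0
    dilation_radius_um: float = Field(default=7.0, gt=0)
    speck_diameter_um: float = Field(default=1.0, gt=0)
    speck_threshold: float = 500.0
    speck_min_area_px: int = Field(default=2, gt=0)
    speck_max_area_px: int = Field(default=80, gt=0)
    denominator: Literal["total", "selected"] = "total"

    @model_validator(mode="after")
    def _check(self) -> "SegmentationParams":
        if self.speck_min_area_px > self.speck_max_area_px:
            raise ValueError("speck_min_area_px must be <= speck_max_area_px")
        if self.nuclei_threshold_method == "fixed" and self.nuclei_fixed_threshold is None:
            raise ValueError("fixed nuclei thresholding needs nuclei_fixed_threshold")
        return self


@dataclass(frozen=True)
class FieldResult:
    """Per-field counts and the speck-positive percentage."""

    n_nuclei_total: int
    n_nuclei_rejected_bright: int
    n_nuclei_selected: int
    n_cells_with_specks: int
    pct_cells_with_specks: float

    def __post_init__(self) -> None:
        assert self.n_nuclei_selected == self.n_nuclei_total - self.n_nuclei_rejected_bright
        assert 0 <= self.n_cells_with_specks <= max(self.n_nuclei_selected, 0)


@dataclass(frozen=True)
class WellResult:
    """Counts pooled over the fields of a well.

    The percentage is computed from the pooled counts, never by
    averaging per-field percentages (fields with different cell counts
    would otherwise be weighted equally).
    """

    plate_id: str
    well: str
    n_fields: int
    n_nuclei_total: int
    n_nuclei_rejected_bright: int
    n_nuclei_selected: int
    n_cells_with_specks: int
    pct_cells_with_specks: float


# ---------------------------------------------------------------------------
# pipeline steps


def segment_nuclei(
    nuclear_channel: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, int]:
    """Segment all nuclei; touching nuclei are split by watershed.

    Global (Otsu or fixed) threshold on a lightly smoothed image, hole
    filling, small-object removal, then a distance-transform watershed
    seeded at distance maxima to separate abutting nuclei.  An all-zero
    or empty-foreground image yields zero nuclei, not an error.

    Returns the label map and the nucleus count.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclear_channel, dtype=float)
    if img.size == 0:
        raise ImagingError("segment_nuclei: empty image")
    smooth = (
        filters.gaussian(img, sigma=params.nuclei_smooth_sigma_px, preserve_range=True)
        if params.nuclei_smooth_sigma_px > 0
        else img
    )
    if params.nuclei_threshold_method == "fixed":
        thr = float(params.nuclei_fixed_threshold)  # type: ignore[arg-type]
    else:
        if np.ptp(smooth) == 0:
            return np.zeros(img.shape, dtype=np.int32), 0
        thr = float(filters.threshold_otsu(smooth))
    mask = smooth > thr
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), 0
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=params.nuclei_min_area_px - 1)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), 0

    dist = ndi.distance_transform_edt(mask)
    dist_s = filters.gaussian(dist, sigma=1.0, preserve_range=True)
    peaks = peak_local_max(
        dist_s,
        min_distance=params.watershed_min_distance_px,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:  # tiny objects with no detected peak
        labels, _ = ndi.label(mask)
    else:
        labels = segmentation.watershed(-dist_s, markers, mask=mask)
    # watershed fragments below the area floor are dropped, then labels
    # are made consecutive so downstream code can index by label id
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < params.nuclei_min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    labels = segmentation.relabel_sequential(labels)[0]
    return labels.astype(np.int32), int(labels.max())


def reject_bright_cells(
    nuclei_labels: np.ndarray,
    reporter_channel: np.ndarray,
    speck_mask: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, int]:
    """Drop nuclei whose masked mean reporter intensity is over-bright.

    Per nucleus, the mean reporter intensity is taken over the nucleus
    footprint minus ``speck_mask`` (so a legitimate speck overlapping a
    nucleus cannot push the cell over the cut).  Nuclei with mean above
    ``bright_intensity_threshold`` are removed from the label map;
    label ids of survivors are preserved.  A nucleus entirely covered by
    the speck mask has no measurable pixels: it is retained (treated as
    not bright) and logged.
    """
    params = params or SegmentationParams()
    labels = np.asarray(nuclei_labels)
    rep = np.asarray(reporter_channel, dtype=float)
    if speck_mask is None:
        speck_mask = np.zeros(labels.shape, dtype=bool)
    if speck_mask.shape != labels.shape or rep.shape != labels.shape:
        raise ValueError("reject_bright_cells: shape mismatch between inputs")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.copy(), 0
    masked = np.where(speck_mask, 0, labels)
    counts = ndi.sum_labels(np.ones_like(rep), masked, index=ids)
    sums = ndi.sum_labels(rep, masked, index=ids)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    covered = ids[counts == 0]
    if covered.size:
        logger.warning(
            "%d nuclei entirely covered by the speck mask; retained as not-bright: %s",
            covered.size, covered.tolist(),
        )
    bright = ids[np.nan_to_num(means, nan=-np.inf) > params.bright_intensity_threshold]
    out = labels.copy()
    if bright.size:
        out[np.isin(out, bright)] = 0
    return out, int(bright.size)


def dilate_nuclei(
    selected_labels: np.ndarray, dilation_radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Grow each nucleus isotropically into a pseudo-cell label map.

    Expansion is label-preserving and collision-aware: every pixel
    within the dilation radius of at least one nucleus is assigned to
    the nucleus whose footprint is nearest (Euclidean distance to the
    nearest pixel of the nucleus); exact ties go to the lower label id.
    A radius below one pixel returns the input unchanged.
    """
    if dilation_radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dilate_nuclei: radius and pixel size must be positive")
    labels = np.asarray(selected_labels)
    r_px = int(round(dilation_radius_um / pixel_size_um))
    if r_px < 1:
        return labels.copy()
    out = labels.copy()
    best = np.where(labels > 0, 0.0, np.inf)
    objects = ndi.find_objects(labels)
    h, w = labels.shape
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        y0 = max(0, sl[0].start - r_px - 1)
        y1 = min(h, sl[0].stop + r_px + 1)
        x0 = max(0, sl[1].start - r_px - 1)
        x1 = min(w, sl[1].stop + r_px + 1)
        crop = labels[y0:y1, x0:x1]
        dist = ndi.distance_transform_edt(crop != idx)
        claim = (dist <= r_px) & (dist < best[y0:y1, x0:x1])
        best[y0:y1, x0:x1][claim] = dist[claim]
        out[y0:y1, x0:x1][claim] = idx
    return out


def segment_specks(
    reporter_channel: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 0.65,
) -> np.ndarray:
    """Segment speck puncta on the reporter channel.

    Local background (diffuse cytoplasm, over-bright cell plateaus) is
    removed by a white top-hat whose structuring element is sized from
    the expected speck diameter; the residue is thresholded and objects
    outside the [min, max] area gate are discarded.  Returns a label map.
    """
    params = params or SegmentationParams()
    rep = np.asarray(reporter_channel, dtype=float)
    if rep.size == 0:
        raise ImagingError("segment_specks: empty image")
    # footprint radius = one expected speck diameter so the opening
    # removes structures broader than a punctum but keeps the punctum
    r = max(2, math.ceil(params.speck_diameter_um / pixel_size_um))
    tophat = morphology.white_tophat(rep, footprint=morphology.disk(r))
    mask = tophat > params.speck_threshold
    labels, _ = ndi.label(mask)
    if labels.max():
        areas = np.bincount(labels.ravel())
        bad = np.flatnonzero(
            (areas < params.speck_min_area_px) | (areas > params.speck_max_area_px)
        )
        labels[np.isin(labels, bad[bad > 0])] = 0
        labels = segmentation.relabel_sequential(labels)[0]
    return labels.astype(np.int32)


def link_targets(
    cell_regions: np.ndarray, speck_labels: np.ndarray
) -> tuple[set[int], int]:
    """Assign specks to pseudo-cell regions by centroid containment.

    A speck belongs to the cell region containing its centroid pixel
    (centroid rounded to the nearest pixel); a cell is speck-positive
    when it holds at least one speck.  Returns the set of speck-positive
    cell ids and the number of specks whose centroid fell in no cell
    region.
    """
    cells = np.asarray(cell_regions)
    specks = np.asarray(speck_labels)
    if cells.shape != specks.shape:
        raise ValueError("link_targets: shape mismatch")
    positive: set[int] = set()
    unassigned = 0
    for prop in regionprops(specks):
        r, c = prop.centroid
        ri = min(max(int(round(r)), 0), cells.shape[0] - 1)
        ci = min(max(int(round(c)), 0), cells.shape[1] - 1)
        cid = int(cells[ri, ci])
        if cid > 0:
            positive.add(cid)
        else:
            unassigned += 1
    return positive, unassigned


def percent_cells_with_specks(n_cells_with_specks: int, n_nuclei: int,
                              where: str = "") -> float:
    """100 * speck-positive cells / nuclei; zero nuclei is an error."""
    if n_nuclei <= 0:
        raise ImagingError(
            f"percent_cells_with_specks undefined: zero nuclei{' in ' + where if where else ''}"
        )
    return 100.0 * n_cells_with_specks / n_nuclei


def suggest_bright_threshold(
    nuclei_labels: np.ndarray, reporter_channel: np.ndarray
) -> float:
    """Suggest a fixed bright-cell cut from per-nucleus mean intensities.

    Otsu's criterion on the distribution of per-nucleus mean reporter
    intensities separates the diffuse-cytoplasm mode from the
    over-bright mode; intended to be run on control wells.
    """
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    if ids.size < 2:
        raise ImagingError("suggest_bright_threshold: need >= 2 nuclei")
    means = ndi.mean(np.asarray(reporter_channel, dtype=float), nuclei_labels, index=ids)
    return float(filters.threshold_otsu(np.asarray(means)))


# ---------------------------------------------------------------------------
# field / well orchestration


def analyze_field(
    pair: FieldImagePair,
    params: SegmentationParams | None = None,
    return_labels: bool = False,
):
    """Run the full six-step pipeline on one field.

    Specks are segmented once on the raw reporter channel; that spot
    mask feeds bright-cell rejection, and linking then uses only the
    surviving cells' dilated regions.
    """
    params = params or SegmentationParams()
    nuclei, n_total = segment_nuclei(pair.nuclear_channel, params)
    specks = segment_specks(pair.reporter_channel, params, pair.pixel_size_um)
    selected, n_rejected = reject_bright_cells(
        nuclei, pair.reporter_channel, specks > 0, params
    )
    cells = dilate_nuclei(selected, params.dilation_radius_um, pair.pixel_size_um)
    positive, _ = link_targets(cells, specks)
    n_pos = len(positive)
    denom = n_total if params.denominator == "total" else n_total - n_rejected
    pct = percent_cells_with_specks(n_pos, denom) if denom > 0 else 0.0
    result = FieldResult(
        n_nuclei_total=n_total,
        n_nuclei_rejected_bright=n_rejected,
        n_nuclei_selected=n_total - n_rejected,
        n_cells_with_specks=n_pos,
        pct_cells_with_specks=pct,
    )
    if return_labels:
        return result, {"nuclei": nuclei, "cells": cells, "specks": specks}
    return result


def analyze_well(
    fields: Sequence[FieldImagePair],
    params: SegmentationParams | None = None,
    plate_id: str = "plate",
    well: str = "well",
) -> WellResult:
    """Analyze all fields of a well and pool counts before the percentage.

    Fields with zero nuclei are excluded from pooling (and logged); if
    every field has zero nuclei the well is undefined and an error names
    it.
    """
    if not fields:
        raise ImagingError(f"analyze_well: no fields for {plate_id}/{well}")
    params = params or SegmentationParams()
    used, results = 0, []
    for i, pair in enumerate(fields):
        res = analyze_field(pair, params)
        if res.n_nuclei_total == 0:
            logger.warning("field %d of %s/%s has zero nuclei; excluded", i, plate_id, well)
            continue
        used += 1
        results.append(res)
    if not results:
        raise ImagingError(f"analyze_well: all fields of {plate_id}/{well} have zero nuclei")
    return pool_field_results(results, params, plate_id, well)


def pool_field_results(
    field_results: Sequence[FieldResult],
    params: SegmentationParams | None = None,
    plate_id: str = "plate",
    well: str = "well",
) -> WellResult:
    """Pool per-field counts into a well result (counts sum; percentage
    is recomputed from the pooled counts)."""
    params = params or SegmentationParams()
    tot = sum(r.n_nuclei_total for r in field_results)
    rej = sum(r.n_nuclei_rejected_bright for r in field_results)
    pos = sum(r.n_cells_with_specks for r in field_results)
    denom = tot if params.denominator == "total" else tot - rej
    return WellResult(
        plate_id=plate_id,
        well=well,
        n_fields=len(field_results),
        n_nuclei_total=tot,
        n_nuclei_rejected_bright=rej,
        n_nuclei_selected=tot - rej,
        n_cells_with_specks=pos,
        pct_cells_with_specks=percent_cells_with_specks(pos, denom, f"{plate_id}/{well}"),
    )
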