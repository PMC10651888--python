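"""smFISH image quantification: projection, masks, puncta, colocalization.

The workflow mirrors a manual confocal analysis: maximum-intensity projection
of each channel; the granule mask from pixels above a (manually set or Otsu)
threshold within the hand-drawn cell boundary; RNA puncta as 8-connected
components of pixels at least `fold_threshold` times the mean cell intensity,
discarding components smaller than `min_area_px`; the colocalization fraction
as the share of puncta whose centroid falls in the granule mask; and the
enrichment level

    E = (puncta px inside SG / SG area) / (puncta px outside SG / (cell - SG))

with an undefined flag when a denominator vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .io_core import GeometryError, ImageStack, SgcapError

logger = logging.getLogger("sgcap")


class DegenerateImageError(SgcapError):
    """Mean intensity is zero; the fold-threshold rule is undefined."""


@dataclass
class GranuleMask:
    """Binary granule (SG) mask within the cell."""

    mask: np.ndarray
    threshold: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class Punctum:
    pixels: np.ndarray  # (n, 2) row/col coordinates
    area: int
    centroid: tuple[float, float]


@dataclass
class PunctaSet:
    puncta: list[Punctum]
    fold_threshold: float
    min_area_px: int

    def __len__(self) -> int:
        return len(self.puncta)


@dataclass
class CellQuant:
    """Per-cell quantification summary."""

    n_puncta_total: int
    n_puncta_in_sg: int
    coloc_fraction: float  # NaN when no puncta
    pix_in: int
    pix_out: int
    a_sg: int
    a_cell: int
    enrichment_level: float  # NaN when undefined
    undefined_reason: str | None = None


def max_project(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Pixelwise maximum-intensity projection over z."""
    arr = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise SgcapError(f"need a non-empty (z, y, x) stack; got {arr.shape}")
    return arr.max(axis=0)


def make_masks(granule_mip: np.ndarray, cell_mask: np.ndarray,
               threshold: float | str = "auto") -> GranuleMask:
    """Granule mask: cell pixels whose intensity strictly exceeds threshold.

    threshold : a number (the study's manually determined mode) or "auto"
    (Otsu over the cell pixels).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if granule_mip.shape != cell_mask.shape:
        raise GeometryError("image and cell mask shapes differ")
    if not cell_mask.any():
        raise GeometryError("cell mask is empty (ROI outside image?)")
    if threshold == "auto":
        threshold = float(threshold_otsu(granule_mip[cell_mask]))
    mask = cell_mask & (granule_mip > float(threshold))
    return GranuleMask(mask=mask, threshold=float(threshold))


def detect_puncta(fish_mip: np.ndarray, cell_mask: np.ndarray,
                  fold_threshold: float = 2.0,
                  min_area_px: int = 12) -> PunctaSet:
    """Detect RNA puncta in the FISH projection.

    Candidate pixels are cell pixels with intensity >= fold_threshold times
    the mean intensity over the cell mask; 8-connected components smaller
    than min_area_px are discarded.  A QC warning is logged when a single
    component covers more than a quarter of the cell (e.g. a uniform image,
    where every pixel meets the >= rule).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if fish_mip.shape != cell_mask.shape:
        raise GeometryError("image and cell mask shapes differ")
    if not cell_mask.any():
        raise GeometryError("cell mask is empty")
    mean_int = float(fish_mip[cell_mask].mean())
    if mean_int <= 0:
        raise DegenerateImageError("mean cell intensity is zero")
    candidates = cell_mask & (fish_mip >= fold_threshold * mean_int)
    labeled = label(candidates, connectivity=2)
    puncta: list[Punctum] = []
    cell_area = int(cell_mask.sum())
    for region in regionprops(labeled):
        if region.area < min_area_px:
            continue
        if region.area > 0.25 * cell_area:
            logger.warning("QC: a single component covers %.0f%% of the cell",
                           100.0 * region.area / cell_area)
        puncta.append(Punctum(pixels=np.asarray(region.coords),
                              area=int(region.area),
                              centroid=(float(region.centroid[0]),
                                        float(region.centroid[1]))))
    return PunctaSet(puncta=puncta, fold_threshold=fold_threshold,
                     min_area_px=min_area_px)


def colocalization_fraction(puncta: PunctaSet, granule: GranuleMask,
                            rule: str = "centroid"
                            ) -> tuple[float, int, int]:
    """Fraction of puncta falling within the granule mask.

    rule="centroid": a punctum counts as inside iff its (rounded) centroid
    pixel lies in the mask; rule="any-overlap": iff any of its pixels does.
    Returns (fraction, n_in, n_total); fraction is NaN when there are no
    puncta.
    """
    n_total = len(puncta)
    if n_total == 0:
        return float("nan"), 0, 0
    mask = granule.mask
    n_in = 0
    for p in puncta.puncta:
        if rule == "centroid":
            r = int(round(p.centroid[0]))
            c = int(round(p.centroid[1]))
            r = min(max(r, 0), mask.shape[0] - 1)
            c = min(max(c, 0), mask.shape[1] - 1)
            inside = bool(mask[r, c])
        elif rule == "any-overlap":
            inside = bool(mask[p.pixels[:, 0], p.pixels[:, 1]].any())
        else:
            raise ValueError(f"unknown rule '{rule}'")
        n_in += inside
    return n_in / n_total, n_in, n_total


def enrichment_level_from_counts(pix_in: int, pix_out: int,
                                 a_sg: int, a_cell: int) -> float:
    """E from the four raw pixel counts; NaN when any denominator vanishes."""
    if a_sg <= 0 or a_cell <= a_sg or pix_out == 0:
        return float("nan")
    return (pix_in / a_sg) / (pix_out / (a_cell - a_sg))


def enrichment_level(puncta: PunctaSet, granule: GranuleMask,
                     cell_mask: np.ndarray) -> tuple[float, dict]:
    """Density-normalized RNA enrichment in the granule.

    E = (pix_in / a_sg) / (pix_out / (a_cell - a_sg)).  Undefined (NaN, with
    a reason) when the SG area is zero, covers the whole cell, or no puncta
    pixel lies outside the SG.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    a_sg = granule.area
    a_cell = int(cell_mask.sum())
    if puncta.puncta:
        coords = np.vstack([p.pixels for p in puncta.puncta])
        inside = granule.mask[coords[:, 0], coords[:, 1]]
        pix_in = int(inside.sum())
        pix_out = int((~inside).sum())
    else:
        pix_in = pix_out = 0
    detail = {"pix_in": pix_in, "pix_out": pix_out,
              "a_sg": a_sg, "a_cell": a_cell}
    if a_sg == 0:
        return float("nan"), {**detail, "reason": "granule mask empty"}
    if a_cell <= a_sg:
        return float("nan"), {**detail, "reason": "granule covers whole cell"}
    if pix_out == 0:
        return float("nan"), {**detail, "reason": "no puncta pixels outside SG"}
    e = enrichment_level_from_counts(pix_in, pix_out, a_sg, a_cell)
    return float(e), detail


def quantify_cell(granule_stack: ImageStack, fish_stack: ImageStack,
                  cell_mask: np.ndarray,
                  granule_threshold: float | str = "auto",
                  fold_threshold: float = 2.0,
                  min_area_px: int = 12,
                  coloc_rule: str = "centroid") -> CellQuant:
    """End-to-end quantification of one cell (both channels + ROI mask)."""
    granule_mip = max_project(granule_stack)
    fish_mip = max_project(fish_stack)
    granule = make_masks(granule_mip, cell_mask, granule_threshold)
    puncta = detect_puncta(fish_mip, cell_mask, fold_threshold, min_area_px)
    frac, n_in, n_total = colocalization_fraction(puncta, granule, coloc_rule)
    e, detail = enrichment_level(puncta, granule, cell_mask)
    return CellQuant(
        n_puncta_total=n_total, n_puncta_in_sg=n_in, coloc_fraction=frac,
        pix_in=detail["pix_in"], pix_out=detail["pix_out"],
        a_sg=detail["a_sg"], a_cell=detail["a_cell"],
        enrichment_level=e, undefined_reason=detail.get("reason"))
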