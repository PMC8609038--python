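"""Image quantification: colocalization, puncta detection, nuclear translocation.

Three small pipelines over 2-D single-channel arrays:

* :func:`pixel_pcc` — pixelwise Pearson correlation between two channels
  (colocalization), reported both as r and r².
* :func:`detect_aggregates` — Gaussian blur → white top-hat (disk structuring
  element) → adaptive threshold → 8-connected labeling → area filter. The
  top-hat (image minus its morphological opening) isolates bright structures
  smaller than the structuring element, i.e. puncta.
* :func:`tfeb_translocation` — nuclei segmented from a DAPI channel (Otsu →
  fill → watershed split → size filter); the cytosol of each cell is a fixed-
  width annulus around its nucleus, contested pixels going to the nearest
  nucleus; readout is mean(nuclear)/mean(cytosolic) intensity per cell.

Plus :func:`puncta_area_fraction` — puncta area over cell area, the
broken-vesicle (galectin-3) readout.

Coordinates are 0-based (row, col); areas are px² (no physical calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

from .errors import ParameterError, UndefinedValueError


@dataclass(frozen=True)
class DetectionParams:
    """Puncta-detection parameters.

    ``threshold_k`` sets the binarization cut at mean + k·SD of the filtered
    image (offset-adaptive: immune to global additive shifts); an
    ``absolute_threshold`` overrides it. Areas outside
    ``[min_area, max_area]`` px² are discarded.
    """

    sigma: float = 1.0
    tophat_radius: int = 5
    threshold_k: float = 3.0
    absolute_threshold: float | None = None
    min_area: int = 4
    max_area: int = 10_000

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"gaussian sigma must be > 0, got {self.sigma}")
        if self.tophat_radius <= 0:
            raise ParameterError(f"top-hat radius must be > 0, got {self.tophat_radius}")
        if self.min_area < 0 or self.max_area < self.min_area:
            raise ParameterError("need 0 <= min_area <= max_area")


@dataclass(frozen=True)
class ColocResult:
    r: float
    r_squared: float
    n_pixels_used: int
    mask_description: str = "all pixels"


@dataclass
class ObjectSet:
    """Detected objects: one row per object (area, centroid, mean intensity)."""

    table: pd.DataFrame
    params: DetectionParams
    image_id: str | None = None
    label_image: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def total_area(self) -> float:
        return float(self.table["area"].sum()) if len(self.table) else 0.0


@dataclass
class CellPartition:
    """Per-cell nuclear/cytosolic means and their ratio.

    ``table`` has one row per cell: ``cell, nuclear_mean, cyto_mean, ratio,
    excluded``; cells with zero cytosolic mean are excluded from
    ``mean_ratio`` and flagged. ``nuclei_labels``/``cyto_labels`` are label
    images (0 = background) with disjoint nuclear and cytosolic masks.
    """

    table: pd.DataFrame
    mean_ratio: float
    nuclei_labels: np.ndarray = field(repr=False)
    cyto_labels: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.table)


def pixel_pcc(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> ColocResult:
    """Pixelwise Pearson correlation between two channels.

    Optionally restricted to a boolean ``mask`` of the same shape. Raises if
    either channel is constant within the mask (correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise UndefinedValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    desc = "all pixels"
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise UndefinedValueError("mask shape must match the channels")
        a, b = a[mask], b[mask]
        desc = f"mask ({a.size} px)"
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedValueError(
            "correlation undefined: constant channel or < 2 pixels in mask"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocResult(r=r, r_squared=r * r, n_pixels_used=int(a.size), mask_description=desc)


def foreground_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Union of pixels above each channel's Otsu background cut."""
    return (a > filters.threshold_otsu(a)) | (b > filters.threshold_otsu(b))


def detect_aggregates(
    img: np.ndarray,
    params: DetectionParams | None = None,
    image_id: str | None = None,
) -> ObjectSet:
    """Detect bright puncta in a single-channel image.

    Pipeline: Gaussian blur → white top-hat with a disk structuring element →
    binarize at mean + k·SD of the filtered image (or an absolute cut) →
    8-connected component labeling → area filter. Mean intensity is measured
    on the original image.
    """
    params = params or DetectionParams()
    params.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ParameterError(f"expected a 2-D single-channel image, got ndim={img.ndim}")

    blurred = filters.gaussian(img, sigma=params.sigma, preserve_range=True)
    footprint = morphology.disk(params.tophat_radius)
    tophat = morphology.white_tophat(blurred, footprint=footprint)

    if params.absolute_threshold is not None:
        cut = params.absolute_threshold
    else:
        cut = tophat.mean() + params.threshold_k * tophat.std()
    binary = tophat > cut
    labels = measure.label(binary, connectivity=2)

    if labels.max() == 0:
        table = pd.DataFrame(
            columns=["label", "area", "centroid_row", "centroid_col", "mean_intensity"]
        )
        return ObjectSet(table=table, params=params, image_id=image_id, label_image=labels)

    props = measure.regionprops_table(
        labels, intensity_image=img,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    table = pd.DataFrame(props).rename(
        columns={
            "centroid-0": "centroid_row",
            "centroid-1": "centroid_col",
            "intensity_mean": "mean_intensity",
        }
    )
    keep = (table["area"] >= params.min_area) & (table["area"] <= params.max_area)
    dropped = set(table.loc[~keep, "label"].astype(int))
    table = table.loc[keep].reset_index(drop=True)
    if dropped:
        labels = np.where(np.isin(labels, list(dropped)), 0, labels)
    return ObjectSet(table=table, params=params, image_id=image_id, label_image=labels)


def aggregate_timecourse(
    stack: Sequence[np.ndarray], params: DetectionParams | None = None
) -> list[int]:
    """Puncta count per frame of a live-imaging series, fixed parameters."""
    frames = list(stack)
    if not frames:
        raise ParameterError("empty image stack")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ParameterError(f"frames have mixed shapes: {sorted(shapes)}")
    return [len(detect_aggregates(f, params)) for f in frames]


@dataclass(frozen=True)
class TranslocationParams:
    """Nucleus segmentation and cytosol-annulus parameters."""

    min_nucleus_area: int = 50
    annulus_width: int = 5
    watershed_min_distance: int = 10

    def validate(self) -> None:
        if self.min_nucleus_area < 1 or self.annulus_width < 1:
            raise ParameterError("min_nucleus_area and annulus_width must be >= 1")


def segment_nuclei(dapi: np.ndarray, params: TranslocationParams | None = None) -> np.ndarray:
    """Label image of nuclei from a DAPI channel.

    Global Otsu threshold → hole filling → distance-transform watershed to
    split touching nuclei → minimum-area filter.
    """
    params = params or TranslocationParams()
    params.validate()
    dapi = np.asarray(dapi, dtype=float)
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=int)
    binary = ndi.binary_fill_holes(dapi > filters.threshold_otsu(dapi))
    if not binary.any():
        return np.zeros(dapi.shape, dtype=int)
    distance = ndi.distance_transform_edt(binary)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance, min_distance=params.watershed_min_distance, labels=binary
    )
    markers = np.zeros(dapi.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=binary)
    # drop undersized fragments, then relabel densely
    for region in measure.regionprops(labels):
        if region.area < params.min_nucleus_area:
            labels[labels == region.label] = 0
    return measure.label(labels > 0, connectivity=2) if labels.max() else labels


def tfeb_translocation(
    dapi: np.ndarray,
    tfeb: np.ndarray,
    params: TranslocationParams | None = None,
) -> CellPartition:
    """Nuclear:cytosolic intensity ratio per cell.

    Cells are found from the DAPI channel; each cell's cytosol is the annulus
    of ``annulus_width`` px around its nucleus, excluding all nuclei, with
    contested pixels assigned to the nearest nucleus. The population readout
    is the arithmetic mean of per-cell ratios.
    """
    params = params or TranslocationParams()
    dapi = np.asarray(dapi, dtype=float)
    tfeb = np.asarray(tfeb, dtype=float)
    if dapi.shape != tfeb.shape:
        raise UndefinedValueError("DAPI and TFEB shapes must match")

    nuclei = segment_nuclei(dapi, params)
    if nuclei.max() == 0:
        warnings.warn("no nuclei detected; empty translocation result", stacklevel=2)
        empty = pd.DataFrame(columns=["cell", "nuclear_mean", "cyto_mean", "ratio", "excluded"])
        return CellPartition(table=empty, mean_ratio=float("nan"),
                             nuclei_labels=nuclei, cyto_labels=nuclei.copy())

    expanded = segmentation.expand_labels(nuclei, distance=params.annulus_width)
    cyto = np.where(nuclei > 0, 0, expanded)

    rows = []
    for cell in range(1, nuclei.max() + 1):
        nuc_mask = nuclei == cell
        cyt_mask = cyto == cell
        nuc_mean = float(tfeb[nuc_mask].mean())
        cyt_mean = float(tfeb[cyt_mask].mean()) if cyt_mask.any() else 0.0
        excluded = cyt_mean == 0.0
        rows.append(
            {
                "cell": cell,
                "nuclear_mean": nuc_mean,
                "cyto_mean": cyt_mean,
                "ratio": np.nan if excluded else nuc_mean / cyt_mean,
                "excluded": excluded,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.loc[~table["excluded"], "ratio"]
    mean_ratio = float(valid.mean()) if len(valid) else float("nan")
    return CellPartition(table=table, mean_ratio=mean_ratio,
                         nuclei_labels=nuclei, cyto_labels=cyto)


def puncta_area_fraction(
    gal3: np.ndarray,
    cell_mask: np.ndarray,
    params: DetectionParams | None = None,
) -> float:
    """Fraction of cell area covered by detected puncta, in [0, 1].

    Detects puncta in the full channel, then counts detected-object pixels
    inside ``cell_mask`` over the mask area — the broken-vesicle readout.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    mask_area = int(cell_mask.sum())
    if mask_area == 0:
        raise UndefinedValueError("empty cell mask")
    objects = detect_aggregates(np.asarray(gal3, dtype=float), params)
    if objects.label_image is None or objects.label_image.max() == 0:
        return 0.0
    puncta_px = int(((objects.label_image > 0) & cell_mask).sum())
    return puncta_px / mask_area
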