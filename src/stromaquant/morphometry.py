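"""Calibrated 2D image morphometry.

Implements the quantities read off thresholded microscopy images:

* collagen fraction — percentage of bright (collagenous) pixels in a region
  of interest of an SHG image, 100·Nc/(Nc+Nb);
* nuclei counting — connected components of the thresholded DAPI channel,
  8-connectivity, small specks removed by a minimum-area filter;
* protein area per cell — thresholded fluorescent-signal area in µm²
  divided by the nuclei count;
* micro-tissue diameter — equivalent circular diameter of the largest
  object in an optical image.

Thresholds default to Otsu's method; a fixed intensity value can be passed
instead, and the threshold actually applied is always reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .io import CalibratedImage

Threshold = float | str  # a fixed intensity value, or the string "otsu"


def _resolve_threshold(values: np.ndarray, threshold: Threshold) -> float:
    """Return the intensity cut to apply; pixels strictly above are bright."""
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(values) == 0:
            raise ValueError(
                "Otsu threshold is degenerate on a constant image; "
                "pass a fixed threshold instead"
            )
        return float(threshold_otsu(values))
    return float(threshold)


@dataclass
class ThresholdedROI:
    """Bright/dark pixel bookkeeping for one thresholded region of interest."""

    mask: np.ndarray          # boolean, True where bright inside the ROI
    n_bright: int             # Nc: collagenous pixels
    n_dark: int               # Nb: non-collagenous pixels
    threshold_used: float
    roi_definition: str = "full image"

    def __post_init__(self) -> None:
        if self.n_bright < 0 or self.n_dark < 0:
            raise ValueError("pixel counts must be non-negative")


def collagen_fraction(
    img: CalibratedImage,
    roi: np.ndarray | None = None,
    threshold: Threshold = "otsu",
    exclusion_mask: np.ndarray | None = None,
) -> tuple[float, ThresholdedROI]:
    """Bright-pixel percentage 100·Nc/(Nc+Nb) inside a region of interest.

    Parameters
    ----------
    img
        Calibrated SHG (or other single-channel) image.
    roi
        Boolean mask selecting the region of interest; default full image.
    threshold
        ``"otsu"`` or a fixed intensity value; pixels strictly above the cut
        count as collagenous.
    exclusion_mask
        Boolean mask of pixels to drop from the ROI (e.g. the micro-scaffold
        signal, which must not count as matrix).

    Returns
    -------
    (fraction, roi_record)
        The percentage in [0, 100] and the bookkeeping record with Nc, Nb
        and the threshold actually applied.
    """
    data = img.data
    sel = np.ones(data.shape, dtype=bool) if roi is None else np.asarray(roi, bool)
    if sel.shape != data.shape:
        raise ValueError("ROI shape does not match image shape")
    provenance = "full image" if roi is None else "user ROI"
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, bool)
        if excl.shape != data.shape:
            raise ValueError("exclusion mask shape does not match image shape")
        sel = sel & ~excl
        provenance += " minus exclusion mask"
    if not sel.any():
        raise ValueError("ROI is empty after applying the exclusion mask")

    cut = _resolve_threshold(data[sel], threshold)
    bright = (data > cut) & sel
    nc = int(bright.sum())
    nb = int(sel.sum()) - nc
    record = ThresholdedROI(
        mask=bright, n_bright=nc, n_dark=nb,
        threshold_used=cut, roi_definition=provenance,
    )
    return 100.0 * nc / (nc + nb), record


def count_nuclei(
    img: CalibratedImage,
    threshold: Threshold = "otsu",
    min_area: int = 20,
) -> int:
    """Count nuclei as 8-connected components of the thresholded image.

    Components smaller than ``min_area`` px² are discarded as noise specks.
    Touching nuclei merge into one component (no watershed separation).
    A blank image returns 0.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    data = img.data
    if np.ptp(data) == 0:
        return 0
    cut = _resolve_threshold(data, threshold)
    mask = data > cut
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())


def protein_area_per_cell(
    protein_img: CalibratedImage,
    nuclei_count: int,
    threshold: Threshold = "otsu",
) -> float:
    """Thresholded fluorescent-signal area divided by the cell count, µm²/cell."""
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1 (division by zero cells is undefined)")
    cut = _resolve_threshold(protein_img.data, threshold)
    bright_px = int((protein_img.data > cut).sum())
    return bright_px * protein_img.pixel_area / nuclei_count


def microtissue_diameter(
    optical_img: CalibratedImage,
    threshold: Threshold = "otsu",
    method: str = "equivalent",
) -> float:
    """Diameter in µm of the largest object in an optical image.

    ``method="equivalent"`` (default) reports the equivalent circular
    diameter 2·√(A/π) of the largest connected component, appropriate for
    near-spherical micro-tissues; ``method="feret"`` reports the maximum
    Feret (caliper) diameter instead.
    """
    cut = _resolve_threshold(optical_img.data, threshold)
    mask = optical_img.data > cut
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no object found above the threshold")
    props = max(regionprops(labels), key=lambda p: p.area)
    if method == "equivalent":
        d_px = 2.0 * math.sqrt(props.area / math.pi)
    elif method == "feret":
        d_px = props.feret_diameter_max
    else:
        raise ValueError(f"unknown diameter method {method!r}")
    return d_px * optical_img.pixel_size


def aggregate_per_sample(values) -> tuple[float, float | None]:
    """Mean and sample standard deviation (n−1) over replicate image values.

    With a single value the SD is undefined and returned as ``None``,
    never 0.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("at least one value is required")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return mean, sd
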