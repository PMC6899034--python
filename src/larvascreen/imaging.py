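"""Well-image quantification: segmentation, morphometry, artifact flagging.

The readout of the growth assay is total organism area per well (plus
object count for the fly screen, where area is normalized per larva).
Segmentation is deliberately simple — wells are uniformly illuminated:

1. global automatic threshold (Otsu on the intensity histogram, hence
   invariant to positive rescaling of the image);
2. morphological opening (diamond footprint, configurable radius) to
   drop speckle;
3. removal of components below ``min_object_px``;
4. labeling with 8-connectivity so elongated diagonal larvae stay whole.

Artifact flagging is an automated proxy for manual well curation: wells
with an implausibly large single object, implausible total area, or
foreground hugging the image border (debris / contamination) are
excluded from hit calling rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import diamond, opening

from .config import SegmentationConfig


@dataclass
class WellMeasurement:
    """Morphometric summary of one well."""

    well_id: str
    total_area: float
    object_count: int
    normalized_area: float | None = None
    artifact: bool = False
    artifact_reason: str | None = None


def segment_well(
    image: np.ndarray, params: SegmentationConfig | None = None
) -> np.ndarray:
    """Segment a grayscale well image into a labeled foreground mask.

    Returns an int label image (0 = background). A constant image yields
    an empty mask, not an error.
    """
    params = params or SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("well image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("well image contains non-finite intensities")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=int)
    thr = threshold_otsu(img)
    mask = img > thr
    if params.opening_radius > 0:
        mask = opening(mask, diamond(params.opening_radius))
    labels = label(mask, connectivity=2)
    if params.min_object_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < params.min_object_px)
        labels[np.isin(labels, small[small > 0])] = 0
        labels = label(labels > 0, connectivity=2)
    return labels


def measure_well(
    mask: np.ndarray, pixel_size: float = 1.0, well_id: str = ""
) -> WellMeasurement:
    """Total foreground area (AU) and component count from a label mask."""
    labels = np.asarray(mask)
    fg = labels > 0
    return WellMeasurement(
        well_id=well_id,
        total_area=float(fg.sum()) * pixel_size,
        object_count=int(labels.max()) if fg.any() else 0,
    )


def normalize_by_count(measurement: WellMeasurement) -> WellMeasurement:
    """Per-animal area normalization (fly mode); zero-count wells are
    artifact-flagged ``no_animals`` instead of failing."""
    if measurement.object_count > 0:
        measurement.normalized_area = measurement.total_area / measurement.object_count
    else:
        measurement.normalized_area = None
        measurement.artifact = True
        measurement.artifact_reason = "no_animals"
    return measurement


def flag_artifact(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    rules: SegmentationConfig | None = None,
) -> tuple[bool, str | None]:
    """Apply artifact rules to a segmented well; returns (flagged, reason)."""
    rules = rules or SegmentationConfig()
    labels = np.asarray(mask)
    fg = labels > 0
    if fg.any():
        sizes = np.bincount(labels.ravel())[1:]
        if sizes.max() > rules.max_object_factor * rules.expected_animal_px:
            return True, "oversized_object"
    if fg.sum() > rules.max_total_area_fraction * fg.size:
        return True, "implausible_total_area"
    border = np.concatenate([fg[0, :], fg[-1, :], fg[1:-1, 0], fg[1:-1, -1]])
    if border.size and border.mean() > rules.max_border_fraction:
        return True, "border_debris"
    return False, None


def quantify_image(
    image: np.ndarray,
    well_id: str = "",
    params: SegmentationConfig | None = None,
    pixel_size: float = 1.0,
    count_normalize: bool = False,
) -> WellMeasurement:
    """Full per-well path: segment, measure, artifact-flag, optionally
    normalize area by animal count."""
    params = params or SegmentationConfig()
    labels = segment_well(image, params)
    m = measure_well(labels, pixel_size=pixel_size, well_id=well_id)
    flagged, reason = flag_artifact(labels, image, params)
    if flagged:
        m.artifact, m.artifact_reason = True, reason
    if count_normalize:
        m = normalize_by_count(m)
    return m


def overlay(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """QC overlay: foreground painted blue over the grayscale image.

    Returns an (H, W, 3) float array in [0, 1]; purely diagnostic.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([gray, gray, gray], axis=-1)
    fg = np.asarray(mask) > 0
    rgb[fg] = [0.1, 0.3, 1.0]
    return rgb


def quantify_image_dir(
    images_dir: str | Path,
    layout: pd.DataFrame,
    params: SegmentationConfig | None = None,
    count_normalize: bool = False,
) -> pd.DataFrame:
    """Quantify ``images/<plate>/<well>.tiff`` (or ``.png``) trees into a
    measurement table matching the layout's non-empty wells."""
    import imageio.v3 as iio

    params = params or SegmentationConfig()
    records = []
    for (plate_id,), plate_layout in layout.groupby(["plate_id"]):
        plate_dir = Path(images_dir) / str(plate_id)
        for well in plate_layout.loc[plate_layout.role != "empty", "well"]:
            path = None
            for ext in (".tiff", ".tif", ".png"):
                cand = plate_dir / f"{well}{ext}"
                if cand.exists():
                    path = cand
                    break
            if path is None:
                continue
            img = iio.imread(path)
            m = quantify_image(
                img, well_id=well, params=params, count_normalize=count_normalize
            )
            records.append({
                "plate_id": plate_id, "well": well,
                "total_area": m.total_area, "object_count": m.object_count,
                "normalized_area": m.normalized_area,
                "artifact": m.artifact, "artifact_reason": m.artifact_reason,
            })
    return pd.DataFrame.from_records(records)
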