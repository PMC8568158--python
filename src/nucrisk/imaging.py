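"""Optical-density conversion and nucleus segmentation.

Feulgen-thionin staining is stoichiometric for DNA, so the per-pixel optical
density OD = -log10(I / I_bg) is proportional to the local DNA amount and its
sum over a nucleus (IOD) to the nuclear DNA content.  This module estimates
the background (white) level of a tile, converts intensities to OD, segments
candidate nuclei by OD thresholding + distance-transform watershed, and crops
each labelled object into a :class:`~nucrisk.qnp.NuclearObject`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure, segmentation

from .qnp import NuclearObject, object_from_mask

OD_MAX_DEFAULT = 3.0  # 8-bit dynamic range: -log10(1/255) ~ 2.4 < 3


@dataclass
class ODImage:
    od: np.ndarray  # per-pixel optical density, in [0, od_max]
    pixel_size: float  # um / pixel
    background_intensity: float
    od_max: float = OD_MAX_DEFAULT


@dataclass
class ROIManifest:
    """ROI metadata linking tiles to patients; polygon in slide pixel
    coordinates (list of [row, col], half-open pixel convention)."""

    roi_id: str
    patient_id: str
    polygon: list
    depth_stratum: str = "mid"
    tile: str = ""

    def __post_init__(self) -> None:
        poly = Polygon([(c, r) for r, c in self.polygon])
        if not poly.is_valid:
            raise ValueError(f"ROI {self.roi_id}: polygon is not simple")
        self._shape = poly

    def contains(self, row: float, col: float) -> bool:
        return self._shape.covers(Point(col, row))


def load_manifest(path: str | Path) -> tuple[list[ROIManifest], dict]:
    data = json.loads(Path(path).read_text())
    rois = [
        ROIManifest(
            roi_id=r["roi_id"], patient_id=r["patient_id"], polygon=r["polygon"],
            depth_stratum=r.get("depth_stratum", "mid"), tile=r.get("tile", ""),
        )
        for r in data["rois"]
    ]
    return rois, {k: v for k, v in data.items() if k != "rois"}


@dataclass
class SegmentationParams:
    # half the diploid mean OD: thresholding a blurred object profile at its
    # half-maximum recovers the true boundary with minimal area bias
    od_threshold: float = 0.25
    min_area: int = 50  # px
    max_area: int = 20000  # px
    min_distance: int = 7  # watershed seed separation, px
    smoothing_sigma: float = 1.0


def estimate_background(image: np.ndarray) -> float:
    """Background (white) level: the mode of the upper intensity quartile.

    Raises on an all-zero image (no background to normalize against)."""
    if image.size == 0:
        raise ValueError("empty image")
    vals = np.asarray(image).ravel()
    if not (vals > 0).any():
        raise ValueError("no background: image is all zero")
    q3 = np.quantile(vals, 0.75)
    upper = vals[vals >= q3].astype(int)
    counts = np.bincount(upper)
    return float(np.argmax(counts))


def to_optical_density(
    image: np.ndarray, background: float, od_max: float = OD_MAX_DEFAULT, pixel_size: float = 1.0
) -> ODImage:
    """Per-pixel OD = -log10(I / background), clipped to [0, od_max];
    zero intensity maps to od_max."""
    if background <= 0:
        raise ValueError("background must be positive")
    img = np.asarray(image, dtype=float)
    with np.errstate(divide="ignore"):
        od = -np.log10(np.where(img > 0, img, np.nan) / background)
    od = np.where(np.isnan(od), od_max, od)
    od = np.clip(od, 0.0, od_max)
    return ODImage(od=od, pixel_size=pixel_size, background_intensity=float(background), od_max=od_max)


def od_to_intensity(od_image: ODImage) -> np.ndarray:
    """Inverse OD transform (round-trips within 1 grey level up to clipping)."""
    return od_image.background_intensity * np.power(10.0, -od_image.od)


def segment_nuclei(od_image: ODImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Label mask of candidate nuclei (0 = background, labels contiguous from 1).

    OD is smoothed and thresholded; holes filled; touching objects split by a
    distance-transform watershed seeded at local maxima; objects outside the
    configured area bounds are removed.  Deterministic for fixed params."""
    params = params or SegmentationParams()
    od = ndimage.gaussian_filter(od_image.od, params.smoothing_sigma)
    binary = ndimage.binary_fill_holes(od > params.od_threshold)
    if not binary.any():
        return np.zeros(od.shape, np.int32)

    distance = ndimage.distance_transform_edt(binary)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance, min_distance=params.min_distance, labels=ndimage.label(binary)[0]
    )
    seeds = np.zeros(od.shape, np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        labels = ndimage.label(binary)[0]
    else:
        labels = segmentation.watershed(-distance, seeds, mask=binary)

    # area filter + relabel contiguously
    out = np.zeros_like(labels, np.int32)
    next_label = 1
    for region in measure.regionprops(labels):
        if params.min_area <= region.area <= params.max_area:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def extract_objects(
    od_image: ODImage,
    label_mask: np.ndarray,
    patient_id: str = "",
    roi_id: str = "",
    origin: tuple[int, int] = (0, 0),
    min_area: int = 10,
    border_margin: int = 0,
) -> tuple[list[NuclearObject], pd.DataFrame]:
    """Crop one :class:`NuclearObject` per label.

    Objects touching the tile border within ``border_margin`` are flagged
    'border' and excluded (a tile-overlap margin makes them another tile's
    responsibility); sub-``min_area`` labels are excluded.  Both are counted
    in the returned rejection log."""
    if label_mask.shape != od_image.od.shape:
        raise ValueError("label mask and OD image shapes differ")
    h, w = label_mask.shape
    objects: list[NuclearObject] = []
    rejected = []
    for region in measure.regionprops(label_mask, intensity_image=od_image.od):
        r0, c0, r1, c1 = region.bbox
        oid = f"{roi_id}_L{region.label:04d}"
        if region.area < min_area:
            rejected.append((oid, "min_area"))
            continue
        if r0 <= border_margin or c0 <= border_margin or r1 >= h - border_margin or c1 >= w - border_margin:
            rejected.append((oid, "border"))
            continue
        pad = 2
        rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
        rr1, cc1 = min(r1 + pad, h), min(c1 + pad, w)
        mask = label_mask[rr0:rr1, cc0:cc1] == region.label
        od_patch = np.where(mask, od_image.od[rr0:rr1, cc0:cc1], 0.0)
        obj = object_from_mask(
            mask, od_patch, pixel_size=od_image.pixel_size,
            object_id=oid, patient_id=patient_id, roi_id=roi_id,
        )
        cy, cx = obj.centroid
        obj.centroid = (cy + rr0 + origin[0], cx + cc0 + origin[1])
        objects.append(obj)
    log = pd.DataFrame(rejected, columns=["object_id", "reason"])
    return objects, log
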