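"""Glial immunostain quantification.

Line-profile intensities over an AAV-expressing region, watershed
particle counting with per-marker minimum sizes (5 px² for Iba1,
10 px² for GFAP), expression indices (count/area × 10,000),
four-section per-animal averages, and per-cell multichannel
co-expression correlation on z-scored intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

MIN_SIZE_IBA1_PX2 = 5
MIN_SIZE_GFAP_PX2 = 10
EXPRESSION_INDEX_SCALE = 10_000.0


@dataclass
class LineProfile:
    positions_px: np.ndarray
    intensities: np.ndarray


def line_profile(image: np.ndarray, start_px: tuple[float, float],
                 angle_deg: float, length_px: int) -> LineProfile:
    """Bilinear-sampled intensities along a fixed-length line.

    ``start_px`` is (row, col); the line runs ``length_px`` samples at
    unit-pixel spacing along ``angle_deg`` (0° = +col).  Raises when
    the line exits the image.
    """
    image = np.asarray(image, dtype=float)
    if length_px <= 0:
        raise ValueError("line length must be positive")
    theta = np.deg2rad(angle_deg)
    t = np.arange(length_px, dtype=float)
    rr = start_px[0] + t * np.sin(theta)
    cc = start_px[1] + t * np.cos(theta)
    if (rr.min() < 0 or cc.min() < 0 or rr.max() > image.shape[0] - 1
            or cc.max() > image.shape[1] - 1):
        raise ValueError("line exits the image")
    vals = ndimage.map_coordinates(image, np.stack([rr, cc]), order=1)
    return LineProfile(positions_px=t, intensities=vals)


@dataclass
class ParticleResult:
    count: int
    labels: np.ndarray
    per_particle_area_px2: list[int]
    threshold_used: float
    min_size_px2: int


def count_particles(
    image: np.ndarray,
    threshold: float | None = None,
    min_size_px2: int = MIN_SIZE_IBA1_PX2,
    *,
    watershed_min_distance_px: int = 3,
) -> ParticleResult:
    """Threshold, binarize, watershed-split and size-filter cells.

    ``threshold=None`` uses Otsu's threshold as a reproducible stand-in
    for manual thresholding.  Touching cells are separated by a
    watershed on the distance transform; objects smaller than
    ``min_size_px2`` are dropped (area ≥ min kept).
    """
    image = np.asarray(image, dtype=float)
    if image.max() == image.min():
        return ParticleResult(count=0, labels=np.zeros(image.shape, int),
                              per_particle_area_px2=[],
                              threshold_used=float(image.max()),
                              min_size_px2=min_size_px2)
    thr = float(threshold) if threshold is not None else float(
        threshold_otsu(image))
    binary = image >= thr
    if not binary.any():
        return ParticleResult(count=0, labels=np.zeros(image.shape, int),
                              per_particle_area_px2=[], threshold_used=thr,
                              min_size_px2=min_size_px2)
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=watershed_min_distance_px,
                           labels=binary, exclude_border=False)
    markers = np.zeros(image.shape, dtype=int)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        labels, _ = ndimage.label(binary)
    else:
        labels = watershed(-dist, markers, mask=binary)
    keep = remove_small_objects(labels > 0, max_size=min_size_px2 - 1) \
        if min_size_px2 > 1 else labels > 0
    labels = labels * keep
    # renumber surviving labels contiguously
    ids = np.unique(labels)
    ids = ids[ids > 0]
    areas = []
    out = np.zeros_like(labels)
    for k, lab in enumerate(ids, start=1):
        sel = labels == lab
        area = int(sel.sum())
        if area < min_size_px2:
            continue
        out[sel] = k
        areas.append(area)
    return ParticleResult(count=len(areas), labels=out,
                          per_particle_area_px2=areas, threshold_used=thr,
                          min_size_px2=min_size_px2)


def expression_index(count: int, area_px2: float) -> float:
    """Positive cells per ROI area, scaled: count / area × 10,000."""
    if area_px2 <= 0:
        raise ValueError("ROI area must be positive")
    return count / area_px2 * EXPRESSION_INDEX_SCALE


def animal_average(section_values: "list[float] | np.ndarray") -> float:
    """Per-animal mean over (typically four) coronal sections."""
    vals = np.asarray(section_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no section values")
    return float(vals.mean())


def coexpression_correlation(per_cell_intensities: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations across cells on z-scored channels.

    ``per_cell_intensities`` is (n_cells, n_channels); each channel is
    z-scored across cells before correlating.  The returned matrix is
    symmetric with a unit diagonal.
    """
    x = np.asarray(per_cell_intensities, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 cells and >= 2 channels")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance channel")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(z, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r
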