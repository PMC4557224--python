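"""From RGB IHC images to labelled centroids.

The processing chain mirrors routine brightfield IHC analysis:

1. colour deconvolution of the RGB image into DAB (brown) and
   hematoxylin (blue) optical-density channels (Ruifrok-Johnston
   unmixing with the standard H-DAB stain matrix);
2. nucleus/particle segmentation of a density channel: Otsu threshold,
   small-object removal, and a distance-transform watershed to separate
   touching blobs;
3. centroid extraction (one representative pixel per object);
4. stained / non-stained classification of centroids by their Euclidean
   distance to the nearest immunostained (brown) pixel.

Images must be registered beforehand when they come from serial
sections; this module performs no registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hdx_from_rgb, separate_stains
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import ShapeMismatchError
from .points import PointSet

__all__ = [
    "ChannelPair",
    "PointSet",
    "colour_deconvolve",
    "segment_nuclei",
    "extract_centroids",
    "classify_stained",
    "stained_mask",
    "detect_cells",
]


@dataclass
class ChannelPair:
    """Brown (DAB) and blue (hematoxylin) density channels."""

    brown: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        if self.brown.shape != self.blue.shape:
            raise ShapeMismatchError("channel shapes differ")


def colour_deconvolve(rgb: np.ndarray) -> ChannelPair:
    """Unmix an RGB brightfield image into DAB and hematoxylin densities.

    Accepts uint8 (0-255) or float (0-1) input.  Negative unmixed
    densities (numerical artefacts of the matrix inversion) are clipped
    to zero, so both channels are finite and non-negative.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    if rgb.dtype != np.float64 and rgb.dtype != np.float32:
        rgb = rgb.astype(np.float64) / 255.0
    stains = separate_stains(rgb, hdx_from_rgb)
    blue = np.clip(stains[..., 0], 0.0, None)
    brown = np.clip(stains[..., 1], 0.0, None)
    return ChannelPair(brown=brown, blue=blue)


def segment_nuclei(
    channel: np.ndarray,
    min_size: int = 5,
    min_peak_distance: int = 5,
) -> np.ndarray:
    """Label blobs in a density channel, splitting touching ones.

    Thresholds at the Otsu level, removes specks below ``min_size``
    pixels and applies a distance-transform watershed seeded at local
    maxima at least ``min_peak_distance`` apart (ties resolved in
    row-major order by the peak finder).  Returns an integer label
    image; a blank channel yields an all-zero labelling.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(channel)) or channel.min() < 0:
        raise ValueError("channel must be finite and non-negative")
    if channel.max() == 0:
        return np.zeros(channel.shape, dtype=np.int32)
    mask = channel > threshold_otsu(channel)
    comp, n_comp = ndimage.label(mask)
    if n_comp:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        mask = sizes[comp] >= min_size
    if not mask.any():
        return np.zeros(channel.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=mask, exclude_border=False
    )
    seeds = np.zeros(channel.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        labels, _ = ndimage.label(mask)
        return labels.astype(np.int32)
    return watershed(-dist, seeds, mask=mask).astype(np.int32)


def extract_centroids(labels: np.ndarray) -> PointSet:
    """One centroid per label, at the rounded mean pixel coordinate.

    All centroids start as non-stained; run :func:`classify_stained`
    afterwards.
    """
    labels = np.asarray(labels)
    coords = []
    for prop in regionprops(labels):
        r, c = prop.centroid
        coords.append((int(round(r)), int(round(c))))
    # rounding can in principle collapse two adjacent centroids; keep unique
    coords = list(dict.fromkeys(coords))
    return PointSet.from_coords(coords, labels.shape)


def classify_stained(
    centroids: PointSet, stained: np.ndarray, max_dist: float = 5.0
) -> PointSet:
    """Flag centroids within ``max_dist`` pixels of a stained area.

    ``stained`` is a binary mask of immunoperoxidase-positive pixels;
    the distance is the Euclidean distance to the nearest positive
    pixel (0 inside the mask).
    """
    stained = np.asarray(stained).astype(bool)
    if stained.shape != centroids.source_shape:
        raise ShapeMismatchError("mask shape must equal the centroid source shape")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not stained.any():
        flags = np.zeros(len(centroids), dtype=bool)
    else:
        dist = ndimage.distance_transform_edt(~stained)
        flags = dist[centroids.rows, centroids.cols] <= max_dist
    return PointSet(centroids.rows, centroids.cols, flags, centroids.source_shape)


def stained_mask(channels: ChannelPair) -> np.ndarray:
    """Binary mask of immunostained (brown) area via Otsu on the DAB channel."""
    brown = channels.brown
    if brown.max() == 0:
        return np.zeros(brown.shape, dtype=np.uint8)
    return (brown > threshold_otsu(brown)).astype(np.uint8)


def detect_cells(rgb: np.ndarray, max_dist: float = 5.0) -> PointSet:
    """Full detection chain: RGB image -> classified centroid set.

    Segments on the summed stain density (so both counterstained and
    strongly DAB-stained nuclei are found) and classifies by distance to
    the Otsu-thresholded brown area.
    """
    channels = colour_deconvolve(rgb)
    labels = segment_nuclei(channels.brown + channels.blue)
    centroids = extract_centroids(labels)
    return classify_stained(centroids, stained_mask(channels), max_dist)
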