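"""Synthetic test images with known ground truth.

Two kinds of fixtures are generated:

* **Binary proof-of-principle images** — 500x500 (by convention) grids
  containing a single point, point pairs at controlled separations, or a
  five-point cluster with controlled spacing.  These drive the
  colocalization, histogram-intersection and sink experiments without
  any real slide material.

* **Pseudo-IHC images** — RGB brightfield look-alikes with brown
  (DAB-like) blobs for immunostained cells, blue (hematoxylin-like)
  blobs for counterstained nuclei and optional pale bone bands, built in
  optical-density space from the Ruifrok-Johnston H-DAB stain vectors so
  that colour deconvolution recovers the generating channels.  The
  ground-truth centroid list and bone mask travel with the image.

All randomness flows from an explicit seed; identical calls are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import combine_stains, rgb_from_hdx

from .errors import CoordinateError, PlacementError
from .points import PointSet

__all__ = [
    "PseudoIHCImage",
    "make_point_image",
    "make_cluster_image",
    "cluster_points",
    "make_pseudo_ihc",
    "PIXEL_SIZE_UM",
]

#: Pixel scale used for micrometre-labelled reporting (~200 px / 100 um).
PIXEL_SIZE_UM = 0.5


@dataclass
class PseudoIHCImage:
    """A synthetic brightfield IHC image with its generation truth."""

    pixels: np.ndarray  # (h, w, 3) uint8
    truth: PointSet
    bone_mask: np.ndarray  # (h, w) uint8 in {0, 1}


def make_point_image(height: int, width: int, points) -> np.ndarray:
    """Binary image with a single 1-pixel per (row, col) in ``points``.

    Duplicate coordinates collapse to a single pixel; an out-of-bounds
    coordinate raises :class:`CoordinateError`.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    img = np.zeros((height, width), dtype=np.uint8)
    for r, c in points:
        if not (0 <= r < height and 0 <= c < width):
            raise CoordinateError(f"point ({r}, {c}) outside {height}x{width} image")
        img[int(r), int(c)] = 1
    return img


def cluster_points(
    center: tuple[int, int], n_points: int, spacing: int, pattern: str = "cross"
) -> list[tuple[int, int]]:
    """Coordinates of a point cluster around ``center``.

    ``cross``: the centre plus axis neighbours at ``spacing`` (a quincunx
    for n_points=5).  ``line``: n collinear points spaced along the row,
    centred on ``center``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    r0, c0 = center
    if pattern == "cross":
        offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
        if n_points > len(offsets):
            raise ValueError("cross pattern supports at most 5 points")
        return [(r0 + dr * spacing, c0 + dc * spacing) for dr, dc in offsets[:n_points]]
    if pattern == "line":
        start = c0 - spacing * ((n_points - 1) // 2)
        return [(r0, start + i * spacing) for i in range(n_points)]
    raise ValueError(f"unknown pattern {pattern!r}")


def make_cluster_image(
    height: int,
    width: int,
    center: tuple[int, int],
    n_points: int = 5,
    spacing: int = 25,
    pattern: str = "cross",
) -> np.ndarray:
    """Binary image containing a point cluster with controlled spacing."""
    pts = cluster_points(center, n_points, spacing, pattern)
    return make_point_image(height, width, pts)


def _gaussian_bump(shape, center, sigma, radius):
    """Truncated Gaussian profile used as a stain density blob."""
    r0, c0 = center
    rr = np.arange(max(0, r0 - radius), min(shape[0], r0 + radius + 1))
    cc = np.arange(max(0, c0 - radius), min(shape[1], c0 + radius + 1))
    d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
    prof = np.exp(-d2 / (2.0 * sigma**2))
    prof[d2 > radius**2] = 0.0
    return (slice(rr[0], rr[-1] + 1), slice(cc[0], cc[-1] + 1)), prof


def make_pseudo_ihc(
    height: int,
    width: int,
    n_stained: int,
    n_unstained: int,
    bone_bands: int = 0,
    seed: int = 0,
    min_separation: int = 24,
    margin: int = 14,
) -> PseudoIHCImage:
    """Generate a pseudo-IHC RGB image with ground-truth centroids.

    Every cell receives a hematoxylin (blue) nucleus blob; stained cells
    additionally receive a larger DAB (brown) blob at the same centre.
    Cell centres are rejection-sampled to keep at least
    ``min_separation`` pixels between them (so segmentation ground truth
    is unambiguous) and to avoid the bone bands.  Raises
    :class:`PlacementError` when the requested counts cannot be placed.
    """
    if n_stained < 0 or n_unstained < 0 or bone_bands < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = n_stained + n_unstained

    bone = np.zeros((height, width), dtype=np.uint8)
    band_h = max(8, height // 16)
    for i in range(bone_bands):
        top = int(rng.integers(0, max(1, height - band_h)))
        bone[top : top + band_h, :] = 1

    forbidden = np.pad(bone, 0).astype(bool)
    centers: list[tuple[int, int]] = []
    max_tries = 2000 * max(1, n_total)
    tries = 0
    while len(centers) < n_total:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n_total} blobs with separation "
                f"{min_separation} in a {height}x{width} image"
            )
        r = int(rng.integers(margin, height - margin))
        c = int(rng.integers(margin, width - margin))
        if forbidden[
            max(0, r - 6) : r + 7, max(0, c - 6) : c + 7
        ].any():
            continue
        if any((r - rr) ** 2 + (c - cc) ** 2 < min_separation**2 for rr, cc in centers):
            continue
        centers.append((r, c))

    hema = np.zeros((height, width), dtype=np.float64)
    dab = np.zeros((height, width), dtype=np.float64)
    stained_flags = np.zeros(n_total, dtype=bool)
    stained_flags[:n_stained] = True
    for i, (r, c) in enumerate(centers):
        amp = float(rng.uniform(0.85, 1.0))
        # nucleus ~7 um across at 0.5 um/px; strong hematoxylin uptake
        sl, prof = _gaussian_bump((height, width), (r, c), sigma=3.5, radius=10)
        hema[sl] += 1.2 * amp * prof
        if stained_flags[i]:
            sl2, prof2 = _gaussian_bump((height, width), (r, c), sigma=4.5, radius=13)
            dab[sl2] += 1.0 * amp * prof2

    stains = np.dstack([hema, dab, np.zeros_like(hema)])
    rgb = combine_stains(stains, rgb_from_hdx)  # float in [0, 1]
    rgb = np.clip(rgb, 0.0, 1.0)
    # bone drawn directly in RGB as a pale green wash
    rgb[bone.astype(bool)] = rgb[bone.astype(bool)] * 0.35 + np.array(
        [0.72 * 0.65, 0.88 * 0.65, 0.72 * 0.65]
    )
    pixels = np.round(rgb * 255).astype(np.uint8)

    truth = PointSet(
        np.array([r for r, _ in centers], dtype=np.intp),
        np.array([c for _, c in centers], dtype=np.intp),
        stained_flags,
        (height, width),
    )
    return PseudoIHCImage(pixels=pixels, truth=truth, bone_mask=bone)
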