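"""Centroid point sets.

A :class:`PointSet` is the discrete representation of detected objects
(cell nuclei, particles): integer pixel coordinates plus a boolean
"stained" flag assigned by proximity to immunostained areas.  It is the
input that the field construction in :mod:`histofield.fields` turns into
a scalar density field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError

__all__ = ["PointSet"]


@dataclass
class PointSet:
    """Labelled centroid coordinates on a pixel grid.

    Parameters
    ----------
    rows, cols : 1-D integer arrays of equal length
        0-based pixel coordinates.
    stained : 1-D boolean array
        True where the object was classified as immunostained.
    source_shape : (height, width)
        Shape of the image the centroids were extracted from.
    """

    rows: np.ndarray
    cols: np.ndarray
    stained: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.stained = np.asarray(self.stained, dtype=bool)
        if not (self.rows.shape == self.cols.shape == self.stained.shape):
            raise ValueError("rows, cols and stained must have equal length")
        h, w = self.source_shape
        if len(self) and (
            self.rows.min() < 0
            or self.cols.min() < 0
            or self.rows.max() >= h
            or self.cols.max() >= w
        ):
            raise CoordinateError(
                f"centroid outside source shape {self.source_shape}"
            )
        if len(np.unique(self.rows * w + self.cols)) != len(self):
            raise ValueError("duplicate (row, col) entries in PointSet")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_coords(
        cls,
        coords,
        source_shape: tuple[int, int],
        stained=None,
    ) -> "PointSet":
        """Build a point set from an iterable of (row, col) pairs."""
        coords = np.atleast_2d(np.asarray(list(coords), dtype=np.intp))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if stained is None:
            stained = np.zeros(len(coords), dtype=bool)
        return cls(coords[:, 0], coords[:, 1], np.asarray(stained, bool), source_shape)

    def subset(self, mask) -> "PointSet":
        mask = np.asarray(mask, bool)
        return PointSet(
            self.rows[mask], self.cols[mask], self.stained[mask], self.source_shape
        )

    def indicator(self) -> np.ndarray:
        """Binary image with a 1 at every centroid pixel."""
        img = np.zeros(self.source_shape, dtype=np.uint8)
        img[self.rows, self.cols] = 1
        return img

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": self.rows, "col": self.cols, "stained": self.stained.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source_shape: tuple[int, int]) -> "PointSet":
        df = pd.read_csv(path)
        return cls(
            df["row"].to_numpy(),
            df["col"].to_numpy(),
            df["stained"].to_numpy().astype(bool),
            source_shape,
        )
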