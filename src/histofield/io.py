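"""Readers, writers, configuration and the end-to-end pipeline.

Fields are stored as 32-bit float TIFF plus a JSON metadata sidecar
(kernel parameters, normalization state, source count) so that a field
written to disk round-trips losslessly.  Binary masks and RGB images use
8-bit TIFF/PNG; centroid tables are CSV with columns ``row,col,stained``.
All image output is uncompressed or losslessly compressed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .coloc import ColocResult, baseline_binary_coloc, colocalize
from .errors import MetadataError
from .fields import RBFParams, ScalarField, point_field
from .geometry import SinkReport, divergence_sinks, field_intersection
from .points import PointSet
from .preprocess import detect_cells

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Parameters of a full analysis run.

    The defaults reproduce the proof-of-principle conditions: direct
    kernel (beta=3, gamma=0.01, peak 100), pair threshold 25, Manders
    threshold 50, 100 histogram bins, 5 px stained-classification range
    and a 0.5 um pixel scale.
    """

    mode: str = "direct"
    beta: float = 3.0
    gamma: float = 0.01
    kernel_shape: str = "separable"
    pair_threshold: float = 25.0
    pair_rule: str = "clip"
    manders_threshold: float = 50.0
    bins: int = 100
    max_dist: float = 5.0
    rel_sink_threshold: float = 0.4
    seed: int = 0
    pixel_size_um: float = 0.5

    def rbf_params(self) -> RBFParams:
        if self.mode in ("direct", "indirect"):
            return getattr(RBFParams, self.mode)(kernel_shape=self.kernel_shape)
        return RBFParams(
            beta=self.beta, gamma=self.gamma, kernel_shape=self.kernel_shape
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def read_image(path) -> np.ndarray:
    """Read a TIFF or PNG image; binary masks come back as {0, 1}.

    Grayscale images are interpreted as masks and thresholded at half
    their dtype range; RGB images are returned as uint8 unchanged.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif path.suffix.lower() == ".png":
            arr = iio.imread(path)
        else:
            raise OSError(f"unsupported image format: {path.suffix!r}")
    except OSError:
        raise
    except Exception as exc:  # corrupt/truncated file
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        return np.asarray(arr, dtype=np.uint8)
    if arr.ndim != 2:
        raise OSError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint8:
        return (arr > 127).astype(np.uint8)
    if arr.dtype == np.uint16:
        return (arr > 32767).astype(np.uint8)
    return (np.asarray(arr, dtype=np.float64) > 0.5).astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    """Write a mask ({0,1} scaled to 0/255) or RGB image, losslessly."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim == 2 and image.max() <= 1:
        image = (image.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.uint8))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, image.astype(np.uint8))
    else:
        raise OSError(f"unsupported image format: {path.suffix!r}")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_field(path, fld: ScalarField) -> None:
    """Write a field as float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, fld.values.astype(np.float32))
    meta = {
        "normalized": fld.normalized,
        "n_sources": fld.n_sources,
        "params": {
            "beta": fld.params.beta,
            "gamma": fld.params.gamma,
            "alpha": fld.params.alpha,
            "mode": fld.params.mode,
            "kernel_shape": fld.params.kernel_shape,
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_field(path) -> ScalarField:
    """Read a field TIFF together with its sidecar metadata."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"field {path} has no metadata sidecar {side.name}")
    meta = json.loads(side.read_text())
    values = tifffile.imread(path).astype(np.float64)
    params = RBFParams(**meta["params"])
    return ScalarField(
        values,
        normalized=bool(meta["normalized"]),
        params=params,
        n_sources=int(meta["n_sources"]),
    )


@dataclass
class AnalysisReport:
    """Serializable record of one pipeline run."""

    config: dict
    inputs: list[str]
    coloc: dict | None = None
    baseline: dict | None = None
    intersection: float | None = None
    sinks: dict | None = None
    n_cells: dict = dc_field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(
    config: RunConfig,
    image_a: np.ndarray,
    image_b: np.ndarray | None = None,
    with_sinks: bool = False,
) -> AnalysisReport:
    """Detect -> field -> analyse for one or two registered RGB images.

    With two images the stained centroids of each are fielded and
    compared (colocalization, histogram intersection, binary baseline);
    with one image only detection and optional sink analysis run.
    Deterministic for fixed inputs and config.
    """
    params = config.rbf_params()
    report = AnalysisReport(config=config.to_dict(), inputs=[])

    pts_a = detect_cells(image_a, config.max_dist)
    stained_a = pts_a.subset(pts_a.stained)
    report.n_cells["a"] = {"total": len(pts_a), "stained": int(pts_a.stained.sum())}
    field_a = point_field(stained_a, pts_a.source_shape, params)

    if image_b is not None:
        pts_b = detect_cells(image_b, config.max_dist)
        stained_b = pts_b.subset(pts_b.stained)
        report.n_cells["b"] = {"total": len(pts_b), "stained": int(pts_b.stained.sum())}
        field_b = point_field(stained_b, pts_b.source_shape, params)
        result = colocalize(
            field_a,
            field_b,
            config.pair_threshold,
            config.manders_threshold,
            config.pair_rule,
        )
        report.coloc = result.to_dict()
        report.baseline = baseline_binary_coloc(
            stained_a.indicator(), stained_b.indicator()
        ).to_dict()
        report.intersection = field_intersection(field_a, field_b, config.bins)

    if with_sinks:
        sink_params = RBFParams(
            beta=params.beta, gamma=params.gamma, kernel_shape="radial"
        )
        smooth = point_field(
            stained_a, pts_a.source_shape, sink_params, support="full"
        )
        report.sinks = divergence_sinks(smooth, config.rel_sink_threshold).to_dict()

    return report
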