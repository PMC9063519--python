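"""Affine chunk placement and mosaic reconstruction.

A single physical sample is often imaged as several chunks (fields of view).
Each chunk carries a homogeneous affine matrix (``ChunkTransformationMatrix``)
and an axis-name list (``ChunkTransformationMatrixAxis``) that place its
pixel grid into the sample's common space.  This toolkit fixes the
conventions the matrix alone leaves open:

* pixel centers sit at integer coordinates 0, 1, ..., n-1 along each axis;
* the matrix multiplies column vectors, ``v' = M @ [v, 1]``;
* data arrays are indexed in the order given by the axis list, and the
  matrix rows/columns follow the same order;
* world units are whatever the sidecar ``PixelSize`` is expressed in.

Only per-axis scaling plus translation is meaningful for stitching; general
affines are accepted for validation (with a warning) but refused for
reconstruction, since resampling under rotation or shear is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TransformError
from .issues import Issue, make_issue

AXIS_NAMES = ("X", "Y", "Z")


@dataclass(frozen=True)
class AffinePlacement:
    """One chunk's placement: homogeneous matrix, axis order, grid shape."""

    matrix: tuple[tuple[float, ...], ...]
    axes: tuple[str, ...]
    shape: tuple[int, ...]

    def __post_init__(self):
        if len(self.axes) != len(self.shape):
            raise TransformError(
                "axes and shape lengths differ", code="E_AXES_MISMATCH"
            )
        if any(n < 1 for n in self.shape):
            raise TransformError("shape must be positive", code="E_AXES_MISMATCH")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def array_matrix(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @staticmethod
    def from_lists(matrix, axes, shape) -> "AffinePlacement":
        return AffinePlacement(
            matrix=tuple(tuple(float(v) for v in row) for row in matrix),
            axes=tuple(axes),
            shape=tuple(int(n) for n in shape),
        )


def validate_transform(
    matrix, axes, image_dims: int, path: str = ""
) -> list[Issue]:
    """Structural checks of one transformation against its image.

    ``axes`` may be None when the axis field is absent; then only the matrix
    itself is checked.  Findings are returned, never raised.
    """
    issues: list[Issue] = []
    m = np.asarray(matrix, dtype=float)
    d = image_dims
    if m.ndim != 2 or m.shape != (d + 1, d + 1):
        issues.append(
            make_issue(
                "E_MATRIX_SHAPE", path,
                f"matrix shape {tuple(m.shape)} is not ({d + 1}, {d + 1}) "
                f"for a {d}D image",
            )
        )
        return issues
    bottom = np.zeros(d + 1)
    bottom[-1] = 1.0
    if not np.array_equal(m[-1], bottom):
        issues.append(
            make_issue(
                "E_MATRIX_HOMOGENEOUS", path,
                f"bottom row {m[-1].tolist()} is not {bottom.tolist()}",
            )
        )
    if axes is not None:
        if len(axes) != d or len(set(axes)) != len(axes):
            issues.append(
                make_issue(
                    "E_AXES_MISMATCH", path,
                    f"axes {list(axes)} do not name {d} distinct axes",
                )
            )
    linear = m[:d, :d]
    if np.any(linear - np.diag(np.diag(linear)) != 0):
        issues.append(
            make_issue(
                "W_NONAXIAL_TRANSFORM", path,
                "matrix has off-diagonal linear terms (rotation/shear)",
            )
        )
    return issues


def map_point(matrix, point) -> np.ndarray:
    """Apply a homogeneous affine to one point (column-vector convention)."""
    m = np.asarray(matrix, dtype=float)
    p = np.asarray(point, dtype=float)
    d = p.shape[-1]
    if m.shape != (d + 1, d + 1):
        raise TransformError(
            f"matrix {m.shape} does not act on {d}D points", code="E_DIM_MISMATCH"
        )
    homogeneous = np.append(p, 1.0)
    return (m @ homogeneous)[:d]


def _scale_translation(placement: AffinePlacement) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-axis scale and translation; refuse anything richer."""
    m = placement.array_matrix
    d = placement.ndim
    if m.shape != (d + 1, d + 1):
        raise TransformError(
            f"matrix {m.shape} does not match a {d}D chunk", code="E_MATRIX_SHAPE"
        )
    linear = m[:d, :d]
    if np.any(linear - np.diag(np.diag(linear)) != 0):
        raise TransformError(
            "rotation/shear terms present; stitching is undefined",
            code="E_UNSUPPORTED_TRANSFORM",
        )
    scale = np.diag(linear).copy()
    if np.any(scale == 0):
        raise TransformError("zero scale term", code="E_SCALE_ZERO")
    return scale, m[:d, d].copy()


def _check_common_frame(placements: list[AffinePlacement]) -> None:
    dims = {p.ndim for p in placements}
    if len(dims) != 1:
        raise TransformError(
            f"chunks mix dimensionalities {sorted(dims)}",
            code="E_MIXED_DIMENSIONALITY",
        )
    axes = {p.axes for p in placements}
    if len(axes) != 1:
        raise TransformError(
            f"chunks mix axis orders {sorted(axes)}", code="E_MIXED_AXES"
        )


def mosaic_extent(
    placements: list[AffinePlacement],
) -> tuple[list[tuple[float, float]], tuple[int, ...], np.ndarray, np.ndarray]:
    """World bounding box and output grid of a chunk layout.

    Returns ``(bbox, grid_shape, origin, out_pixel)`` where ``bbox`` is a
    half-open interval per axis covering every chunk's pixel cells, the
    output pixel size per axis is the minimum absolute scale over chunks,
    ``origin`` is the world coordinate of output pixel center (0, ..., 0),
    and ``grid_shape`` counts output pixels per axis.
    """
    if not placements:
        raise ValueError("no placements given")
    _check_common_frame(placements)
    d = placements[0].ndim

    per_chunk = [(_scale_translation(p), p.shape) for p in placements]
    out_pixel = np.min(
        [np.abs(scale) for (scale, _), _ in per_chunk], axis=0
    )

    lo = np.full(d, np.inf)
    hi = np.full(d, -np.inf)
    for (scale, translation), shape in per_chunk:
        # mapped centers of the first and last pixel along each axis
        first = translation
        last = scale * (np.asarray(shape) - 1) + translation
        lo = np.minimum(lo, np.minimum(first, last))
        hi = np.maximum(hi, np.maximum(first, last))

    grid_shape = tuple(int(round(v)) + 1 for v in (hi - lo) / out_pixel)
    bbox = [
        (float(l), float(l + n * s))
        for l, n, s in zip(lo, grid_shape, out_pixel)
    ]
    return bbox, grid_shape, lo, out_pixel


@dataclass
class Mosaic:
    """A reconstructed image/volume plus per-pixel contribution counts."""

    data: np.ndarray
    coverage: np.ndarray
    origin: np.ndarray
    pixel_size: np.ndarray
    axes: tuple[str, ...]


def _output_indices(
    placement: AffinePlacement, origin: np.ndarray, out_pixel: np.ndarray
) -> list[np.ndarray]:
    """Per-axis output index vectors for one chunk's pixel centers."""
    scale, translation = _scale_translation(placement)
    indices = []
    for a in range(placement.ndim):
        centers = scale[a] * np.arange(placement.shape[a]) + translation[a]
        indices.append(np.rint((centers - origin[a]) / out_pixel[a]).astype(int))
    return indices


def stitch(
    chunks: list[tuple[np.ndarray, AffinePlacement]],
    overlap_policy: str = "mean",
    fill: float = 0.0,
) -> Mosaic:
    """Reconstruct the mosaic of a list of (pixel grid, placement) chunks.

    Each chunk pixel center is mapped to world space and rounded
    (ties-to-even) to the nearest output pixel.  Overlaps combine per
    ``overlap_policy``: ``"mean"`` averages all contributors, ``"last"``
    keeps the last writer in input order.  Pixels no chunk covers take
    ``fill``; the coverage mask counts contributors per pixel.
    """
    if overlap_policy not in ("mean", "last"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    if not chunks:
        raise ValueError("no chunks given")
    for data, placement in chunks:
        if tuple(data.shape) != placement.shape:
            raise TransformError(
                f"chunk data shape {data.shape} does not match placement "
                f"shape {placement.shape}",
                code="E_MATRIX_SHAPE",
            )

    placements = [p for _, p in chunks]
    _, grid_shape, origin, out_pixel = mosaic_extent(placements)

    accum = np.zeros(grid_shape, dtype=float)
    coverage = np.zeros(grid_shape, dtype=int)
    last = np.full(grid_shape, fill, dtype=float)

    for data, placement in chunks:
        idx = _output_indices(placement, origin, out_pixel)
        mesh = np.meshgrid(*idx, indexing="ij")
        np.add.at(accum, tuple(mesh), data.astype(float))
        np.add.at(coverage, tuple(mesh), 1)
        if overlap_policy == "last":
            # assign pixel by pixel so duplicate targets resolve to the
            # last source pixel in C order, deterministically
            flat_targets = np.ravel_multi_index(
                tuple(m.ravel() for m in mesh), grid_shape
            )
            last.ravel()[flat_targets] = data.astype(float).ravel()

    covered = coverage > 0
    if overlap_policy == "mean":
        out = np.full(grid_shape, fill, dtype=float)
        out[covered] = accum[covered] / coverage[covered]
    else:
        out = last
    return Mosaic(
        data=out,
        coverage=coverage,
        origin=origin,
        pixel_size=out_pixel,
        axes=placements[0].axes,
    )
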