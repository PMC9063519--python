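"""Load a chunk group from a dataset and stitch it into one mosaic.

Arrays on disk are row-major ([Z,]Y,X for TIFF stacks, Y,X for PNG); the
sidecar's ``ChunkTransformationMatrixAxis`` declares the index order the
matrix uses, so each chunk is transposed from storage order to the declared
order before stitching, and back when the mosaic is written out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .chunks import AffinePlacement, Mosaic, stitch
from .entities import parse_filename
from .errors import NameParseError, TransformError
from .fixtures import write_minimal_ome_tiff
from .registry import default_registry
from .sidecars import resolve_sidecar
from .validator import index_dataset


def _storage_axes(ndim: int) -> tuple[str, ...]:
    if ndim == 2:
        return ("Y", "X")
    if ndim == 3:
        return ("Z", "Y", "X")
    raise ValueError(f"unsupported dimensionality {ndim}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/OME-TIFF pixel grid in storage order ([Z,]Y,X)."""
    path = Path(path)
    if path.name.endswith(".png"):
        return np.asarray(Image.open(path))
    return np.asarray(tifffile.imread(str(path)))


def load_chunk_group(
    root: str | Path,
    subject: str,
    sample: str,
    suffix: str,
    session: str | None = None,
) -> list[tuple[np.ndarray, AffinePlacement, str]]:
    """Collect the chunks of one subject+sample+suffix group with placements."""
    root = Path(root)
    registry = default_registry()
    index = index_dataset(root, registry)
    group: list[tuple[np.ndarray, AffinePlacement, str]] = []
    for f in index.data_files:
        e = f.parsed.entities
        if (
            e.subject != subject
            or e.sample != sample
            or e.session != session
            or f.parsed.suffix != suffix
            or e.chunk is None
        ):
            continue
        doc, _ = resolve_sidecar(f.rel_path, root)
        matrix = doc.get("ChunkTransformationMatrix")
        axes = doc.get("ChunkTransformationMatrixAxis")
        if matrix is None:
            raise TransformError(
                f"{f.rel_path} has no ChunkTransformationMatrix",
                code="E_MATRIX_SHAPE",
                path=f.rel_path,
            )
        data = read_image(root / f.rel_path)
        natural = _storage_axes(data.ndim)
        declared = tuple(axes) if axes else natural
        if sorted(declared) != sorted(natural):
            raise TransformError(
                f"{f.rel_path}: axis names {declared} do not cover {natural}",
                code="E_AXES_MISMATCH",
                path=f.rel_path,
            )
        data = np.transpose(data, [natural.index(a) for a in declared])
        placement = AffinePlacement.from_lists(matrix, declared, data.shape)
        group.append((data, placement, f.rel_path))
    return group


def stitch_sample(
    root: str | Path,
    subject: str,
    sample: str,
    suffix: str,
    session: str | None = None,
    overlap_policy: str = "mean",
    fill: float = 0.0,
) -> Mosaic:
    """Stitch every chunk of one sample into a single image or volume."""
    group = load_chunk_group(root, subject, sample, suffix, session)
    if not group:
        raise ValueError(
            f"no chunked files for sub-{subject} sample-{sample} {suffix}"
        )
    return stitch(
        [(data, placement) for data, placement, _ in group],
        overlap_policy=overlap_policy,
        fill=fill,
    )


def write_mosaic(
    path: str | Path,
    mosaic: Mosaic,
    pixel_size: tuple[float, ...] | None = None,
    units: str = "um",
) -> Path:
    """Write a mosaic as OME-TIFF with a synthesized minimal header.

    ``pixel_size`` is the physical size of one output pixel per X, Y[, Z]
    axis; when omitted the mosaic's world pixel size is used as-is, which is
    correct when the chunk matrices are expressed in physical units.
    """
    natural = _storage_axes(len(mosaic.axes))
    perm = [mosaic.axes.index(a) for a in natural]
    data = np.transpose(mosaic.data, perm)
    # shape and physical sizes in X, Y[, Z] order
    xyz = list(reversed(natural))
    shape = tuple(int(mosaic.data.shape[mosaic.axes.index(a)]) for a in xyz)
    if pixel_size is None:
        pixel_size = tuple(
            float(mosaic.pixel_size[mosaic.axes.index(a)]) for a in xyz
        )
    arr = data
    if arr.dtype != np.uint8:
        rounded = np.rint(arr)
        if np.all(rounded >= 0) and np.all(rounded <= 255) and np.allclose(arr, rounded):
            arr = rounded.astype(np.uint8)
        else:
            arr = arr.astype(np.float32)
    return write_minimal_ome_tiff(path, shape, pixel_size, units, data=arr)


def inspect_file(path: str | Path) -> dict:
    """Parse a filename (and OME header, if any) into a plain dict."""
    path = Path(path)
    info: dict = {"name": path.name}
    try:
        parsed = parse_filename(path.name)
    except NameParseError as exc:
        info["error"] = {"code": exc.code, "message": str(exc)}
        return info
    info["entities"] = parsed.entities.as_dict()
    info["suffix"] = parsed.suffix
    info["extension"] = parsed.extension
    info["expected_path"] = parsed.relative_path
    if parsed.extension in (".ome.tif", ".ome.btf") and path.is_file():
        from .sidecars import parse_ome_header

        header = parse_ome_header(path)
        info["ome"] = {
            "SizeX": header.size_x,
            "SizeY": header.size_y,
            "SizeZ": header.size_z,
            "PhysicalSizeX": header.physical_size_x,
            "PhysicalSizeY": header.physical_size_y,
            "PhysicalSizeZ": header.physical_size_z,
        }
    return info
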