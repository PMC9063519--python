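"""Synthetic Microscopy-BIDS datasets: valid templates and single-defect mutants.

Two templates ship with the toolkit, mirroring the two canonical example
dataset shapes (a non-tiled 2D PNG study and a chunked 3D OME-TIFF study):

* ``png2d`` — 2 subjects x 2 samples of bright-field (BF) 16x16 8-bit PNGs,
  with a stained pair (stain-LFB) on the second subject, inheritance-tested
  sidecars, samples/participants tables with animal metadata and a
  ``derived_from`` link.
* ``ometiff3d`` — 1 subject, 1 sample, 4 SPIM chunks of 8x8x4 voxels stored
  as OME-TIFF with minimal OME-XML headers, placed on a 2x2 XY grid by
  translation-only ChunkTransformationMatrix entries, so the stitched mosaic
  is a 16x16x4 volume with a closed-form expected array.

Pixel content is a deterministic gradient plus seeded integer noise, so all
trees are byte-identical for a given seed and stitched mosaics can be
recomputed exactly.  The mutation catalogue applies exactly one minimal
defect to a generated tree; every defect maps to one validator issue code,
which is how the negative half of the rule set is exercised end to end.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import FixtureError

_OME_NS = "http://www.openmicroscopy.org/Schemas/OME/2016-06"

#: micro sign as an XML character reference: TIFF description tags must stay
#: 7-bit ASCII, and the reference parses back to the OME spelling "µm"
_UNIT_TO_OME = {"mm": "mm", "um": "&#181;m", "nm": "nm"}


@dataclass(frozen=True)
class Template:
    """Parameters of one shipped dataset template."""

    name: str
    subjects: int
    samples_per_subject: int
    chunks: int
    suffix: str
    extension: str
    includes_session: bool
    image_shape: tuple[int, ...]  # (X, Y) or (X, Y, Z)
    pixel_size: tuple[float, ...]
    pixel_size_units: str
    seed: int = 0


TEMPLATES: dict[str, Template] = {
    "png2d": Template(
        name="png2d",
        subjects=2,
        samples_per_subject=2,
        chunks=0,
        suffix="BF",
        extension=".png",
        includes_session=False,
        image_shape=(16, 16),
        pixel_size=(1.0, 1.0),
        pixel_size_units="um",
    ),
    "ometiff3d": Template(
        name="ometiff3d",
        subjects=1,
        samples_per_subject=1,
        chunks=4,
        suffix="SPIM",
        extension=".ome.tif",
        includes_session=False,
        image_shape=(8, 8, 4),
        pixel_size=(0.5, 0.5, 0.5),
        pixel_size_units="um",
    ),
}

_SAMPLE_LABELS = "ABCDEFGH"


def _pattern(shape: tuple[int, ...], seed_key: list[int]) -> np.ndarray:
    """Gradient + seeded noise, in array index order (so [Z,]Y,X on disk)."""
    rng = np.random.default_rng(seed_key)
    grids = np.indices(shape)
    base = sum((i + 2) * g for i, g in enumerate(grids)) * 7 % 193
    noise = rng.integers(0, 32, size=shape)
    return ((base + noise) % 256).astype(np.uint8)


def _write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(row.get(c) or "n/a" for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def minimal_ome_xml(
    shape: tuple[int, ...],
    pixel_size: tuple[float, ...],
    units: str,
    dtype: str = "uint8",
) -> str:
    """Minimal OME-XML for a (X, Y[, Z]) image with physical pixel sizes."""
    sx, sy = shape[0], shape[1]
    sz = shape[2] if len(shape) == 3 else 1
    unit = _UNIT_TO_OME[units]
    physical = (
        f'PhysicalSizeX="{pixel_size[0]!r}" PhysicalSizeXUnit="{unit}" '
        f'PhysicalSizeY="{pixel_size[1]!r}" PhysicalSizeYUnit="{unit}"'
    )
    if len(shape) == 3:
        physical += f' PhysicalSizeZ="{pixel_size[2]!r}" PhysicalSizeZUnit="{unit}"'
    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        f'<OME xmlns="{_OME_NS}">'
        '<Image ID="Image:0">'
        f'<Pixels ID="Pixels:0" DimensionOrder="XYZCT" Type="{dtype}" '
        f'SizeX="{sx}" SizeY="{sy}" SizeZ="{sz}" SizeC="1" SizeT="1" '
        f"{physical}>"
        "<TiffData/></Pixels></Image></OME>"
    )


def write_minimal_ome_tiff(
    path: str | Path,
    shape: tuple[int, ...],
    pixel_size: tuple[float, ...],
    units: str = "um",
    data: np.ndarray | None = None,
    seed: int = 0,
) -> Path:
    """Write an OME-TIFF whose first IFD carries a minimal OME-XML header.

    ``shape`` is (X, Y) or (X, Y, Z); ``data``, when given, is indexed
    [Z,]Y,X (row-major as stored).  Re-reading through
    :func:`micr_bids.sidecars.parse_ome_header` recovers sizes and physical
    sizes exactly.  The XML is synthesized here (no writer-generated UUIDs
    or timestamps), so output is byte-deterministic.
    """
    if len(shape) not in (2, 3):
        raise ValueError(f"shape must be 2D or 3D, got {shape}")
    if len(pixel_size) != len(shape):
        raise ValueError("pixel_size length must match shape length")
    if units not in _UNIT_TO_OME:
        raise ValueError(f"unsupported unit {units!r}")
    index_shape = tuple(reversed(shape))  # [Z,]Y,X storage order
    if data is None:
        data = _pattern(index_shape, [seed])
    if tuple(data.shape) != index_shape:
        raise ValueError(f"data shape {data.shape} does not match {index_shape}")
    xml = minimal_ome_xml(shape, pixel_size, units, dtype=str(data.dtype))
    path = Path(path)
    try:
        # a Z-stack is a stack of grayscale planes, never RGB components
        tifffile.imwrite(
            str(path), data, description=xml, metadata=None,
            photometric="minisblack",
        )
    except OSError as exc:
        raise FixtureError(
            f"cannot write {path}: {exc}", code="E_WRITE_FAILED", path=str(path)
        ) from exc
    return path


def _chunk_grid_translations(template: Template) -> list[tuple[float, float, float]]:
    """(Z, Y, X) translations of the 2x2 XY chunk grid, in pixel units."""
    nx, ny = template.image_shape[0], template.image_shape[1]
    return [(0.0, 0.0, 0.0), (0.0, 0.0, float(nx)), (0.0, float(ny), 0.0), (0.0, float(ny), float(nx))]


def chunk_matrix(translation_zyx: tuple[float, float, float]) -> list[list[float]]:
    tz, ty, tx = translation_zyx
    return [
        [1.0, 0.0, 0.0, tz],
        [0.0, 1.0, 0.0, ty],
        [0.0, 0.0, 1.0, tx],
        [0.0, 0.0, 0.0, 1.0],
    ]


def _chunk_seed_key(seed: int, subject: int, sample: int, chunk: int) -> list[int]:
    return [seed, subject, sample, chunk]


def chunk_array(template: Template, seed: int, chunk: int) -> np.ndarray:
    """The pixel grid of one generated chunk, indexed [Z,]Y,X."""
    index_shape = tuple(reversed(template.image_shape))
    return _pattern(index_shape, _chunk_seed_key(seed, 1, 1, chunk))


def ometiff3d_expected_mosaic(seed: int = 0) -> np.ndarray:
    """Closed-form stitched volume of the ometiff3d template: the chunks
    pasted at their grid translations, indexed (Z, Y, X)."""
    template = TEMPLATES["ometiff3d"]
    nx, ny, nz = template.image_shape
    out = np.zeros((nz, 2 * ny, 2 * nx), dtype=float)
    for chunk, (tz, ty, tx) in enumerate(_chunk_grid_translations(template), start=1):
        arr = chunk_array(template, seed, chunk)
        out[
            int(tz): int(tz) + nz,
            int(ty): int(ty) + ny,
            int(tx): int(tx) + nx,
        ] = arr
    return out


def _common_sidecar_fields(template: Template) -> dict:
    return {
        "PixelSize": list(template.pixel_size),
        "PixelSizeUnits": template.pixel_size_units,
        "Magnification": 10,
        "ImageAcquisitionProtocol": "synthetic fixture protocol v1",
        "SampleEnvironment": "ex vivo",
        "BodyPart": "BRAIN",
        "SampleFixation": "4% paraformaldehyde",
    }


def generate_dataset(
    template: Template | str, root: str | Path, seed: int | None = None
) -> list[str]:
    """Write a complete valid dataset tree; return sorted relative paths.

    The tree passes :func:`micr_bids.validator.validate_dataset` with zero
    errors by construction, and is byte-identical for a given seed.
    """
    if isinstance(template, str):
        try:
            template = TEMPLATES[template]
        except KeyError:
            raise FixtureError(
                f"unknown template {template!r}", code="E_UNKNOWN_DEFECT"
            ) from None
    seed = template.seed if seed is None else seed
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FixtureError(
            f"{root} is not empty", code="E_ROOT_NOT_EMPTY", path=str(root)
        )
    root.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def record(path: Path) -> Path:
        manifest.append(str(path.relative_to(root)))
        return path

    _write_json(
        record(root / "dataset_description.json"),
        {
            "Name": f"Synthetic microscopy fixture ({template.name})",
            "BIDSVersion": "1.7.0",
            "DatasetType": "raw",
        },
    )

    subjects = [f"{i:02d}" for i in range(1, template.subjects + 1)]
    samples = list(_SAMPLE_LABELS[: template.samples_per_subject])
    species = ["mus musculus", "rattus norvegicus"]
    strains = [
        ("C57BL/6J", "RRID:IMSR_JAX:000664"),
        ("Wistar", "RRID:RGD_13508588"),
    ]

    _write_tsv(
        record(root / "participants.tsv"),
        ["participant_id", "species", "strain", "strain_rrid"],
        [
            {
                "participant_id": f"sub-{sub}",
                "species": species[i % len(species)],
                "strain": strains[i % len(strains)][0],
                "strain_rrid": strains[i % len(strains)][1],
            }
            for i, sub in enumerate(subjects)
        ],
    )
    _write_json(
        record(root / "participants.json"),
        {
            "species": {"Description": "binomial species name (NCBI Taxonomy)"},
            "strain": {"Description": "name of the strain of the species"},
            "strain_rrid": {"Description": "research resource identifier of the strain"},
        },
    )

    sample_rows = []
    for sub in subjects:
        for j, sample in enumerate(samples):
            sample_rows.append(
                {
                    "sample_id": f"sample-{sample}",
                    "participant_id": f"sub-{sub}",
                    "sample_type": "tissue",
                    "pathology": None,
                    # every non-first sample is a slice of the first
                    "derived_from": f"sample-{samples[0]}" if j else None,
                }
            )
    _write_tsv(
        record(root / "samples.tsv"),
        ["sample_id", "participant_id", "sample_type", "pathology", "derived_from"],
        sample_rows,
    )
    _write_json(
        record(root / "samples.json"),
        {
            "sample_type": {"Description": "biosample type"},
            "pathology": {"Description": "pathology of the sample"},
            "derived_from": {"Description": "sample_id this sample derives from"},
        },
    )

    # root-level inherited sidecar for the modality (device metadata)
    _write_json(
        record(root / f"{template.suffix}.json"),
        {
            "Manufacturer": "Fixture Scientific",
            "InstitutionName": "Synthetic Imaging Laboratory",
        },
    )

    for si, sub in enumerate(subjects, start=1):
        micr = root / f"sub-{sub}" / "micr"
        micr.mkdir(parents=True)
        for sj, sample in enumerate(samples, start=1):
            # second subject's files carry the stain entity
            stain = "_stain-LFB" if si == 2 else ""
            stem = f"sub-{sub}_sample-{sample}{stain}"
            sidecar_fields = dict(_common_sidecar_fields(template))
            if stain:
                sidecar_fields["SampleStaining"] = "luxol fast blue"

            if template.chunks == 0:
                name = f"{stem}_{template.suffix}{template.extension}"
                index_shape = tuple(reversed(template.image_shape))
                arr = _pattern(index_shape, _chunk_seed_key(seed, si, sj, 0))
                Image.fromarray(arr, mode="L").save(record(micr / name))
                _write_json(
                    record(micr / f"{stem}_{template.suffix}.json"), sidecar_fields
                )
            else:
                # shared sample-level sidecar; per-chunk placement sidecars
                _write_json(
                    record(micr / f"{stem}_{template.suffix}.json"), sidecar_fields
                )
                for chunk, translation in enumerate(
                    _chunk_grid_translations(template), start=1
                ):
                    cstem = f"{stem}_chunk-{chunk:02d}_{template.suffix}"
                    arr = chunk_array(template, seed, chunk)
                    write_minimal_ome_tiff(
                        record(micr / f"{cstem}{template.extension}"),
                        template.image_shape,
                        template.pixel_size,
                        template.pixel_size_units,
                        data=arr,
                    )
                    _write_json(
                        record(micr / f"{cstem}.json"),
                        {
                            "ChunkTransformationMatrix": chunk_matrix(translation),
                            "ChunkTransformationMatrixAxis": ["Z", "Y", "X"],
                        },
                    )
    return sorted(manifest)


# ----------------------------------------------------------------------
# mutation catalogue


@dataclass(frozen=True)
class Defect:
    """One minimal mutation and the issue code it must trigger."""

    code: str
    issue: str
    templates: tuple[str, ...]
    description: str
    apply: object = field(compare=False, default=None)


def _first_data_file(root: Path) -> Path:
    files = sorted(
        p
        for p in root.glob("sub-*/micr/*")
        if p.is_file() and not p.name.endswith(".json")
    )
    if not files:
        raise FixtureError("no data files found", code="E_UNKNOWN_DEFECT")
    return files[0]


def _first_sidecar_with(root: Path, field_name: str) -> tuple[Path, dict]:
    for p in sorted(root.glob("sub-*/micr/*.json")):
        doc = json.loads(p.read_text(encoding="utf-8"))
        if field_name in doc:
            return p, doc
    raise FixtureError(
        f"no sidecar carries {field_name!r}", code="E_UNKNOWN_DEFECT"
    )


def _edit_sidecar(root: Path, field_name: str, mutate) -> str:
    path, doc = _first_sidecar_with(root, field_name)
    mutate(doc)
    _write_json(path, doc)
    return str(path.relative_to(root))


def _edit_table(root: Path, name: str, mutate_lines) -> str:
    path = root / name
    lines = path.read_text(encoding="utf-8").rstrip("\n").split("\n")
    path.write_text("\n".join(mutate_lines(lines)) + "\n", encoding="utf-8")
    return name


def _rename(path: Path, new_name: str) -> None:
    path.rename(path.with_name(new_name))


def _set_table_cell(lines: list[str], column: str, row: int, value: str) -> list[str]:
    header = lines[0].split("\t")
    col = header.index(column)
    cells = lines[row].split("\t")
    cells[col] = value
    lines[row] = "\t".join(cells)
    return lines


def _d_drop_sample_type(root: Path) -> str:
    def mutate(lines):
        header = lines[0].split("\t")
        col = header.index("sample_type")
        return ["\t".join(c for i, c in enumerate(l.split("\t")) if i != col) for l in lines]

    return "dropped sample_type column from " + _edit_table(root, "samples.tsv", mutate)


def _d_unknown_sample_type(root: Path) -> str:
    _edit_table(root, "samples.tsv", lambda l: _set_table_cell(l, "sample_type", 1, "banana"))
    return "set first sample_type to 'banana'"


def _d_duplicate_sample(root: Path) -> str:
    _edit_table(root, "samples.tsv", lambda l: l + [l[1]])
    return "duplicated the first samples.tsv row"


def _d_cycle_derived_from(root: Path) -> str:
    # first participant: A <- B while B <- A already holds
    def mutate(lines):
        return _set_table_cell(lines, "derived_from", 1, "sample-B")

    _edit_table(root, "samples.tsv", mutate)
    return "pointed sample-A's derived_from at sample-B, closing a cycle"


def _d_derived_from_unknown(root: Path) -> str:
    _edit_table(
        root, "samples.tsv", lambda l: _set_table_cell(l, "derived_from", 1, "sample-ZZZ")
    )
    return "pointed a derived_from at a nonexistent sample"


def _d_bad_rrid(root: Path) -> str:
    _edit_table(
        root, "participants.tsv", lambda l: _set_table_cell(l, "strain_rrid", 1, "IMSR_JAX:000664")
    )
    return "stripped the RRID: prefix from a strain_rrid"


def _d_bad_suffix(root: Path) -> str:
    target = _first_data_file(root)
    stem, ext = target.name.split(".", 1)
    parts = stem.split("_")
    parts[-1] = "XYZ"
    _rename(target, "_".join(parts) + "." + ext)
    return f"renamed {target.name} with suffix XYZ"


def _d_unknown_extension(root: Path) -> str:
    target = _first_data_file(root)
    _rename(target, target.name.rsplit(".", 1)[0] + ".jpg")
    return f"renamed {target.name} to a .jpg extension"


def _d_entity_order(root: Path) -> str:
    target = sorted(root.glob("sub-*/micr/*stain-*_*"))
    target = [p for p in target if not p.name.endswith(".json")][0]
    name = target.name
    swapped = name.replace("_sample-", "_TMP-").replace("_stain-", "_sample-").replace(
        "_TMP-", "_stain-"
    )
    _rename(target, swapped)
    return f"swapped sample and stain entity order in {name}"


def _d_missing_required_entity(root: Path) -> str:
    target = _first_data_file(root)
    parts = target.name.split("_")
    parts = [p for p in parts if not p.startswith("sample-")]
    _rename(target, "_".join(parts))
    return f"removed the sample entity from {target.name}"


def _d_misplace_file(root: Path) -> str:
    target = _first_data_file(root)
    shutil.move(str(target), str(target.parent.parent / target.name))
    return f"moved {target.name} out of its micr/ directory"


def _d_path_entity_mismatch(root: Path) -> str:
    target = _first_data_file(root)
    _rename(target, target.name.replace("sub-", "sub-9", 1))
    return f"changed the sub label inside the filename of {target.name}"


def _d_corrupt_json(root: Path) -> str:
    path = sorted(root.glob("sub-*/micr/*.json"))[0]
    path.write_text('{"PixelSize": [', encoding="utf-8")
    return f"truncated {path.relative_to(root)}"


def _d_missing_pixel_size(root: Path) -> str:
    return "removed PixelSize from " + _edit_sidecar(
        root, "PixelSize", lambda doc: doc.pop("PixelSize")
    )


def _d_vocab_violation(root: Path) -> str:
    return "set SampleEnvironment to 'frozen' in " + _edit_sidecar(
        root, "SampleEnvironment", lambda doc: doc.update(SampleEnvironment="frozen")
    )


def _d_pixel_size_mismatch(root: Path) -> str:
    def mutate(doc):
        doc["PixelSize"] = [v * 2 for v in doc["PixelSize"]]

    return "doubled sidecar PixelSize in " + _edit_sidecar(root, "PixelSize", mutate)


def _d_wrong_matrix_shape(root: Path) -> str:
    def mutate(doc):
        doc["ChunkTransformationMatrix"] = [
            row[:3] for row in doc["ChunkTransformationMatrix"][:3]
        ]

    return "truncated a ChunkTransformationMatrix to 3x3 in " + _edit_sidecar(
        root, "ChunkTransformationMatrix", mutate
    )


def _d_bad_matrix_bottom(root: Path) -> str:
    def mutate(doc):
        doc["ChunkTransformationMatrix"][-1] = [0.0, 0.0, 1.0, 1.0]

    return "broke the homogeneous bottom row in " + _edit_sidecar(
        root, "ChunkTransformationMatrix", mutate
    )


def _d_missing_samples_table(root: Path) -> str:
    (root / "samples.tsv").unlink()
    return "deleted samples.tsv"


def _d_sample_not_in_table(root: Path) -> str:
    # drop the last row: a leaf of the derivation graph, so no dangling
    # derived_from reference is introduced alongside
    _edit_table(root, "samples.tsv", lambda lines: lines[:-1])
    return "deleted the last samples.tsv row"


def _d_remove_description_key(root: Path) -> str:
    path = root / "dataset_description.json"
    doc = json.loads(path.read_text(encoding="utf-8"))
    doc.pop("BIDSVersion")
    _write_json(path, doc)
    return "removed BIDSVersion from dataset_description.json"


def _d_sidecar_superset(root: Path) -> str:
    target = _first_data_file(root)
    stem, _ = target.name.split(".", 1)
    parts = stem.split("_")
    parts.insert(len(parts) - 1, "chunk-77")
    extra = target.parent / ("_".join(parts) + ".json")
    _write_json(extra, {"Magnification": 40})
    return f"added superset sidecar {extra.name}"


def _d_stain_undescribed(root: Path) -> str:
    return "removed SampleStaining from " + _edit_sidecar(
        root, "SampleStaining", lambda doc: doc.pop("SampleStaining")
    )


def _d_species_not_binomial(root: Path) -> str:
    _edit_table(
        root, "participants.tsv", lambda l: _set_table_cell(l, "species", 1, "mouse")
    )
    return "set a species cell to the single word 'mouse'"


def _d_old_bids_version(root: Path) -> str:
    path = root / "dataset_description.json"
    doc = json.loads(path.read_text(encoding="utf-8"))
    doc["BIDSVersion"] = "1.6.0"
    _write_json(path, doc)
    return "set BIDSVersion to 1.6.0"


def _d_pad_inconsistent(root: Path) -> str:
    files = sorted(root.glob("sub-*/micr/*chunk-04*"))
    for target in files:
        _rename(target, target.name.replace("chunk-04", "chunk-4"))
    return "renamed chunk-04 files to chunk-4"


DEFECTS: dict[str, Defect] = {
    d.code: d
    for d in [
        Defect("drop_sample_type_column", "E_MISSING_SAMPLE_TYPE", ("png2d", "ometiff3d"),
               "samples.tsv loses its mandatory sample_type column", _d_drop_sample_type),
        Defect("unknown_sample_type", "E_UNKNOWN_SAMPLE_TYPE", ("png2d", "ometiff3d"),
               "a sample_type outside the biosample vocabulary", _d_unknown_sample_type),
        Defect("duplicate_sample_row", "E_DUP_SAMPLE", ("png2d", "ometiff3d"),
               "a duplicated (participant, sample) row", _d_duplicate_sample),
        Defect("cycle_derived_from", "E_DERIVED_FROM_CYCLE", ("png2d",),
               "two samples deriving from each other", _d_cycle_derived_from),
        Defect("derived_from_unknown", "E_DERIVED_FROM_UNKNOWN", ("png2d",),
               "derived_from pointing at no sample", _d_derived_from_unknown),
        Defect("bad_rrid", "E_BAD_RRID", ("png2d", "ometiff3d"),
               "a strain_rrid without the RRID: prefix", _d_bad_rrid),
        Defect("bad_suffix", "E_UNKNOWN_SUFFIX", ("png2d", "ometiff3d"),
               "a data filename with an unregistered suffix", _d_bad_suffix),
        Defect("unknown_extension", "E_UNKNOWN_EXTENSION", ("png2d",),
               "a data filename with an unregistered extension", _d_unknown_extension),
        Defect("entity_order", "E_ENTITY_ORDER", ("png2d",),
               "stain preceding sample in a filename", _d_entity_order),
        Defect("missing_required_entity", "E_MISSING_REQUIRED_ENTITY", ("png2d", "ometiff3d"),
               "a data filename without the sample entity", _d_missing_required_entity),
        Defect("misplace_file", "E_MISPLACED_FILE", ("png2d", "ometiff3d"),
               "a data file outside its micr/ directory", _d_misplace_file),
        Defect("path_entity_mismatch", "E_PATH_ENTITY_MISMATCH", ("png2d", "ometiff3d"),
               "filename sub label disagreeing with its directory", _d_path_entity_mismatch),
        Defect("corrupt_json", "E_JSON_MALFORMED", ("png2d", "ometiff3d"),
               "a truncated sidecar JSON", _d_corrupt_json),
        Defect("missing_pixel_size", "E_MISSING_REQUIRED_FIELD", ("png2d", "ometiff3d"),
               "a sidecar without the required PixelSize", _d_missing_pixel_size),
        Defect("vocab_violation", "E_VOCAB_VIOLATION", ("png2d", "ometiff3d"),
               "SampleEnvironment outside its vocabulary", _d_vocab_violation),
        Defect("pixel_size_mismatch", "E_PIXELSIZE_MISMATCH", ("ometiff3d",),
               "sidecar PixelSize disagreeing with the OME header", _d_pixel_size_mismatch),
        Defect("wrong_matrix_shape", "E_MATRIX_SHAPE", ("ometiff3d",),
               "a 3x3 matrix on a 3D image", _d_wrong_matrix_shape),
        Defect("bad_matrix_bottom", "E_MATRIX_HOMOGENEOUS", ("ometiff3d",),
               "a non-homogeneous bottom row", _d_bad_matrix_bottom),
        Defect("missing_samples_table", "E_SAMPLES_TSV_MISSING", ("png2d", "ometiff3d"),
               "samples.tsv deleted while sample entities exist", _d_missing_samples_table),
        Defect("sample_not_in_table", "E_SAMPLE_NOT_IN_TABLE", ("png2d",),
               "a data file whose sample row is gone", _d_sample_not_in_table),
        Defect("remove_description_key", "E_DESC_MISSING_KEY", ("png2d", "ometiff3d"),
               "dataset_description.json without BIDSVersion", _d_remove_description_key),
        Defect("sidecar_superset", "E_SIDECAR_ENTITY_SUPERSET", ("png2d",),
               "a sidecar carrying entities its data file lacks", _d_sidecar_superset),
        Defect("stain_undescribed", "W_STAIN_UNDESCRIBED", ("png2d",),
               "a stained file without staining metadata", _d_stain_undescribed),
        Defect("species_not_binomial", "W_SPECIES_NOT_BINOMIAL", ("png2d", "ometiff3d"),
               "a one-word species name", _d_species_not_binomial),
        Defect("old_bids_version", "W_VERSION_PREDATES_MICROSCOPY", ("png2d", "ometiff3d"),
               "a BIDSVersion predating the microscopy data type", _d_old_bids_version),
        Defect("pad_inconsistent", "W_PAD_INCONSISTENT", ("ometiff3d",),
               "mixed chunk index zero-padding widths", _d_pad_inconsistent),
    ]
}


def mutate_dataset(root: str | Path, defect_code: str) -> str:
    """Apply exactly one defect from the catalogue to a generated dataset.

    Returns a one-line description of the change.  The resulting tree
    triggers the defect's mapped issue code at least once when validated.
    """
    root = Path(root)
    try:
        defect = DEFECTS[defect_code]
    except KeyError:
        raise FixtureError(
            f"unknown defect code {defect_code!r}", code="E_UNKNOWN_DEFECT"
        ) from None
    return defect.apply(root)
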