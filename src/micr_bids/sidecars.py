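"""Sidecar JSON resolution, validation, and OME-TIFF header consistency.

Each image file may be described by several JSON files along its path
(dataset root, subject, session, and the ``micr`` directory itself), per the
BIDS Inheritance Principle: a JSON applies to a data file when its suffix
matches and its entities are a subset of the data file's, and deeper or more
specific files override shallower ones field by field.

OME-TIFF files additionally embed an OME-XML header.  The sidecar remains
authoritative; the header is only cross-checked where both state the same
physical quantity (pixel sizes), after conversion to micrometres.  The
mm/um/nm lattice converts by powers of 10^3, so the comparison tolerance
(default 1e-4 relative) only has to absorb decimal-string round-trips.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

import tifffile

from . import chunks
from .entities import ParsedName, split_extension, _RANK, _ATTR
from .errors import NameParseError, SidecarError
from .issues import Issue, make_issue
from .registry import STAINING_FIELDS, SchemaRegistry, default_registry

#: length-unit token -> micrometres per unit; accepts both the sidecar
#: spellings and the OME-XML micro sign.
_TO_UM = {"mm": 1e3, "um": 1.0, "µm": 1.0, "μm": 1.0, "nm": 1e-3}


def to_micrometres(value: float, unit: str) -> float | None:
    factor = _TO_UM.get(unit)
    return None if factor is None else value * factor


@dataclass
class SidecarDoc:
    """Merged metadata for one data file, with contribution provenance."""

    fields: dict[str, object] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def get(self, name: str, default=None):
        return self.fields.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.fields


@dataclass(frozen=True)
class OmeHeader:
    """The subset of the OME-XML Pixels element this toolkit reads."""

    size_x: int
    size_y: int
    size_z: int = 1
    physical_size_x: float | None = None
    physical_size_y: float | None = None
    physical_size_z: float | None = None
    physical_size_x_unit: str = "µm"
    physical_size_y_unit: str = "µm"
    physical_size_z_unit: str = "µm"


def _parse_sidecar_stem(stem: str) -> tuple[dict[str, str], str] | None:
    """Lenient parse of a sidecar filename stem: entity subset + suffix.

    Returns None when the stem does not follow the grammar at all (such
    files are simply not sidecar candidates).
    """
    tokens = stem.split("_")
    if not tokens or any(not t for t in tokens):
        return None
    suffix = tokens[-1]
    entities: dict[str, str] = {}
    last_rank = -1
    for token in tokens[:-1]:
        key, dash, value = token.partition("-")
        if not dash or key not in _RANK or _RANK[key] <= last_rank or not value:
            return None
        last_rank = _RANK[key]
        entities[key] = value
    return entities, suffix


def resolve_sidecar(
    data_file: str, root: str | Path
) -> tuple[SidecarDoc, list[Issue]]:
    """Collect and merge the JSON sidecars applicable to one data file.

    ``data_file`` is the dataset-relative path of the image.  Returns the
    merged document (deepest file wins per field) together with any issues
    found along the way (malformed JSON, sidecars carrying entities the data
    file lacks).
    """
    root = Path(root)
    rel = PurePosixPath(data_file)
    try:
        data_stem, _ = split_extension(rel.name)
    except NameParseError:
        raise ValueError(f"{data_file!r} is not a parseable data filename")
    parsed_data = _parse_sidecar_stem(data_stem)
    if parsed_data is None:
        raise ValueError(f"{data_file!r} is not a parseable data filename")
    data_entities, data_suffix = parsed_data

    # Directories from root-most to the file's own directory.
    levels = [root]
    for part in rel.parent.parts:
        levels.append(levels[-1] / part)

    issues: list[Issue] = []
    doc = SidecarDoc()
    for depth, directory in enumerate(levels):
        if not directory.is_dir():
            continue
        candidates = []
        for entry in sorted(directory.iterdir()):
            if not entry.is_file() or not entry.name.endswith(".json"):
                continue
            if entry.name in ("dataset_description.json", "samples.json", "participants.json"):
                continue
            parsed = _parse_sidecar_stem(entry.name[: -len(".json")])
            if parsed is None:
                continue
            entities, suffix = parsed
            if suffix != data_suffix:
                continue
            shared_match = all(
                data_entities.get(k) == v for k, v in entities.items() if k in data_entities
            )
            if not shared_match:
                continue  # belongs to a different file
            extra = set(entities) - set(data_entities)
            if extra:
                issues.append(
                    make_issue(
                        "E_SIDECAR_ENTITY_SUPERSET",
                        str(entry.relative_to(root)),
                        f"sidecar carries entities {sorted(extra)} absent from "
                        f"{rel.name}",
                    )
                )
                continue
            candidates.append((len(entities), entry))
        # within one directory, fewer entities merge first (less specific)
        for _, entry in sorted(candidates, key=lambda c: (c[0], c[1].name)):
            try:
                fields = json.loads(entry.read_text(encoding="utf-8"))
            except (json.JSONDecodeError, UnicodeDecodeError) as exc:
                issues.append(
                    make_issue(
                        "E_JSON_MALFORMED",
                        str(entry.relative_to(root)),
                        f"could not parse JSON: {exc}",
                    )
                )
                continue
            if not isinstance(fields, dict):
                issues.append(
                    make_issue(
                        "E_JSON_MALFORMED",
                        str(entry.relative_to(root)),
                        "sidecar top level is not a JSON object",
                    )
                )
                continue
            doc.fields.update(fields)
            doc.provenance.append(str(entry.relative_to(root)))
    return doc, issues


# -- field validation ----------------------------------------------------

def _is_number(value) -> bool:
    return isinstance(value, (int, float)) and not isinstance(value, bool)


def _kind_ok(value, kind: str) -> bool:
    if kind == "string":
        return isinstance(value, str)
    if kind == "number":
        return _is_number(value)
    if kind == "number-array":
        return isinstance(value, list) and value and all(_is_number(v) for v in value)
    if kind == "string-array":
        return isinstance(value, list) and value and all(isinstance(v, str) for v in value)
    if kind == "matrix":
        return (
            isinstance(value, list)
            and value
            and all(isinstance(r, list) and r for r in value)
            and len({len(r) for r in value}) == 1
            and all(_is_number(v) for r in value for v in r)
        )
    if kind == "vocab":
        return isinstance(value, str)
    raise ValueError(f"unknown value kind {kind!r}")


def pixel_spec_issues(doc: SidecarDoc, path: str) -> list[Issue]:
    """Shape checks for PixelSize / PixelSizeUnits beyond the generic kinds."""
    issues: list[Issue] = []
    sizes = doc.get("PixelSize")
    if sizes is not None and _kind_ok(sizes, "number-array"):
        if len(sizes) not in (2, 3) or any(v <= 0 for v in sizes):
            issues.append(
                make_issue(
                    "E_FIELD_TYPE", path,
                    "PixelSize must hold 2 or 3 strictly positive numbers",
                    field="PixelSize",
                )
            )
    return issues


def validate_sidecar(
    doc: SidecarDoc,
    parsed: ParsedName,
    path: str,
    registry: SchemaRegistry | None = None,
    strict: bool = False,
) -> list[Issue]:
    """Validate one merged sidecar against the registry's field specs.

    Unknown fields pass silently; requirement levels follow the registry
    (required fields error when absent, recommended ones warn only in strict
    mode).  Chunk transformation matrices are delegated to
    :mod:`micr_bids.chunks` when the chunk entity is in play.
    """
    registry = registry or default_registry()
    issues: list[Issue] = []
    specs = registry.all_fields()

    for name, spec in sorted(specs.items()):
        if name not in doc:
            if spec.level == "required":
                issues.append(
                    make_issue(
                        "E_MISSING_REQUIRED_FIELD", path,
                        f"required field {name!r} is absent", field=name,
                    )
                )
            elif spec.level == "recommended" and strict:
                issues.append(
                    make_issue(
                        "W_MISSING_RECOMMENDED_FIELD", path,
                        f"recommended field {name!r} is absent", field=name,
                    )
                )
            continue
        value = doc.get(name)
        if not _kind_ok(value, spec.value_kind):
            issues.append(
                make_issue(
                    "E_FIELD_TYPE", path,
                    f"field {name!r} should be of kind {spec.value_kind}",
                    field=name,
                )
            )
            continue
        if spec.value_kind == "vocab":
            allowed = registry.vocabulary(spec.vocabulary)
            if value not in allowed:
                issues.append(
                    make_issue(
                        "E_VOCAB_VIOLATION", path,
                        f"field {name!r} value {value!r} is outside its vocabulary",
                        field=name,
                    )
                )

    issues.extend(pixel_spec_issues(doc, path))

    if parsed.entities.stain is not None and not any(
        f in doc for f in STAINING_FIELDS
    ):
        issues.append(
            make_issue(
                "W_STAIN_UNDESCRIBED", path,
                "stain entity present but none of "
                + "/".join(STAINING_FIELDS)
                + " is given",
            )
        )

    if parsed.entities.chunk is not None and "ChunkTransformationMatrix" in doc:
        matrix = doc.get("ChunkTransformationMatrix")
        axes = doc.get("ChunkTransformationMatrixAxis")
        if _kind_ok(matrix, "matrix"):
            sizes = doc.get("PixelSize")
            if _kind_ok(sizes, "number-array") and len(sizes) in (2, 3):
                dims = len(sizes)
            elif _kind_ok(axes, "string-array"):
                dims = len(axes)
            else:
                dims = len(matrix) - 1
            axes_list = axes if _kind_ok(axes, "string-array") else None
            issues.extend(
                chunks.validate_transform(matrix, axes_list, dims, path=path)
            )
    return issues


# -- OME-TIFF header -----------------------------------------------------

def parse_ome_header(path: str | Path) -> OmeHeader:
    """Read the OME-XML Pixels attributes from the first IFD of an OME-TIFF."""
    try:
        with tifffile.TiffFile(str(path)) as tif:
            description = tif.pages[0].description
        if not description:
            raise ValueError("empty ImageDescription tag")
        root = ET.fromstring(description)
        pixels = root.find(".//{*}Pixels")
        if pixels is None:
            raise ValueError("no Pixels element in OME-XML")
        attrs = pixels.attrib

        def num(name, cast, default=None):
            raw = attrs.get(name)
            return default if raw is None else cast(raw)

        return OmeHeader(
            size_x=num("SizeX", int, 1),
            size_y=num("SizeY", int, 1),
            size_z=num("SizeZ", int, 1),
            physical_size_x=num("PhysicalSizeX", float),
            physical_size_y=num("PhysicalSizeY", float),
            physical_size_z=num("PhysicalSizeZ", float),
            physical_size_x_unit=attrs.get("PhysicalSizeXUnit", "µm"),
            physical_size_y_unit=attrs.get("PhysicalSizeYUnit", "µm"),
            physical_size_z_unit=attrs.get("PhysicalSizeZUnit", "µm"),
        )
    except Exception as exc:
        raise SidecarError(
            f"cannot read OME header of {path}: {exc}",
            code="E_OME_HEADER_UNREADABLE",
            path=str(path),
        ) from exc


def check_ome_consistency(
    doc: SidecarDoc,
    header: OmeHeader,
    path: str = "",
    tolerance: float = 1e-4,
) -> list[Issue]:
    """Compare sidecar PixelSize with the OME header's physical sizes.

    Both are converted to micrometres; axes the header does not declare are
    not findings (the sidecar is authoritative, the header optional).
    """
    issues: list[Issue] = []
    sizes = doc.get("PixelSize")
    units = doc.get("PixelSizeUnits")
    if not (_kind_ok(sizes, "number-array") and isinstance(units, str)):
        return issues
    if len(sizes) not in (2, 3):
        return issues
    header_axes = [
        ("X", header.physical_size_x, header.physical_size_x_unit),
        ("Y", header.physical_size_y, header.physical_size_y_unit),
        ("Z", header.physical_size_z, header.physical_size_z_unit),
    ]
    for (axis, hvalue, hunit), svalue in zip(header_axes, sizes):
        if hvalue is None:
            continue
        sidecar_um = to_micrometres(svalue, units)
        header_um = to_micrometres(hvalue, hunit)
        if sidecar_um is None or header_um is None:
            continue
        denom = max(abs(sidecar_um), abs(header_um))
        if denom == 0 or abs(sidecar_um - header_um) / denom > tolerance:
            issues.append(
                make_issue(
                    "E_PIXELSIZE_MISMATCH", path,
                    f"axis {axis}: sidecar {sidecar_um} um vs OME header "
                    f"{header_um} um",
                    axis=axis,
                )
            )
    return issues
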