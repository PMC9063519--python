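"""Walk a dataset tree, apply every microscopy rule, aggregate findings.

Validation is structural and metadata-level: pixel data is never opened
except to read OME-TIFF headers.  The run is deterministic — directory
walks are sorted and the report is ordered by (path, code, message) — so
two runs over the same tree produce byte-identical JSON reports.

Files whose path disagrees with their filename entities are recorded as
issues and excluded from all cross-checks (samples table matching, sidecar
validation): their identity cannot be trusted.  Likewise a data file whose
sidecar chain contains malformed JSON is reported once and its field-level
validation is skipped rather than cascading spurious missing-field errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

from .entities import ParsedName, parse_filename
from .errors import DatasetError, NameParseError, TableError
from .issues import Issue, ValidationReport, make_issue
from .registry import SchemaRegistry, default_registry
from .sidecars import (
    SidecarDoc,
    check_ome_consistency,
    parse_ome_header,
    resolve_sidecar,
    validate_sidecar,
)
from .errors import SidecarError
from .tables import read_table, validate_participants, validate_samples

#: version at which the micr data type entered the upstream specification
MICROSCOPY_SINCE = (1, 7)

_OME_EXTENSIONS = (".ome.tif", ".ome.btf")
_ROOT_TABLES = ("participants.tsv", "samples.tsv")


@dataclass
class ValidationConfig:
    """Validator knobs: strictness and user vocabulary extensions."""

    strict: bool = False
    vocab_extra: dict[str, list[str]] = dataclass_field(default_factory=dict)
    ome_tolerance: float = 1e-4


@dataclass(frozen=True)
class DataFile:
    rel_path: str
    parsed: ParsedName


@dataclass
class DatasetIndex:
    """The walked tree: data files that parsed and sit where they belong."""

    root: str
    has_description: bool
    data_files: list[DataFile] = dataclass_field(default_factory=list)
    tables: dict[str, str] = dataclass_field(default_factory=dict)
    issues: list[Issue] = dataclass_field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted({f.parsed.entities.subject for f in self.data_files})

    @property
    def observed_pairs(self) -> set[tuple[str, str]]:
        return {
            (f.parsed.entities.subject, f.parsed.entities.sample)
            for f in self.data_files
        }


def _skip(name: str) -> bool:
    return name.startswith(".") or name == "derivatives"


def _index_micr_dir(
    micr: Path,
    root: Path,
    sub_label: str,
    ses_label: str | None,
    registry: SchemaRegistry,
    index: DatasetIndex,
) -> None:
    for entry in sorted(micr.iterdir()):
        rel = str(entry.relative_to(root))
        if entry.is_dir() or _skip(entry.name):
            continue
        if entry.name.endswith(".json"):
            continue  # sidecar candidates resolve per data file
        try:
            parsed = parse_filename(entry.name, registry)
        except NameParseError as exc:
            index.issues.append(make_issue(exc.code, rel, str(exc)))
            continue
        entities = parsed.entities
        if entities.subject != sub_label or entities.session != ses_label:
            index.issues.append(
                make_issue(
                    "E_PATH_ENTITY_MISMATCH", rel,
                    f"filename labels (sub-{entities.subject}, "
                    f"ses-{entities.session}) disagree with directory "
                    f"(sub-{sub_label}, ses-{ses_label})",
                )
            )
            continue
        index.data_files.append(DataFile(rel_path=rel, parsed=parsed))


def _index_loose_files(
    directory: Path, root: Path, registry: SchemaRegistry, index: DatasetIndex
) -> None:
    """Flag grammar-conforming data files that sit outside a micr/ directory."""
    for entry in sorted(directory.iterdir()):
        if not entry.is_file() or entry.name.endswith(".json") or _skip(entry.name):
            continue
        try:
            parse_filename(entry.name, registry)
        except (NameParseError, ValueError):
            continue  # not microscopy data; none of our business
        index.issues.append(
            make_issue(
                "E_MISPLACED_FILE",
                str(entry.relative_to(root)),
                "microscopy data file outside a micr/ directory",
            )
        )


def index_dataset(
    root: str | Path, registry: SchemaRegistry | None = None
) -> DatasetIndex:
    """Enumerate the tree; raise ``E_NOT_A_DATASET`` if it is not one."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    registry = registry or default_registry()

    has_description = (root / "dataset_description.json").is_file()
    sub_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and d.name.startswith("sub-")
    )
    if not has_description and not sub_dirs:
        raise DatasetError(
            f"{root} has neither dataset_description.json nor sub-* directories",
            code="E_NOT_A_DATASET",
            path=str(root),
        )

    index = DatasetIndex(root=str(root), has_description=has_description)
    for name in _ROOT_TABLES:
        if (root / name).is_file():
            index.tables[name] = str(root / name)

    for sub_dir in sub_dirs:
        sub_label = sub_dir.name[len("sub-"):]
        _index_loose_files(sub_dir, root, registry, index)
        for entry in sorted(sub_dir.iterdir()):
            if not entry.is_dir() or _skip(entry.name):
                continue
            if entry.name == "micr":
                _index_micr_dir(entry, root, sub_label, None, registry, index)
            elif entry.name.startswith("ses-"):
                ses_label = entry.name[len("ses-"):]
                _index_loose_files(entry, root, registry, index)
                for sub_entry in sorted(entry.iterdir()):
                    if not sub_entry.is_dir() or _skip(sub_entry.name):
                        continue
                    if sub_entry.name == "micr":
                        _index_micr_dir(
                            sub_entry, root, sub_label, ses_label, registry, index
                        )
                    else:
                        index.issues.append(
                            make_issue(
                                "W_NON_MICR_DATA",
                                str(sub_entry.relative_to(root)),
                                "non-microscopy data type directory skipped",
                            )
                        )
            else:
                index.issues.append(
                    make_issue(
                        "W_NON_MICR_DATA",
                        str(entry.relative_to(root)),
                        "non-microscopy data type directory skipped",
                    )
                )
    return index


def _parse_version(version: str) -> tuple[int, ...] | None:
    parts = version.split(".")
    try:
        return tuple(int(p) for p in parts[:2])
    except ValueError:
        return None


def _check_description(root: Path, index: DatasetIndex) -> list[Issue]:
    issues: list[Issue] = []
    path = "dataset_description.json"
    if not index.has_description:
        issues.append(
            make_issue(
                "E_MISSING_DATASET_DESCRIPTION", path,
                "dataset_description.json is required at the dataset root",
            )
        )
        return issues
    try:
        doc = json.loads((root / path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        issues.append(make_issue("E_JSON_MALFORMED", path, f"could not parse: {exc}"))
        return issues
    if not isinstance(doc, dict):
        issues.append(make_issue("E_JSON_MALFORMED", path, "top level is not an object"))
        return issues
    for key in ("Name", "BIDSVersion"):
        if key not in doc:
            issues.append(
                make_issue("E_DESC_MISSING_KEY", path, f"missing required key {key!r}")
            )
    version = doc.get("BIDSVersion")
    if isinstance(version, str):
        parsed = _parse_version(version)
        if parsed is not None and parsed < MICROSCOPY_SINCE:
            issues.append(
                make_issue(
                    "W_VERSION_PREDATES_MICROSCOPY", path,
                    f"BIDSVersion {version} predates the microscopy data type "
                    "(introduced in 1.7.0)",
                )
            )
    return issues


def _group_key(f: DataFile) -> tuple:
    e = f.parsed.entities
    return (e.subject, e.session, e.sample, e.acquisition, e.stain, f.parsed.suffix)


def _check_index_padding(index: DatasetIndex) -> list[Issue]:
    """Within one sample+suffix group, index widths should be uniform."""
    issues: list[Issue] = []
    groups: dict[tuple, list[DataFile]] = {}
    for f in index.data_files:
        groups.setdefault(_group_key(f), []).append(f)
    for key, files in sorted(groups.items()):
        for attr in ("chunk", "run"):
            widths = {
                len(getattr(f.parsed.entities, attr))
                for f in files
                if getattr(f.parsed.entities, attr) is not None
            }
            if len(widths) > 1:
                issues.append(
                    make_issue(
                        "W_PAD_INCONSISTENT",
                        sorted(f.rel_path for f in files)[0],
                        f"{attr} indices of group {key[:3]} mix zero-padding "
                        f"widths {sorted(widths)}",
                    )
                )
    return issues


def _check_chunk_groups(
    index: DatasetIndex, docs: dict[str, SidecarDoc]
) -> list[Issue]:
    """All chunks of one group must agree on axes and dimensionality."""
    issues: list[Issue] = []
    groups: dict[tuple, list[DataFile]] = {}
    for f in index.data_files:
        if f.parsed.entities.chunk is not None:
            groups.setdefault(_group_key(f), []).append(f)
    for key, files in sorted(groups.items()):
        axes_seen: set[tuple[str, ...]] = set()
        dims_seen: set[int] = set()
        for f in files:
            doc = docs.get(f.rel_path)
            if doc is None:
                continue
            axes = doc.get("ChunkTransformationMatrixAxis")
            matrix = doc.get("ChunkTransformationMatrix")
            if isinstance(axes, list) and all(isinstance(a, str) for a in axes):
                axes_seen.add(tuple(axes))
                dims_seen.add(len(axes))
            elif isinstance(matrix, list) and matrix:
                dims_seen.add(len(matrix) - 1)
        anchor = sorted(f.rel_path for f in files)[0]
        if len(axes_seen) > 1:
            issues.append(
                make_issue(
                    "E_MIXED_AXES", anchor,
                    f"chunks of group {key[:3]} declare different axis orders "
                    f"{sorted(axes_seen)}",
                )
            )
        if len(dims_seen) > 1:
            issues.append(
                make_issue(
                    "E_MIXED_DIMENSIONALITY", anchor,
                    f"chunks of group {key[:3]} mix dimensionalities "
                    f"{sorted(dims_seen)}",
                )
            )
    return issues


def validate_dataset(
    root: str | Path, config: ValidationConfig | None = None
) -> ValidationReport:
    """Run every rule over a dataset tree and return the full report."""
    root = Path(root)
    config = config or ValidationConfig()
    registry = default_registry()
    if config.vocab_extra:
        registry = registry.with_vocab_extensions(config.vocab_extra)

    report = ValidationReport(root=str(root))
    try:
        index = index_dataset(root, registry)
    except DatasetError as exc:
        report.add(make_issue(exc.code, ".", str(exc)))
        return report.finalize()
    report.extend(index.issues)
    report.extend(_check_description(root, index))

    # -- tables ----------------------------------------------------------
    if "participants.tsv" not in index.tables:
        report.add(
            make_issue(
                "W_NO_PARTICIPANTS_TABLE", "participants.tsv",
                "participants.tsv is recommended but absent",
            )
        )
    else:
        try:
            table = read_table(index.tables["participants.tsv"])
            table.path = "participants.tsv"
            report.extend(validate_participants(table))
        except TableError as exc:
            report.add(make_issue(exc.code, "participants.tsv", str(exc)))

    if "samples.tsv" not in index.tables:
        if index.data_files:
            report.add(
                make_issue(
                    "E_SAMPLES_TSV_MISSING", "samples.tsv",
                    "samples.tsv is required when sample entities are present",
                )
            )
    else:
        try:
            table = read_table(index.tables["samples.tsv"])
            table.path = "samples.tsv"
            report.extend(
                validate_samples(table, index.observed_pairs, registry)
            )
        except TableError as exc:
            report.add(make_issue(exc.code, "samples.tsv", str(exc)))

    # -- per-file sidecars ----------------------------------------------
    docs: dict[str, SidecarDoc] = {}
    for f in index.data_files:
        doc, sidecar_issues = resolve_sidecar(f.rel_path, root)
        report.extend(sidecar_issues)
        docs[f.rel_path] = doc
        if any(i.code == "E_JSON_MALFORMED" for i in sidecar_issues):
            continue  # cannot trust the merged document
        report.extend(
            validate_sidecar(
                doc, f.parsed, f.rel_path, registry, strict=config.strict
            )
        )
        if f.parsed.extension in _OME_EXTENSIONS:
            try:
                header = parse_ome_header(root / f.rel_path)
            except SidecarError as exc:
                report.add(make_issue(exc.code, f.rel_path, str(exc)))
            else:
                report.extend(
                    check_ome_consistency(
                        doc, header, f.rel_path, tolerance=config.ome_tolerance
                    )
                )

    report.extend(_check_index_padding(index))
    report.extend(_check_chunk_groups(index, docs))

    # identical findings reached through several files collapse to one
    report.issues = list(dict.fromkeys(report.issues))
    return report.finalize()
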