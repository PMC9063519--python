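"""Validation findings: issue codes, severities, and the report container.

The catalogue below is the single source of truth for which codes exist and
what severity each carries.  A code never appears with two severities; the
``E_`` / ``W_`` prefixes are a mnemonic, but severity is always looked up
here, never derived from the prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

#: code -> (severity, one-line description)
CATALOGUE: dict[str, tuple[str, str]] = {
    # filename grammar
    "E_BAD_GRAMMAR": ("error", "Filename token is not a well-formed key-value entity"),
    "E_UNKNOWN_ENTITY": ("error", "Filename uses an entity key not in the microscopy grammar"),
    "E_ENTITY_ORDER": ("error", "Entities appear out of canonical order"),
    "E_MISSING_REQUIRED_ENTITY": ("error", "Filename lacks the subject or sample entity"),
    "E_UNKNOWN_SUFFIX": ("error", "Suffix is not a registered microscopy modality"),
    "E_UNKNOWN_EXTENSION": ("error", "Extension is not one of .png/.tif/.ome.tif/.ome.btf"),
    # registry lookups
    "E_UNKNOWN_CATEGORY": ("error", "Metadata category is not one of the four registered"),
    "E_UNKNOWN_VOCABULARY": ("error", "No controlled vocabulary registered under this name"),
    # tabular metadata
    "E_TSV_MALFORMED": ("error", "TSV is ragged, has an empty header, or duplicate columns"),
    "E_SAMPLES_TSV_MISSING": ("error", "samples.tsv absent although sample entities are present"),
    "E_MISSING_SAMPLE_TYPE": ("error", "samples.tsv lacks the mandatory sample_type value"),
    "E_UNKNOWN_SAMPLE_TYPE": ("error", "sample_type is outside the biosample-type vocabulary"),
    "E_DUP_SAMPLE": ("error", "Duplicate (participant_id, sample_id) pair in samples.tsv"),
    "E_DERIVED_FROM_UNKNOWN": ("error", "derived_from references no sample of this participant"),
    "E_DERIVED_FROM_CYCLE": ("error", "derived_from references form a cycle"),
    "E_SAMPLE_NOT_IN_TABLE": ("error", "A (subject, sample) pair on disk is absent from samples.tsv"),
    "E_DUP_PARTICIPANT": ("error", "Duplicate participant_id in participants.tsv"),
    "E_BAD_RRID": ("error", "strain_rrid does not match the RRID:<token> pattern"),
    "W_SAMPLE_UNUSED": ("warning", "samples.tsv row never seen among data filenames"),
    "W_SPECIES_NOT_BINOMIAL": ("warning", "species is not a two-word lowercase binomial name"),
    "W_NO_PARTICIPANTS_TABLE": ("warning", "participants.tsv is recommended but absent"),
    # sidecar metadata
    "E_JSON_MALFORMED": ("error", "Sidecar JSON could not be parsed"),
    "E_SIDECAR_ENTITY_SUPERSET": ("error", "Sidecar carries entities its data file lacks"),
    "E_MISSING_REQUIRED_FIELD": ("error", "A required metadata field is absent from the sidecar"),
    "E_FIELD_TYPE": ("error", "Metadata field value has the wrong type or shape"),
    "E_VOCAB_VIOLATION": ("error", "Metadata field value outside its controlled vocabulary"),
    "E_PIXELSIZE_MISMATCH": ("error", "Sidecar PixelSize disagrees with the OME header"),
    "E_OME_HEADER_UNREADABLE": ("error", "OME-TIFF header could not be read or parsed"),
    "W_MISSING_RECOMMENDED_FIELD": ("warning", "A recommended metadata field is absent (strict mode)"),
    "W_STAIN_UNDESCRIBED": ("warning", "stain entity present but no staining metadata given"),
    # chunk transformations
    "E_MATRIX_SHAPE": ("error", "ChunkTransformationMatrix is not (d+1)x(d+1)"),
    "E_MATRIX_HOMOGENEOUS": ("error", "Matrix bottom row is not [0, ..., 0, 1]"),
    "E_AXES_MISMATCH": ("error", "Axis names mismatch the dimensionality or repeat"),
    "E_DIM_MISMATCH": ("error", "Point dimensionality mismatches the matrix"),
    "E_MIXED_DIMENSIONALITY": ("error", "Chunks of one group mix 2D and 3D placements"),
    "E_MIXED_AXES": ("error", "Chunks of one group use different axis orders"),
    "E_UNSUPPORTED_TRANSFORM": ("error", "Rotation/shear present; stitching is undefined"),
    "E_SCALE_ZERO": ("error", "A scale term of the transformation is zero"),
    "W_NONAXIAL_TRANSFORM": ("warning", "Matrix has off-diagonal terms beyond scaling+translation"),
    # dataset structure
    "E_NOT_A_DATASET": ("error", "No dataset_description.json and no sub-* directories"),
    "E_MISSING_DATASET_DESCRIPTION": ("error", "dataset_description.json is absent"),
    "E_DESC_MISSING_KEY": ("error", "dataset_description.json lacks Name or BIDSVersion"),
    "E_MISPLACED_FILE": ("error", "Data file is outside its micr/ directory"),
    "E_PATH_ENTITY_MISMATCH": ("error", "Filename sub/ses labels disagree with the directory"),
    "W_VERSION_PREDATES_MICROSCOPY": ("warning", "BIDSVersion predates the microscopy data type (1.7.0)"),
    "W_PAD_INCONSISTENT": ("warning", "Inconsistent index zero-padding within one group"),
    "W_NON_MICR_DATA": ("warning", "Non-microscopy data type directory skipped"),
    # fixtures
    "E_ROOT_NOT_EMPTY": ("error", "Target directory for generation is not empty"),
    "E_UNKNOWN_DEFECT": ("error", "Defect code not in the mutation catalogue"),
    "E_WRITE_FAILED": ("error", "Could not write the requested fixture file"),
}

ERROR_CODES = frozenset(c for c, (s, _) in CATALOGUE.items() if s == "error")
WARNING_CODES = frozenset(c for c, (s, _) in CATALOGUE.items() if s == "warning")


def severity_of(code: str) -> str:
    return CATALOGUE[code][0]


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    code: str
    path: str
    message: str
    context: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.code not in CATALOGUE:
            raise KeyError(f"unknown issue code {self.code!r}")

    @property
    def severity(self) -> str:
        return severity_of(self.code)

    def as_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
            "context": dict(self.context),
        }


def make_issue(code: str, path: str, message: str, **context: object) -> Issue:
    ctx = tuple(sorted((k, str(v)) for k, v in context.items()))
    return Issue(code=code, path=path, message=message, context=ctx)


@dataclass
class ValidationReport:
    """Aggregate of findings over one dataset, deterministically ordered."""

    root: str = ""
    issues: list[Issue] = field(default_factory=list)

    def add(self, issue: Issue) -> None:
        self.issues.append(issue)

    def extend(self, issues) -> None:
        self.issues.extend(issues)

    def finalize(self) -> "ValidationReport":
        """Sort issues by (path, code, message) for reproducible output."""
        self.issues.sort(key=lambda i: (i.path, i.code, i.message))
        return self

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def codes(self, severity: str | None = None) -> set[str]:
        return {i.code for i in self.issues if severity is None or i.severity == severity}


def format_report(report: ValidationReport, mode: str = "text") -> str:
    """Render a report as human text or a stable machine-readable JSON string."""
    if mode == "json":
        doc = {
            "root": report.root,
            "summary": {
                "errors": len(report.errors),
                "warnings": len(report.warnings),
            },
            "issues": [i.as_dict() for i in report.issues],
        }
        return json.dumps(doc, indent=2, sort_keys=True)
    if mode != "text":
        raise ValueError(f"unknown report mode {mode!r}")
    lines: list[str] = []
    for severity, found in (("error", report.errors), ("warning", report.warnings)):
        if found:
            lines.append(f"{severity.upper()}S:")
            for i in found:
                lines.append(f"  [{i.code}] {i.path}: {i.message}")
    lines.append(f"{len(report.errors)} errors, {len(report.warnings)} warnings")
    return "\n".join(lines)


def report_from_json(doc: str) -> ValidationReport:
    """Inverse of :func:`format_report` in json mode."""
    data = json.loads(doc)
    report = ValidationReport(root=data.get("root", ""))
    for item in data["issues"]:
        report.add(
            Issue(
                code=item["code"],
                path=item["path"],
                message=item["message"],
                context=tuple(sorted((k, v) for k, v in item.get("context", {}).items())),
            )
        )
    return report
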