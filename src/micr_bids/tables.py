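"""Dataset-level tables: ``samples.tsv`` and ``participants.tsv``.

Both follow the BIDS TSV dialect: UTF-8, tab-separated, first row is the
header, and the literal cell ``n/a`` marks a missing value.  ``samples.tsv``
is the authoritative listing of physical samples: it requires a
``sample_type`` column (biosample-type vocabulary) and may record sample
provenance through ``derived_from`` (e.g. a slice cut from a block), which
must stay within one participant and be acyclic.  ``participants.tsv``
carries subject attributes, including the recommended animal-metadata
columns ``species`` (binomial name), ``strain``, and ``strain_rrid``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import TableError
from .issues import Issue, make_issue
from .registry import SchemaRegistry, default_registry

_RRID_RE = re.compile(r"^RRID:\S+$")
_BINOMIAL_RE = re.compile(r"^[a-z]+ [a-z]+$")

MISSING = "n/a"


@dataclass
class Table:
    """A rectangular TSV: ordered header plus rows of ``column -> value``.

    Missing values (``n/a`` cells) are ``None``.
    """

    path: str
    columns: list[str]
    rows: list[dict[str, str | None]]

    def column(self, name: str) -> list[str | None]:
        return [row.get(name) for row in self.rows]


def read_table(path: str | Path) -> Table:
    """Read a BIDS TSV file; raise ``E_TSV_MALFORMED`` on structural defects."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    # allow a single trailing newline
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise TableError("empty table", code="E_TSV_MALFORMED", path=str(path))
    header = lines[0].split("\t")
    if any(not c for c in header):
        raise TableError(
            "empty column name in header", code="E_TSV_MALFORMED", path=str(path)
        )
    if len(set(header)) != len(header):
        raise TableError(
            "duplicate column names", code="E_TSV_MALFORMED", path=str(path)
        )
    rows: list[dict[str, str | None]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise TableError(
                f"row {lineno} has {len(cells)} cells, header has {len(header)}",
                code="E_TSV_MALFORMED",
                path=str(path),
            )
        rows.append(
            {col: (None if cell == MISSING else cell) for col, cell in zip(header, cells)}
        )
    return Table(path=str(path), columns=header, rows=rows)


def _strip_prefix(value: str, prefix: str) -> str:
    return value[len(prefix):] if value.startswith(prefix) else value


def derivation_ancestors(
    edges: dict[str, str | None]
) -> dict[str, set[str]]:
    """Resolve every sample's full chain of ancestors through ``derived_from``.

    ``edges`` maps sample id -> parent id (or None).  Exactly the members of
    a cycle appear among their own ancestors, which callers treat as a
    defect; chains merely leading into a cycle do not.
    """
    ancestors: dict[str, set[str]] = {}
    for node in edges:
        chain: set[str] = set()
        parent = edges.get(node)
        while parent is not None and parent not in chain:
            chain.add(parent)
            parent = edges.get(parent)
        ancestors[node] = chain
    return ancestors


def validate_samples(
    table: Table,
    observed: set[tuple[str, str]] | None = None,
    registry: SchemaRegistry | None = None,
) -> list[Issue]:
    """Check samples.tsv content and cross-check against filenames.

    ``observed`` holds (subject label, sample label) pairs gathered from data
    filenames; rows and files are matched after stripping the ``sub-`` /
    ``sample-`` id prefixes the table conventionally carries.
    """
    registry = registry or default_registry()
    issues: list[Issue] = []
    path = table.path

    if "sample_type" not in table.columns:
        issues.append(
            make_issue(
                "E_MISSING_SAMPLE_TYPE", path, "samples.tsv lacks the mandatory sample_type column"
            )
        )
    for required in ("sample_id", "participant_id"):
        if required not in table.columns:
            issues.append(
                make_issue(
                    "E_TSV_MALFORMED", path, f"samples.tsv lacks the {required} column"
                )
            )
            return issues

    sample_types = set(registry.vocabulary("sample_type"))
    seen_pairs: set[tuple[str, str]] = set()
    per_participant: dict[str, dict[str, str | None]] = {}

    for idx, row in enumerate(table.rows, start=2):
        sample = _strip_prefix(row.get("sample_id") or "", "sample-")
        participant = _strip_prefix(row.get("participant_id") or "", "sub-")
        pair = (participant, sample)
        if pair in seen_pairs:
            issues.append(
                make_issue(
                    "E_DUP_SAMPLE", path,
                    f"duplicate sample {sample!r} for participant {participant!r}",
                    row=idx,
                )
            )
        seen_pairs.add(pair)
        if "sample_type" in table.columns:
            stype = row.get("sample_type")
            if stype is None:
                issues.append(
                    make_issue(
                        "E_MISSING_SAMPLE_TYPE", path,
                        f"sample {sample!r} has no sample_type", row=idx,
                    )
                )
            elif stype not in sample_types:
                issues.append(
                    make_issue(
                        "E_UNKNOWN_SAMPLE_TYPE", path,
                        f"sample_type {stype!r} is not a registered biosample type",
                        row=idx,
                    )
                )
        derived = row.get("derived_from")
        if derived is not None:
            derived = _strip_prefix(derived, "sample-")
        per_participant.setdefault(participant, {})[sample] = derived

    # derived_from resolution, scoped within each participant
    for participant, edges in sorted(per_participant.items()):
        for sample, parent in sorted(edges.items()):
            if parent is not None and parent not in edges:
                issues.append(
                    make_issue(
                        "E_DERIVED_FROM_UNKNOWN", path,
                        f"sample {sample!r} of participant {participant!r} derives "
                        f"from unknown sample {parent!r}",
                    )
                )
        ancestors = derivation_ancestors(edges)
        cyclic = sorted(s for s, anc in ancestors.items() if s in anc)
        for sample in cyclic:
            issues.append(
                make_issue(
                    "E_DERIVED_FROM_CYCLE", path,
                    f"derived_from cycle involving sample {sample!r} "
                    f"of participant {participant!r}",
                )
            )

    if observed is not None:
        for pair in sorted(observed - seen_pairs):
            issues.append(
                make_issue(
                    "E_SAMPLE_NOT_IN_TABLE", path,
                    f"data files exist for subject {pair[0]!r} sample {pair[1]!r} "
                    "but samples.tsv has no such row",
                )
            )
        for pair in sorted(seen_pairs - observed):
            issues.append(
                make_issue(
                    "W_SAMPLE_UNUSED", path,
                    f"samples.tsv row for subject {pair[0]!r} sample {pair[1]!r} "
                    "matches no data file",
                )
            )
    return issues


def validate_participants(table: Table) -> list[Issue]:
    """Check participants.tsv: unique ids, RRID shape, binomial species."""
    issues: list[Issue] = []
    path = table.path
    if "participant_id" not in table.columns:
        issues.append(
            make_issue("E_TSV_MALFORMED", path, "participants.tsv lacks participant_id")
        )
        return issues
    seen: set[str] = set()
    for idx, row in enumerate(table.rows, start=2):
        pid = row.get("participant_id") or ""
        if pid in seen:
            issues.append(
                make_issue(
                    "E_DUP_PARTICIPANT", path,
                    f"duplicate participant_id {pid!r}", row=idx,
                )
            )
        seen.add(pid)
        species = row.get("species")
        if species is not None and not _BINOMIAL_RE.match(species):
            issues.append(
                make_issue(
                    "W_SPECIES_NOT_BINOMIAL", path,
                    f"species {species!r} is not a two-word lowercase binomial name",
                    row=idx,
                )
            )
        rrid = row.get("strain_rrid")
        if rrid is not None and not _RRID_RE.match(rrid):
            issues.append(
                make_issue(
                    "E_BAD_RRID", path,
                    f"strain_rrid {rrid!r} does not match RRID:<token>", row=idx,
                )
            )
    return issues
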