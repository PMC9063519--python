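"""Microscopy filename grammar: entities, suffixes, extensions, paths.

A microscopy data filename is a sequence of ``key-value`` entity tokens in a
fixed canonical order, a modality suffix, and an extension::

    sub-<label>[_ses-<label>]_sample-<label>[_acq-<label>][_stain-<label>]
        [_run-<index>][_chunk-<index>]_<suffix>.<extension>

``sub`` and ``sample`` are mandatory: the physical object under the
microscope is a sample taken from a subject, and both must be identifiable
from the filename alone.  Labels are case-sensitive alphanumeric strings;
``run`` and ``chunk`` take decimal indices (any zero-padding width).  The
two-part OME extensions ``.ome.tif`` / ``.ome.btf`` are treated as atomic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import PurePosixPath

from .errors import NameParseError
from .registry import SchemaRegistry, default_registry

#: Canonical entity order (key, attribute name, takes_index)
ENTITY_TABLE = (
    ("sub", "subject", False),
    ("ses", "session", False),
    ("sample", "sample", False),
    ("acq", "acquisition", False),
    ("stain", "stain", False),
    ("run", "run", True),
    ("chunk", "chunk", True),
)
ENTITY_KEYS = tuple(k for k, _, _ in ENTITY_TABLE)
_RANK = {k: i for i, (k, _, _) in enumerate(ENTITY_TABLE)}
_ATTR = {k: a for k, a, _ in ENTITY_TABLE}
_IS_INDEX = {k: ix for k, _, ix in ENTITY_TABLE}

_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")
_INDEX_RE = re.compile(r"^[0-9]+$")

#: Two-part extensions matched before the generic single-part rule.
_ATOMIC_EXTENSIONS = (".ome.tif", ".ome.btf")


@dataclass(frozen=True)
class EntitySet:
    """The entity values of one filename; ``subject`` and ``sample`` required."""

    subject: str
    sample: str
    session: str | None = None
    acquisition: str | None = None
    stain: str | None = None
    run: str | None = None
    chunk: str | None = None

    def __post_init__(self):
        for key in ENTITY_KEYS:
            value = getattr(self, _ATTR[key])
            if value is None:
                if key in ("sub", "sample"):
                    raise NameParseError(
                        f"entity {key!r} is required", code="E_MISSING_REQUIRED_ENTITY"
                    )
                continue
            pattern = _INDEX_RE if _IS_INDEX[key] else _LABEL_RE
            if not pattern.match(value):
                raise NameParseError(
                    f"invalid value {value!r} for entity {key!r}", code="E_BAD_GRAMMAR"
                )

    def items(self) -> list[tuple[str, str]]:
        """(key, value) pairs in canonical order, present entities only."""
        return [
            (key, getattr(self, _ATTR[key]))
            for key in ENTITY_KEYS
            if getattr(self, _ATTR[key]) is not None
        ]

    def as_dict(self) -> dict[str, str]:
        return dict(self.items())


@dataclass(frozen=True)
class ParsedName:
    entities: EntitySet
    suffix: str
    extension: str

    @property
    def filename(self) -> str:
        return build_filename(self.entities, self.suffix, self.extension)

    @property
    def relative_path(self) -> str:
        return relative_path_for(self)


def split_extension(name: str) -> tuple[str, str]:
    """Split off the extension, treating OME two-part extensions as atomic."""
    for ext in _ATOMIC_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)], ext
    if "." not in name:
        raise NameParseError(f"no extension in {name!r}", code="E_BAD_GRAMMAR")
    stem, _, tail = name.rpartition(".")
    return stem, "." + tail


def parse_filename(
    name: str, registry: SchemaRegistry | None = None
) -> ParsedName:
    """Parse a bare microscopy filename into entities, suffix, and extension.

    Raises :class:`NameParseError` with a symbolic code on any grammar
    violation; a valid parse always satisfies the canonical entity order and
    carries a registered suffix and extension.
    """
    if "/" in name or "\\" in name:
        raise ValueError(f"{name!r} is not a bare filename")
    registry = registry or default_registry()

    stem, extension = split_extension(name)
    if extension not in registry.formats:
        raise NameParseError(
            f"unknown extension {extension!r}", code="E_UNKNOWN_EXTENSION"
        )

    tokens = stem.split("_")
    if any(not t for t in tokens) or len(tokens) < 2:
        raise NameParseError(f"malformed name {name!r}", code="E_BAD_GRAMMAR")

    suffix = tokens[-1]
    if not _LABEL_RE.match(suffix):
        raise NameParseError(
            f"suffix token {suffix!r} is not alphanumeric", code="E_BAD_GRAMMAR"
        )

    values: dict[str, str] = {}
    last_rank = -1
    for token in tokens[:-1]:
        if "-" not in token:
            raise NameParseError(
                f"token {token!r} is not key-value", code="E_BAD_GRAMMAR"
            )
        key, _, value = token.partition("-")
        if key not in _RANK:
            raise NameParseError(
                f"unknown entity key {key!r}", code="E_UNKNOWN_ENTITY"
            )
        if _RANK[key] <= last_rank:
            raise NameParseError(
                f"entity {key!r} out of canonical order", code="E_ENTITY_ORDER"
            )
        last_rank = _RANK[key]
        pattern = _INDEX_RE if _IS_INDEX[key] else _LABEL_RE
        if not pattern.match(value):
            raise NameParseError(
                f"invalid value {value!r} for entity {key!r}", code="E_BAD_GRAMMAR"
            )
        values[key] = value

    if "sub" not in values or "sample" not in values:
        raise NameParseError(
            "subject and sample entities are required",
            code="E_MISSING_REQUIRED_ENTITY",
        )
    if suffix not in registry.suffixes:
        raise NameParseError(f"unknown suffix {suffix!r}", code="E_UNKNOWN_SUFFIX")

    entities = EntitySet(**{_ATTR[k]: v for k, v in values.items()})
    return ParsedName(entities=entities, suffix=suffix, extension=extension)


def build_filename(
    entities: EntitySet,
    suffix: str,
    extension: str,
    registry: SchemaRegistry | None = None,
) -> str:
    """Emit the canonical-order filename; inverse of :func:`parse_filename`."""
    registry = registry or default_registry()
    registry.lookup_suffix(suffix)
    registry.lookup_format(extension)
    parts = [f"{key}-{value}" for key, value in entities.items()]
    parts.append(suffix)
    return "_".join(parts) + extension


def relative_path_for(parsed: ParsedName) -> str:
    """Dataset-relative location: ``sub-<label>/[ses-<label>/]micr/<name>``."""
    e = parsed.entities
    path = PurePosixPath(f"sub-{e.subject}")
    if e.session is not None:
        path = path / f"ses-{e.session}"
    return str(path / "micr" / parsed.filename)
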