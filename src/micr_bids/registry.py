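"""The machine-readable rule tables of Microscopy-BIDS.

The registry holds the modality suffixes, supported file formats, metadata
field specifications grouped into four categories (DeviceHardware,
ImageAcquisition, Sample, ChunkTransformations), and the controlled
vocabularies.  It is loaded from a versioned JSON document shipped with the
package, so the rules themselves are data, auditable and diffable, and the
code is only the access layer.

Requirement levels are a toolkit policy: the upstream microscopy extension
marks almost everything "recommended", but an uninterpretable image is of
little use, so ``PixelSize`` (and its companion ``PixelSizeUnits``) are
required here.  The policy can be relaxed by treating the dataset with the
default errors-only strictness, under which only required fields produce
errors, or tightened with strict mode, which also surfaces missing
recommended fields as warnings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

from .errors import RegistryError

CATEGORIES = ("DeviceHardware", "ImageAcquisition", "Sample", "ChunkTransformations")
LEVELS = ("required", "recommended", "optional")
VALUE_KINDS = ("string", "number", "number-array", "string-array", "matrix", "vocab")

#: The three staining/immunostaining description fields recommended whenever
#: the stain entity is used in a filename.
STAINING_FIELDS = ("SampleStaining", "SamplePrimaryAntibody", "SampleSecondaryAntibody")

#: The three animal-metadata columns recommended for participants.tsv.
ANIMAL_COLUMNS = ("species", "strain", "strain_rrid")


@dataclass(frozen=True)
class ModalitySuffix:
    token: str
    long_name: str


@dataclass(frozen=True)
class FormatSpec:
    extension: str
    family: str
    tiled_allowed: bool
    carries_embedded_metadata: bool


@dataclass(frozen=True)
class MetadataFieldSpec:
    name: str
    category: str
    level: str
    value_kind: str
    vocabulary: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.level not in LEVELS:
            raise ValueError(f"bad level {self.level!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"bad value kind {self.value_kind!r}")
        if self.value_kind == "vocab" and not self.vocabulary:
            raise ValueError(f"vocab field {self.name!r} names no vocabulary")


@dataclass
class SchemaRegistry:
    """All rule tables, plus user vocabulary extensions."""

    version: str
    suffixes: dict[str, ModalitySuffix]
    formats: dict[str, FormatSpec]
    categories: dict[str, list[MetadataFieldSpec]]
    vocabularies: dict[str, list[str]]
    vocab_extensions: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def lookup_suffix(self, token: str) -> ModalitySuffix:
        try:
            return self.suffixes[token]
        except KeyError:
            raise RegistryError(
                f"unknown modality suffix {token!r}", code="E_UNKNOWN_SUFFIX"
            ) from None

    def lookup_format(self, extension: str) -> FormatSpec:
        try:
            return self.formats[extension]
        except KeyError:
            raise RegistryError(
                f"unknown extension {extension!r}", code="E_UNKNOWN_EXTENSION"
            ) from None

    def field_requirements(self, category: str) -> list[MetadataFieldSpec]:
        try:
            return list(self.categories[category])
        except KeyError:
            raise RegistryError(
                f"unknown metadata category {category!r}", code="E_UNKNOWN_CATEGORY"
            ) from None

    def all_fields(self) -> dict[str, MetadataFieldSpec]:
        return {f.name: f for specs in self.categories.values() for f in specs}

    def vocabulary(self, name: str) -> list[str]:
        if name not in self.vocabularies:
            raise RegistryError(
                f"unknown vocabulary {name!r}", code="E_UNKNOWN_VOCABULARY"
            )
        values = list(self.vocabularies[name])
        values.extend(v for v in self.vocab_extensions.get(name, []) if v not in values)
        return values

    # -- extension -------------------------------------------------------
    def with_vocab_extensions(self, extra: dict[str, list[str]]) -> "SchemaRegistry":
        """Return a copy whose vocabularies are extended with user values."""
        merged = {k: list(v) for k, v in self.vocab_extensions.items()}
        for name, values in extra.items():
            if name not in self.vocabularies:
                raise RegistryError(
                    f"unknown vocabulary {name!r}", code="E_UNKNOWN_VOCABULARY"
                )
            merged.setdefault(name, []).extend(values)
        return SchemaRegistry(
            version=self.version,
            suffixes=self.suffixes,
            formats=self.formats,
            categories=self.categories,
            vocabularies=self.vocabularies,
            vocab_extensions=merged,
        )


def _load_tables() -> dict:
    with resources.files("micr_bids.data").joinpath("registry.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def default_registry() -> SchemaRegistry:
    """The registry shipped with the package (BIDS 1.7.0 microscopy rules)."""
    raw = _load_tables()
    suffixes = {
        token: ModalitySuffix(token, long_name)
        for token, long_name in raw["suffixes"].items()
    }
    formats = {
        f["extension"]: FormatSpec(**f) for f in raw["formats"]
    }
    categories = {
        cat: [
            MetadataFieldSpec(category=cat, **spec) for spec in specs
        ]
        for cat, specs in raw["categories"].items()
    }
    return SchemaRegistry(
        version=raw["registry_version"],
        suffixes=suffixes,
        formats=formats,
        categories=categories,
        vocabularies=raw["vocabularies"],
    )
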