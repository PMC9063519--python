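"""Exception hierarchy.

Every exception carries a symbolic ``code`` drawn from the issue catalogue
(:mod:`micr_bids.issues`), so callers that aggregate findings can convert a
raised error into an :class:`~micr_bids.issues.Issue` without string matching.
"""

from __future__ import annotations


class MicrBidsError(Exception):
    """Base class for all toolkit errors."""

    def __init__(self, message: str, *, code: str, path: str | None = None):
        super().__init__(message)
        self.code = code
        self.path = path

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return f"[{self.code}] {base}" if self.code else base


class NameParseError(MicrBidsError):
    """A filename violates the entity grammar or uses unregistered tokens."""


class RegistryError(MicrBidsError):
    """Lookup of an unregistered suffix, category, or vocabulary."""


class TableError(MicrBidsError):
    """A TSV table could not be read as a rectangular header+rows grid."""


class SidecarError(MicrBidsError):
    """Sidecar resolution failed (malformed JSON, unreadable OME header)."""


class TransformError(MicrBidsError):
    """A chunk transformation cannot be applied (not merely invalid)."""


class DatasetError(MicrBidsError):
    """The directory under validation is not a dataset at all."""


class FixtureError(MicrBidsError):
    """Fixture generation or mutation failed."""
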