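"""Render the shipped rule tables as markdown, straight from the registry.

Every page is generated from the live :class:`~micr_bids.registry.SchemaRegistry`
(and the issue catalogue), never hand-maintained, so the documentation can
be diffed against the rules it documents by simply regenerating it.
"""

from __future__ import annotations

from .issues import CATALOGUE
from .registry import CATEGORIES, SchemaRegistry, default_registry


def _table(headers: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(headers) + " |"]
    lines.append("|" + "|".join(" --- " for _ in headers) + "|")
    for row in rows:
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines)


def render_registry_docs(
    registry: SchemaRegistry | None = None, mode: str = "markdown"
) -> dict[str, str]:
    """One markdown page per metadata category, plus suffix, vocabulary,
    file-format, and issue-code pages.  Deterministic output."""
    if mode != "markdown":
        raise ValueError(f"unsupported mode {mode!r}")
    registry = registry or default_registry()
    version = registry.version
    pages: dict[str, str] = {}

    pages["suffixes.md"] = "\n".join(
        [
            f"# Modality suffixes (registry {version})",
            "",
            _table(
                ["Suffix", "Modality"],
                [
                    [token, registry.suffixes[token].long_name]
                    for token in sorted(registry.suffixes)
                ],
            ),
            "",
        ]
    )

    pages["formats.md"] = "\n".join(
        [
            f"# File formats (registry {version})",
            "",
            _table(
                ["Extension", "Family", "Tiled allowed", "Embedded metadata"],
                [
                    [
                        ext,
                        spec.family,
                        str(spec.tiled_allowed).lower(),
                        str(spec.carries_embedded_metadata).lower(),
                    ]
                    for ext, spec in sorted(registry.formats.items())
                ],
            ),
            "",
        ]
    )

    for category in CATEGORIES:
        rows = [
            [
                spec.name,
                spec.level,
                spec.value_kind,
                spec.vocabulary or "",
            ]
            for spec in sorted(
                registry.field_requirements(category), key=lambda s: s.name
            )
        ]
        pages[f"fields_{category}.md"] = "\n".join(
            [
                f"# {category} metadata fields (registry {version})",
                "",
                _table(["Field", "Level", "Kind", "Vocabulary"], rows),
                "",
            ]
        )

    vocab_sections = [f"# Controlled vocabularies (registry {version})", ""]
    for name in sorted(registry.vocabularies):
        vocab_sections.append(f"## {name}")
        vocab_sections.append("")
        vocab_sections.extend(f"- {value}" for value in registry.vocabulary(name))
        vocab_sections.append("")
    pages["vocabularies.md"] = "\n".join(vocab_sections)

    pages["issue_codes.md"] = "\n".join(
        [
            "# Issue code catalogue",
            "",
            _table(
                ["Code", "Severity", "Description"],
                [
                    [code, severity, description]
                    for code, (severity, description) in sorted(CATALOGUE.items())
                ],
            ),
            "",
        ]
    )
    return pages


def write_registry_docs(directory, registry: SchemaRegistry | None = None) -> list[str]:
    """Write the rendered pages under ``directory``; return filenames."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pages = render_registry_docs(registry)
    for name, text in sorted(pages.items()):
        (directory / name).write_text(text, encoding="utf-8")
    return sorted(pages)
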