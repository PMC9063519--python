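"""Filename grammar: parsing, building, ordering, and path placement."""

import pytest
from hypothesis import given, strategies as st

from micr_bids.entities import (
    ENTITY_KEYS,
    EntitySet,
    build_filename,
    parse_filename,
    relative_path_for,
)
from micr_bids.errors import NameParseError
from micr_bids.registry import default_registry


@pytest.mark.parametrize(
    "name,entities,suffix,extension",
    [
        ("sub-01_sample-A_BF.png", {"sub": "01", "sample": "A"}, "BF", ".png"),
        (
            "sub-01_sample-A_stain-LFB_chunk-01_SPIM.ome.tif",
            {"sub": "01", "sample": "A", "stain": "LFB", "chunk": "01"},
            "SPIM",
            ".ome.tif",
        ),
        (
            "sub-01_ses-02_sample-B_acq-high_run-2_TEM.tif",
            {"sub": "01", "ses": "02", "sample": "B", "acq": "high", "run": "2"},
            "TEM",
            ".tif",
        ),
        ("sub-x_sample-y_2PE.ome.btf", {"sub": "x", "sample": "y"}, "2PE", ".ome.btf"),
    ],
)
def test_parse_valid_names(name, entities, suffix, extension):
    parsed = parse_filename(name)
    assert parsed.entities.as_dict() == entities
    assert parsed.suffix == suffix
    assert parsed.extension == extension


@pytest.mark.parametrize(
    "name,code",
    [
        ("sub-01_BF.png", "E_MISSING_REQUIRED_ENTITY"),
        ("sample-A_BF.png", "E_MISSING_REQUIRED_ENTITY"),
        ("sub-01_chunk-01_sample-A_SEM.png", "E_ENTITY_ORDER"),
        ("sub-01_sample-A_sample-B_BF.png", "E_ENTITY_ORDER"),
        ("sub-01_task-rest_sample-A_BF.png", "E_UNKNOWN_ENTITY"),
        ("sub-01_sample-A_MRI.png", "E_UNKNOWN_SUFFIX"),
        ("sub-01_sample-A_BF.jpg", "E_UNKNOWN_EXTENSION"),
        ("sub-01_sample-A_BF.PNG", "E_UNKNOWN_EXTENSION"),
        ("sub-_sample-A_BF.png", "E_BAD_GRAMMAR"),
        ("sub-01_sample-A.b_BF.png", "E_BAD_GRAMMAR"),
        ("sub-01_sample_BF.png", "E_BAD_GRAMMAR"),
        ("sub-01_sample-A_chunk-x_BF.png", "E_BAD_GRAMMAR"),
        ("sub-01__sample-A_BF.png", "E_BAD_GRAMMAR"),
        ("BF.png", "E_BAD_GRAMMAR"),
    ],
)
def test_parse_rejects_bad_names(name, code):
    with pytest.raises(NameParseError) as err:
        parse_filename(name)
    assert err.value.code == code


def test_parse_requires_bare_filename():
    with pytest.raises(ValueError):
        parse_filename("sub-01/micr/sub-01_sample-A_BF.png")


@pytest.mark.parametrize(
    "kwargs,suffix,ext,expected",
    [
        (dict(subject="01", sample="A"), "BF", ".png", "sub-01_sample-A_BF.png"),
        (
            dict(subject="01", session="01", sample="B", run="2"),
            "TEM",
            ".tif",
            "sub-01_ses-01_sample-B_run-2_TEM.tif",
        ),
    ],
)
def test_build_filename_canonical_order(kwargs, suffix, ext, expected):
    assert build_filename(EntitySet(**kwargs), suffix, ext) == expected


def test_build_rejects_missing_sample():
    with pytest.raises((NameParseError, TypeError)):
        EntitySet(subject="01", sample=None)


def test_build_rejects_unregistered_tokens():
    e = EntitySet(subject="01", sample="A")
    with pytest.raises(Exception) as err:
        build_filename(e, "MRI", ".png")
    assert err.value.code == "E_UNKNOWN_SUFFIX"
    with pytest.raises(Exception) as err:
        build_filename(e, "BF", ".jpg")
    assert err.value.code == "E_UNKNOWN_EXTENSION"


@pytest.mark.parametrize(
    "name,expected",
    [
        ("sub-01_sample-A_BF.png", "sub-01/micr/sub-01_sample-A_BF.png"),
        (
            "sub-01_ses-02_sample-A_BF.png",
            "sub-01/ses-02/micr/sub-01_ses-02_sample-A_BF.png",
        ),
    ],
)
def test_relative_path_places_session_directory(name, expected):
    assert relative_path_for(parse_filename(name)) == expected


_label = st.text(alphabet="abcdefgh0123456789", min_size=1, max_size=4)
_index = st.text(alphabet="0123456789", min_size=1, max_size=3)
_registry = default_registry()


@st.composite
def entity_sets(draw):
    return EntitySet(
        subject=draw(_label),
        sample=draw(_label),
        session=draw(st.none() | _label),
        acquisition=draw(st.none() | _label),
        stain=draw(st.none() | _label),
        run=draw(st.none() | _index),
        chunk=draw(st.none() | _index),
    )


@given(
    entities=entity_sets(),
    suffix=st.sampled_from(sorted(_registry.suffixes)),
    extension=st.sampled_from(sorted(_registry.formats)),
)
def test_parse_build_round_trip(entities, suffix, extension):
    """parse(build(x)) == x exactly, for arbitrary valid entity sets."""
    name = build_filename(entities, suffix, extension)
    parsed = parse_filename(name)
    assert parsed.entities == entities
    assert parsed.suffix == suffix
    assert parsed.extension == extension


@given(entities=entity_sets(), suffix=st.sampled_from(sorted(_registry.suffixes)))
def test_separator_mutations_never_parse(entities, suffix):
    """Flipping any single '_' or '-' separator yields an error, never a
    silently different parse."""
    name = build_filename(entities, suffix, ".png")
    stem = name[: -len(".png")]
    for i, ch in enumerate(stem):
        if ch not in "_-":
            continue
        mutated = stem[:i] + ("-" if ch == "_" else "_") + stem[i + 1:] + ".png"
        with pytest.raises(NameParseError):
            parse_filename(mutated)


def test_canonical_order_is_total():
    assert ENTITY_KEYS == ("sub", "ses", "sample", "acq", "stain", "run", "chunk")
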