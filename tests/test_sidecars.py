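"""Sidecar inheritance, field validation, and OME header consistency."""

import json

import pytest

from micr_bids.entities import parse_filename
from micr_bids.errors import SidecarError
from micr_bids.sidecars import (
    OmeHeader,
    SidecarDoc,
    check_ome_consistency,
    parse_ome_header,
    resolve_sidecar,
    to_micrometres,
    validate_sidecar,
)

DATA = "sub-01/micr/sub-01_sample-A_BF.png"


def _tree(tmp_path, sidecars: dict[str, dict | str]):
    """Lay out a minimal tree with the given sidecar files."""
    (tmp_path / "sub-01" / "micr").mkdir(parents=True)
    for rel, doc in sidecars.items():
        path = tmp_path / rel
        text = doc if isinstance(doc, str) else json.dumps(doc)
        path.write_text(text, encoding="utf-8")
    return tmp_path


def test_single_file_sidecar(tmp_path):
    root = _tree(
        tmp_path, {"sub-01/micr/sub-01_sample-A_BF.json": {"PixelSize": [1, 1]}}
    )
    doc, issues = resolve_sidecar(DATA, root)
    assert issues == []
    assert doc.fields == {"PixelSize": [1, 1]}
    assert doc.provenance == ["sub-01/micr/sub-01_sample-A_BF.json"]


def test_deeper_sidecar_overrides_and_merges(tmp_path):
    root = _tree(
        tmp_path,
        {
            "BF.json": {"Manufacturer": "RootCo", "Magnification": 10},
            "sub-01/micr/sub-01_sample-A_BF.json": {
                "PixelSize": [1, 1],
                "Magnification": 40,
            },
        },
    )
    doc, issues = resolve_sidecar(DATA, root)
    assert issues == []
    assert doc.fields == {
        "Manufacturer": "RootCo",
        "Magnification": 40,  # file level wins on conflict
        "PixelSize": [1, 1],
    }
    assert doc.provenance[0] == "BF.json"


def test_merge_idempotent_and_monotone(tmp_path):
    root = _tree(tmp_path, {"BF.json": {"Manufacturer": "RootCo"}})
    before, _ = resolve_sidecar(DATA, root)
    again, _ = resolve_sidecar(DATA, root)
    assert before.fields == again.fields
    # adding a deeper sidecar only adds/overrides, never removes
    (root / "sub-01" / "sub-01_BF.json").write_text(
        json.dumps({"InstitutionName": "Lab"}), encoding="utf-8"
    )
    after, _ = resolve_sidecar(DATA, root)
    assert set(before.fields) <= set(after.fields)


def test_unrelated_and_superset_sidecars(tmp_path):
    root = _tree(
        tmp_path,
        {
            # different sample: silently inapplicable
            "sub-01/micr/sub-01_sample-B_BF.json": {"Magnification": 10},
            # superset entities: an error finding
            "sub-01/micr/sub-01_sample-A_chunk-01_BF.json": {"Magnification": 40},
        },
    )
    doc, issues = resolve_sidecar(DATA, root)
    assert doc.fields == {}
    assert [i.code for i in issues] == ["E_SIDECAR_ENTITY_SUPERSET"]


def test_malformed_json_is_reported(tmp_path):
    root = _tree(tmp_path, {"sub-01/micr/sub-01_sample-A_BF.json": '{"PixelSize": ['})
    doc, issues = resolve_sidecar(DATA, root)
    assert [i.code for i in issues] == ["E_JSON_MALFORMED"]
    assert doc.fields == {}


def _doc(fields):
    return SidecarDoc(fields=dict(fields))


_BASE = {"PixelSize": [1.0, 1.0], "PixelSizeUnits": "um"}
_PARSED = parse_filename("sub-01_sample-A_BF.png")


def test_validate_sidecar_clean():
    assert validate_sidecar(_doc(_BASE), _PARSED, "p") == []


@pytest.mark.parametrize(
    "fields,code",
    [
        ({"PixelSizeUnits": "um"}, "E_MISSING_REQUIRED_FIELD"),
        ({**_BASE, "SampleEnvironment": "frozen"}, "E_VOCAB_VIOLATION"),
        ({**_BASE, "Magnification": "forty"}, "E_FIELD_TYPE"),
        ({**_BASE, "PixelSize": [1.0, -1.0]}, "E_FIELD_TYPE"),
        ({**_BASE, "PixelSize": [1, 1, 1, 1]}, "E_FIELD_TYPE"),
    ],
)
def test_validate_sidecar_defects(fields, code):
    issues = validate_sidecar(_doc(fields), _PARSED, "p")
    assert [i.code for i in issues] == [code]


def test_unknown_fields_pass_silently():
    issues = validate_sidecar(_doc({**_BASE, "MyCustomField": 3}), _PARSED, "p")
    assert issues == []


def test_strict_mode_surfaces_recommended_fields():
    issues = validate_sidecar(_doc(_BASE), _PARSED, "p", strict=True)
    assert issues
    assert {i.code for i in issues} == {"W_MISSING_RECOMMENDED_FIELD"}


def test_stain_entity_without_staining_fields_warns():
    parsed = parse_filename("sub-01_sample-A_stain-LFB_BF.png")
    issues = validate_sidecar(_doc(_BASE), parsed, "p")
    assert [i.code for i in issues] == ["W_STAIN_UNDESCRIBED"]
    fixed = {**_BASE, "SampleStaining": "luxol fast blue"}
    assert validate_sidecar(_doc(fixed), parsed, "p") == []


def test_chunk_matrix_delegation():
    parsed = parse_filename("sub-01_sample-A_chunk-01_BF.png")
    fields = {
        **_BASE,
        "ChunkTransformationMatrix": [[1, 0], [0, 1]],  # 2x2 for a 2D image
        "ChunkTransformationMatrixAxis": ["Y", "X"],
    }
    issues = validate_sidecar(_doc(fields), parsed, "p")
    assert "E_MATRIX_SHAPE" in {i.code for i in issues}


# -- unit conversion and OME consistency ---------------------------------

@pytest.mark.parametrize(
    "value,unit,expected",
    [(0.5, "um", 0.5), (500, "nm", 0.5), (0.0005, "mm", 0.5), (1, "µm", 1.0)],
)
def test_to_micrometres_exact_on_unit_lattice(value, unit, expected):
    assert to_micrometres(value, unit) == expected


def _header(px, unit="µm"):
    return OmeHeader(
        size_x=8, size_y=8,
        physical_size_x=px, physical_size_y=px,
        physical_size_x_unit=unit, physical_size_y_unit=unit,
    )


def test_ome_consistency_exact_match():
    doc = _doc({"PixelSize": [0.5, 0.5], "PixelSizeUnits": "um"})
    assert check_ome_consistency(doc, _header(0.5)) == []


def test_ome_consistency_across_units():
    doc = _doc({"PixelSize": [0.5, 0.5], "PixelSizeUnits": "um"})
    assert check_ome_consistency(doc, _header(500, "nm")) == []


def test_ome_consistency_mismatch():
    doc = _doc({"PixelSize": [1, 1], "PixelSizeUnits": "um"})
    issues = check_ome_consistency(doc, _header(0.5))
    assert {i.code for i in issues} == {"E_PIXELSIZE_MISMATCH"}


def test_missing_header_sizes_are_not_findings():
    doc = _doc({"PixelSize": [1, 1], "PixelSizeUnits": "um"})
    assert check_ome_consistency(doc, OmeHeader(size_x=8, size_y=8)) == []


def test_unreadable_ome_header(tmp_path):
    bogus = tmp_path / "sub-01_sample-A_SPIM.ome.tif"
    bogus.write_text("not a tiff", encoding="utf-8")
    with pytest.raises(SidecarError) as err:
        parse_ome_header(bogus)
    assert err.value.code == "E_OME_HEADER_UNREADABLE"
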