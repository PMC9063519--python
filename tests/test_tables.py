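"""TSV reading and samples/participants validation."""

import networkx as nx
import numpy as np
import pytest

from micr_bids.errors import TableError
from micr_bids.tables import (
    Table,
    derivation_ancestors,
    read_table,
    validate_participants,
    validate_samples,
)


def _write(tmp_path, text):
    path = tmp_path / "table.tsv"
    path.write_text(text, encoding="utf-8")
    return path


def test_read_table_basic(tmp_path):
    path = _write(
        tmp_path,
        "sample_id\tparticipant_id\tsample_type\n"
        "sample-A\tsub-01\ttissue\n"
        "sample-B\tsub-01\tn/a\n",
    )
    table = read_table(path)
    assert table.columns == ["sample_id", "participant_id", "sample_type"]
    assert len(table.rows) == 2
    assert table.rows[0]["sample_type"] == "tissue"
    assert table.rows[1]["sample_type"] is None  # "n/a" maps to missing


@pytest.mark.parametrize(
    "text",
    [
        "a\tb\nx\n",  # ragged row
        "a\t\nx\ty\n",  # empty header cell
        "a\ta\nx\ty\n",  # duplicate column
        "",  # empty file
    ],
)
def test_read_table_malformed(tmp_path, text):
    with pytest.raises(TableError) as err:
        read_table(_write(tmp_path, text))
    assert err.value.code == "E_TSV_MALFORMED"


def _samples(rows, columns=None):
    columns = columns or ["sample_id", "participant_id", "sample_type", "derived_from"]
    full = [{c: r.get(c) for c in columns} for r in rows]
    return Table(path="samples.tsv", columns=columns, rows=full)


def test_validate_samples_clean():
    table = _samples(
        [
            {"sample_id": "sample-A", "participant_id": "sub-01", "sample_type": "tissue"},
            {"sample_id": "sample-B", "participant_id": "sub-01",
             "sample_type": "tissue", "derived_from": "sample-A"},
        ]
    )
    assert validate_samples(table, {("01", "A"), ("01", "B")}) == []


@pytest.mark.parametrize(
    "mutation,expected",
    [
        (dict(sample_type=None), "E_MISSING_SAMPLE_TYPE"),
        (dict(sample_type="banana"), "E_UNKNOWN_SAMPLE_TYPE"),
        (dict(derived_from="sample-Z"), "E_DERIVED_FROM_UNKNOWN"),
    ],
)
def test_validate_samples_single_defects(mutation, expected):
    row = {"sample_id": "sample-A", "participant_id": "sub-01", "sample_type": "tissue"}
    row.update(mutation)
    issues = validate_samples(_samples([row]), {("01", "A")})
    assert [i.code for i in issues] == [expected]


def test_validate_samples_duplicate_pair():
    row = {"sample_id": "sample-A", "participant_id": "sub-01", "sample_type": "tissue"}
    issues = validate_samples(_samples([row, dict(row)]), {("01", "A")})
    assert [i.code for i in issues] == ["E_DUP_SAMPLE"]


def test_validate_samples_cycle():
    table = _samples(
        [
            {"sample_id": "sample-A", "participant_id": "sub-01",
             "sample_type": "tissue", "derived_from": "sample-B"},
            {"sample_id": "sample-B", "participant_id": "sub-01",
             "sample_type": "tissue", "derived_from": "sample-A"},
        ]
    )
    issues = validate_samples(table, {("01", "A"), ("01", "B")})
    assert {i.code for i in issues} == {"E_DERIVED_FROM_CYCLE"}


def test_derivation_is_scoped_per_participant():
    """A sample of one participant cannot derive from another participant's."""
    table = _samples(
        [
            {"sample_id": "sample-A", "participant_id": "sub-01", "sample_type": "tissue"},
            {"sample_id": "sample-B", "participant_id": "sub-02",
             "sample_type": "tissue", "derived_from": "sample-A"},
        ]
    )
    issues = validate_samples(table, {("01", "A"), ("02", "B")})
    assert [i.code for i in issues] == ["E_DERIVED_FROM_UNKNOWN"]


def test_filename_cross_checks():
    table = _samples(
        [{"sample_id": "sample-A", "participant_id": "sub-01", "sample_type": "tissue"}]
    )
    issues = validate_samples(table, {("01", "B")})
    assert {i.code for i in issues} == {"E_SAMPLE_NOT_IN_TABLE", "W_SAMPLE_UNUSED"}


def test_ancestor_resolution_matches_graph_closure():
    """Chain resolution equals the transitive closure computed by networkx
    on random acyclic reference graphs (up to 50 nodes)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(2, 51))
        edges: dict[str, str | None] = {}
        for i in range(n):
            if i > 0 and rng.random() < 0.7:
                edges[f"s{i}"] = f"s{int(rng.integers(0, i))}"
            else:
                edges[f"s{i}"] = None
        graph = nx.DiGraph()
        graph.add_nodes_from(edges)
        graph.add_edges_from(
            (child, parent) for child, parent in edges.items() if parent is not None
        )
        expected = {node: nx.descendants(graph, node) for node in graph}
        assert derivation_ancestors(edges) == expected


@pytest.mark.parametrize(
    "row,codes",
    [
        ({"participant_id": "sub-01", "species": "mus musculus",
          "strain_rrid": "RRID:IMSR_JAX:000664"}, []),
        ({"participant_id": "sub-01", "species": "mouse"}, ["W_SPECIES_NOT_BINOMIAL"]),
        ({"participant_id": "sub-01", "species": "Mus musculus"},
         ["W_SPECIES_NOT_BINOMIAL"]),
        ({"participant_id": "sub-01", "strain_rrid": "IMSR_JAX:000664"},
         ["E_BAD_RRID"]),
    ],
)
def test_validate_participants_rows(row, codes):
    columns = ["participant_id", "species", "strain", "strain_rrid"]
    table = Table(
        path="participants.tsv",
        columns=columns,
        rows=[{c: row.get(c) for c in columns}],
    )
    assert [i.code for i in validate_participants(table)] == codes


def test_validate_participants_duplicate():
    columns = ["participant_id"]
    table = Table(
        path="participants.tsv",
        columns=columns,
        rows=[{"participant_id": "sub-01"}, {"participant_id": "sub-01"}],
    )
    assert [i.code for i in validate_participants(table)] == ["E_DUP_PARTICIPANT"]
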