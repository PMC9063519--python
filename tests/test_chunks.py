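"""Affine chunk placement and mosaic stitching against a scatter oracle."""

import numpy as np
import pytest

from micr_bids.chunks import (
    AffinePlacement,
    map_point,
    mosaic_extent,
    stitch,
    validate_transform,
)
from micr_bids.errors import TransformError


def _axial(scale, translation, shape, axes=None):
    d = len(shape)
    matrix = np.eye(d + 1)
    matrix[:d, :d] = np.diag(scale)
    matrix[:d, d] = translation
    axes = axes or ("X", "Y", "Z")[:d]
    return AffinePlacement.from_lists(matrix.tolist(), axes, shape)


# -- validate_transform --------------------------------------------------

def test_identity_transform_is_clean():
    assert validate_transform(np.eye(3).tolist(), ["X", "Y"], 2) == []


@pytest.mark.parametrize(
    "matrix,axes,dims,code",
    [
        (np.eye(4).tolist(), ["X", "Y"], 2, "E_MATRIX_SHAPE"),
        ([[1, 0, 0], [0, 1, 0], [0, 1, 1]], ["X", "Y"], 2, "E_MATRIX_HOMOGENEOUS"),
        (np.eye(3).tolist(), ["X", "X"], 2, "E_AXES_MISMATCH"),
        (np.eye(3).tolist(), ["X", "Y", "Z"], 2, "E_AXES_MISMATCH"),
        ([[1, 0.5, 0], [0, 1, 0], [0, 0, 1]], ["X", "Y"], 2, "W_NONAXIAL_TRANSFORM"),
    ],
)
def test_validate_transform_defects(matrix, axes, dims, code):
    assert code in {i.code for i in validate_transform(matrix, axes, dims)}


# -- map_point -----------------------------------------------------------

@pytest.mark.parametrize(
    "matrix,point,expected",
    [
        (np.eye(3), (3, 7), (3, 7)),
        ([[2, 0, 10], [0, 2, 0], [0, 0, 1]], (1, 1), (12, 2)),
        (
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 5], [0, 0, 0, 1]],
            (1, 2, 3),
            (1, 2, 8),
        ),
    ],
)
def test_map_point(matrix, point, expected):
    assert np.allclose(map_point(matrix, point), expected)


def test_map_point_dim_mismatch():
    with pytest.raises(TransformError) as err:
        map_point(np.eye(3), (1, 2, 3))
    assert err.value.code == "E_DIM_MISMATCH"


# -- mosaic_extent -------------------------------------------------------

def test_extent_single_identity_chunk():
    bbox, shape, origin, pixel = mosaic_extent([_axial((1, 1), (0, 0), (4, 4))])
    assert bbox == [(0.0, 4.0), (0.0, 4.0)]
    assert shape == (4, 4)
    assert np.allclose(origin, (0, 0)) and np.allclose(pixel, (1, 1))


def test_extent_two_adjacent_chunks():
    placements = [
        _axial((1, 1), (0, 0), (4, 4)),
        _axial((1, 1), (4, 0), (4, 4)),
    ]
    bbox, shape, _, _ = mosaic_extent(placements)
    assert shape == (8, 4)
    assert bbox == [(0.0, 8.0), (0.0, 4.0)]


def test_extent_mixed_axes_rejected():
    placements = [
        _axial((1, 1), (0, 0), (4, 4), axes=("X", "Y")),
        _axial((1, 1), (0, 0), (4, 4), axes=("Y", "X")),
    ]
    with pytest.raises(TransformError) as err:
        mosaic_extent(placements)
    assert err.value.code == "E_MIXED_AXES"


def test_extent_mixed_dimensionality_rejected():
    placements = [
        _axial((1, 1), (0, 0), (4, 4)),
        _axial((1, 1, 1), (0, 0, 0), (4, 4, 2)),
    ]
    with pytest.raises(TransformError) as err:
        mosaic_extent(placements)
    assert err.value.code == "E_MIXED_DIMENSIONALITY"


# -- stitch --------------------------------------------------------------

def test_stitch_four_quadrants():
    chunks = []
    for value, translation in zip(
        (1, 2, 3, 4), ((0, 0), (2, 0), (0, 2), (2, 2))
    ):
        chunks.append(
            (np.full((2, 2), value), _axial((1, 1), translation, (2, 2)))
        )
    mosaic = stitch(chunks)
    expected = np.block([[np.full((2, 2), 1), np.full((2, 2), 3)],
                         [np.full((2, 2), 2), np.full((2, 2), 4)]])
    assert np.array_equal(mosaic.data, expected)
    assert np.all(mosaic.coverage == 1)


def test_stitch_mean_of_coincident_chunks():
    placement = _axial((1, 1), (0, 0), (2, 2))
    mosaic = stitch(
        [(np.zeros((2, 2)), placement), (np.full((2, 2), 2.0), placement)],
        overlap_policy="mean",
    )
    assert np.all(mosaic.data == 1.0)
    assert np.all(mosaic.coverage == 2)


def test_stitch_refuses_rotation():
    placement = AffinePlacement.from_lists(
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]], ("X", "Y"), (2, 2)
    )
    with pytest.raises(TransformError) as err:
        stitch([(np.zeros((2, 2)), placement)])
    assert err.value.code == "E_UNSUPPORTED_TRANSFORM"


def test_stitch_refuses_zero_scale():
    placement = _axial((0, 1), (0, 0), (2, 2))
    with pytest.raises(TransformError) as err:
        stitch([(np.zeros((2, 2)), placement)])
    assert err.value.code == "E_SCALE_ZERO"


def test_uncovered_pixels_take_fill():
    chunks = [
        (np.ones((2, 2)), _axial((1, 1), (0, 0), (2, 2))),
        (np.ones((2, 2)), _axial((1, 1), (4, 4), (2, 2))),
    ]
    mosaic = stitch(chunks, fill=-1.0)
    assert mosaic.data.shape == (6, 6)
    assert np.all(mosaic.data[mosaic.coverage == 0] == -1.0)


# -- oracle equivalence --------------------------------------------------

def scatter_oracle(chunks, policy="mean", fill=0.0):
    """Brute-force per-pixel scatter: map every pixel center with explicit
    loops and scalar arithmetic, combine contributors per policy."""
    d = chunks[0][1].ndim
    scales = []
    translations = []
    for _, p in chunks:
        m = np.asarray(p.matrix, float)
        scales.append([m[a][a] for a in range(d)])
        translations.append([m[a][d] for a in range(d)])
    out_pixel = [
        min(abs(s[a]) for s in scales) for a in range(d)
    ]
    los, his = [np.inf] * d, [-np.inf] * d
    for (_, p), s, t in zip(chunks, scales, translations):
        for a in range(d):
            ends = (t[a], s[a] * (p.shape[a] - 1) + t[a])
            los[a] = min(los[a], *ends)
            his[a] = max(his[a], *ends)
    shape = tuple(round((h - l) / w) + 1 for l, h, w in zip(los, his, out_pixel))
    contributions: dict[tuple, list] = {}
    for (data, p), s, t in zip(chunks, scales, translations):
        for idx in np.ndindex(*p.shape):
            target = tuple(
                # banker's rounding, matching the documented ties-to-even rule
                round((s[a] * idx[a] + t[a] - los[a]) / out_pixel[a])
                for a in range(d)
            )
            contributions.setdefault(target, []).append(float(data[idx]))
    out = np.full(shape, fill, dtype=float)
    coverage = np.zeros(shape, dtype=int)
    for target, values in contributions.items():
        coverage[target] = len(values)
        out[target] = sum(values) / len(values) if policy == "mean" else values[-1]
    return out, coverage


def _random_layout(rng, d):
    n_chunks = int(rng.integers(1, 10))
    chunks = []
    for _ in range(n_chunks):
        shape = tuple(int(rng.integers(2, 5)) for _ in range(d))
        scale = tuple(int(rng.integers(1, 3)) for _ in range(d))
        translation = tuple(int(rng.integers(0, 8)) for _ in range(d))
        data = rng.integers(0, 256, size=shape).astype(float)
        chunks.append((data, _axial(scale, translation, shape)))
    return chunks


@pytest.mark.parametrize("d", [2, 3])
@pytest.mark.parametrize("policy", ["mean", "last"])
def test_stitch_matches_scatter_oracle(d, policy):
    rng = np.random.default_rng(20 + d)
    for _ in range(25):
        chunks = _random_layout(rng, d)
        mosaic = stitch(chunks, overlap_policy=policy, fill=-7.0)
        expected, coverage = scatter_oracle(chunks, policy=policy, fill=-7.0)
        assert np.array_equal(mosaic.data, expected)
        assert np.array_equal(mosaic.coverage, coverage)


def test_non_overlapping_conservation_and_policy_invariance():
    """Without overlaps the pixel sum is conserved and both policies agree."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        # 2x2 grid of unit-scale chunks: disjoint by construction
        chunks = []
        total = 0.0
        for gy in range(2):
            for gx in range(2):
                shape = (3, 4)
                data = rng.integers(0, 256, size=shape).astype(float)
                total += data.sum()
                chunks.append(
                    (data, _axial((1, 1), (gx * 3, gy * 4), shape))
                )
        mean = stitch(chunks, overlap_policy="mean")
        last = stitch(chunks, overlap_policy="last")
        assert np.all(mean.coverage <= 1)
        assert mean.data.sum() == total
        assert np.array_equal(mean.data, last.data)


def test_mean_is_order_invariant():
    rng = np.random.default_rng(11)
    chunks = _random_layout(rng, 2)
    forward = stitch(chunks, overlap_policy="mean")
    backward = stitch(list(reversed(chunks)), overlap_policy="mean")
    assert np.allclose(forward.data, backward.data)
    assert np.array_equal(forward.coverage, backward.coverage)
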