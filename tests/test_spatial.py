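"""Distance fields, query distances and geometric null distributions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import cKDTree

from betacell3d.io import LabeledVolume
from betacell3d.skeletons import Microtubule
from betacell3d.spatial import (
    distance_field,
    end_distance,
    enrichment,
    make_distribution,
    max_ecdf_gap,
    membrane_shell,
    object_distance,
    object_distances,
    random_reference,
    sample_field,
)


def _vol(data, spacing=(16, 16, 16)):
    return LabeledVolume(np.asarray(data, np.uint8), spacing)


def kdtree_field(mask, spacing):
    """Independent oracle: min distance from every voxel center to any
    target voxel center, via a KD-tree over scaled coordinates."""
    spacing = np.asarray(spacing, float)
    pts = np.argwhere(mask) * spacing
    tree = cKDTree(pts)
    grid = np.indices(mask.shape).reshape(3, -1).T * spacing
    d, _ = tree.query(grid)
    return d.reshape(mask.shape)


def test_single_voxel_isotropic():
    data = np.zeros((7, 7, 7))
    data[3, 3, 3] = 1
    f = distance_field(_vol(data))
    assert f.values[3, 3, 3] == 0.0
    assert f.values[0, 3, 3] == pytest.approx(48.0)  # 3 voxels at 16 nm


def test_anisotropic_spacing_arithmetic():
    data = np.zeros((5, 5, 5))
    data[2, 2, 2] = 1
    f = distance_field(_vol(data, spacing=(20, 10, 10)))
    assert f.values[3, 2, 2] == pytest.approx(20.0)  # one z voxel
    assert f.values[2, 4, 2] == pytest.approx(20.0)  # two y voxels


def test_missing_label_errors():
    with pytest.raises(ValueError):
        distance_field(_vol(np.zeros((3, 3, 3))))


@given(st.integers(0, 2**16), st.sampled_from([(16, 16, 16), (20, 10, 10)]))
def test_field_matches_kdtree_oracle(seed, spacing):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(6, 20, size=3))
    mask = rng.random(shape) < 0.05
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    f = distance_field(_vol(mask, spacing))
    np.testing.assert_allclose(f.values, kdtree_field(mask, spacing), atol=1e-6)


@given(st.integers(0, 2**16))
def test_lipschitz_along_rays(seed):
    """|d(p) - d(q)| <= ||p - q|| for voxel neighbors along random rays."""
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 12, 12)) < 0.03
    mask[6, 6, 6] = True
    spacing = (20.0, 16.0, 16.0)
    f = distance_field(_vol(mask, spacing))
    for axis, step in zip(range(3), spacing):
        d = np.abs(np.diff(f.values, axis=axis))
        assert d.max() <= step + 1e-6


def test_object_distance_adjacent_overlap():
    target = np.zeros((5, 5, 5))
    target[2, 2, 2] = 1
    f = distance_field(_vol(target))
    query = np.zeros((5, 5, 5), np.int32)
    query[2, 2, 4] = 1  # one-voxel gap
    assert object_distance(LabeledVolume(query, (16,) * 3), 1, f) == pytest.approx(32.0)
    query[2, 2, 3] = 1  # adjacent
    assert object_distance(LabeledVolume(query, (16,) * 3), 1, f) == pytest.approx(16.0)
    query[2, 2, 2] = 1  # overlapping
    assert object_distance(LabeledVolume(query, (16,) * 3), 1, f) == 0.0


@given(st.integers(0, 2**16))
def test_object_distance_symmetric(seed):
    """min-over-voxels distance is symmetric for binary masks."""
    rng = np.random.default_rng(seed)
    a = rng.random((10, 10, 10)) < 0.05
    b = rng.random((10, 10, 10)) < 0.05
    a[1, 1, 1] = b[8, 8, 8] = True
    va, vb = _vol(a), _vol(b)
    dab = object_distance(va, 1, distance_field(vb))
    dba = object_distance(vb, 1, distance_field(va))
    assert dab == pytest.approx(dba)


def test_object_distances_match_per_label_minimum():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int32)
    target = np.zeros((12, 12, 12))
    target[0, 0, 0] = 1
    f = distance_field(_vol(target))
    got = object_distances(LabeledVolume(labels, (16,) * 3), f)
    for lab in (1, 2, 3):
        assert got[lab] == pytest.approx(f.values[labels == lab].min())


def test_end_distance_closer_rule():
    target = np.zeros((3, 3, 64))
    target[1, 1, 0] = 1
    f = distance_field(_vol(target))
    mt = Microtubule(7, [(16, 16, 100.0), (16, 16, 700.0)])
    d0, d1 = end_distance(mt, f, which="both")
    assert (d0, d1) == (pytest.approx(96.0), pytest.approx(704.0))
    assert end_distance(mt, f, which="closer") == pytest.approx(96.0)
    on_target = Microtubule(8, [(16, 16, 4.0), (16, 16, 500.0)])
    assert end_distance(on_target, f, which="closer") == 0.0


def test_end_outside_bounds_names_mt():
    target = np.zeros((3, 3, 3))
    target[0, 0, 0] = 1
    f = distance_field(_vol(target))
    mt = Microtubule(42, [(0, 0, 0), (0, 0, 5000.0)])
    with pytest.raises(ValueError, match="42"):
        end_distance(mt, f)


def test_sampled_ends_match_point_oracle(small_cell):
    """Closer-end values agree with brute-force point-to-target-voxel minima
    to within one voxel diagonal (nearest-voxel sampling tolerance)."""
    seg, skel, _ = small_cell
    from betacell3d.skeletons import build_network

    net = build_network(skel)
    f = distance_field(seg.nucleus)
    spacing = np.asarray(seg.spacing_nm)
    tree = cKDTree(np.argwhere(seg.nucleus.mask()) * spacing)
    diag = np.linalg.norm(spacing)
    for mt in list(net)[:50]:
        sampled = end_distance(mt, f, which="closer")
        exact = min(tree.query(np.asarray(mt.ends))[0])
        assert abs(sampled - exact) <= diag


# --- random references and distributions ----------------------------------


def _ball_domain():
    n = 21
    idx = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij", sparse=True)
    return ((zz**2 + yy**2 + xx**2) * 16.0**2) <= 150.0**2


def test_reference_normalized_and_monotone():
    cell = _vol(_ball_domain())
    target = np.zeros(cell.shape)
    target[10, 10, 10] = 1
    ref = random_reference(_vol(target), cell, None, bin_width_nm=20.0)
    assert ref.fraction.sum() == pytest.approx(1.0)
    assert np.all(np.diff(ref.ecdf) >= -1e-12)
    assert ref.ecdf[-1] == pytest.approx(1.0)


def test_reference_empty_domain_errors():
    cell = _vol(np.ones((3, 3, 3)))
    with pytest.raises(ValueError, match="empty domain"):
        random_reference(cell, cell, None)  # target covers the whole domain


def test_boundary_shell_target_concentrates_small_distances():
    cell = _vol(_ball_domain())
    shell = membrane_shell(cell)
    ref = random_reference(shell, cell, None, bin_width_nm=20.0)
    # no domain voxel is farther from the shell than the ball radius, and
    # most of the ball's volume sits close to its boundary
    assert ref.bin_edges[-1] <= 150.0 + 20.0
    k = np.searchsorted(ref.bin_edges[1:], 60.0)
    assert ref.ecdf[k] > 0.5


def test_distribution_all_zero_values():
    cell = _vol(_ball_domain())
    target = np.zeros(cell.shape)
    target[10, 10, 10] = 1
    ref = random_reference(_vol(target), cell, None, bin_width_nm=20.0)
    d = make_distribution(np.zeros(5), ref)
    assert d.ecdf[0] == pytest.approx(1.0)
    assert enrichment(d, 100.0) == pytest.approx(1.0 - ref.ecdf[4])


def test_coarse_bins_aggregate_fine_bins():
    cell = _vol(_ball_domain())
    target = np.zeros(cell.shape)
    target[10, 10, 10] = 1
    rng = np.random.default_rng(0)
    vals = rng.random(500) * 140  # inside both binned ranges
    fine = make_distribution(vals, random_reference(_vol(target), cell, None, 20.0))
    coarse = make_distribution(vals, random_reference(_vol(target), cell, None, 100.0))
    k = 5  # 100 / 20
    n_coarse = len(coarse.fraction)
    padded = np.pad(fine.fraction, (0, max(0, n_coarse * k - len(fine.fraction))))
    summed = np.add.reduceat(padded, np.arange(0, n_coarse * k, k))
    np.testing.assert_allclose(summed, coarse.fraction, atol=1e-12)


def test_distribution_rejects_negative():
    cell = _vol(_ball_domain())
    target = np.zeros(cell.shape)
    target[10, 10, 10] = 1
    ref = random_reference(_vol(target), cell, None)
    with pytest.raises(ValueError, match="non-negative"):
        make_distribution(np.array([-1.0]), ref)


def test_enrichment_zero_for_reference_sample():
    """Values drawn as the reference's own voxel multiset give a vanishing
    ecdf gap and enrichment."""
    cell = _vol(_ball_domain())
    target = np.zeros(cell.shape)
    target[10, 10, 10] = 1
    f = distance_field(_vol(target))
    domain = cell.mask() & ~(target > 0)
    ref = random_reference(_vol(target), cell, None, 20.0, field=f)
    vals = f.values[domain]
    d = make_distribution(vals, ref)
    assert max_ecdf_gap(d) < 1e-9
    assert enrichment(d, 100.0) == pytest.approx(0.0, abs=1e-9)


def test_sample_field_rejects_outside_points():
    target = np.zeros((4, 4, 4))
    target[0, 0, 0] = 1
    f = distance_field(_vol(target))
    with pytest.raises(ValueError, match="outside"):
        sample_field(f, np.array([[0.0, 0.0, 500.0]]))
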