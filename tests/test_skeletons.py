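"""Microtubule network construction and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from betacell3d.io import LabeledVolume, SkeletonFile
from betacell3d.skeletons import (
    Microtubule,
    MicrotubuleNetwork,
    SkeletonTopologyError,
    build_network,
    mean_length_um,
    polyline_length,
    rasterize_microtubules,
    summarize_network,
    tortuosity,
)


def _skel(points_by_comp):
    nodes, edges, comps = {}, [], {}
    nid = 0
    for k, pts in enumerate(points_by_comp, start=1):
        first = nid + 1
        for p in pts:
            nid += 1
            nodes[nid] = np.asarray(p, float)
            comps[nid] = k
        edges.extend((i, i + 1) for i in range(first, nid))
    return SkeletonFile(nodes, edges, comps)


def test_three_node_chain():
    net = build_network(_skel([[(0, 0, 0), (100, 0, 0), (200, 0, 0)]]))
    assert net.count == 1
    assert net.microtubules[0].length_nm == pytest.approx(200.0)


def test_branching_component_names_node():
    skel = _skel([[(0, 0, 0), (1, 0, 0), (2, 0, 0)]])
    skel.nodes[4] = np.array([1.0, 1.0, 0.0])
    skel.edges.append((2, 4))  # node 2 now has degree 3
    skel.components[4] = 1
    with pytest.raises(SkeletonTopologyError, match="node 2"):
        build_network(skel)


def test_cycle_rejected():
    skel = _skel([[(0, 0, 0), (1, 0, 0), (1, 1, 0)]])
    skel.edges.append((3, 1))
    with pytest.raises(SkeletonTopologyError, match="loop"):
        build_network(skel)


def test_single_node_rejected():
    skel = _skel([[(0, 0, 0), (1, 0, 0)]])
    skel.nodes[9] = np.zeros(3)
    skel.components[9] = 2
    with pytest.raises(SkeletonTopologyError, match="single node"):
        build_network(skel)


def test_random_components_match_brute_force():
    """Counts and per-component lengths equal explicit edge-length sums."""
    rng = np.random.default_rng(0)
    comps = [rng.random((rng.integers(2, 8), 3)) * 5000 for _ in range(50)]
    net = build_network(_skel(comps))
    assert net.count == 50
    expected = sorted(
        float(np.sum(np.linalg.norm(np.diff(np.asarray(c), axis=0), axis=1)))
        for c in comps
    )
    got = sorted(mt.length_nm for mt in net)
    np.testing.assert_allclose(got, expected)


def test_polyline_length_345():
    mt = Microtubule(1, [(0, 0, 0), (300, 400, 0)])
    assert polyline_length(mt) == pytest.approx(500.0)


def test_length_invariant_under_collinear_subdivision():
    pts = np.array([(0, 0, 0), (100, 50, 0), (200, 50, 300)], float)
    fine = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        for t in np.linspace(0, 1, 11)[1:]:
            fine.append(a + t * (b - a))
    assert polyline_length(Microtubule(1, np.array(fine))) == pytest.approx(
        polyline_length(Microtubule(2, pts))
    )


@given(st.integers(0, 2**16))
def test_length_matches_pairwise_sum_oracle(seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((20, 3)) * 1000
    oracle = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(19)
    )
    assert polyline_length(Microtubule(1, pts)) == pytest.approx(oracle)


def test_tortuosity_straight_and_half_circle():
    straight = Microtubule(1, [(0, 0, i * 10.0) for i in range(5)])
    assert tortuosity(straight) == pytest.approx(1.0)
    t = np.linspace(0, np.pi, 2000)
    half = Microtubule(2, np.stack([np.zeros_like(t), np.sin(t), np.cos(t)], axis=1) * 500)
    assert tortuosity(half) == pytest.approx(np.pi / 2, rel=1e-4)


def test_tortuosity_closed_path_errors():
    mt = Microtubule(1, [(0, 0, 0), (100, 0, 0), (0, 0, 0)])
    with pytest.raises(ValueError, match="closed"):
        tortuosity(mt)


@given(st.integers(0, 2**16))
def test_tortuosity_at_least_one(seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((8, 3)) * 500
    mt = Microtubule(1, pts)
    chord = np.linalg.norm(pts[-1] - pts[0])
    if chord > 1e-9:
        assert tortuosity(mt) >= 1.0 - 1e-12


def test_length_additivity_on_concatenation():
    rng = np.random.default_rng(3)
    a = rng.random((5, 3)) * 100
    b = rng.random((4, 3)) * 100
    joint = np.concatenate([a, b])
    split = (
        polyline_length(Microtubule(1, a))
        + np.linalg.norm(b[0] - a[-1])
        + polyline_length(Microtubule(2, b))
    )
    assert polyline_length(Microtubule(3, joint)) == pytest.approx(split)


# --- rasterization --------------------------------------------------------


def _brute_force_raster(net, template, diameter):
    spacing = np.asarray(template.spacing_nm)
    out = np.zeros(template.shape, np.uint8)
    for idx in np.ndindex(template.shape):
        center = np.asarray(idx) * spacing
        best = np.inf
        for mt in net:
            for a, b in zip(mt.points[:-1], mt.points[1:]):
                ab = b - a
                denom = ab @ ab
                t = 0.0 if denom == 0 else np.clip((center - a) @ ab / denom, 0, 1)
                best = min(best, np.linalg.norm(center - (a + t * ab)))
        if best <= diameter / 2:
            out[idx] = 1
    return out


def test_axis_aligned_line_is_one_voxel_thick():
    """25 nm diameter at 16 nm spacing: radius 12.5 < 16, so only the voxels
    the filament passes through are marked."""
    template = LabeledVolume(np.zeros((5, 5, 9), np.uint8), (16, 16, 16))
    net = MicrotubuleNetwork([Microtubule(1, [(32, 32, 0), (32, 32, 128)])])
    mask = rasterize_microtubules(net, template, diameter_nm=25.0)
    assert mask.data.sum() == 9
    assert mask.data[2, 2, :].all()


def test_rasterize_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    template = LabeledVolume(np.zeros((14, 12, 10), np.uint8), (20, 16, 16))
    mts = [Microtubule(i + 1, rng.random((4, 3)) * [260, 176, 144]) for i in range(3)]
    net = MicrotubuleNetwork(mts)
    for diameter in (25.0, 40.0, 64.0):
        got = rasterize_microtubules(net, template, diameter)
        oracle = _brute_force_raster(net, template, diameter)
        np.testing.assert_array_equal(got.data, oracle)


def test_empty_network_all_zero():
    template = LabeledVolume(np.zeros((4, 4, 4), np.uint8), (16,) * 3)
    mask = rasterize_microtubules(MicrotubuleNetwork([]), template)
    assert mask.data.sum() == 0


def test_raster_monotone_in_diameter():
    rng = np.random.default_rng(11)
    template = LabeledVolume(np.zeros((16, 16, 16), np.uint8), (16,) * 3)
    net = MicrotubuleNetwork([Microtubule(1, rng.random((5, 3)) * 240)])
    counts = [
        rasterize_microtubules(net, template, d).data.sum() for d in (20, 30, 50, 80)
    ]
    assert counts == sorted(counts)


# --- summaries ------------------------------------------------------------


def test_summary_single_mt():
    net = MicrotubuleNetwork([Microtubule(1, [(0, 0, 0), (0, 0, 1000.0)])])
    s = summarize_network(net)
    assert s["mt_count"] == 1
    assert s["mt_mean_length_um"] == 1.0
    assert s["mt_cumulative_length_um"] == 1
    assert s["mt_mean_tortuosity"] == 1.0


def test_summary_empty_errors():
    with pytest.raises(ValueError):
        summarize_network(MicrotubuleNetwork([]))


def test_mean_length_requires_count():
    with pytest.raises(ValueError):
        mean_length_um(100.0, 0)
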