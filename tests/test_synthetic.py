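"""The ground-truthed synthetic cell generator."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from betacell3d.interactions import AnalysisConfig
from betacell3d.pipeline import analyze_cell
from betacell3d.spatial import (
    distance_field,
    enrichment,
    make_distribution,
    random_reference,
)
from betacell3d.synthetic import (
    GranuleParams,
    MicrotubuleParams,
    PackingError,
    SyntheticCellConfig,
    _arc_points,
    _truncated_lognormal_quantiles,
    _truncated_normal_quantiles,
    generate_cell,
    sample_uniform_points,
)
from conftest import small_config


def test_same_seed_bitwise_identical():
    cfg = small_config(seed=9)
    seg1, skel1, _ = generate_cell(cfg)
    seg2, skel2, _ = generate_cell(small_config(seed=9))
    np.testing.assert_array_equal(seg1.granules.data, seg2.granules.data)
    np.testing.assert_array_equal(seg1.mitochondria.data, seg2.mitochondria.data)
    assert sorted(skel1.nodes) == sorted(skel2.nodes)
    for nid in skel1.nodes:
        np.testing.assert_array_equal(skel1.nodes[nid], skel2.nodes[nid])
    seg3, _, _ = generate_cell(small_config(seed=10))
    assert not np.array_equal(seg3.granules.data, seg1.granules.data)


def test_degenerate_no_granules_no_microtubules():
    cfg = small_config(
        seed=2,
        granules=GranuleParams(count=0),
        microtubules=MicrotubuleParams(count=0),
    )
    seg, skel, gt = generate_cell(cfg)
    assert seg.granules is None and seg.microtubule_mask is None and skel is None
    assert gt.totals["sg_count"] == 0 and gt.totals["mt_count"] == 0
    res = analyze_cell(seg, None, AnalysisConfig())
    assert res.summary.mt_count is None and res.summary.sg_count is None
    assert res.summary.nucleus_volume_pct > 0


def test_anchored_ends_satisfy_thresholds_by_construction(small_cell):
    """Centriole-anchored ends sit within 200 nm of the centrioles, Golgi-
    anchored ends on a cisterna, and free ends keep clear of both."""
    seg, skel, gt = small_cell
    from betacell3d.skeletons import build_network
    from betacell3d.spatial import end_distances

    net = build_network(skel)
    d_cent = end_distances(net, distance_field(seg.centrioles))
    d_golgi = end_distances(net, distance_field(seg.golgi))
    anchors = gt.per_mt.set_index("mt_id")["anchor"]
    for mt_id, anchor in anchors.items():
        dc = d_cent.set_index("mt_id").loc[mt_id, "closer_nm"]
        dg = d_golgi.set_index("mt_id").loc[mt_id, "closer_nm"]
        if anchor == "centriole":
            assert dc < 200.0
        elif anchor == "golgi":
            assert dg < 20.0
            assert dc >= 200.0
        else:
            assert dc >= 200.0 and dg >= 20.0


def test_granules_do_not_overlap(small_cell):
    seg, _, gt = small_cell
    sg = gt.per_sg
    centers = sg[["center_z_nm", "center_y_nm", "center_x_nm"]].to_numpy()
    radii = sg["diameter_nm"].to_numpy() / 2
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=float(2 * radii.max()), output_type="ndarray")
    gaps = (
        np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        - radii[pairs[:, 0]]
        - radii[pairs[:, 1]]
    )
    assert gaps.min() > 0
    # instance masks: every label present with positive volume
    labels = np.unique(seg.granules.data)
    assert len(labels) - 1 == len(sg)


def test_granules_inside_cell_and_off_nucleus(small_cell):
    seg, _, _ = small_cell
    assert seg.validate() == []
    assert not (seg.granules.mask() & seg.nucleus.mask()).any()
    assert not (seg.granules.mask() & (seg.mitochondria.data > 0)).any()


def test_arc_points_exact_length_and_chord():
    a, b = np.zeros(3), np.array([0.0, 0.0, 2000.0])
    w = np.array([0.0, 1.0, 0.0])
    pts = _arc_points(a, b, 2100.0, w, step=10.0)
    arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    assert arc == pytest.approx(2100.0, rel=1e-4)
    np.testing.assert_allclose(pts[0], a, atol=1e-9)
    np.testing.assert_allclose(pts[-1], b, atol=1e-6)
    # degenerate curvature: a straight polyline
    straight = _arc_points(a, b, 2000.0, w, step=10.0)
    assert np.sum(np.linalg.norm(np.diff(straight, axis=0), axis=1)) == pytest.approx(2000.0)
    assert np.abs(straight[:, 1]).max() == 0.0


def test_stratified_quantiles_hit_target_means():
    rng = np.random.default_rng(0)
    lengths = _truncated_lognormal_quantiles(
        400, 8500.0, 0.2, 4000.0, 10500.0, rng, mean_target=8500.0
    )
    assert np.mean(lengths) == pytest.approx(8500.0, rel=5e-3)
    assert lengths.min() >= 4000.0 and lengths.max() <= 10500.0
    taus = _truncated_normal_quantiles(400, 1.05, 0.02, 1.005, 1.10, rng)
    assert np.mean(taus) == pytest.approx(1.05, abs=1e-3)


def test_microtubule_metrics_recovered(small_cell):
    """Realized polylines carry the configured length and tortuosity stats."""
    _, _, gt = small_cell
    mt = gt.per_mt
    assert np.mean(mt["length_nm"]) == pytest.approx(2500.0, rel=0.01)
    assert np.mean(mt["tortuosity"]) == pytest.approx(1.05, abs=0.005)
    np.testing.assert_allclose(mt["length_nm"], mt["target_length_nm"], rtol=1e-3)


def test_granule_diameter_recovery(small_cell):
    seg, _, gt = small_cell
    from betacell3d.morphometry import granule_stats

    df = granule_stats(seg.granules)
    measured = df["equivalent_diameter_um"].mean() * 1000
    assert measured == pytest.approx(gt.per_sg["diameter_nm"].mean(), rel=0.02)


def test_pm_enrichment_toggle():
    """With the membrane weight on, granules are enriched near the membrane
    relative to the geometric null; with it off they are not."""
    from betacell3d.spatial import membrane_shell, object_distances

    results = {}
    for lam in (0.0, 1.0):
        cfg = small_config(
            seed=4,
            granules=GranuleParams(
                count=250, diameter_median_nm=250, diameter_sigma=0.05,
                pm_enrichment_lambda_um=lam, associated_pm_lambda_um=lam,
                associated_fraction=0.0,
            ),
            microtubules=MicrotubuleParams(count=0),
        )
        seg, _, _ = generate_cell(cfg)
        shell = membrane_shell(seg.cell_mask)
        f = distance_field(shell)
        ref = random_reference(shell, seg.cell_mask, seg.nucleus, 20.0, field=f)
        vals = object_distances(seg.granules, f).to_numpy()
        results[lam] = enrichment(make_distribution(vals, ref), 500.0)
    assert results[1.0] > results[0.0]
    assert results[1.0] > 0.05


def test_packing_error_when_infeasible():
    cfg = small_config(
        seed=5,
        granules=GranuleParams(count=40000, diameter_median_nm=400, diameter_sigma=0.05),
    )
    with pytest.raises(PackingError):
        generate_cell(cfg)


def test_infeasible_length_mean_rejected():
    """A target mean outside the truncation window cannot be calibrated."""
    with pytest.raises(ValueError, match="not attainable"):
        _truncated_lognormal_quantiles(
            10, 20000.0, 0.2, 1000.0, 3000.0,
            np.random.default_rng(0), mean_target=20000.0,
        )


def test_sample_uniform_points():
    rng = np.random.default_rng(0)
    domain = np.zeros((5, 5, 5), bool)
    domain[2, 3, 4] = True
    pts = sample_uniform_points(domain, 7, rng, (50, 50, 50))
    np.testing.assert_array_equal(pts, np.tile([100, 150, 200], (7, 1)))
    with pytest.raises(ValueError):
        sample_uniform_points(np.zeros((2, 2, 2), bool), 1, rng, (50, 50, 50))


def test_canvas_too_small_rejected():
    with pytest.raises(ValueError, match="too small"):
        SyntheticCellConfig(shape=(64, 64, 64), spacing_nm=(50, 50, 50))
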