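"""Shared fixtures: a fast small-canvas synthetic cell and its analysis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from betacell3d.interactions import AnalysisConfig
from betacell3d.pipeline import analyze_cell
from betacell3d.synthetic import (
    CentrioleParams,
    GolgiParams,
    GranuleParams,
    MicrotubuleParams,
    MitochondriaParams,
    SyntheticCellConfig,
    generate_cell,
)

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def small_config(seed: int = 1, **overrides) -> SyntheticCellConfig:
    """A 4.8 µm cell on a 96³ canvas: every structure present, seconds to build."""
    kwargs = dict(
        shape=(96, 96, 96),
        spacing_nm=(50.0, 50.0, 50.0),
        cell_semiaxes_um=(2.0, 2.1, 2.2),
        nucleus_semiaxes_um=(0.95, 0.95, 0.9),
        nucleus_offset_um=(0.0, 0.5, 0.45),
        centrioles=CentrioleParams(offset_um=(0.0, -0.9, -1.3), length_nm=400, radius_nm=100),
        golgi=GolgiParams(standoff_um=0.25, radial_gap_um=0.25, thickness_nm=140),
        mitochondria=MitochondriaParams(count=8, radius_nm=180, length_um_range=(0.8, 1.5)),
        granules=GranuleParams(
            count=300, diameter_median_nm=300, diameter_sigma=0.08,
            pm_enrichment_lambda_um=1.2, associated_pm_lambda_um=0.8,
            associated_fraction=0.30,
        ),
        microtubules=MicrotubuleParams(
            count=60, length_mean_um=2.5, length_sigma=0.2, length_range_um=(1.2, 3.6),
            fraction_centriole_anchored=0.05, fraction_golgi_anchored=0.10,
            pm_enrichment_lambda_um=1.0, step_nm=80,
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticCellConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cell():
    """(segmentation, skeleton, ground truth) for the small reference cell."""
    return generate_cell(small_config(seed=1))


@pytest.fixture(scope="session")
def small_analysis(small_cell):
    seg, skel, _ = small_cell
    return analyze_cell(seg, skel, AnalysisConfig())


def digitized_sphere(radius_nm: float, spacing_nm: float,
                     offset_vox=(0.37, 0.21, 0.44)) -> np.ndarray:
    """Boolean ball: voxel centers within radius of a generic off-grid center."""
    n = int(np.ceil(radius_nm / spacing_nm)) + 3
    idx = np.arange(-n, n + 1)
    c = np.asarray(offset_vox)
    zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij", sparse=True)
    d2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) * spacing_nm**2
    return d2 <= radius_nm**2
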