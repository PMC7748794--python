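"""Ground-truthed synthetic beta-cell segmentations and skeletons.

The generator builds, on a calibrated voxel canvas, an ellipsoidal cell
containing a nucleus, a centriole pair, a stack of curved perforated Golgi
cisternae hugging the nucleus, tubular mitochondria, several thousand
near-spherical insulin secretory granules and hundreds of non-branching
curved microtubules - the statistical structure the downstream analysis
assumes - together with exact bookkeeping of everything it placed.

Design notes
------------
* Microtubules are built constructively: per filament a target arc length L
  and tortuosity tau are drawn, the chord c = L / tau is placed inside the
  cytoplasm by rejection, and the filament is laid down as the circular arc
  of length L over that chord.  This gives exact, independent control of
  the length and tortuosity distributions even though the cell confines the
  filaments - a persistent random walk reflected at the membrane cannot hit
  a target mean length and mean tortuosity simultaneously.
* Lengths, tortuosities and granule diameters are sampled by stratified
  quantiles of their (truncated) distributions, randomly permuted, so the
  realized sample means sit on the configured means to well below a
  percent even at a few hundred objects.
* Anchoring and association are enforced through the same voxel-sampled
  distance fields the analysis uses, so the configured counts are recovered
  exactly by the pipeline: anchored ends start inside the anchor threshold,
  free ends keep a sampled clearance beyond it, granules placed as
  associated overlap a microtubule-mask voxel, and non-associated
  candidates are rejected whenever their digitized sphere would measure
  under the association threshold - the same computation the classifier
  performs.
* Every stochastic step draws from a named substream of the master seed, so
  e.g. adding mitochondria does not perturb granule placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, optimize, stats

from .io import CellSegmentation, LabeledVolume, SkeletonFile, write_skeleton_xml
from .skeletons import Microtubule, MicrotubuleNetwork, rasterize_microtubules, NM_PER_UM

__all__ = [
    "SyntheticCellConfig",
    "GroundTruth",
    "generate_cell",
    "sample_uniform_points",
    "PackingError",
]

UM_PER_NM = 1e-3
NM_PER_UM_F = 1000.0


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


class _WeightedSampler:
    """O(log n) categorical draws via the cumulative-weight inverse."""

    def __init__(self, weights: np.ndarray):
        cum = np.cumsum(weights, dtype=np.float64)
        self.cum = cum / cum[-1]

    def draw(self, rng: np.random.Generator, n: int | None = None):
        u = rng.random() if n is None else rng.random(n)
        return np.searchsorted(self.cum, u, side="right")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CentrioleParams:
    present: bool = True
    length_nm: float = 500.0
    radius_nm: float = 120.0
    offset_um: tuple[float, float, float] = (0.0, -2.2, -3.4)  # from cell center


@dataclass
class GolgiParams:
    n_slabs: int = 3
    thickness_nm: float = 160.0
    cap_angle_deg: float = 55.0
    standoff_um: float = 0.30       # gap between nucleus surface and first cisterna
    radial_gap_um: float = 0.35     # spacing between cisternae
    perforation_fraction: float = 0.25
    axis: tuple[float, float, float] = (0.0, -0.6, -0.8)  # cone axis from nucleus center


@dataclass
class MitochondriaParams:
    count: int = 40
    radius_nm: float = 240.0
    length_um_range: tuple[float, float] = (2.0, 4.0)


@dataclass
class GranuleParams:
    count: int = 5000
    diameter_median_nm: float = 380.0
    diameter_sigma: float = 0.10          # lognormal sigma (log scale)
    pm_enrichment_lambda_um: float = 5.0  # 0 = uniform placement
    associated_pm_lambda_um: float = 0.5  # steeper near-membrane weight for associated SGs
    associated_fraction: float = 0.30
    min_gap_nm: float = 30.0


@dataclass
class MicrotubuleParams:
    count: int = 400
    length_mean_um: float = 8.5
    length_sigma: float = 0.20            # lognormal sigma before truncation
    length_range_um: tuple[float, float] = (4.0, 10.5)
    tortuosity_mean: float = 1.05
    tortuosity_sd: float = 0.02
    tortuosity_range: tuple[float, float] = (1.005, 1.10)
    fraction_centriole_anchored: float = 0.03
    fraction_golgi_anchored: float = 0.05
    pm_enrichment_lambda_um: float = 2.0  # 0 = uniform end placement
    step_nm: float = 100.0
    diameter_nm: float = 25.0


@dataclass
class SyntheticCellConfig:
    """Study conditions for one synthetic cell.

    The defaults are the package's reference regime: a 12.8 µm canvas at
    50 nm voxels holding a ~650 µm³ cell with ~15% nucleus, 400 microtubules
    of mean length 8.5 µm and mean tortuosity 1.05 (3% centriole-anchored,
    5% Golgi-anchored, membrane-enriched ends), and 5,000 granules with
    lognormal diameters (median 380 nm), 30% of them microtubule-associated
    and preferentially placed near the plasma membrane.
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    spacing_nm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    cell_semiaxes_um: tuple[float, float, float] = (5.5, 5.9, 6.2)
    nucleus_semiaxes_um: tuple[float, float, float] = (3.05, 3.0, 2.95)
    nucleus_offset_um: tuple[float, float, float] = (0.0, 1.5, 1.3)
    centrioles: CentrioleParams = field(default_factory=CentrioleParams)
    golgi: GolgiParams = field(default_factory=GolgiParams)
    mitochondria: MitochondriaParams = field(default_factory=MitochondriaParams)
    granules: GranuleParams = field(default_factory=GranuleParams)
    microtubules: MicrotubuleParams = field(default_factory=MicrotubuleParams)
    seed: int = 0
    cell_id: str = "synthetic"
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        extent_um = np.asarray(self.shape) * np.asarray(self.spacing_nm) * UM_PER_NM
        if np.any(2 * np.asarray(self.cell_semiaxes_um) >= extent_um - 0.2):
            raise ValueError(
                f"canvas {tuple(np.round(extent_um, 2))} µm is too small for the "
                f"cell ellipsoid with semi-axes {self.cell_semiaxes_um} µm"
            )
        if not 0 <= self.granules.associated_fraction <= 1:
            raise ValueError("associated_fraction must be in [0, 1]")
        mt = self.microtubules
        if not 0 <= mt.fraction_centriole_anchored + mt.fraction_golgi_anchored <= 1:
            raise ValueError("anchored fractions must sum to at most 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCellConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticCellConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("centrioles", CentrioleParams),
            ("golgi", GolgiParams),
            ("mitochondria", MitochondriaParams),
            ("granules", GranuleParams),
            ("microtubules", MicrotubuleParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("shape", "spacing_nm", "cell_semiaxes_um", "nucleus_semiaxes_um",
                    "nucleus_offset_um"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generation-time bookkeeping for parameter-recovery checks."""

    per_mt: pd.DataFrame
    per_sg: pd.DataFrame
    totals: dict


# ---------------------------------------------------------------------------
# distribution helpers


def _truncated_lognormal_quantiles(n, median, sigma, lo, hi, rng, mean_target=None):
    """n stratified quantiles of a lognormal truncated to [lo, hi], permuted.

    If ``mean_target`` is given the log-median is recalibrated so the
    truncated mean equals it.
    """
    if lo is None:
        lo, hi = 0.0, np.inf
    mu = np.log(median)
    if mean_target is not None:
        def trunc_mean(m):
            a = (np.log(lo) - m) / sigma if lo > 0 else -np.inf
            b = (np.log(hi) - m) / sigma if np.isfinite(hi) else np.inf
            z = stats.norm.cdf(b) - stats.norm.cdf(a)
            num = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
            return np.exp(m + sigma**2 / 2) * num / z
        # the truncated mean is monotone in the log-median and spans
        # (trunc_mean(log lo), trunc_mean(log hi)) over this bracket
        lo_m, hi_m = np.log(max(lo, 1e-6)), np.log(hi if np.isfinite(hi) else 100 * mean_target)
        f_lo, f_hi = trunc_mean(lo_m) - mean_target, trunc_mean(hi_m) - mean_target
        if f_lo * f_hi > 0:
            raise ValueError(
                f"mean {mean_target} is not attainable for a lognormal truncated "
                f"to [{lo}, {hi}] with sigma {sigma}"
            )
        mu = optimize.brentq(lambda m: trunc_mean(m) - mean_target, lo_m, hi_m)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    qlo, qhi = dist.cdf(lo), dist.cdf(hi) if np.isfinite(hi) else 1.0
    u = qlo + (np.arange(n) + 0.5) / n * (qhi - qlo)
    vals = dist.ppf(u)
    return rng.permutation(vals)


def _truncated_normal_quantiles(n, mean_target, sd, lo, hi, rng):
    """n stratified quantiles of a normal truncated to [lo, hi] with the
    location recalibrated so the truncated mean equals ``mean_target``."""
    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm(a, b, loc=loc, scale=sd).mean()
    loc = optimize.brentq(lambda m: trunc_mean(m) - mean_target, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    dist = stats.truncnorm(a, b, loc=loc, scale=sd)
    u = (np.arange(n) + 0.5) / n
    return rng.permutation(dist.ppf(u))


def _unit_vectors(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _arc_points(a, b, length, bulge_dir, step):
    """Circular arc from a to b of given arc length, bulging toward
    ``bulge_dir`` (already orthonormal to the chord), sampled at ~step nm."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    chord = float(np.linalg.norm(b - a))
    n_pts = max(2, int(np.ceil(length / step))) + 1
    if length <= chord * (1 + 1e-12):
        t = np.linspace(0.0, 1.0, n_pts)
        return a + t[:, None] * (b - a)
    ratio = chord / length
    theta = optimize.brentq(
        lambda th: np.sin(th / 2) / (th / 2) - ratio, 1e-9, 2 * np.pi - 1e-9
    )
    alpha = theta / 2
    radius = chord / (2 * np.sin(alpha))
    mid = (a + b) / 2
    u = (b - a) / chord
    w = np.asarray(bulge_dir, float)
    center = mid - w * radius * np.cos(alpha)
    t = np.linspace(-alpha, alpha, n_pts)
    return center + radius * (np.cos(t)[:, None] * w + np.sin(t)[:, None] * u)


# ---------------------------------------------------------------------------
# geometry scaffold


class _Scaffold:
    """Masks, distance fields and coordinate helpers shared by the samplers."""

    def __init__(self, cfg: SyntheticCellConfig):
        self.cfg = cfg
        self.shape = np.asarray(cfg.shape)
        self.spacing = np.asarray(cfg.spacing_nm, float)
        self.center_nm = (self.shape - 1) / 2.0 * self.spacing
        self.cell_semi_nm = np.asarray(cfg.cell_semiaxes_um) * NM_PER_UM_F
        self.nuc_center_nm = self.center_nm + np.asarray(cfg.nucleus_offset_um) * NM_PER_UM_F
        self.nuc_semi_nm = np.asarray(cfg.nucleus_semiaxes_um) * NM_PER_UM_F

    def grid_coords(self):
        z = np.arange(self.shape[0]) * self.spacing[0]
        y = np.arange(self.shape[1]) * self.spacing[1]
        x = np.arange(self.shape[2]) * self.spacing[2]
        return np.meshgrid(z, y, x, indexing="ij", sparse=True)

    def ellipsoid_mask(self, center_nm, semi_nm):
        zz, yy, xx = self.grid_coords()
        q = (
            ((zz - center_nm[0]) / semi_nm[0]) ** 2
            + ((yy - center_nm[1]) / semi_nm[1]) ** 2
            + ((xx - center_nm[2]) / semi_nm[2]) ** 2
        )
        return q <= 1.0

    def inside_cell(self, pts, margin_nm=0.0):
        d = (pts - self.center_nm) / (self.cell_semi_nm - margin_nm)
        return np.einsum("ij,ij->i", d, d) <= 1.0

    def outside_nucleus(self, pts, margin_nm=0.0):
        d = (pts - self.nuc_center_nm) / (self.nuc_semi_nm + margin_nm)
        return np.einsum("ij,ij->i", d, d) >= 1.0

    def voxel_of(self, pts):
        idx = np.rint(np.atleast_2d(pts) / self.spacing).astype(int)
        return np.clip(idx, 0, self.shape - 1)

    def at(self, volume, pts):
        idx = self.voxel_of(pts)
        return volume[idx[:, 0], idx[:, 1], idx[:, 2]]


def _rng_stream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent substream of the master seed."""
    digest = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), digest)))


# ---------------------------------------------------------------------------
# organelle builders


def _build_centrioles(scaf: _Scaffold) -> np.ndarray | None:
    p = scaf.cfg.centrioles
    if not p.present:
        return None
    c1 = scaf.center_nm + np.asarray(p.offset_um) * NM_PER_UM_F
    c2 = c1 + np.array([0.0, 450.0, 350.0])
    half = p.length_nm / 2.0
    template = LabeledVolume(np.zeros(scaf.shape, np.uint8), tuple(scaf.spacing))
    barrels = [
        Microtubule(1, np.stack([c1 - [half, 0, 0], c1 + [half, 0, 0]])),
        Microtubule(2, np.stack([c2 - [0, half, 0], c2 + [0, half, 0]])),
    ]
    vol = rasterize_microtubules(
        MicrotubuleNetwork(barrels), template, diameter_nm=2 * p.radius_nm
    )
    return vol.data.astype(bool)


def _build_golgi(scaf: _Scaffold, rng: np.random.Generator,
                 cell: np.ndarray, nucleus: np.ndarray,
                 d_cent: np.ndarray | None) -> np.ndarray | None:
    p = scaf.cfg.golgi
    if p.n_slabs <= 0:
        return None
    axis = np.asarray(p.axis, float)
    axis /= np.linalg.norm(axis)
    cap_cos = np.cos(np.deg2rad(p.cap_angle_deg))
    zz, yy, xx = scaf.grid_coords()
    dz = zz - scaf.nuc_center_nm[0]
    dy = yy - scaf.nuc_center_nm[1]
    dx = xx - scaf.nuc_center_nm[2]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = (dz * axis[0] + dy * axis[1] + dx * axis[2]) / np.where(r > 0, r, 1.0)
    base = float(np.max(scaf.nuc_semi_nm)) + p.standoff_um * NM_PER_UM_F
    golgi = np.zeros(scaf.shape, bool)
    for k in range(p.n_slabs):
        radius = base + k * p.radial_gap_um * NM_PER_UM_F
        shell = (np.abs(r - radius) <= p.thickness_nm / 2.0) & (cos_angle >= cap_cos)
        golgi |= shell
    golgi &= cell & ~nucleus
    if d_cent is not None:
        # keep the Golgi clear of the pericentriolar region
        golgi &= d_cent > 700.0
    if p.perforation_fraction > 0 and golgi.any():
        vox = np.argwhere(golgi)
        area_per_hole = np.pi * 130.0**2
        voxel_area = float(np.mean(scaf.spacing)) ** 2
        n_holes = int(p.perforation_fraction * len(vox) * voxel_area / area_per_hole * 3)
        if n_holes:
            picks = vox[rng.integers(0, len(vox), size=n_holes)]
            centers = picks * scaf.spacing
            hole = np.zeros(scaf.shape, bool)
            rr = 130.0
            for c in centers:
                lo = np.maximum(np.floor((c - rr) / scaf.spacing), 0).astype(int)
                hi = np.minimum(np.ceil((c + rr) / scaf.spacing), scaf.shape - 1).astype(int)
                sz = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
                gz, gy, gx = np.meshgrid(*sz, indexing="ij")
                d2 = ((gz * scaf.spacing[0] - c[0]) ** 2
                      + (gy * scaf.spacing[1] - c[1]) ** 2
                      + (gx * scaf.spacing[2] - c[2]) ** 2)
                sub = hole[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
                sub |= d2 <= rr**2
                hole[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
            golgi &= ~hole
    return golgi if golgi.any() else None


def _build_mitochondria(scaf: _Scaffold, rng: np.random.Generator,
                        cell: np.ndarray, nucleus: np.ndarray,
                        d_static: np.ndarray | None) -> np.ndarray | None:
    p = scaf.cfg.mitochondria
    if p.count <= 0:
        return None
    labels = np.zeros(scaf.shape, np.int32)
    template = LabeledVolume(np.zeros(scaf.shape, np.uint8), tuple(scaf.spacing))
    occupied_pts: list[np.ndarray] = []
    margin = p.radius_nm + 120.0
    placed = 0
    attempts = 0
    while placed < p.count:
        attempts += 1
        if attempts > 400 * p.count:
            raise PackingError(
                f"could only place {placed}/{p.count} mitochondria; lower the count"
            )
        length = rng.uniform(*p.length_um_range) * NM_PER_UM_F
        tau = rng.uniform(1.05, 1.5)
        chord = length / tau
        a = scaf.center_nm + (rng.random(3) - 0.5) * 2 * scaf.cell_semi_nm
        u = _unit_vectors(rng)[0]
        b = a + chord * u
        ends = np.stack([a, b])
        if not (scaf.inside_cell(ends, margin).all()
                and scaf.outside_nucleus(ends, margin).all()):
            continue
        w1 = _unit_vectors(rng)[0]
        w1 -= u * (w1 @ u)
        n = np.linalg.norm(w1)
        if n < 1e-6:
            continue
        pts = _arc_points(a, b, length, w1 / n, step=150.0)
        ok = (scaf.inside_cell(pts, margin).all()
              and scaf.outside_nucleus(pts, margin).all())
        if ok and d_static is not None:
            ok = bool((scaf.at(d_static, pts) > margin).all())
        if ok and occupied_pts:
            prev = np.concatenate(occupied_pts)
            dmin = np.min(np.linalg.norm(pts[:, None, :] - prev[None, :, :], axis=2))
            ok = dmin > 2 * p.radius_nm + 100.0
        if not ok:
            continue
        placed += 1
        occupied_pts.append(pts)
        tube = rasterize_microtubules(
            MicrotubuleNetwork([Microtubule(placed, pts)]), template,
            diameter_nm=2 * p.radius_nm,
        )
        labels[(tube.data > 0) & (labels == 0)] = placed
    return labels if placed else None


# ---------------------------------------------------------------------------
# microtubules


def _sample_anchor_sets(scaf, cyto, d_cent, d_golgi, golgi):
    """Voxel index lists for anchored and free microtubule ends."""
    free_ok = cyto.copy()
    if d_cent is not None:
        free_ok &= d_cent >= 280.0
    if d_golgi is not None:
        free_ok &= d_golgi >= 60.0
    cent_ok = None
    if d_cent is not None:
        cent_ok = cyto & (d_cent > 0) & (d_cent < 140.0)
        if d_golgi is not None:
            cent_ok &= d_golgi >= 60.0
    golgi_ok = None
    if golgi is not None:
        golgi_ok = golgi.copy()
        if d_cent is not None:
            golgi_ok &= d_cent >= 280.0
    return free_ok, cent_ok, golgi_ok


def sample_microtubule(
    scaf: _Scaffold,
    anchor: str,
    length_nm: float,
    tau: float,
    rng: np.random.Generator,
    ctx: dict,
    max_attempts: int = 400,
) -> np.ndarray | None:
    """One microtubule polyline of exact arc length and tortuosity.

    ``anchor`` is 'centriole', 'golgi' or 'free'.  Returns None when no
    placement was found within the attempt budget (the caller may then swap
    in a shorter length).
    """
    p = scaf.cfg.microtubules
    chord = length_nm / tau
    margin = 1.5 * float(np.max(scaf.spacing))
    for _ in range(max_attempts):
        if anchor == "free":
            a = _draw_weighted_point(ctx["free_idx"], ctx["free_p"], scaf, rng)
        elif anchor == "centriole":
            a = _draw_weighted_point(ctx["cent_idx"], None, scaf, rng)
        elif anchor == "golgi":
            a = _draw_weighted_point(ctx["golgi_idx"], None, scaf, rng)
        else:
            raise ValueError(f"unknown anchor class {anchor!r}")
        u = _unit_vectors(rng, 16)
        b = a + chord * u
        good = scaf.inside_cell(b, margin)
        cand = b[good]
        if len(cand) == 0:
            continue
        lam = ctx["pm_lambda_nm"]
        if lam > 0:
            # membrane-parallel enrichment: prefer the far end closest to the
            # membrane, so the filament runs as a near-membrane secant
            order = np.argsort(scaf.at(ctx["d_out"], cand))
            cand = cand[order]
        for bk in cand:
            vb = scaf.voxel_of(bk)[0]
            if not ctx["free_end_ok"][vb[0], vb[1], vb[2]]:
                continue
            uk = (bk - a) / chord
            w1 = _unit_vectors(rng)[0]
            w1 -= uk * (w1 @ uk)
            n = np.linalg.norm(w1)
            if n < 1e-6:
                continue
            w1 /= n
            w2 = np.cross(uk, w1)
            phis = rng.permutation(np.arange(8)) * (np.pi / 4)
            if lam > 0:
                # try outward-bulging arcs first: the filament sags back
                # toward the membrane instead of cutting through the interior
                mid = (a + bk) / 2
                outward = mid - scaf.center_nm
                nrm = np.linalg.norm(outward)
                if nrm > 1e-6:
                    outward /= nrm
                    score = [np.cos(p) * (w1 @ outward) + np.sin(p) * (w2 @ outward)
                             for p in phis]
                    phis = phis[np.argsort(score)[::-1]]
            for phi in phis:
                w = np.cos(phi) * w1 + np.sin(phi) * w2
                pts = _arc_points(a, bk, length_nm, w, step=p.step_nm)
                if not scaf.inside_cell(pts, margin).all():
                    continue
                if not scaf.outside_nucleus(pts, 30.0).all():
                    continue
                coll = scaf.at(ctx["solid"], pts)
                if anchor == "golgi":
                    # the anchored end starts on a cisterna; exempt the first
                    # stretch from the collision test
                    coll = coll[5:]
                if coll.any():
                    continue
                return pts
    return None


def _draw_weighted_point(idx: np.ndarray, sampler: "_WeightedSampler | None",
                         scaf: _Scaffold, rng: np.random.Generator) -> np.ndarray:
    k = rng.integers(0, len(idx)) if sampler is None else sampler.draw(rng)
    jitter = (rng.random(3) - 0.5) * 0.6 * scaf.spacing
    return idx[k] * scaf.spacing + jitter


def _build_microtubules(scaf, rng, cyto, d_cent, d_golgi, d_out, golgi, solid):
    p = scaf.cfg.microtubules
    m = p.count
    if m <= 0:
        return [], []
    lengths = _truncated_lognormal_quantiles(
        m, p.length_mean_um * NM_PER_UM_F, p.length_sigma,
        p.length_range_um[0] * NM_PER_UM_F, p.length_range_um[1] * NM_PER_UM_F,
        rng, mean_target=p.length_mean_um * NM_PER_UM_F,
    )
    taus = _truncated_normal_quantiles(
        m, p.tortuosity_mean, p.tortuosity_sd, *p.tortuosity_range, rng=rng
    )
    n_cent = round(p.fraction_centriole_anchored * m)
    n_golgi = round(p.fraction_golgi_anchored * m)
    anchors = (["centriole"] * n_cent + ["golgi"] * n_golgi
               + ["free"] * (m - n_cent - n_golgi))
    free_ok, cent_ok, golgi_ok = _sample_anchor_sets(scaf, cyto, d_cent, d_golgi, golgi)
    if n_cent and (cent_ok is None or not cent_ok.any()):
        raise ValueError("centriole-anchored microtubules requested but no centrioles present")
    if n_golgi and (golgi_ok is None or not golgi_ok.any()):
        raise ValueError("Golgi-anchored microtubules requested but no Golgi present")
    free_idx = np.argwhere(free_ok)
    lam = p.pm_enrichment_lambda_um * NM_PER_UM_F
    free_p = _WeightedSampler(np.exp(-d_out[free_ok] / lam)) if lam > 0 else None
    ctx = {
        "free_idx": free_idx,
        "free_p": free_p,
        "cent_idx": np.argwhere(cent_ok) if cent_ok is not None else None,
        "golgi_idx": np.argwhere(golgi_ok) if golgi_ok is not None else None,
        "free_end_ok": free_ok,
        "solid": solid,
        "d_out": d_out,
        "pm_lambda_nm": lam,
    }
    polylines, records = [], []
    order = np.argsort([{"centriole": 0, "golgi": 1, "free": 2}[a] for a in anchors])
    lengths = list(lengths)
    for mt_i in order:
        anchor = anchors[mt_i]
        for trial in range(4):
            pts = sample_microtubule(scaf, anchor, lengths[mt_i], taus[mt_i], rng, ctx)
            if pts is not None:
                break
            # swap in a shorter length from a not-yet-built free microtubule
            remaining = [j for j in order if j > mt_i and anchors[j] == "free"
                         and lengths[j] < lengths[mt_i]]
            if not remaining:
                break
            j = remaining[int(rng.integers(0, len(remaining)))]
            lengths[mt_i], lengths[j] = lengths[j], lengths[mt_i]
        if pts is None:
            raise PackingError(
                f"could not place microtubule {mt_i} (anchor={anchor}, "
                f"length={lengths[mt_i]:.0f} nm); lower the count or lengths"
            )
        seg = np.diff(pts, axis=0)
        arc = float(np.sum(np.linalg.norm(seg, axis=1)))
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        polylines.append(pts)
        records.append(
            {
                "mt_id": len(polylines),
                "anchor": anchor,
                "target_length_nm": float(lengths[mt_i]),
                "target_tortuosity": float(taus[mt_i]),
                "length_nm": arc,
                "tortuosity": arc / chord,
            }
        )
    return polylines, records


# ---------------------------------------------------------------------------
# granules


class _CellList:
    """Uniform-grid neighbor lookup for sphere overlap tests."""

    def __init__(self, bin_nm: float):
        self.bin = bin_nm
        self.cells: dict[tuple, list[tuple[np.ndarray, float]]] = {}

    def _key(self, c):
        return tuple((c // self.bin).astype(int))

    def conflicts(self, c, r, gap):
        kz, ky, kx = self._key(c)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for oc, orr in self.cells.get((kz + dz, ky + dy, kx + dx), ()):
                        if np.linalg.norm(c - oc) < r + orr + gap:
                            return True
        return False

    def add(self, c, r):
        self.cells.setdefault(self._key(c), []).append((np.asarray(c), r))


def sample_granules(
    scaf: _Scaffold,
    rng: np.random.Generator,
    cyto: np.ndarray,
    d_obstacle: np.ndarray,
    d_out: np.ndarray,
    tube_mask: np.ndarray | None,
    d_tube: np.ndarray | None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place all granules and rasterize them as an instance label volume.

    Associated granules are centered so that their digitized sphere contains
    a microtubule-mask voxel (voxel distance 0); the rest keep a clearance
    beyond the association threshold.  Spheres never overlap each other, the
    nucleus, mitochondria, Golgi, centrioles or the cell exterior.
    """
    p = scaf.cfg.granules
    n = p.count
    if n == 0:
        return np.zeros(scaf.shape, np.int32), pd.DataFrame(
            columns=["label", "diameter_nm", "center_z_nm", "center_y_nm",
                     "center_x_nm", "associated", "pm_distance_nm"]
        )
    diameters = _truncated_lognormal_quantiles(
        n, p.diameter_median_nm, p.diameter_sigma, 0.0, np.inf, rng
    )
    n_assoc = round(p.associated_fraction * n)
    if n_assoc > 0 and (tube_mask is None or not tube_mask.any()):
        raise ValueError("associated granules requested but there is no microtubule mask")
    # big spheres are placed first within each group: late small spheres fit
    # the remaining gaps far more easily than the reverse
    order_assoc = np.argsort(-diameters[:n_assoc])
    order_free = n_assoc + np.argsort(-diameters[n_assoc:])
    half_diag = 0.5 * float(np.linalg.norm(scaf.spacing))
    grid = _CellList(bin_nm=float(diameters.max()) + p.min_gap_nm + 1)
    lam_free = p.pm_enrichment_lambda_um * NM_PER_UM_F
    lam_assoc = (p.associated_pm_lambda_um or p.pm_enrichment_lambda_um) * NM_PER_UM_F

    centers = np.zeros((n, 3))
    assoc_flags = np.zeros(n, bool)
    if n_assoc:
        tube_idx = np.argwhere(tube_mask & cyto)
        if len(tube_idx) == 0:
            tube_idx = np.argwhere(tube_mask)
        tube_p = (_WeightedSampler(np.exp(-scaf.at(d_out, tube_idx * scaf.spacing) / lam_assoc))
                  if lam_assoc > 0 else None)
    cyto_idx = np.argwhere(cyto)
    cyto_p = _WeightedSampler(np.exp(-d_out[cyto] / lam_free)) if lam_free > 0 else None

    assoc_cut = 20.0  # the association threshold the classifier applies

    def sphere_min_tube_nm(c, r):
        """Min tube-field value over the digitized sphere's voxels - exactly
        the per-granule distance the association classifier will measure."""
        lo = np.maximum(np.floor((c - r) / scaf.spacing), 0).astype(int)
        hi = np.minimum(np.ceil((c + r) / scaf.spacing), scaf.shape - 1).astype(int)
        sz = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
        gz, gy, gx = np.meshgrid(*sz, indexing="ij")
        d2 = ((gz * scaf.spacing[0] - c[0]) ** 2
              + (gy * scaf.spacing[1] - c[1]) ** 2
              + (gx * scaf.spacing[2] - c[2]) ** 2)
        sel = d2 <= r**2
        if not sel.any():
            return np.inf
        sub = d_tube[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        return float(sub[sel].min())

    def place(i, associated):
        r = diameters[i] / 2.0
        for _ in range(8000):
            if associated:
                k = (tube_p.draw(rng) if tube_p is not None
                     else rng.integers(0, len(tube_idx)))
                v_nm = tube_idx[k] * scaf.spacing
                offset = _unit_vectors(rng)[0] * rng.random() * max(0.0, r - 1.0)
                c = v_nm + offset
            else:
                k = (cyto_p.draw(rng) if cyto_p is not None
                     else rng.integers(0, len(cyto_idx)))
                c = cyto_idx[k] * scaf.spacing + (rng.random(3) - 0.5) * scaf.spacing
            vc = scaf.voxel_of(c)[0]
            if d_obstacle[vc[0], vc[1], vc[2]] < r + half_diag + 50.0:
                continue
            if not associated and d_tube is not None:
                if sphere_min_tube_nm(c, r) < assoc_cut:
                    continue
            if grid.conflicts(c, r, p.min_gap_nm):
                continue
            grid.add(c, r)
            centers[i] = c
            assoc_flags[i] = associated
            return
        raise PackingError(
            f"could not place granule {i} (diameter {diameters[i]:.0f} nm); lower the count"
        )

    for i in order_assoc:
        place(i, True)
    for i in order_free:
        place(i, False)

    labels = np.zeros(scaf.shape, np.int32)
    for i in range(n):
        c, r = centers[i], diameters[i] / 2.0
        lo = np.maximum(np.floor((c - r) / scaf.spacing), 0).astype(int)
        hi = np.minimum(np.ceil((c + r) / scaf.spacing), scaf.shape - 1).astype(int)
        sz = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
        gz, gy, gx = np.meshgrid(*sz, indexing="ij")
        d2 = ((gz * scaf.spacing[0] - c[0]) ** 2
              + (gy * scaf.spacing[1] - c[1]) ** 2
              + (gx * scaf.spacing[2] - c[2]) ** 2)
        sub = labels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub[d2 <= r**2] = i + 1
    vox = scaf.voxel_of(centers)
    df = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "diameter_nm": diameters,
            "center_z_nm": centers[:, 0],
            "center_y_nm": centers[:, 1],
            "center_x_nm": centers[:, 2],
            "associated": assoc_flags,
            "pm_distance_nm": d_out[vox[:, 0], vox[:, 1], vox[:, 2]],
        }
    )
    return labels, df


# ---------------------------------------------------------------------------
# point sampling utility (null-model checks)


def sample_uniform_points(
    domain: np.ndarray,
    n: int,
    rng: np.random.Generator,
    spacing_nm,
) -> np.ndarray:
    """n points drawn uniformly over the voxels of a boolean domain mask,
    returned as (z, y, x) nm positions of the chosen voxel centers."""
    idx = np.argwhere(domain)
    if len(idx) == 0:
        raise ValueError("empty domain")
    picks = idx[rng.integers(0, len(idx), size=n)]
    return picks * np.asarray(spacing_nm, float)


# ---------------------------------------------------------------------------
# top level


def generate_cell(
    cfg: SyntheticCellConfig | None = None,
) -> tuple[CellSegmentation, SkeletonFile | None, GroundTruth]:
    """Generate one synthetic cell: segmentation bundle, skeleton file and
    generation-time ground truth.  Deterministic for a fixed config/seed."""
    cfg = cfg or SyntheticCellConfig()
    scaf = _Scaffold(cfg)
    spacing = tuple(float(s) for s in cfg.spacing_nm)

    cell = scaf.ellipsoid_mask(scaf.center_nm, scaf.cell_semi_nm)
    nucleus = scaf.ellipsoid_mask(scaf.nuc_center_nm, scaf.nuc_semi_nm)
    nucleus &= cell

    centrioles = _build_centrioles(scaf)
    d_cent = None
    if centrioles is not None:
        d_cent = ndimage.distance_transform_edt(
            ~centrioles, sampling=spacing).astype(np.float32)
    golgi = _build_golgi(scaf, _rng_stream(cfg.seed, "golgi"), cell, nucleus, d_cent)
    d_golgi = None
    if golgi is not None:
        d_golgi = ndimage.distance_transform_edt(
            ~golgi, sampling=spacing).astype(np.float32)
    if d_cent is not None and d_golgi is not None:
        d_static = np.minimum(d_cent, d_golgi)
    else:
        d_static = d_cent if d_cent is not None else d_golgi
    mito = _build_mitochondria(scaf, _rng_stream(cfg.seed, "mitochondria"),
                               cell, nucleus, d_static)

    solid = nucleus.copy()
    for extra in (centrioles, golgi):
        if extra is not None:
            solid |= extra
    if mito is not None:
        solid |= mito > 0
    cyto = cell & ~solid

    d_out = ndimage.distance_transform_edt(cell, sampling=spacing).astype(np.float32)

    polylines, mt_records = _build_microtubules(
        scaf, _rng_stream(cfg.seed, "microtubules"),
        cyto, d_cent, d_golgi, d_out, golgi, solid,
    )

    template = LabeledVolume(np.zeros(scaf.shape, np.uint8), spacing)
    tube = None
    if polylines:
        net = MicrotubuleNetwork(
            [Microtubule(i + 1, pts) for i, pts in enumerate(polylines)]
        )
        tube = rasterize_microtubules(net, template, cfg.microtubules.diameter_nm)
    tube_mask = tube.data.astype(bool) if tube is not None else None
    d_tube = (ndimage.distance_transform_edt(~tube_mask, sampling=spacing).astype(np.float32)
              if tube_mask is not None and tube_mask.any() else None)

    obstacle = solid | ~cell
    d_obstacle = ndimage.distance_transform_edt(~obstacle, sampling=spacing).astype(np.float32)
    granule_labels, sg_df = sample_granules(
        scaf, _rng_stream(cfg.seed, "granules"),
        cyto, d_obstacle, d_out, tube_mask, d_tube,
    )

    def vol(name, data):
        return LabeledVolume(data, spacing) if data is not None else None

    seg = CellSegmentation(
        cell_mask=LabeledVolume(cell.astype(np.uint8), spacing),
        nucleus=LabeledVolume(nucleus.astype(np.uint8), spacing),
        centrioles=vol("centrioles", centrioles.astype(np.uint8) if centrioles is not None else None),
        golgi=vol("golgi", golgi.astype(np.uint8) if golgi is not None else None),
        mitochondria=vol("mitochondria", mito),
        granules=vol("granules", granule_labels if cfg.granules.count else None),
        microtubule_mask=tube,
        cell_id=cfg.cell_id,
        condition=cfg.condition,
        metadata={"generator": "betacell3d.synthetic", "seed": cfg.seed},
    )

    skel = None
    if polylines:
        nodes, edges, components = {}, [], {}
        nid = 0
        for k, pts in enumerate(polylines, start=1):
            first = nid + 1
            for ptx in pts:
                nid += 1
                nodes[nid] = np.asarray(ptx, float)
                components[nid] = k
            edges.extend((i, i + 1) for i in range(first, nid))
        skel = SkeletonFile(nodes, edges, components, source_dialect="annotation-xml")

    mt_df = pd.DataFrame(mt_records) if mt_records else pd.DataFrame(
        columns=["mt_id", "anchor", "target_length_nm", "target_tortuosity",
                 "length_nm", "tortuosity"]
    )
    vv_um3 = float(np.prod(spacing)) * 1e-9
    cell_v = float(cell.sum()) * vv_um3
    nuc_v = float(nucleus.sum()) * vv_um3
    cyto_v = cell_v - nuc_v
    n_sg = len(sg_df)
    n_assoc = int(sg_df["associated"].sum()) if n_sg else 0
    cum_len_um = float(mt_df["length_nm"].sum()) / NM_PER_UM if len(mt_df) else 0.0
    totals = {
        "cell_volume_um3": cell_v,
        "nucleus_volume_um3": nuc_v,
        "cytoplasm_volume_um3": cyto_v,
        "nucleus_volume_pct": 100.0 * nuc_v / cell_v,
        "sg_count": n_sg,
        "sg_associated_count": n_assoc,
        "sg_associated_pct": 100.0 * n_assoc / n_sg if n_sg else None,
        "sg_mean_diameter_nm": float(sg_df["diameter_nm"].mean()) if n_sg else None,
        "mt_count": len(mt_df),
        "mt_centriole_anchored": int((mt_df["anchor"] == "centriole").sum()),
        "mt_golgi_anchored": int((mt_df["anchor"] == "golgi").sum()),
        "mt_mean_length_nm": float(mt_df["length_nm"].mean()) if len(mt_df) else None,
        "mt_cumulative_length_um": cum_len_um,
        "mt_mean_tortuosity": float(mt_df["tortuosity"].mean()) if len(mt_df) else None,
        "assoc_sg_density_per_um3": n_assoc / cyto_v if n_sg else None,
        "tubulin_density_um_per_um3": cum_len_um / cyto_v if len(mt_df) else None,
    }
    return seg, skel, GroundTruth(per_mt=mt_df, per_sg=sg_df, totals=totals)


def write_synthetic_cell(cfg: SyntheticCellConfig, directory: str | Path) -> Path:
    """Generate a cell and write it in the standard per-cell layout together
    with its ground-truth tables.  Returns the manifest path."""
    from .io import write_cell

    seg, skel, gt = generate_cell(cfg)
    directory = Path(directory)
    polylines = None
    if skel is not None:
        by_comp: dict[int, list] = {}
        for nid in sorted(skel.nodes):
            by_comp.setdefault(skel.components[nid], []).append(skel.nodes[nid])
        polylines = [np.stack(v) for _, v in sorted(by_comp.items())]
    manifest = write_cell(seg, directory, skeleton_polylines=polylines)
    gt.per_mt.to_csv(directory / "ground_truth_microtubules.csv", index=False)
    gt.per_sg.to_csv(directory / "ground_truth_granules.csv", index=False)
    pd.Series(gt.totals).to_csv(directory / "ground_truth_totals.csv", header=False)
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return manifest
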