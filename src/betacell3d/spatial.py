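"""Anisotropy-aware Euclidean distance fields and geometric null models.

The central object is the distance field of an organelle: the exact
Euclidean distance (in nm, honoring per-axis voxel spacing) from every voxel
center to the nearest voxel of the target mask.  Observed distance
distributions (granules, microtubule ends, microtubule pixels) are compared
against the *random reference* rho_X of the target: the distribution of the
field over every cytoplasmic voxel (cell minus nucleus minus the target
itself).  rho_X captures the purely geometric effect of the target's spatial
arrangement - it is what the observed distribution would look like if the
query objects were scattered uniformly through the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabeledVolume
from .skeletons import Microtubule, MicrotubuleNetwork

__all__ = [
    "DistanceField",
    "RandomReference",
    "DistanceDistribution",
    "distance_field",
    "membrane_shell",
    "sample_field",
    "object_distance",
    "object_distances",
    "end_distance",
    "end_distances",
    "random_reference",
    "make_distribution",
    "max_ecdf_gap",
    "enrichment",
]


@dataclass
class DistanceField:
    """Euclidean distance (nm) from each voxel center to the nearest target voxel."""

    target: str
    values: np.ndarray
    spacing_nm: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RandomReference:
    """The geometric null rho_X: distances of all cytoplasmic voxels to target X."""

    target: str
    bin_edges: np.ndarray  # len nbins + 1, starts at 0
    fraction: np.ndarray   # len nbins, sums to 1
    ecdf: np.ndarray       # len nbins, cumulative fraction at right bin edges
    bin_width_nm: float
    n_voxels: int
    domain: str = "cell minus nucleus minus target"


@dataclass
class DistanceDistribution:
    """Observed distances of query objects to a target, binned on the same
    grid as the paired random reference."""

    query: str
    target: str
    values: np.ndarray
    bin_edges: np.ndarray
    fraction: np.ndarray
    ecdf: np.ndarray
    reference: RandomReference = dc_field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.values)


def distance_field(target: LabeledVolume, label: int | None = None) -> DistanceField:
    """Exact anisotropic Euclidean distance transform of a target label.

    ``label=None`` means all foreground.  Distances are voxel-center to
    voxel-center; the field is exactly 0 on target voxels.
    """
    mask = target.mask(label)
    if not mask.any():
        raise ValueError(f"target label {label!r} is absent; cannot build a distance field")
    values = ndimage.distance_transform_edt(~mask, sampling=target.spacing_nm)
    return DistanceField("target", values.astype(np.float32), target.spacing_nm)


def membrane_shell(cell_mask: LabeledVolume) -> LabeledVolume:
    """The plasma-membrane proxy: the background-adjacent shell of the cell
    mask (cell voxels with at least one 6-neighbor outside the mask)."""
    m = cell_mask.mask()
    eroded = ndimage.binary_erosion(m)  # 6-connectivity cross by default
    return cell_mask.like((m & ~eroded).astype(np.uint8))


def sample_field(field: DistanceField, points_nm: np.ndarray, context: str = "point") -> np.ndarray:
    """Field values at the voxels containing physical points (nearest voxel
    center, no interpolation - sub-voxel interpolation would add complexity
    below the data resolution).  Raises for points outside the field bounds,
    naming the offender via ``context``."""
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    spacing = np.asarray(field.spacing_nm)
    idx = np.rint(pts / spacing).astype(int)
    shape = np.asarray(field.shape)
    bad = np.any((idx < 0) | (idx >= shape), axis=1)
    if bad.any():
        k = int(np.argmax(bad))
        raise ValueError(f"{context} at {pts[k]} nm lies outside the field bounds {tuple(shape)}")
    return field.values[idx[:, 0], idx[:, 1], idx[:, 2]]


def object_distance(query: LabeledVolume, label: int, field: DistanceField) -> float:
    """Minimum of the field over one query object's voxels (surface-to-surface
    semantics at voxel resolution; 0 if the objects overlap)."""
    mask = query.mask(label)
    if not mask.any():
        raise ValueError(f"query label {label} is absent")
    return float(field.values[mask].min())


def object_distances(query: LabeledVolume, field: DistanceField) -> pd.Series:
    """Per-label minimum field value for every instance label in ``query``
    (one value per object, the convention used for granule distributions)."""
    labels = query.labels()
    if labels.size == 0:
        return pd.Series(dtype=float, name="distance_nm")
    mins = ndimage.minimum(field.values, labels=query.data, index=labels)
    return pd.Series(np.asarray(mins, dtype=float), index=labels, name="distance_nm")


def end_distance(mt: Microtubule, field: DistanceField, which: str = "closer"):
    """Field distance of a microtubule's ends to the target.

    ``which='both'`` returns the pair, ``which='closer'`` the minimum of the
    two - when relating microtubule ends to an organelle only the end nearer
    to it is informative.
    """
    e0, e1 = mt.ends
    d = sample_field(field, np.stack([e0, e1]), context=f"end of microtubule {mt.id}")
    if which == "both":
        return float(d[0]), float(d[1])
    if which == "closer":
        return float(d.min())
    raise ValueError(f"which must be 'both' or 'closer', got {which!r}")


def end_distances(net: MicrotubuleNetwork, field: DistanceField) -> pd.DataFrame:
    """End distances for every microtubule of a network."""
    rows = []
    for mt in net:
        d0, d1 = end_distance(mt, field, which="both")
        rows.append({"mt_id": mt.id, "end0_nm": d0, "end1_nm": d1, "closer_nm": min(d0, d1)})
    return pd.DataFrame(rows)


def _bin_edges(max_value: float, bin_width_nm: float) -> np.ndarray:
    n_bins = max(1, int(np.ceil((max_value + 1e-9) / bin_width_nm)))
    return np.arange(n_bins + 1, dtype=float) * bin_width_nm


def random_reference(
    target: LabeledVolume,
    cell_mask: LabeledVolume,
    nucleus: LabeledVolume | None,
    bin_width_nm: float = 20.0,
    label: int | None = None,
    field: DistanceField | None = None,
    name: str = "target",
) -> RandomReference:
    """The random reference distribution rho_X of a target organelle.

    Distances of every voxel in (cell AND NOT nucleus AND NOT target) to the
    target, binned at ``bin_width_nm``.  The nucleus and the target itself
    are excluded from the domain; other organelles are not.
    """
    if field is None:
        field = distance_field(target, label)
    domain = cell_mask.mask() & ~target.mask(label)
    if nucleus is not None:
        domain &= ~nucleus.mask()
    if not domain.any():
        raise ValueError(f"empty domain for the random reference of {name}")
    dists = field.values[domain]
    edges = _bin_edges(float(dists.max()), bin_width_nm)
    counts, _ = np.histogram(dists, bins=edges)
    frac = counts / counts.sum()
    return RandomReference(
        target=name,
        bin_edges=edges,
        fraction=frac,
        ecdf=np.cumsum(frac),
        bin_width_nm=float(bin_width_nm),
        n_voxels=int(domain.sum()),
    )


def make_distribution(
    values: np.ndarray,
    reference: RandomReference,
    query: str = "query",
) -> DistanceDistribution:
    """Bin observed distances on the reference's grid so the two histograms
    and cumulative curves are directly comparable."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build a distribution from no distances")
    if np.any(values < 0):
        raise ValueError("distances must be non-negative")
    edges = reference.bin_edges
    # values at or beyond the last edge land in the last bin
    clipped = np.minimum(values, edges[-1] - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    frac = counts / counts.sum()
    return DistanceDistribution(
        query=query,
        target=reference.target,
        values=values,
        bin_edges=edges,
        fraction=frac,
        ecdf=np.cumsum(frac),
        reference=reference,
    )


def _ecdf_at(ecdf: np.ndarray, edges: np.ndarray, at_nm: float) -> float:
    """Step-function value of a binned ecdf at a distance (fraction <= at_nm,
    at bin granularity)."""
    if at_nm < edges[0]:
        return 0.0
    k = int(np.searchsorted(edges[1:], at_nm, side="left"))
    return float(ecdf[min(k, len(ecdf) - 1)])


def max_ecdf_gap(dist: DistanceDistribution) -> float:
    """Largest absolute gap between the observed and reference cumulative
    curves over the shared bin grid (a Kolmogorov-Smirnov-style statistic at
    bin resolution)."""
    if dist.reference is None:
        raise ValueError("distribution has no paired random reference")
    return float(np.max(np.abs(dist.ecdf - dist.reference.ecdf)))


def enrichment(dist: DistanceDistribution, at_nm: float) -> float:
    """Observed minus reference cumulative fraction at a distance.

    Positive values mean the query objects sit closer to the target than
    uniformly scattered points would (enrichment near the target).
    """
    if dist.reference is None:
        raise ValueError("distribution has no paired random reference")
    obs = _ecdf_at(dist.ecdf, dist.bin_edges, at_nm)
    ref = _ecdf_at(dist.reference.ecdf, dist.reference.bin_edges, at_nm)
    return obs - ref
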