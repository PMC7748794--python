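"""Microtubule objects and per-filament / per-network metrics.

A traced microtubule is a simple open path: an ordered polyline of >= 2
points in nm.  Its length is the arc length of the polyline and its
tortuosity the arc length divided by the end-to-end chord, the standard
tortuosity index (1 = perfectly straight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabeledVolume, SkeletonFile

__all__ = [
    "Microtubule",
    "MicrotubuleNetwork",
    "SkeletonTopologyError",
    "build_network",
    "polyline_length",
    "tortuosity",
    "rasterize_microtubules",
    "summarize_network",
]

NM_PER_UM = 1000.0


class SkeletonTopologyError(ValueError):
    """Raised when a skeleton component is not a simple open path."""


@dataclass
class Microtubule:
    """One traced microtubule as an ordered polyline in nm."""

    id: int
    points: np.ndarray  # (n, 3) float, (z, y, x) nm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a microtubule needs an (n >= 2, 3) polyline")

    @property
    def length_nm(self) -> float:
        return polyline_length(self)

    @property
    def tortuosity(self) -> float:
        return tortuosity(self)

    @property
    def ends(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass
class MicrotubuleNetwork:
    """The collection of microtubules of one cell."""

    microtubules: list[Microtubule] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.microtubules)

    @property
    def cumulative_length_nm(self) -> float:
        return float(sum(mt.length_nm for mt in self.microtubules))

    @property
    def mean_length_nm(self) -> float:
        if not self.microtubules:
            raise ValueError("empty network has no mean length")
        return self.cumulative_length_nm / self.count

    @property
    def mean_tortuosity(self) -> float:
        if not self.microtubules:
            raise ValueError("empty network has no mean tortuosity")
        return float(np.mean([mt.tortuosity for mt in self.microtubules]))

    def __iter__(self):
        return iter(self.microtubules)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per microtubule: id, length, tortuosity, end coordinates."""
        rows = []
        for mt in self.microtubules:
            e0, e1 = mt.ends
            rows.append(
                {
                    "mt_id": mt.id,
                    "length_nm": mt.length_nm,
                    "tortuosity": mt.tortuosity,
                    "end0_z_nm": e0[0], "end0_y_nm": e0[1], "end0_x_nm": e0[2],
                    "end1_z_nm": e1[0], "end1_y_nm": e1[1], "end1_x_nm": e1[2],
                }
            )
        return pd.DataFrame(rows)


def build_network(skel: SkeletonFile) -> MicrotubuleNetwork:
    """Turn a skeleton file into validated microtubules.

    Every connected component must be a simple open path (all node degrees
    <= 2, no cycles, at least two nodes).  Points are ordered by walking from
    one degree-1 node to the other; for a two-node path the walk starts at
    the lower node id (deterministic tie-break).
    """
    adj: dict[int, list[int]] = {nid: [] for nid in skel.nodes}
    for a, b in skel.edges:
        adj[a].append(b)
        adj[b].append(a)
    seen: set[int] = set()
    mts: list[Microtubule] = []
    comp_id = 0
    for start in sorted(skel.nodes):
        if start in seen:
            continue
        # collect the component by BFS
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            cur = queue.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.append(nxt)
                    queue.append(nxt)
        comp_id += 1
        for nid in comp:
            if len(adj[nid]) > 2:
                raise SkeletonTopologyError(
                    f"component {comp_id} branches at node {nid} (degree {len(adj[nid])})"
                )
        if len(comp) == 1:
            raise SkeletonTopologyError(
                f"component {comp_id} is an isolated single node (id {comp[0]})"
            )
        endpoints = sorted(n for n in comp if len(adj[n]) == 1)
        if not endpoints:
            raise SkeletonTopologyError(
                f"component {comp_id} is a closed loop (nodes {sorted(comp)[:5]}...)"
            )
        # walk the path from the lower-id endpoint
        order = [endpoints[0]]
        prev = None
        while True:
            cur = order[-1]
            nxt = [n for n in adj[cur] if n != prev]
            if not nxt:
                break
            prev = cur
            order.append(nxt[0])
        if len(order) != len(comp):
            raise SkeletonTopologyError(f"component {comp_id} is not a simple path")
        pts = np.stack([skel.nodes[n] for n in order])
        mts.append(Microtubule(id=comp_id, points=pts))
    return MicrotubuleNetwork(mts)


def polyline_length(mt: Microtubule) -> float:
    """Arc length in nm: the sum of consecutive point distances."""
    seg = np.diff(mt.points, axis=0)
    return float(np.sum(np.linalg.norm(seg, axis=1)))


def tortuosity(mt: Microtubule) -> float:
    """Arc length over end-to-end chord length; exactly 1 for a straight path."""
    chord = float(np.linalg.norm(mt.points[-1] - mt.points[0]))
    if chord == 0.0:
        raise ValueError(f"microtubule {mt.id} has zero end-to-end distance (closed path)")
    return polyline_length(mt) / chord


def rasterize_microtubules(
    net: MicrotubuleNetwork,
    template: LabeledVolume,
    diameter_nm: float = 25.0,
) -> LabeledVolume:
    """Binary mask of all voxels whose center lies within ``diameter_nm / 2``
    of any polyline segment.

    Traced skeletons have zero width; the mask restores the physical filament
    thickness (25 nm outer diameter for a microtubule).  Voxel centers sit at
    ``index * spacing``.  Polyline points outside the template bounds are
    clipped with a warning.
    """
    spacing = np.asarray(template.spacing_nm)
    shape = np.asarray(template.shape)
    radius = diameter_nm / 2.0
    out = np.zeros(template.shape, dtype=np.uint8)
    clipped = 0
    upper = (shape - 1) * spacing
    for mt in net:
        pts = mt.points
        if np.any(pts < -radius) or np.any(pts > upper + radius):
            clipped += 1
        for a, b in zip(pts[:-1], pts[1:]):
            lo = np.maximum(np.ceil((np.minimum(a, b) - radius) / spacing), 0).astype(int)
            hi = np.minimum(np.floor((np.maximum(a, b) + radius) / spacing), shape - 1).astype(int)
            if np.any(hi < lo):
                continue
            zz, yy, xx = np.meshgrid(
                *(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij"
            )
            centers = np.stack([zz, yy, xx], axis=-1) * spacing
            d = _point_segment_distance(centers.reshape(-1, 3), a, b)
            sel = (d <= radius).reshape(zz.shape)
            out[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1][sel] = 1
    if clipped:
        warnings.warn(f"{clipped} microtubules extend beyond the template bounds; clipped")
    return template.like(out)


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def mean_length_um(cumulative_length_um: float, count: int) -> float:
    """Mean microtubule length in µm (2 decimals) from the per-cell totals."""
    if count <= 0:
        raise ValueError("count must be positive")
    return round(cumulative_length_um / count, 2)


def summarize_network(net: MicrotubuleNetwork) -> dict:
    """Per-cell network summary in reporting units (lengths in µm rounded to
    2 decimals, cumulative length to the nearest µm, tortuosity to 2
    decimals); raw nm values are retained alongside."""
    if net.count == 0:
        raise ValueError("cannot summarize an empty microtubule network")
    mean_um = net.mean_length_nm / NM_PER_UM
    cum_um = net.cumulative_length_nm / NM_PER_UM
    return {
        "mt_count": net.count,
        "mt_mean_length_um": round(mean_um, 2),
        "mt_cumulative_length_um": round(cum_um),
        "mt_mean_tortuosity": round(net.mean_tortuosity, 2),
        "mt_mean_length_nm_raw": net.mean_length_nm,
        "mt_cumulative_length_nm_raw": net.cumulative_length_nm,
        "mt_mean_tortuosity_raw": net.mean_tortuosity,
    }
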