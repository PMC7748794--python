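"""Reading and writing of label volumes, skeleton annotation files and
per-cell directory layouts.

All physical quantities are carried in nanometres.  Arrays are indexed
``(z, y, x)`` throughout the package; a voxel with index ``i`` along an axis
with spacing ``s`` sits at physical coordinate ``i * s`` (the voxel *center*),
so the voxel containing a physical point ``p`` is ``round(p / s)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import h5py
import numpy as np
import tifffile
import yaml

__all__ = [
    "LabeledVolume",
    "CellSegmentation",
    "SkeletonFile",
    "SkeletonParseError",
    "read_label_volume",
    "write_label_volume",
    "read_skeleton",
    "write_skeleton_xml",
    "load_cell",
    "write_cell",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


class SkeletonParseError(ValueError):
    """Raised for structurally invalid skeleton annotation files."""


@dataclass
class LabeledVolume:
    """A 3D integer label array with physical calibration.

    Parameters
    ----------
    data:
        3D array of non-negative integer labels; 0 is background.
    spacing_nm:
        Voxel edge length in nm per axis, ordered ``(z, y, x)``.
    origin_nm:
        Physical coordinate of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float]
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype == bool:
            self.data = self.data.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be rank 3, got rank {self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must have an integer dtype, got {self.data.dtype}")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError(f"spacing_nm must be three positive lengths, got {self.spacing_nm}")
        self.origin_nm = tuple(float(o) for o in self.origin_nm)
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        z, y, x = self.spacing_nm
        return z * y * x

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_volume_nm3 * 1e-9

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        lab = np.unique(self.data)
        return lab[lab > 0]

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all foreground if ``label`` is None."""
        if label is None:
            return self.data > 0
        return self.data == label

    def like(self, data: np.ndarray) -> "LabeledVolume":
        """A new volume sharing this volume's calibration."""
        return LabeledVolume(data, self.spacing_nm, self.origin_nm)


@dataclass
class SkeletonFile:
    """Node/edge skeleton annotation in physical nm coordinates.

    ``nodes`` maps node id to a ``(z, y, x)`` position in nm.  ``components``
    maps node id to a component id taken from the file's grouping (one
    annotation "thing" per traced structure) or, for formats without grouping,
    from edge connectivity.
    """

    nodes: dict[int, np.ndarray]
    edges: list[tuple[int, int]]
    components: dict[int, int]
    source_dialect: str = "annotation-xml"

    def __post_init__(self) -> None:
        ids = set(self.nodes)
        for a, b in self.edges:
            for nid in (a, b):
                if nid not in ids:
                    raise SkeletonParseError(f"edge references unknown node id {nid}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class CellSegmentation:
    """The bundle of segmentation masks for one cell.

    ``cell_mask`` and ``nucleus`` are required; the remaining organelles are
    optional and recorded as ``None`` when absent.  All member volumes must
    share shape and spacing.
    """

    cell_mask: LabeledVolume
    nucleus: LabeledVolume
    centrioles: LabeledVolume | None = None
    golgi: LabeledVolume | None = None
    mitochondria: LabeledVolume | None = None
    granules: LabeledVolume | None = None
    microtubule_mask: LabeledVolume | None = None
    cell_id: str = "cell"
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    _OPTIONAL = ("centrioles", "golgi", "mitochondria", "granules", "microtubule_mask")

    def __post_init__(self) -> None:
        ref = self.cell_mask
        for name in ("nucleus",) + self._OPTIONAL:
            vol = getattr(self, name)
            if vol is None:
                continue
            if vol.shape != ref.shape:
                raise ValueError(
                    f"shape mismatch between cell_mask {ref.shape} and {name} {vol.shape}"
                )
            if vol.spacing_nm != ref.spacing_nm:
                raise ValueError(
                    f"spacing mismatch between cell_mask {ref.spacing_nm} "
                    f"and {name} {vol.spacing_nm}"
                )

    @property
    def spacing_nm(self) -> tuple[float, float, float]:
        return self.cell_mask.spacing_nm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell_mask.shape

    def present(self, name: str) -> bool:
        return getattr(self, name, None) is not None

    def validate(self) -> list[str]:
        """Containment checks; violations are reported, never silently fixed."""
        issues: list[str] = []
        cell = self.cell_mask.mask()
        if not cell.any():
            issues.append("cell_mask is empty")
            return issues
        if np.any(self.nucleus.mask() & ~cell):
            n = int(np.count_nonzero(self.nucleus.mask() & ~cell))
            issues.append(f"nucleus has {n} voxels outside the cell mask")
        if self.granules is not None:
            outside = self.granules.mask() & ~cell
            if outside.any():
                bad = np.unique(self.granules.data[outside])
                issues.append(
                    f"{bad.size} granule labels have voxels outside the cell mask "
                    f"(e.g. labels {bad[:5].tolist()})"
                )
        return issues


# ---------------------------------------------------------------------------
# label volume I/O

def read_label_volume(
    path: str | Path,
    spacing_nm: tuple[float, float, float] | None = None,
    dataset: str = "labels",
) -> LabeledVolume:
    """Read a 3D label volume from a multi-page TIFF or an HDF5 dataset.

    ``spacing_nm`` overrides any calibration stored in the file; it is
    required when the file carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    origin = (0.0, 0.0, 0.0)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            ds = fh[dataset]
            data = ds[()]
            if spacing_nm is None and "spacing_nm" in ds.attrs:
                spacing_nm = tuple(float(s) for s in ds.attrs["spacing_nm"])
            if "origin_nm" in ds.attrs:
                origin = tuple(float(o) for o in ds.attrs["origin_nm"])
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if spacing_nm is None and desc:
            try:
                meta = json.loads(desc)
                spacing_nm = tuple(float(s) for s in meta["spacing_nm"])
                origin = tuple(float(o) for o in meta.get("origin_nm", origin))
            except (ValueError, KeyError, TypeError):
                pass
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r} (expected TIFF or HDF5)")
    if spacing_nm is None:
        raise ValueError(f"{path} carries no voxel spacing; pass spacing_nm explicitly")
    return LabeledVolume(np.asarray(data), spacing_nm, origin)


def write_label_volume(vol: LabeledVolume, path: str | Path, dataset: str = "labels") -> None:
    """Write a label volume; the result round-trips bit-identically through
    :func:`read_label_volume`, including the spacing metadata."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(dataset, data=vol.data, compression="gzip")
            ds.attrs["spacing_nm"] = np.asarray(vol.spacing_nm)
            ds.attrs["origin_nm"] = np.asarray(vol.origin_nm)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        desc = json.dumps({"spacing_nm": vol.spacing_nm, "origin_nm": vol.origin_nm})
        tifffile.imwrite(path, vol.data, description=desc, photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r} (expected TIFF or HDF5)")


# ---------------------------------------------------------------------------
# skeleton I/O

def read_skeleton(
    path: str | Path,
    spacing_nm: tuple[float, float, float] | None = None,
) -> SkeletonFile:
    """Read a skeleton annotation file (annotation-tool XML dialect or SWC).

    XML node coordinates are in voxel units and are scaled to nm with the
    file's ``<scale>`` element (or ``spacing_nm`` if the file has none).
    SWC coordinates are multiplied by ``spacing_nm`` when given, else taken
    to be nm already.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such skeleton file: {path}")
    if path.suffix.lower() == ".swc":
        return _read_swc(path, spacing_nm)
    return _read_annotation_xml(path, spacing_nm)


def _read_annotation_xml(path: Path, spacing_nm) -> SkeletonFile:
    tree = ElementTree.parse(path)
    root = tree.getroot()
    scale_el = root.find("./parameters/scale")
    if scale_el is not None:
        scale = (
            float(scale_el.get("z")),
            float(scale_el.get("y")),
            float(scale_el.get("x")),
        )
    elif spacing_nm is not None:
        scale = tuple(float(s) for s in spacing_nm)
    else:
        raise SkeletonParseError(
            f"{path} has no <scale> element and no spacing_nm was supplied"
        )
    nodes: dict[int, np.ndarray] = {}
    components: dict[int, int] = {}
    edges: list[tuple[int, int]] = []
    for thing in root.iter("thing"):
        comp_id = int(thing.get("id", len(set(components.values())) + 1))
        for node in thing.iter("node"):
            nid = int(node.get("id"))
            if nid in nodes:
                raise SkeletonParseError(f"duplicate node id {nid} in {path}")
            pos = np.array(
                [
                    float(node.get("z")) * scale[0],
                    float(node.get("y")) * scale[1],
                    float(node.get("x")) * scale[2],
                ]
            )
            nodes[nid] = pos
            components[nid] = comp_id
        for edge in thing.iter("edge"):
            edges.append((int(edge.get("source")), int(edge.get("target"))))
    for a, b in edges:
        for nid in (a, b):
            if nid not in nodes:
                raise SkeletonParseError(f"edge references unknown node id {nid} in {path}")
    return SkeletonFile(nodes, edges, components, source_dialect="annotation-xml")


def _read_swc(path: Path, spacing_nm) -> SkeletonFile:
    scale = tuple(float(s) for s in spacing_nm) if spacing_nm is not None else (1.0, 1.0, 1.0)
    nodes: dict[int, np.ndarray] = {}
    edges: list[tuple[int, int]] = []
    parents: dict[int, int] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SkeletonParseError(f"malformed SWC line in {path}: {line!r}")
        nid = int(parts[0])
        if nid in nodes:
            raise SkeletonParseError(f"duplicate node id {nid} in {path}")
        x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
        nodes[nid] = np.array([z * scale[0], y * scale[1], x * scale[2]])
        parents[nid] = int(parts[6])
    for nid, par in parents.items():
        if par == -1:
            continue
        if par not in nodes:
            raise SkeletonParseError(f"edge references unknown node id {par} in {path}")
        edges.append((par, nid))
    components = _components_from_edges(set(nodes), edges)
    return SkeletonFile(nodes, edges, components, source_dialect="swc")


def _components_from_edges(ids: set[int], edges: list[tuple[int, int]]) -> dict[int, int]:
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = sorted({find(i) for i in ids})
    root_to_comp = {r: k + 1 for k, r in enumerate(roots)}
    return {i: root_to_comp[find(i)] for i in ids}


def write_skeleton_xml(
    polylines: list[np.ndarray],
    path: str | Path,
    spacing_nm: tuple[float, float, float],
) -> None:
    """Write polylines (each an ``(n, 3)`` array of (z, y, x) nm positions) as
    one annotation "thing" each, coordinates in voxel units with the spacing
    recorded as the file scale."""
    sz, sy, sx = (float(s) for s in spacing_nm)
    root = ElementTree.Element("things")
    params = ElementTree.SubElement(root, "parameters")
    ElementTree.SubElement(
        params, "scale", {"x": repr(sx), "y": repr(sy), "z": repr(sz)}
    )
    nid = 0
    for k, pts in enumerate(polylines, start=1):
        pts = np.asarray(pts, dtype=float)
        thing = ElementTree.SubElement(root, "thing", {"id": str(k)})
        nodes_el = ElementTree.SubElement(thing, "nodes")
        edges_el = ElementTree.SubElement(thing, "edges")
        first = nid + 1
        for p in pts:
            nid += 1
            ElementTree.SubElement(
                nodes_el,
                "node",
                {
                    "id": str(nid),
                    "x": repr(float(p[2] / sx)),
                    "y": repr(float(p[1] / sy)),
                    "z": repr(float(p[0] / sz)),
                },
            )
        for i in range(first, nid):
            ElementTree.SubElement(edges_el, "edge", {"source": str(i), "target": str(i + 1)})
    ElementTree.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# per-cell directory layout

_REQUIRED_VOLUMES = ("cell", "nucleus")
_VOLUME_FIELDS = {
    "cell": "cell_mask",
    "nucleus": "nucleus",
    "centrioles": "centrioles",
    "golgi": "golgi",
    "mitochondria": "mitochondria",
    "granules": "granules",
    "microtubule_mask": "microtubule_mask",
}


def load_cell(
    directory: str | Path,
    manifest: str | Path | dict | None = None,
) -> tuple[CellSegmentation, SkeletonFile | None]:
    """Load one cell from a directory described by a YAML manifest.

    The manifest maps organelle names to files and states the voxel spacing;
    ``cell`` and ``nucleus`` are required, everything else optional.  Missing
    optional organelles are recorded as absent, not as all-zero masks.
    """
    directory = Path(directory)
    if manifest is None:
        manifest = directory / "cell.yaml"
    if not isinstance(manifest, dict):
        manifest = yaml.safe_load(Path(manifest).read_text())
    spacing = tuple(float(s) for s in manifest["spacing_nm"])
    axis_order = manifest.get("axis_order", "zyx")
    volumes = manifest.get("volumes", {})
    for name in _REQUIRED_VOLUMES:
        if name not in volumes:
            raise KeyError(f"manifest is missing the required volume {name!r}")
    kwargs: dict = {}
    shapes: dict[str, tuple] = {}
    for name, fname in volumes.items():
        if name not in _VOLUME_FIELDS:
            warnings.warn(f"ignoring unknown organelle {name!r} in manifest")
            continue
        vol = read_label_volume(directory / fname, spacing_nm=spacing)
        if axis_order != "zyx":
            perm = ["zyx".index(ax) for ax in axis_order]
            vol = LabeledVolume(np.transpose(vol.data, perm), spacing)
        shapes[name] = vol.shape
        kwargs[_VOLUME_FIELDS[name]] = vol
    distinct = {}
    for name, shp in shapes.items():
        distinct.setdefault(shp, []).append(name)
    if len(distinct) > 1:
        desc = "; ".join(f"{shp}: {', '.join(names)}" for shp, names in distinct.items())
        raise ValueError(f"masks disagree in shape ({desc})")
    cell = CellSegmentation(
        cell_id=str(manifest.get("cell_id", directory.name)),
        condition=str(manifest.get("condition", "")),
        metadata={k: v for k, v in manifest.items() if k not in ("volumes", "skeleton")},
        **kwargs,
    )
    for issue in cell.validate():
        warnings.warn(f"{cell.cell_id}: {issue}")
    skel = None
    if manifest.get("skeleton"):
        skel = read_skeleton(directory / manifest["skeleton"], spacing_nm=spacing)
    return cell, skel


def write_cell(
    cell: CellSegmentation,
    directory: str | Path,
    skeleton_polylines: list[np.ndarray] | None = None,
    fmt: str = "h5",
) -> Path:
    """Write a cell bundle (and optionally its skeleton) in the directory
    layout that :func:`load_cell` consumes.  Returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    volumes: dict[str, str] = {}
    for name, attr in _VOLUME_FIELDS.items():
        vol = getattr(cell, attr)
        if vol is None:
            continue
        fname = f"{name}.{fmt}"
        write_label_volume(vol, directory / fname)
        volumes[name] = fname
    manifest = {
        "cell_id": cell.cell_id,
        "condition": cell.condition,
        "spacing_nm": list(cell.spacing_nm),
        "axis_order": "zyx",
        "volumes": volumes,
    }
    if skeleton_polylines is not None:
        write_skeleton_xml(skeleton_polylines, directory / "microtubules.xml", cell.spacing_nm)
        manifest["skeleton"] = "microtubules.xml"
    out = directory / "cell.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out
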