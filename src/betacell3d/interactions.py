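"""Threshold-based classification of microtubule and granule interactions.

Conventions, stated once and applied everywhere:

* a microtubule is *centrosomal* if one of its ends is strictly closer than
  200 nm to the centriole mask (the pericentriolar material is a shell
  around the structure, so distances are to centriole surface voxels, not to
  a centroid);
* a microtubule is *Golgi-connected* if its closer end is strictly closer
  than 20 nm to a Golgi cisterna;
* a granule is *microtubule-associated* if the minimal distance between its
  voxels and a microtubule is strictly below 20 nm, measured by default
  against the 25-nm-thick rasterized tube mask (the thickness the physical
  filament has; the zero-width skeleton convention is available via
  ``against='skeleton'`` and shifts distances by the 12.5 nm tube radius);
* a granule is *near the plasma membrane* if its distance to the cell-mask
  boundary is at most 500 nm (inclusive).

Densities are normalized to cytoplasmic volume (cell minus nucleus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CellSegmentation, LabeledVolume
from .skeletons import MicrotubuleNetwork, rasterize_microtubules, NM_PER_UM
from . import spatial

__all__ = [
    "AnalysisConfig",
    "InteractionResult",
    "classify_centrosomal",
    "classify_golgi_connected",
    "classify_sg_association",
    "near_pm_fractions",
    "densities",
    "analyze_interactions",
]


@dataclass
class AnalysisConfig:
    """All distance thresholds of the analysis, in nm.

    The defaults are the conventional values for beta-cell volume-EM data:
    200 nm pericentriolar radius, 20 nm structural-connection and
    association cutoffs, 500 nm near-membrane band, 25 nm microtubule
    thickness, 20 nm histogram bins.
    """

    centrosomal_threshold_nm: float = 200.0
    connection_threshold_nm: float = 20.0
    association_threshold_nm: float = 20.0
    near_pm_threshold_nm: float = 500.0
    mt_diameter_nm: float = 25.0
    bin_width_nm: float = 20.0
    sg_mt_against: str = "tube"  # 'tube' (rasterized 25 nm mask) or 'skeleton'

    def __post_init__(self) -> None:
        for name in (
            "centrosomal_threshold_nm", "connection_threshold_nm",
            "association_threshold_nm", "near_pm_threshold_nm",
            "mt_diameter_nm", "bin_width_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sg_mt_against not in ("tube", "skeleton"):
            raise ValueError("sg_mt_against must be 'tube' or 'skeleton'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InteractionResult:
    """Per-object flags and the derived per-cell fractions and densities."""

    per_mt: pd.DataFrame = field(repr=False, default=None)
    per_sg: pd.DataFrame = field(repr=False, default=None)
    centrosomal_pct: float | None = None
    golgi_connected_pct: float | None = None
    associated_pct: float | None = None
    assoc_near_pm_pct: float | None = None
    not_assoc_near_pm_pct: float | None = None
    assoc_sg_density_per_um3: float | None = None
    tubulin_density_um_per_um3: float | None = None
    config: AnalysisConfig | None = None


def classify_centrosomal(
    net: MicrotubuleNetwork,
    centriole_field: spatial.DistanceField,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Flag microtubules with an end strictly within the pericentriolar
    threshold of the centrioles."""
    df = spatial.end_distances(net, centriole_field)
    df = df.rename(columns={
        "end0_nm": "centriole_end0_nm",
        "end1_nm": "centriole_end1_nm",
        "closer_nm": "centriole_closer_nm",
    })
    df["centrosomal"] = df["centriole_closer_nm"] < cfg.centrosomal_threshold_nm
    return df


def classify_golgi_connected(
    net: MicrotubuleNetwork,
    golgi_field: spatial.DistanceField,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Flag microtubules whose closer end is strictly within the structural
    connection threshold of the Golgi."""
    df = spatial.end_distances(net, golgi_field)
    df = df.rename(columns={
        "end0_nm": "golgi_end0_nm",
        "end1_nm": "golgi_end1_nm",
        "closer_nm": "golgi_closer_nm",
    })
    df["golgi_connected"] = df["golgi_closer_nm"] < cfg.connection_threshold_nm
    return df


def classify_sg_association(
    granules: LabeledVolume,
    mt_field: spatial.DistanceField | None,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Flag granules whose minimal voxel distance to a microtubule is
    strictly below the association threshold.

    ``mt_field=None`` (no microtubules) classifies every granule as not
    associated, with a warning.
    """
    labels = granules.labels()
    if mt_field is None:
        warnings.warn("no microtubule mask; all granules classified not associated")
        dist = np.full(labels.size, np.inf)
    else:
        dist = spatial.object_distances(granules, mt_field).to_numpy()
    return pd.DataFrame(
        {
            "label": labels.astype(int),
            "mt_distance_nm": dist,
            "associated": dist < cfg.association_threshold_nm,
        }
    )


def near_pm_fractions(per_sg: pd.DataFrame, cfg: AnalysisConfig) -> tuple[float | None, float | None]:
    """Percent of associated and of not-associated granules within the
    near-membrane band (inclusive threshold).  Requires ``pm_distance_nm``
    and ``associated`` columns; a group with no members yields None."""
    if len(per_sg) == 0:
        raise ValueError("no granules to classify")
    out = []
    for flag in (True, False):
        grp = per_sg[per_sg["associated"] == flag]
        if len(grp) == 0:
            out.append(None)
        else:
            near = grp["pm_distance_nm"] <= cfg.near_pm_threshold_nm
            out.append(100.0 * float(near.sum()) / len(grp))
    return tuple(out)


def densities(
    associated_count: int,
    cumulative_mt_length_um: float,
    cell_volume_um3: float,
    nucleus_volume_um3: float,
) -> tuple[float, float]:
    """(associated granules per µm³ cytoplasm, µm of microtubule polymer per
    µm³ cytoplasm).  Cytoplasm is cell volume minus nucleus volume."""
    cyto = cell_volume_um3 - nucleus_volume_um3
    if cyto <= 0:
        raise ValueError("cytoplasm volume (cell minus nucleus) must be positive")
    return associated_count / cyto, cumulative_mt_length_um / cyto


def associated_sg_density(
    sg_count: int,
    associated_pct: float,
    cell_volume_um3: float,
    nucleus_volume_um3: float,
) -> float:
    """Associated-granule density (µm^-3) from a count and a percentage, the
    form in which per-cell tables report it."""
    n_assoc = sg_count * associated_pct / 100.0
    return densities(n_assoc, 0.0, cell_volume_um3, nucleus_volume_um3)[0]


def analyze_interactions(
    cell: CellSegmentation,
    net: MicrotubuleNetwork | None,
    cfg: AnalysisConfig | None = None,
    fields: dict[str, spatial.DistanceField] | None = None,
) -> InteractionResult:
    """Run every classification for one cell.

    ``fields`` may supply precomputed distance fields under the keys
    ``centrioles``, ``golgi``, ``pm`` and ``mt``; missing ones are computed
    here.  Classifications whose organelle is absent are left as None.
    """
    cfg = cfg or AnalysisConfig()
    fields = dict(fields or {})
    res = InteractionResult(config=cfg)

    per_mt = None
    if net is not None and net.count:
        per_mt = net.to_dataframe()[["mt_id", "length_nm", "tortuosity"]]
        if cell.centrioles is not None:
            if "centrioles" not in fields:
                fields["centrioles"] = spatial.distance_field(cell.centrioles)
            cent = classify_centrosomal(net, fields["centrioles"], cfg)
            per_mt = per_mt.merge(cent, on="mt_id")
            res.centrosomal_pct = 100.0 * float(per_mt["centrosomal"].sum()) / net.count
        if cell.golgi is not None:
            if "golgi" not in fields:
                fields["golgi"] = spatial.distance_field(cell.golgi)
            gol = classify_golgi_connected(net, fields["golgi"], cfg)
            per_mt = per_mt.merge(gol, on="mt_id")
            res.golgi_connected_pct = 100.0 * float(per_mt["golgi_connected"].sum()) / net.count
    res.per_mt = per_mt

    if cell.granules is not None and cell.granules.labels().size:
        mt_field = fields.get("mt")
        if mt_field is None and net is not None and net.count:
            if cfg.sg_mt_against == "tube":
                mask = cell.microtubule_mask
                if mask is None:
                    mask = rasterize_microtubules(net, cell.cell_mask, cfg.mt_diameter_nm)
            else:
                # zero-width skeleton convention: voxels traversed by the polylines
                mask = rasterize_microtubules(
                    net, cell.cell_mask, max(cell.spacing_nm) * 1.0001
                )
            if mask.mask().any():
                mt_field = spatial.distance_field(mask)
        per_sg = classify_sg_association(cell.granules, mt_field, cfg)
        if "pm" not in fields:
            fields["pm"] = spatial.distance_field(spatial.membrane_shell(cell.cell_mask))
        per_sg["pm_distance_nm"] = spatial.object_distances(
            cell.granules, fields["pm"]
        ).to_numpy()
        res.per_sg = per_sg
        n_sg = len(per_sg)
        res.associated_pct = 100.0 * float(per_sg["associated"].sum()) / n_sg
        res.assoc_near_pm_pct, res.not_assoc_near_pm_pct = near_pm_fractions(per_sg, cfg)

    from .morphometry import mask_volume_um3  # local import to avoid a cycle

    cell_vol = mask_volume_um3(cell.cell_mask)
    nuc_vol = mask_volume_um3(cell.nucleus)
    n_assoc = int(res.per_sg["associated"].sum()) if res.per_sg is not None else 0
    cum_um = net.cumulative_length_nm / NM_PER_UM if net is not None and net.count else 0.0
    if cell_vol > nuc_vol:
        sg_dens, tub_dens = densities(n_assoc, cum_um, cell_vol, nuc_vol)
        if res.per_sg is not None:
            res.assoc_sg_density_per_um3 = sg_dens
        if net is not None and net.count:
            res.tubulin_density_um_per_um3 = tub_dens
    return res
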