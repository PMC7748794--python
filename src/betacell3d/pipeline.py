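"""Per-cell orchestration: network metrics, morphometry, distance
distributions with their geometric nulls, interaction classification, and
the combined multi-cell summary table."""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CellSegmentation, SkeletonFile, load_cell
from .interactions import AnalysisConfig, InteractionResult, analyze_interactions
from .morphometry import CellSummary, cell_summary, granule_stats
from .skeletons import (
    MicrotubuleNetwork,
    build_network,
    rasterize_microtubules,
    summarize_network,
)
from . import spatial

__all__ = ["CellResult", "PipelineRun", "analyze_cell", "run_analysis",
           "export_distributions"]

# distribution queries run for every cell, per available target
_END_TARGETS = ("centrioles", "golgi", "nucleus", "pm")
_SG_TARGETS = ("pm", "nucleus", "golgi", "mt")


@dataclass
class CellResult:
    """Everything the analysis produced for one cell."""

    cell_id: str
    summary: CellSummary | None = None
    network_summary: dict | None = None
    granules: pd.DataFrame | None = field(repr=False, default=None)
    interactions: InteractionResult | None = field(repr=False, default=None)
    distributions: dict = field(repr=False, default_factory=dict)
    references: dict = field(repr=False, default_factory=dict)
    error: str | None = None


@dataclass
class PipelineRun:
    """A full multi-cell run: per-cell results plus the combined table."""

    results: list[CellResult]
    config: AnalysisConfig
    combined: pd.DataFrame

    @property
    def failures(self) -> list[CellResult]:
        return [r for r in self.results if r.error is not None]

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.combined.to_csv(outdir / "combined_summary.csv", index=False)
        log = {
            "betacell3d_version": __version__,
            "thresholds": self.config.to_dict(),
            "cells": [r.cell_id for r in self.results],
            "failures": {r.cell_id: r.error for r in self.failures},
        }
        (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
        for r in self.results:
            if r.error is not None:
                continue
            cdir = outdir / r.cell_id
            cdir.mkdir(exist_ok=True)
            if r.granules is not None:
                r.granules.to_csv(cdir / "granules.csv", index=False)
            if r.interactions is not None and r.interactions.per_mt is not None:
                r.interactions.per_mt.to_csv(cdir / "microtubules.csv", index=False)
            if r.interactions is not None and r.interactions.per_sg is not None:
                r.interactions.per_sg.to_csv(cdir / "granule_classification.csv", index=False)
            export_distributions(r, cdir / "distributions", figures=False)
        return outdir / "combined_summary.csv"


def analyze_cell(
    cell: CellSegmentation,
    skel: SkeletonFile | None = None,
    cfg: AnalysisConfig | None = None,
) -> CellResult:
    """Run the full analysis for one cell."""
    cfg = cfg or AnalysisConfig()
    res = CellResult(cell_id=cell.cell_id)

    net: MicrotubuleNetwork | None = None
    if skel is not None and skel.n_nodes:
        net = build_network(skel)

    # --- distance fields -------------------------------------------------
    fields: dict[str, spatial.DistanceField] = {}
    pm_shell = spatial.membrane_shell(cell.cell_mask)
    fields["pm"] = spatial.distance_field(pm_shell)
    fields["pm"].target = "pm"
    fields["nucleus"] = spatial.distance_field(cell.nucleus)
    fields["nucleus"].target = "nucleus"
    for name in ("centrioles", "golgi"):
        vol = getattr(cell, name)
        if vol is not None and vol.mask().any():
            fields[name] = spatial.distance_field(vol)
            fields[name].target = name

    mt_mask = cell.microtubule_mask
    if mt_mask is None and net is not None and net.count:
        mt_mask = rasterize_microtubules(net, cell.cell_mask, cfg.mt_diameter_nm)
    if mt_mask is not None and mt_mask.mask().any():
        fields["mt"] = spatial.distance_field(mt_mask)
        fields["mt"].target = "mt"

    # --- geometric nulls -------------------------------------------------
    target_vols = {
        "pm": pm_shell,
        "nucleus": cell.nucleus,
        "centrioles": cell.centrioles,
        "golgi": cell.golgi,
        "mt": mt_mask,
    }
    for name, f in fields.items():
        res.references[name] = spatial.random_reference(
            target_vols[name], cell.cell_mask, cell.nucleus,
            bin_width_nm=cfg.bin_width_nm, field=f, name=name,
        )

    # --- observed distributions -----------------------------------------
    if net is not None and net.count:
        res.network_summary = summarize_network(net)
        for target in _END_TARGETS:
            if target not in fields:
                continue
            closer = spatial.end_distances(net, fields[target])["closer_nm"].to_numpy()
            res.distributions[f"mt_ends_to_{target}"] = spatial.make_distribution(
                closer, res.references[target], query="mt_ends"
            )
        if "mt" in fields and "pm" in fields:
            pix = fields["pm"].values[mt_mask.mask()]
            res.distributions["mt_pixels_to_pm"] = spatial.make_distribution(
                pix, res.references["pm"], query="mt_pixels"
            )

    inter = analyze_interactions(cell, net, cfg, fields=fields)
    res.interactions = inter

    if cell.granules is not None and cell.granules.labels().size:
        res.granules = granule_stats(cell.granules)
        for target in _SG_TARGETS:
            if target not in fields:
                continue
            vals = spatial.object_distances(cell.granules, fields[target])
            res.distributions[f"sg_to_{target}"] = spatial.make_distribution(
                vals.to_numpy(), res.references[target], query="sg"
            )
            if inter.per_sg is not None and target in ("nucleus", "golgi"):
                inter.per_sg[f"{target}_distance_nm"] = vals.to_numpy()

    res.summary = cell_summary(cell, res.granules, res.network_summary, inter)
    return res


def run_analysis(
    inputs: list,
    cfg: AnalysisConfig | None = None,
) -> PipelineRun:
    """Analyze many cells; per-cell failures are isolated and reported, the
    run continues for the remaining cells.

    ``inputs`` items are either ``(CellSegmentation, SkeletonFile | None)``
    pairs or cell directories understood by :func:`betacell3d.io.load_cell`.
    """
    cfg = cfg or AnalysisConfig()
    results: list[CellResult] = []
    for item in inputs:
        cell_id = None
        try:
            if isinstance(item, (str, Path)):
                cell_id = Path(item).name
                cell, skel = load_cell(item)
            else:
                cell, skel = item
            cell_id = cell.cell_id
            results.append(analyze_cell(cell, skel, cfg))
        except Exception:
            results.append(CellResult(cell_id=str(cell_id), error=traceback.format_exc()))
    rows = [r.summary.to_series() for r in results if r.summary is not None]
    combined = (
        pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
        if rows else pd.DataFrame()
    )
    return PipelineRun(results=results, config=cfg, combined=_round_report(combined))


_ROUND_RULES = {
    "pct": 1,       # fractions: one decimal
    "length_um": 2,  # lengths: two decimals
    "density": 2,   # densities: two decimals
    "tortuosity": 2,
}


def _round_report(df: pd.DataFrame) -> pd.DataFrame:
    """Centralized report rounding: fractions 1 dp, lengths 2 dp,
    densities 2 dp; raw values live in the per-cell exports."""
    if df.empty:
        return df
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind not in "fc":
            continue
        if col.endswith("_pct"):
            out[col] = out[col].round(1)
        elif "density" in col or "tortuosity" in col:
            out[col] = out[col].round(2)
        elif col.endswith("_um") or col.endswith("_um2") or col.endswith("_um3"):
            out[col] = out[col].round(2)
    return out


def export_distributions(
    result: CellResult,
    outdir: str | Path,
    figures: bool = True,
) -> list[Path]:
    """Write one CSV (and optionally one figure) per distribution: observed
    histogram, reference fraction and both cumulative curves on shared bins;
    plus violin summaries of associated vs not-associated granule distances.
    Figures are presentation artifacts only - every number lives in a CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, dist in result.distributions.items():
        ref = dist.reference
        df = pd.DataFrame(
            {
                "bin_left_nm": dist.bin_edges[:-1],
                "bin_right_nm": dist.bin_edges[1:],
                "observed_fraction": dist.fraction,
                "reference_fraction": ref.fraction,
                "observed_ecdf": dist.ecdf,
                "reference_ecdf": ref.ecdf,
            }
        )
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        if figures:
            written.append(_plot_distribution(name, dist, outdir))
    if figures and result.interactions is not None and result.interactions.per_sg is not None:
        written.append(_plot_violins(result.interactions.per_sg, outdir))
    return written


def _plot_distribution(name, dist, outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = dist.reference
    mid = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2000.0  # µm
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(mid, dist.fraction, width=np.diff(dist.bin_edges) / 1000.0,
           color="tab:blue", alpha=0.5, label="observed")
    ax.plot(mid, ref.fraction, "k-", lw=1, label="random reference")
    ax2 = ax.twinx()
    ax2.plot(mid, dist.ecdf, "r:", lw=1.2, label="observed ecdf")
    ax2.plot(mid, ref.ecdf, "k:", lw=1.2, label="reference ecdf")
    ax2.set_ylim(0, 1.02)
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("fraction")
    ax2.set_ylabel("cumulative fraction")
    ax.set_title(name.replace("_", " "))
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, fontsize=7)
    fig.tight_layout()
    path = outdir / f"{name}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_violins(per_sg: pd.DataFrame, outdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = [c for c in ("pm_distance_nm", "nucleus_distance_nm", "golgi_distance_nm")
               if c in per_sg.columns]
    fig, axes = plt.subplots(1, max(1, len(targets)), figsize=(3 * max(1, len(targets)), 3.2))
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, targets):
        groups = [
            per_sg.loc[per_sg["associated"], col].to_numpy() / 1000.0,
            per_sg.loc[~per_sg["associated"], col].to_numpy() / 1000.0,
        ]
        groups = [g for g in groups if len(g)]
        if groups:
            ax.violinplot(groups, showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1))
        ax.set_xticklabels(["assoc.", "not assoc."][: len(groups)], fontsize=8)
        ax.set_ylabel(col.replace("_nm", " (µm)"))
    fig.tight_layout()
    path = outdir / "sg_association_violins.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
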