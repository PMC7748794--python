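# betacell3d

Whole-cell 3D morphometry and microtubule–organelle interaction analysis
for volume-EM segmentations of pancreatic β cells.

Focused ion beam scanning electron microscopy (FIB-SEM) can now image an
entire primary β cell at nanometre, near-isotropic resolution — fine enough
to trace every microtubule (25 nm outer diameter) alongside the nucleus,
centrioles, Golgi cisternae, mitochondria and the several thousand insulin
secretory granules (SGs) the cell stores. Turning those per-cell label
volumes and skeleton tracings into biology requires a reproducible
quantification layer, which this package provides:

* **Microtubule network metrics** — per-filament arc length and tortuosity
  (arc/chord, 1 = straight), per-cell count, mean/cumulative length, and
  rasterization of zero-width tracings back to 25 nm tubes;
* **Organelle morphometrics** — volumes, smoothed iso-surface areas,
  volume-equivalent diameters, sphericity π^⅓(6V)^⅔/A, volume fractions;
* **Distance distributions against geometric nulls** — exact anisotropic
  Euclidean distance fields; for each target X the random reference ρ_X
  (distances of all cytoplasmic voxels to X) against which observed
  granule, microtubule-end (closer-end rule) and microtubule-pixel
  distributions are compared as histograms and cumulative curves, with an
  enrichment scalar ecdf_obs(d) − ecdf_ρ(d);
* **Interaction classification** — centrosomal microtubules (end < 200 nm
  from the centrioles), Golgi-connected microtubules (closer end < 20 nm),
  microtubule-associated granules (granule-to-tube distance < 20 nm),
  near-membrane fractions (≤ 500 nm), associated-SG density and
  polymerized-tubulin density per µm³ cytoplasm (cell minus nucleus);
* **A ground-truthed synthetic β-cell generator** — every pipeline stage is
  exercised end-to-end, with exact bookkeeping, on cells it builds itself;
  no microscope data needed.

Input formats: multi-page TIFF or HDF5 label volumes (binary or instance
labels), annotation-tool XML or SWC skeletons, one YAML manifest per cell.
Outputs: CSV tables (per-granule, per-microtubule, per-distribution,
per-cell summary), PNG figures, and a YAML run log recording the thresholds
used.

## Worked example

Generate a small synthetic cell (4.8 µm across, 60 microtubules, 300
granules) and run the complete analysis:

```python
from betacell3d import AnalysisConfig, analyze_cell
from betacell3d.synthetic import (
    SyntheticCellConfig, CentrioleParams, GranuleParams, MicrotubuleParams,
    MitochondriaParams, GolgiParams, generate_cell,
)

cfg = SyntheticCellConfig(
    shape=(96, 96, 96), spacing_nm=(50, 50, 50),
    cell_semiaxes_um=(2.0, 2.1, 2.2),
    nucleus_semiaxes_um=(0.95, 0.95, 0.9), nucleus_offset_um=(0, 0.5, 0.45),
    centrioles=CentrioleParams(offset_um=(0, -0.9, -1.3), length_nm=400, radius_nm=100),
    golgi=GolgiParams(standoff_um=0.25, radial_gap_um=0.25, thickness_nm=140),
    mitochondria=MitochondriaParams(count=8, radius_nm=180, length_um_range=(0.8, 1.5)),
    granules=GranuleParams(count=300, diameter_median_nm=300, diameter_sigma=0.08,
                           associated_fraction=0.30),
    microtubules=MicrotubuleParams(count=60, length_mean_um=2.5, length_sigma=0.2,
                                   length_range_um=(1.2, 3.6),
                                   fraction_centriole_anchored=0.05,
                                   fraction_golgi_anchored=0.10, step_nm=80),
    seed=1,
)
seg, skel, truth = generate_cell(cfg)
result = analyze_cell(seg, skel, AnalysisConfig())
print(result.summary.to_series().to_string())
```

prints

```text
cell_id                       synthetic
condition                     synthetic
cell_volume_um3                  38.716
nucleus_volume_um3                3.395
nucleus_volume_pct             8.768984
mitochondria_volume_um3          1.0285
mitochondria_volume_pct        2.656524
golgi_volume_um3               0.306625
golgi_volume_pct               0.791985
sg_count                            300
sg_total_volume_um3             4.36875
sg_total_volume_pct           11.284094
sg_mean_volume_um3             0.014563
sg_mean_surface_um2            0.273771
sg_mean_diameter_um            0.301046
sg_associated_pct                  30.0
assoc_sg_near_pm_pct          85.555556
not_assoc_sg_near_pm_pct           80.0
mt_count                             60
mt_mean_length_um                   2.5
mt_cumulative_length_um             150
mt_mean_tortuosity                 1.05
mt_centriole_connected_pct          5.0
mt_golgi_connected_pct             10.0
assoc_sg_density_per_um3       2.548059
tubulin_density_um_per_um3     4.247181
```

Reading it: the pipeline measured back exactly the study conditions the
generator was configured with — 60 microtubules of mean length 2.50 µm and
mean tortuosity 1.05, 5% of them centriole-connected and 10%
Golgi-connected, 300 granules of which 30.0% are microtubule-associated —
and derived the composite quantities from them (2.55 associated granules
and 4.25 µm of microtubule polymer per µm³ of cytoplasm).
`result.distributions` holds every observed-vs-ρ distance distribution
(`sg_to_pm`, `mt_ends_to_golgi`, `mt_pixels_to_pm`, …), and
`truth.per_mt` / `truth.per_sg` the generator's ground truth.

The same workflow from the shell:

```sh
betacell3d simulate --config cell.yaml --seed 1 --out cells/c1
betacell3d analyze --cell cells/c1 --out runs/r1
betacell3d report --runs runs --out combined.csv
```

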