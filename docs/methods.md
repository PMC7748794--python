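# Methods

`betacell3d` quantifies whole-cell 3D segmentations of pancreatic β cells:
organelle label volumes (plasma membrane / cell outline, nucleus, centrioles,
Golgi cisternae, mitochondria, insulin secretory granules) plus manually
traced microtubule skeletons. This note records the models, conventions and
numerical choices behind each stage, what the synthetic data generator does
and does not emulate, and the known limitations.

## Coordinate and sampling conventions

Arrays are indexed `(z, y, x)`. A voxel with index `i` along an axis with
spacing `s` nm sits at physical position `i·s` (voxel-center convention);
the voxel containing a physical point `p` is `round(p / s)`. All internal
arithmetic is in nanometres, so volumes with different voxel sizes (e.g.
skeletons traced at finer resolution than the binned masks) compose without
unit juggling. Point-in-field lookups use the containing voxel with no
interpolation: sub-voxel interpolation would add complexity below the
resolution of the masks. The documented sampling tolerance of any
point-sampled distance is therefore half a voxel diagonal.

## Microtubule metrics

A traced skeleton is a node/edge annotation file (annotation-tool XML
dialect with a `<scale>` element, or SWC). Each connected component must be
a simple open path — node degrees ≤ 2, no cycles, at least two nodes —
otherwise the component is rejected with the offending node named; closed
loops are not biologically expected and are treated as tracing errors.
Points are ordered by walking from one degree-1 node to the other (the
lower node id starts, a deterministic tie-break).

* **Length** is the polyline arc length Σ‖pᵢ₊₁ − pᵢ‖₂.
* **Tortuosity** is arc length over end-to-end chord length, the standard
  tortuosity index: exactly 1 for a straight filament. The index is
  undefined for closed paths (chord 0), which raise.
* **Rasterization** restores the physical 25 nm outer diameter of the
  filament: a voxel belongs to the tube mask iff its center lies within
  diameter/2 of any polyline segment (no anti-aliasing — downstream
  consumers are binary-mask analyses). With 25 nm tubes on coarser grids
  the mask is a sparse trace of the filament rather than a connected line;
  every analysis that consumes it (association distances, microtubule-pixel
  distributions) is defined on voxels, so sparseness only reduces sample
  density, not correctness.

Network summaries report count, mean and cumulative length (µm, 2 decimals
and nearest integer respectively) and mean tortuosity (2 decimals); raw nm
values are kept alongside in all exports.

## Morphometry

Volumes are voxel counts times the physical voxel volume. Surface areas
come from a marching-cubes iso-surface of the binary mask (0.5 level,
physical spacing, object padded so the surface closes) followed by Taubin
mesh smoothing (λ = 0.5, ν = −0.53). Voxel-face counting would overestimate
a sphere's area by ~50%; a raw marching-cubes mesh still overestimates by
~9% and does not converge with finer voxels. The number of smoothing passes
scales with the object's equivalent radius in voxels (`r_vox/3`, at least
one pass), keeping the total smoothing length a fixed fraction of the
object size: large objects converge (a digitized 500 nm sphere is recovered
to 0.8/0.4/0.2% in area at 32/16/8 nm spacing, errors falling
monotonically) while granule-sized objects (~4 voxel radius at 50 nm) are
not shrunk away (≈1% area error; ≈5% for the very smallest, ~3-voxel
objects). Sphericity π^{1/3}(6V)^{2/3}/A can exceed 1 by a few percent for
very small objects for the same discretization reason; values are reported
unclipped.

Equivalent diameter is the volume-equivalent sphere diameter
(6V/π)^{1/3}. Note that caliper- or star-convex-style diameters of the
same granules read systematically larger (≈0.41 µm vs 0.37 µm at typical
granule volumes); per-granule tables therefore carry volume, surface and
equivalent diameter so either convention can be reconstructed. Objects
touching the canvas boundary are flagged `truncated`, not dropped.

Cytoplasmic volume — the normalizer for all densities — is cell volume
minus nucleus volume.

## Distance fields and geometric nulls

Distance fields are exact anisotropic Euclidean distance transforms
(per-axis spacing in nm) from the target mask; distances are voxel-center
to voxel-center and an object's distance to a target is the minimum of the
field over the object's voxels (surface-to-surface semantics at voxel
resolution, 0 on overlap). The plasma membrane is represented by the
background-adjacent shell of the cell mask, since the membrane was
segmented as the cell outline.

For each target X the *random reference* ρ_X is the distribution of the
field over every voxel of (cell ∧ ¬nucleus ∧ ¬X). The nucleus is excluded
because query objects cannot occupy it; other organelles are deliberately
not excluded, so ρ_X describes uniformly scattered points in the same
geometry. Observed distributions (one value per granule; the closer of the
two ends per microtubule; every tube-mask voxel for microtubule pixels,
voxel-weighted) are binned on the reference's grid — 20 nm bins by default,
200 nm available — and compared by cumulative curves. The *enrichment
scalar* at distance d is ecdf_observed(d) − ecdf_reference(d); positive
values mean the queries sit closer to the target than geometry alone would
put them.

## Interaction classification

Thresholds (all configurable, surfaced in every run log):

| rule | threshold | comparator |
| --- | --- | --- |
| centrosomal microtubule | end within 200 nm of centriole mask | strict `<` |
| Golgi-connected microtubule | closer end within 20 nm of cisternae | strict `<` |
| granule–microtubule association | min granule-voxel distance to 25 nm tube mask, 20 nm | strict `<` |
| granule near membrane | ≤ 500 nm from cell outline | inclusive `≤` |

Pericentriolar distance is measured from centriole mask voxels (a shell
around the structure), not from a centroid. Association is computed against
the rasterized 25 nm tube by default; `sg_mt_against: skeleton` switches to
the zero-width polyline trace (distances shift by the 12.5 nm tube radius).
Derived quantities: associated-granule density (associated count per µm³
cytoplasm) and polymerized tubulin density (µm of filament per µm³
cytoplasm).

## The synthetic cell generator

The generator emits a full `CellSegmentation`, a skeleton file and exact
generation-time bookkeeping, so every pipeline stage is testable without
microscope data. The reference regime (the defaults) is a 12.8 µm canvas at
50 nm voxels holding an ellipsoidal cell of ~840 µm³ with ~13% nucleus, a
centriole pair, three perforated spherical-cap Golgi cisternae hugging the
nucleus, 40 tubular mitochondria, 400 microtubules (mean length 8.5 µm,
mean tortuosity 1.05, 3% centriole-anchored, 5% Golgi-anchored,
membrane-enriched) and 5,000 granules (lognormal diameters, median 380 nm,
30% microtubule-associated, membrane-enriched). These figures sit inside
the ranges observed for primary mouse β cells; the canvas edge was chosen
so that a cell large enough for 8.5 µm filaments at tortuosity 1.05 fits —
an arc of length L with tortuosity τ needs a chord of L/τ, so the cell
diameter bounds the realizable length/tortuosity combinations, and a
~12 µm cell accommodates the configured distribution while one under 9 µm
cannot.

Key mechanisms:

* **Constructive microtubules.** Per filament a target length L (stratified
  quantiles of a truncated lognormal, recalibrated so the truncated mean
  equals the configured mean) and tortuosity τ (truncated normal, same
  treatment) are drawn; the chord L/τ is placed inside the cytoplasm by
  rejection and the filament laid down as the circular arc of length L over
  it. Length and tortuosity are thus exact per filament. A confined
  persistent random walk was considered and rejected: reflection at the
  membrane couples realized length and curvature, so a walk cannot hit a
  target mean length and mean tortuosity simultaneously.
* **Membrane-parallel enrichment.** With the microtubule membrane weight
  on, filament start points are drawn with weight e^(−d_PM/λ), the far
  chord end is chosen as the candidate closest to the membrane, and
  outward-bulging arcs are tried first — filaments then run as
  near-membrane secants sagging back toward the membrane, reproducing the
  membrane enrichment of both microtubule ends and microtubule pixels seen
  in β cells.
* **Exact anchoring.** Anchored filaments start at voxels sampled strictly
  inside the classification threshold (centriole-anchored: field < 140 nm;
  Golgi-anchored: on a cisterna voxel, field 0); all other ends keep a
  sampled clearance beyond the thresholds (≥ 280 nm / ≥ 60 nm). Because the
  generator validates candidates through the same voxel-sampled fields the
  classifier uses, the classifier recovers the anchored counts exactly.
* **Granules.** Diameters are stratified lognormal quantiles. Associated
  granules are centered so their digitized sphere contains a tube-mask
  voxel (measured distance 0); candidate non-associated granules are
  rejected if their digitized sphere would measure < 20 nm to the tube —
  the same computation the classifier performs, so the association fraction
  is recovered exactly without an artificial avoidance halo. Spheres never
  overlap each other (uniform-grid neighbor lookup, 30 nm minimum gap), the
  nucleus, mitochondria, Golgi, centrioles or the cell exterior; placement
  is big-to-small within each group because late small spheres fit
  remaining gaps far more easily than the reverse. Membrane enrichment uses
  weight e^(−d_PM/λ) with a steeper weight (λ = 0.5 µm vs 5 µm) for
  associated granules, which reproduces the observed ordering that
  associated granules are at least as membrane-concentrated as
  non-associated ones. λ = 0 gives uniform placement for null-model tests.
* **Determinism.** Every stochastic step draws from a named substream of
  the master seed (seed, hash of stream name), so adding one organelle
  class does not perturb another's placement, and identical seeds give
  bit-identical volumes and skeletons.

What the generator does **not** emulate: image intensities or segmentation
noise (masks are clean by construction), granule polydispersity beyond a
lognormal, Golgi vesicles and cisternal substructure, microtubule
bundling/branching, mitochondrial networks (tubes are independent), or any
dynamics. Passing recovery tests therefore demonstrates that the *analysis*
is correct on geometry with known ground truth — not that segmentation
errors on real data are harmless.

## Problem sizes and numerical choices

The bundled test and acceptance runs use a 96³ canvas (4.8 µm cell,
300 granules, 60 microtubules) for unit-level checks and the 256³
reference regime above for the end-to-end recovery and the acceptance
script; both complete in minutes on one CPU. Distance-transform
correctness is pinned by exhaustive KD-tree oracles on random masks up to
32³; the null-model machinery by the closed-form r² shell law for a point
target in a digitized ball (L1 histogram error ≈ 1% at 16 nm spacing) and
by uniform-query self-consistency (max ecdf gap ≈ 0.01 at 10⁴ queries).
Rejection-sampling budgets (8,000 attempts per granule, 400 per filament
with length swapping between unbuilt filaments) raise `PackingError` with
actionable advice when a configuration is infeasible rather than looping
forever.

## Limitations

* Distances are straight-line Euclidean; no geodesic (obstacle-avoiding)
  variants, matching the convention of the underlying measurements.
* Surface areas of ~3-voxel objects carry up to ~5% bias; relative
  comparisons between granules are unaffected.
* The 20 nm association threshold is below one voxel at 50 nm spacing, so
  in practice association at that resolution means voxel overlap with the
  tube mask; at 16 nm masks the threshold is resolved.
* Per-microtubule end identity (plus/minus) and polarity are out of scope;
  ends are interchangeable and the closer-end rule is symmetric.
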