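# mitoloc

Quantitative analysis of mitochondrial membrane potential and 3D network
morphology in budding yeast from dual-channel fluorescence z-stacks.

Yeast cells carrying a dual-reporter construct express two fluorescent
markers that are both targeted to mitochondria, but imported differently: a
green marker (preSU9-GFP) enters mitochondria regardless of the membrane
potential (MMP) and marks the network's structure, while a red marker
(preCOX4-mCherry) is imported in proportion to the MMP and delocalises to
the cytosol when the potential collapses. Two measurements follow:

* **Membrane potential (coloc workflow).** Per cell, the Pearson correlation
  coefficient (PCC) between the green and red channels over the voxels of a
  cell mask (Otsu threshold of the σ = 5 px Gaussian-blurred channel sum).
  High PCC ⇒ both markers co-localise ⇒ intact MMP; the PCC falls as the red
  marker spreads through the cytosol. The coefficient of determination R²
  of the least-squares fit red ~ green is reported alongside (R² = PCC² for
  a single predictor).

* **Network morphology (morph workflow).** The green channel is Otsu-
  thresholded and split into 26-connected objects; objects below 0.1 μm³ are
  discarded as artefacts. Each object's surface area is estimated by
  classifying its surface voxels (≥ 1 exposed face) into 15 local
  exposed-face configuration classes, each weighted to correct the staircase
  bias of raw face counting (weights calibrated against analytic sphere
  areas, including anisotropic z-spacing). Five shape descriptors are
  computed per object *k* with voxels *p(k)*, centroid *c*, volume *V* and
  surface area *A*:

  - compactness = Var[d(k)] / V, with d(k) the voxel–centroid distance;
  - distribution isotropy = Σ over axis pairs of max/min second-moment
    ratios of axial radial distances (minimum 3, attained for rotationally
    symmetric objects);
  - isoperimetric quotient IPQ = V / ((4/3)π (A/4π)^{3/2});
  - sphericity = π^{1/3} (6V)^{2/3} / A;
  - radius variance = Var[r(j)] over surface voxels j (0 for a sphere).

  Per cell, each object's relative volume Vs = V_object / V_total × 100 and
  the **fragmentation index f = Σ { Vs : Vs ≤ 20 }** — the share of the
  network held in small fragments. Per-cell descriptor means are weighted
  by object surface area; populations are summarised as mean f ± SEM over
  cells and a Vs histogram with bins of 10.

A seeded synthetic scene generator renders ground-truthed dual-channel
stacks (tubular or spherical mitochondria in an ellipsoidal cell, a
controllable delocalised fraction φ of the red marker, Gaussian PSF,
Poisson + Gaussian noise, anisotropic voxel spacing), so the whole pipeline
is testable without microscopy data.

## Worked example

```python
import numpy as np
from mitoloc import analyze_cell, batch_coloc
from mitoloc.scenes import build_cell_scene, plan_vs_partition, rasterise, full_roi

# one cell with tubular fragments, 45% of the mitochondrial volume in small
# pieces, and 60% of the potential-dependent marker delocalised
rng = np.random.default_rng(7)
spec = build_cell_scene(plan_vs_partition(45, rng), "tubular",
                        rng_seed=7, red_delocalised_fraction=0.6)
stack, truth = rasterise(spec)

morph = analyze_cell(stack, cell_label="rho0_like")
print(f"objects: {len(morph.objects)}  total volume: {morph.total_volume:.2f} um^3")
print("Vs (%):", [round(o.vs, 1) for o in morph.objects])
print(f"fragmentation index f = {morph.f:.1f}")
print(f"weighted compactness  = {morph.weighted_features['compactness']:.3f} um^-1")

res = batch_coloc(stack, [full_roi(stack, "rho0_like")])[0]
print(f"PCC = {res.pcc:.3f}  R^2 = {res.r2:.3f}  over {res.n_voxels} voxels")
```

prints

```
objects: 6  total volume: 2.21 um^3
Vs (%): [10.3, 9.0, 55.1, 9.0, 8.0, 8.5]
fragmentation index f = 44.9
weighted compactness  = 0.217 um^-1
PCC = 0.976  R^2 = 0.953  over 4180 voxels
```

The cell holds one main network piece (Vs = 55.1%) plus five fragments each
below the 20% threshold, so f recovers the designed 45% within measurement
error. Rendering the same geometry with φ = 0 gives PCC = 0.993, with φ = 1
(full delocalisation, collapsed MMP) PCC = 0.017.

## Command line

```sh
mitoloc simulate scene_spec.json --out scene/        # render a synthetic scene
mitoloc morph scene/scene.tif --rois scene/rois.csv --out morph/
mitoloc coloc scene/scene.tif --rois scene/rois.csv --out coloc/
mitoloc report morph/                                # population summary
```

Inputs are TIFF z-stacks (one or two channels; 32-bit data are rescaled to
the 16-bit range) with per-cell rectangular ROIs in a CSV/JSON sidecar;
outputs are per-object and per-cell CSV tables plus JSON summaries, with the
resolved configuration written alongside for provenance.

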