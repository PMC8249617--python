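# clearvasc

Quantification of compound extravasation and blood-vessel architecture in
3D microscopy volumes of optically cleared tissue, plus a 2D
transcardial-perfusion-degree quantifier. Animal imaging data are replaced
throughout by seeded synthetic phantoms with exact ground truth, so every
pipeline stage is testable offline.

## What it does

* **phantoms** — seeded generators for calibrated 3D vessel volumes (solid
  thin tubes + hollow wall-labeled large tubes), tracer volumes with focal
  extravasation spots and bright Z-elongated artifacts, 2D two-channel
  perfusion slides with a 4-class ground-truth map, and tissue-shrinkage
  sample draws. Same spec + seed ⇒ bit-identical output.
* **imstore** — calibrated `VoxelGrid` / `LabelMask` containers; TIFF I/O
  with µm spacing in the resolution tags; CSV tables; GraphML (lossless
  round-trip) and SWC-like graph export. Axis order is `(z, y, x)`,
  physical coordinate = index × spacing, all quantities in µm/µm²/µm³.
* **pixelclass** — trainable pixel classifier: a fixed, documented
  multiscale 2D filter bank (Gaussian, gradient magnitude, Laplacian,
  Hessian and structure-tensor eigenvalues, optional DoG) feeding a random
  forest fitted on sparse scribble annotations. Optional Gaussian
  probability smoothing before the argmax; 3D stacks classified slice-wise.
* **extravasation** — Richardson–Lucy deconvolution with a parametric
  anisotropic Gaussian PSF; spot-mask postprocessing (four per-slice 3×3
  dilations, mask scaled to {0,255}, 3D Gaussian σ=3, threshold 50–255);
  26-connected spot morphometry (volume, anisotropy-aware surface area,
  centroid, bounding box, mean intensity); exclusion of spots < 10,000 µm³;
  albumin mode: threshold 60–255 minus the vessel mask → extravascular
  volume.
* **vasculature** — vessel-mask postprocessing (σ=0.9 smoothing, threshold
  170–255 tumor / 105–255 normal brain, median radius 3/1); adjustable
  slice-wise lumen filling of hollow vessels within a physical area range,
  swept over the XY/YZ/XZ orientations in two iterations (plus an
  independent brute-force oracle used in tests); isotropic resampling and
  distance-ordered homotopic thinning to a centerline skeleton; spatial
  graph with per-point EDT radii; pruning of segments < 10 µm; per-segment
  length, chord, tortuosity (arc/chord) and mean diameter; the exponential
  diameter correction `CF(MD) = (Y0 − Plateau)·exp(−K·MD) + Plateau`
  (defaults Y0=3.7, Plateau=1.3, K=0.5861) and its least-squares fitting.
* **perfusion** — per-section class areas and percentages of total vascular
  area, tumor-level vascular-area-weighted averages, per-class mean
  intensities, `asin(√p)` transform, and the OCS/CPS volume-change
  correction `CF = med(OCS) − med(CPS)` with volume rescaling.
* **cli** — one `clearvasc` entry point wiring YAML configs and flags to
  the pipelines (flags override config; a resolved-config copy is written
  next to the outputs; exit codes 0/1/2 = ok/user error/internal error).

## CLI

```sh
# generate a phantom dataset (TIFF channels + truth JSON)
clearvasc simulate --config examples.yaml --kind vessels --out sim/

# train the pixel classifier on sparse scribble TIFFs, then segment
clearvasc train --image img.tif --labels scribbles.tif --out model.joblib
clearvasc segment --model model.joblib --image img.tif --out mask.tif

# extravasation spots from a segmented binary mask
clearvasc spots --mask seg.tif --intensity dextran.tif --out spots/ \
    --dilations 4 --post-sigma 3 --threshold 50:255 --min-volume 10000

# vessel tracing and morphometry
clearvasc vessels --mask vessel_seg.tif --out vessels/ \
    --sigma 0.9 --threshold 170:255 --median-radius 3 \
    --fill-orientations XY,YZ,XZ --fill-iterations 2 \
    --min-seg-length 10 --correct-diameters 3.7,1.3,0.5861

# 2D perfusion-degree quantification and the shrinkage correction
clearvasc perfusion --class-mask s1.tif --class-mask s2.tif --out perf/
clearvasc shrink --ocs -71,-70,-72 --cps -12,-11,-13 --volume 29
```

A YAML config may carry any of the documented pipeline-config keys (e.g.
`post_sigma`, `threshold`, `min_volume`, `fill_area_range`,
`fill_orientations`, `fill_iterations`, `min_segment_length`); unknown keys
are rejected.

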