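# actinet

Automatic extraction and quantification of actin filament networks from
fluorescence micrographs.

The actin cytoskeleton of plant (and other) cells is a dense, dynamic web
of filaments and bundles.  Comparing its architecture across genotypes,
tissues or treatments requires turning micrographs into numbers — by
hand an error-prone, subjective and slow task.  `actinet` does it
automatically: given a single-channel image (or confocal z-stack) of
labelled actin and a region-of-interest mask, it

1. **extracts** a one-pixel-wide network skeleton
   (top-hat background subtraction → multi-scale Hessian vesselness
   enhancement → percentile threshold → small-object removal →
   topology-preserving thinning, run through a dual rotate-before/after
   workflow that aligns the cell's long axis with the horizontal);
2. **labels** individual filaments across branch points, re-joining the
   straightest continuations at every junction;
3. **measures** seventeen quantities per cell/filament: ROI size, cell
   orientation θ, skeleton density, structure sizes, branch ratio,
   branch-point density, filament widths, 2D/3D lengths, in-plane angles
   θ_f ∈ (−π/2, π/2] and z angles θ_z, mean filament length, signed and
   unsigned Menger curvature |⟨κ⟩| and ⟨|κ|⟩ sampled over λ = 475 nm,
   deviation from the endpoint chord, and 2D/3D branch angles θ_b.

A synthetic-scene generator (spline filaments rendered at 19×
supersampling, Gaussian-PSF blur, exact block-mean downscaling,
PSF-blurred salt-and-pepper noise) provides images whose centreline
ground truth is known perfectly, and a validation harness scores
extraction with pixel-tolerant sensitivity TPR = TP/(TP+FN) and
precision PPV = TP/(TP+FP) across sweeps of SNR, network density,
threshold and numerical aperture.

See `docs/methods.md` for the full description of the algorithms,
parameters and their defaults.

## Worked example

Generate a noisy synthetic scene, extract its network and measure it:

```bash
actinet simulate --seed 7 --n 1 --noise-max 2.0 --out scenes
# (an all-true ROI mask; for real data, draw the cell outline instead)
python -c "import numpy as np, tifffile; \
  tifffile.imwrite('scenes/roi.tif', np.full((200,200),255,np.uint8))"
actinet extract scenes/scene_0000.tif scenes/roi.tif --out out
actinet measure scenes/scene_0000.tif scenes/roi.tif --out out
```

The extract step prints

```
scene_0000.tif: 1241 skeleton px, 38 filaments, 47 branch points
```

— at this noise level (realised SNR ≈ 5.8, recorded in the scene's
manifest) the ten generated filaments cross and fragment into 38
labelled filaments joined at 47 branch points.  `out/scene_0000.json`
holds the seventeen measures; a few of them:

```
cellSize      40000          # ROI pixels (the full 200x200 frame)
skelDensity   0.031          # skeleton covers ~3.1% of the ROI
branchRatio   1.24           # branch points per labelled filament
avgLen        3248.           # mean 3D filament length, nm
filLenXY[:3]  [95.0, 6221.1, 7217.2]       # per-filament 2D lengths, nm
curvature[:3] [2.60e-4, 2.96e-4, 4.19e-4]  # unsigned curvature, 1/nm
```

so the longest filaments span ~6–7 µm and bend with radii of a few
micrometres (1/κ).  Companion CSVs (`*_cell.csv`, `*_filaments.csv`)
hold the same values in tabular form; every output carries a JSON
sidecar with the package version, configuration hash and parameters.

For real data: `actinet measure cell.tif cell_roi.tif --config my.yaml`
(the YAML can override pixel size, z spacing and every extraction
parameter), or `actinet batch images/ --roi-suffix _roi.tif` for a
directory.  `actinet validate sweep.yaml --seed 1` runs a robustness
sweep from a small spec file and writes tidy and summary CSVs plus a
sensitivity/precision plot.

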