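# fibrequant

Quantification of the 3D hierarchical fibrous architecture of soft tissue
from microtomographic volumes: per-voxel structure-tensor orientation
fields, orientation distribution functions and second-order orientation
tensors, fibre waviness (period and amplitude in the orientation-tensor
eigenframe), fibre cross-section morphometry, local thickness maps of
segmented layers, and bead-marker tissue elongation — together with a
synthetic phantom generator that provides exact ground truth for every
stage.

## Package layout

| module | contents |
|---|---|
| `fibrequant.phantoms` | wavy-fibre / cylinder / slab / bead phantoms with ground truth, imaging-noise model |
| `fibrequant.volio` | TIFF / raw+sidecar volume I/O, thresholding, morphological cleaning, Euclidean distance maps, ROI cropping |
| `fibrequant.orientation` | grey-level gradients, Gaussian-window structure tensors, orientation fields, (θ, φ) angles, ODF + peaks, 3D/2D orientation tensors |
| `fibrequant.waviness` | orientation-tensor eigenframe, transverse fibre profiles, extrema and sine-fit waviness estimators |
| `fibrequant.morphometry` | perpendicular resampling, sub-pixel section measures (P, A, d_e, ξ, x_G), track linking, misalignment filter, density statistics, single-fibre profiles |
| `fibrequant.macrostructure` | inscribed-sphere local thickness, bead detection, elongation λ = l/l₀ |
| `fibrequant.pipeline` / `fibrequant.cli` | declarative YAML runs, stage chaining, deterministic JSON reports, `fibrequant` CLI |

## CLI

```bash
# generate a phantom (spec.yaml holds FibrePhantomSpec fields)
fibrequant simulate --spec spec.yaml --seed 7 --out phantom/

# stage-by-stage
fibrequant segment --input phantom/volume.tif --out mask.tif
fibrequant orient --input phantom/volume.tif --mask mask.tif \
    --out orient/ --window 17 --min-coherence 0.2
fibrequant thickness --mask mask.tif --out thick/
fibrequant elongate --reference ref.tif --deformed def.tif --out elong/

# or one declarative run (byte-identical report under a fixed seed)
fibrequant run --config run.yaml
```

A run config looks like:

```yaml
stages: [simulate, segment, orient]
seed: 7
output_dir: out
simulate:
  shape: [96, 96, 96]
  voxel_size: 1.0
  mean_direction: [0, 1, 0]
  kappa: 4.0
  radius_mean: 3.0
  n_fibres: 250
  period: 60.0
  noise: {blur_sigma: 1.0}
orient:
  window: 9        # common presets: 21 / 17 / 21 voxels, 7 px (2D)
  min_coherence: 0.2
  min_depth: 1.0
```

## Conventions

- Grids are `(x, y, z)`-ordered; `e_x` mediolateral, `e_y` anteroposterior,
  `e_z` inferosuperior; isotropic voxels; physical coordinates in µm with
  the voxel centre at `index × voxel_size`.
- Fibre vectors are axial: they are canonicalised to `p_y ≥ 0` (ties:
  `p_x ≥ 0`, then `p_z ≥ 0`) so that θ ∈ [0°, 180°] (angle to `e_z`) and
  φ ∈ [0°, 180°) (in-plane angle to `e_x`) are unique.
- Structure-tensor windows use σ = w/6, truncated at the window edge.
- Local thickness uses the inscribed-sphere definition with voxel-centre
  distances; the grid border counts as background.
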