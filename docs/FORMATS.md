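# File formats

## Images and volumes (NIfTI)

Activity images, attenuation maps, CT volumes and reconstructions are
float32 NIfTI (`.nii` / `.nii.gz`). In-memory arrays are `(ny, nx)` per
slice or `(nz, ny, nx)` per volume; on disk the axial dimension is the
third NIfTI axis. Pixel size (cm) and slice thickness are carried in the
header zooms and survive round trips exactly.

## Sinograms

A sinogram file is either

* a NIfTI of shape `(n_angles, n_bins[, n_slices])`, or
* a raw little-endian float32 binary of the same data flattened,

and is always accompanied by a JSON sidecar `<name>.json`:

```json
{
  "format": "nifti" | "raw-float32",
  "shape": [60, 64],
  "angles_deg": [0.0, 6.0, ...],
  "n_bins": 64,
  "bin_width_cm": 0.625,
  "flattening": "angle-major, bin-fastest"
}
```

Reading a sinogram without its sidecar is an error that names the missing
file. Flat detection-bin index: `i = angle_index * n_bins + bin_index`
(slice-major for volumes).

## Sparse matrix caches

System matrices and scatter kernels can be cached as text triplet files:

```
# {"shape": [3840, 4096], "nnz": 123456, "kind": "system", ...}
0 17 0.625
...
```

one `i j value` triple per line after a single `#` JSON header line, which
records the shape plus free-form provenance fields (energy, window,
slab mode, scale, grid factor for scatter kernels).

## Experiment configuration

YAML or JSON mapping with the fields of `ExperimentConfig` (phantom, grid,
angles, counts, seed, iterations, methods, window, scatter settings).
Missing keys take defaults; unknown keys fail fast. `spectrecon
run-experiment` writes the fully resolved configuration beside its outputs
as `config.resolved.yaml`, a `metrics.csv` table, a `manifest.json`
recording all parameters and the seed, and a `profiles.png` overlay.
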