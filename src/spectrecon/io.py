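"""Shared file I/O: NIfTI volumes, sinogram sidecar dialect, sparse caches.

Disk formats (see FORMATS.md at the repository root):

* images / mu-maps: NIfTI, float32, pixel size carried in the header zooms;
* sinograms: NIfTI of shape (n_angles, n_bins[, n_slices]) or raw float32
  binary, either way accompanied by a ``<name>.json`` sidecar recording the
  angles, bin width and flattening order (angle-major, bin-fastest);
* system/scatter matrices: text triplet files ``i j value`` with a ``#``
  header line recording the shape and provenance fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.sparse as sp

from .geometry import AcquisitionGeometry, GridSpec, Sinogram

__all__ = [
    "read_volume",
    "write_volume",
    "read_sinogram",
    "write_sinogram",
    "save_sparse_triplets",
    "load_sparse_triplets",
]


def write_volume(values: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write an image or volume as float32 NIfTI with grid spacing in the header."""
    arr = np.asarray(values, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, 0, -1)  # (nz, ny, nx) -> (ny, nx, nz)
    affine = np.diag([grid.pixel_size, grid.pixel_size, grid.slice_thickness, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((grid.pixel_size, grid.pixel_size, grid.slice_thickness))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI volume; returns (values, grid) with (nz, ny, nx) ordering."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr2 = arr[..., 0]
        grid = GridSpec(arr2.shape[1], arr2.shape[0], 1, float(zooms[0]),
                        float(zooms[2]) if len(zooms) > 2 else float(zooms[0]))
        return arr2, grid
    if arr.ndim == 3:
        vol = np.moveaxis(arr, -1, 0)
        grid = GridSpec(vol.shape[2], vol.shape[1], vol.shape[0], float(zooms[0]),
                        float(zooms[2]))
        return vol, grid
    if arr.ndim == 2:
        return arr, GridSpec(arr.shape[1], arr.shape[0], 1, float(zooms[0]), float(zooms[0]))
    raise ValueError(f"malformed volume {path}: ndim={arr.ndim}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")


def write_sinogram(sino: Sinogram, path: str | Path, raw: bool = False) -> None:
    """Write a sinogram plus its JSON sidecar.

    ``raw=True`` writes flat float32 binary instead of NIfTI; either way the
    sidecar records the geometry and the flattening order.
    """
    path = Path(path)
    counts = np.asarray(sino.counts, dtype=np.float32)
    if raw:
        counts.ravel().tofile(path)
    else:
        nib.save(nib.Nifti1Image(counts, np.eye(4)), str(path))
    sidecar = {
        "format": "raw-float32" if raw else "nifti",
        "shape": list(counts.shape),
        "angles_deg": list(sino.geometry.angles),
        "n_bins": sino.geometry.n_bins,
        "bin_width_cm": sino.geometry.bin_width,
        "flattening": "angle-major, bin-fastest",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_sinogram(path: str | Path) -> Sinogram:
    """Read a sinogram written by :func:`write_sinogram` (sidecar required)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sinogram sidecar {sidecar} not found (required next to {path.name})"
        )
    meta = json.loads(sidecar.read_text())
    geom = AcquisitionGeometry(
        n_bins=int(meta["n_bins"]),
        bin_width=float(meta["bin_width_cm"]),
        angles=tuple(meta["angles_deg"]),
    )
    shape = tuple(meta["shape"])
    if meta["format"] == "raw-float32":
        counts = np.fromfile(path, dtype=np.float32).reshape(shape)
    else:
        counts = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64).reshape(shape)
    return Sinogram(counts.astype(float), geom)


def save_sparse_triplets(
    matrix: sp.spmatrix, path: str | Path, header: dict | None = None
) -> None:
    """Write a sparse matrix as a text triplet file with a JSON header line."""
    coo = sp.coo_matrix(matrix)
    meta = {"shape": list(coo.shape), "nnz": int(coo.nnz)}
    if header:
        meta.update(header)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {v:.17g}\n")


def load_sparse_triplets(path: str | Path) -> tuple[sp.csr_matrix, dict]:
    """Read a triplet file written by :func:`save_sparse_triplets`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing header line")
        meta = json.loads(first[1:].strip())
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(v))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=tuple(meta["shape"]))
    return mat, meta
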