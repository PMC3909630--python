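"""Siddon ray tracing, system-matrix construction, forward and back projection.

The system matrix A holds detection probabilities a_ij: here the intersection
length of detection ray i with pixel j (parallel-beam, one ray per bin through
the bin centre). The attenuated variant folds in exponential tissue
attenuation along the path from each emitting pixel's centre to the detector:

    a^mu_ij = a_ij * exp(-sum_k r_ik mu_k)

with the sum running over pixels strictly downstream of the emitting pixel
(self-attenuation across the emitting pixel is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import (
    AcquisitionGeometry,
    ActivityImage,
    AttenuationMap,
    GridSpec,
    Sinogram,
)

__all__ = [
    "SystemMatrix",
    "ray_trace",
    "ray_endpoints",
    "build_system_matrix",
    "attenuate_system_matrix",
    "forward_project",
    "back_project",
]


def ray_trace(
    grid: GridSpec,
    entry_point,
    exit_point,
) -> list[tuple[int, float]]:
    """Trace a ray through the grid, Siddon style.

    Parameters
    ----------
    grid : GridSpec
    entry_point, exit_point : (x, y) world coordinates in cm, on or outside
        the grid bounding box.

    Returns
    -------
    list of (flat pixel index, intersection length cm) in traversal order
    from ``entry_point`` towards ``exit_point``. The lengths sum to the
    length of the ray's chord through the grid. Empty list when the ray
    misses the grid.
    """
    p0 = np.asarray(entry_point, dtype=float)
    p1 = np.asarray(exit_point, dtype=float)
    d = p1 - p0
    ray_len = float(np.hypot(d[0], d[1]))
    if ray_len == 0.0:
        raise ValueError("degenerate (zero-length) ray")

    xmin, xmax, ymin, ymax = grid.extent
    lo = (xmin, ymin)
    hi = (xmax, ymax)
    tmin, tmax = 0.0, 1.0
    for ax in (0, 1):
        if d[ax] != 0.0:
            t1 = (lo[ax] - p0[ax]) / d[ax]
            t2 = (hi[ax] - p0[ax]) / d[ax]
            tmin = max(tmin, min(t1, t2))
            tmax = min(tmax, max(t1, t2))
        elif not (lo[ax] <= p0[ax] <= hi[ax]):
            return []
    if tmax <= tmin:
        return []

    ps = grid.pixel_size
    # parameter values at which the ray crosses pixel-boundary lines
    ts = [tmin, tmax]
    for ax, (low, n) in enumerate(((xmin, grid.nx), (ymin, grid.ny))):
        if d[ax] == 0.0:
            continue
        planes = low + ps * np.arange(n + 1)
        tp = (planes - p0[ax]) / d[ax]
        ts.append(tp[(tp > tmin) & (tp < tmax)])
    ts = np.unique(np.concatenate([np.atleast_1d(np.asarray(t)) for t in ts]))

    tm = 0.5 * (ts[:-1] + ts[1:])
    seg = (ts[1:] - ts[:-1]) * ray_len
    mx = p0[0] + tm * d[0]
    my = p0[1] + tm * d[1]
    ix = np.floor((mx - xmin) / ps).astype(int)
    iy = np.floor((my - ymin) / ps).astype(int)
    ix = np.clip(ix, 0, grid.nx - 1)
    iy = np.clip(iy, 0, grid.ny - 1)
    keep = seg > 1e-12 * ps
    return [
        (int(jy) * grid.nx + int(jx), float(s))
        for jx, jy, s in zip(ix[keep], iy[keep], seg[keep])
    ]


def ray_endpoints(
    grid: GridSpec, geom: AcquisitionGeometry, angle_index: int, bin_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit points of a detection ray, well outside the grid.

    The exit point lies on the detector side; traversal order from the
    returned entry point therefore runs towards the detector.
    """
    u, v = geom.ray_directions()
    s = geom.bin_offsets()[bin_index]
    half = 0.5 * float(np.hypot(grid.nx, grid.ny)) * grid.pixel_size + grid.pixel_size
    center = s * u[angle_index]
    return center - half * v[angle_index], center + half * v[angle_index]


def detector_distance(grid: GridSpec) -> float:
    """Distance from the world origin to the (conceptual) detector plane, cm."""
    return 0.5 * float(np.hypot(grid.nx, grid.ny)) * grid.pixel_size + grid.pixel_size


@dataclass
class SystemMatrix:
    """Sparse detection probabilities a_ij (n rays x m pixels), one slice."""

    matrix: sp.csr_matrix
    grid: GridSpec
    geometry: AcquisitionGeometry
    attenuated: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def sensitivity(self) -> np.ndarray:
        """Column sums sum_i a_ij: the sensitivity image, flat (m,)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def build_system_matrix(grid: GridSpec, geom: AcquisitionGeometry) -> SystemMatrix:
    """Geometric system matrix from Siddon intersection lengths.

    One ray per detector bin through the bin centre; a_ij is the chord length
    of ray i inside pixel j (cm). Deterministic for a given grid/geometry.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for ia in range(geom.n_angles):
        for ib in range(geom.n_bins):
            p0, p1 = ray_endpoints(grid, geom, ia, ib)
            i = ia * geom.n_bins + ib
            for j, r in ray_trace(grid, p0, p1):
                rows.append(i)
                cols.append(j)
                vals.append(r)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(geom.n_rays, grid.n_pixels), dtype=float
    )
    return SystemMatrix(mat, grid, geom, attenuated=False)


def attenuate_system_matrix(A: SystemMatrix, mu: AttenuationMap) -> SystemMatrix:
    """Apply exponential attenuation along each ray.

    Each geometric entry a_ij is multiplied by exp(-L_ij) where L_ij is the
    line integral of mu over the pixels strictly between pixel j and the
    detector along ray i (the emitting pixel does not attenuate itself).
    """
    if A.attenuated:
        raise ValueError("system matrix is already attenuated")
    if mu.values.shape != (A.grid.ny, A.grid.nx):
        raise ValueError(
            f"attenuation map shape {mu.values.shape} does not match grid "
            f"({A.grid.ny}, {A.grid.nx})"
        )
    grid, geom = A.grid, A.geometry
    mu_flat = mu.values.ravel()
    out = A.matrix.tolil(copy=True)
    for ia in range(geom.n_angles):
        for ib in range(geom.n_bins):
            p0, p1 = ray_endpoints(grid, geom, ia, ib)
            trace = ray_trace(grid, p0, p1)
            if not trace:
                continue
            i = ia * geom.n_bins + ib
            js = np.array([t[0] for t in trace])
            rs = np.array([t[1] for t in trace])
            rmu = rs * mu_flat[js]
            # downstream integral excluding the emitting pixel itself
            downstream = np.concatenate([np.cumsum(rmu[::-1])[::-1][1:], [0.0]])
            factors = np.exp(-downstream)
            row = out.rows[i]
            data = out.data[i]
            fmap = dict(zip(js.tolist(), factors.tolist()))
            out.data[i] = [d * fmap.get(j, 1.0) for j, d in zip(row, data)]
    return SystemMatrix(out.tocsr(), grid, geom, attenuated=True)


def _as_flat_image(f, m: int) -> np.ndarray:
    arr = f.flat if isinstance(f, ActivityImage) else np.asarray(f, float).ravel()
    if arr.size != m:
        raise ValueError(f"image size {arr.size} incompatible with matrix ({m})")
    return arr


def forward_project(A: SystemMatrix, f) -> Sinogram:
    """Line-integral forward projection: g_i = sum_j a_ij f_j."""
    arr = _as_flat_image(f, A.shape[1])
    g = A.matrix @ arr
    geom = A.geometry
    return Sinogram(g.reshape(geom.n_angles, geom.n_bins), geom)


def back_project(A: SystemMatrix, g) -> np.ndarray:
    """Adjoint of forward projection: b_j = sum_i a_ij g_i, returned (ny, nx)."""
    arr = g.flat if isinstance(g, Sinogram) else np.asarray(g, float).ravel()
    if arr.size != A.shape[0]:
        raise ValueError(f"sinogram size {arr.size} incompatible with matrix")
    b = A.matrix.T @ arr
    return b.reshape(A.grid.ny, A.grid.nx)
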