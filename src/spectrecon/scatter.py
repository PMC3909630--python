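"""First-order Compton scatter kernel beta_ij = dSC_i/df_j.

The photopeak sinogram mixes primary photons with photons that Compton
scattered once and still fell inside the energy window. Because the scatter
contribution SC_i is linear in the activity, it can be written
SC_i = sum_j beta_ij f_j with a kernel beta that depends only on the
attenuation map, the acquisition geometry and the energy window — so it is
built once per reconstruction and SC is refreshed from the current activity
estimate at the cost of one matrix product per iteration.

Scatter model (single scatter, collimated exit)
-----------------------------------------------
A photon emitted in pixel j reaches a scatter site s lying on detection ray
i, scatters there by the angle theta between the j->s direction and the ray
direction, and — if its degraded energy E' passes the acceptance window —
travels along the ray to the detector. Per fine emission pixel j (emission
positions are taken at the centres of the, optionally coarsened, scatter
grid cells):

    beta_ij = scale * sum_s  r_s * rho_e(s) * dV / max(d_js, p_c)^2
              * T(j->s; mu, E0) * (dsigma/dOmega)(E0, theta)
              * W(E'(theta)) * T(s->exit; mu', E')

where r_s is the chord of ray i in scatter cell s (the collimated tube
restricts scatter sites to the ray), rho_e the electron density inferred
from mu, dV the fine-pixel volume, d_js the emission-to-site distance
(guarded below one coarse pixel p_c), T the exponential attenuation factors
— the second leg uses mu rescaled to E' via the water mu(E) table — and W
the window acceptance. The kernel is normalised so its entries are
commensurate with the chord-length system matrix a_ij (the common
parallel-hole collimator acceptance cancels between primary and scatter);
residual calibration, including higher scatter orders the single-scatter sum
misses, is carried by the dimensionless ``scale`` factor.

Multi-slice ("New3") mode additionally lets the slices above and below emit
into the central slice's detection rays, with out-of-plane distances folded
into theta and into the first attenuation leg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ct import ENERGY_RANGE, water_mu, _TABLE_E, _TABLE_MU
from .geometry import AcquisitionGeometry, ActivityImage, AttenuationMap, GridSpec
from .kn import (
    ELECTRON_REST_ENERGY_KEV,
    R_E2_CM2,
    EnergyWindow,
    window_acceptance,
)
from .projector import ray_endpoints, ray_trace

__all__ = [
    "RHO_E_WATER",
    "ScatterKernel",
    "build_scatter_kernel",
    "estimate_scatter",
]

#: electron density of water, electrons / cm^3
RHO_E_WATER = 3.343e23


def _water_mu_vec(E: np.ndarray) -> np.ndarray:
    """Vectorised water mu(E), clipped to the table's energy range."""
    E = np.clip(E, ENERGY_RANGE[0], ENERGY_RANGE[1])
    return np.exp(np.interp(np.log(E), np.log(_TABLE_E), np.log(_TABLE_MU)))


def _line_integral_samples(
    mu2d: np.ndarray, grid: GridSpec, p0x, p0y, p1x, p1y, n_samp: int
) -> np.ndarray:
    """Midpoint-sampled line integrals of mu between point pairs (vectorised).

    All arguments broadcast; returns integral values with the broadcast shape.
    Points outside the grid sample mu = 0.
    """
    p0x, p0y, p1x, p1y = np.broadcast_arrays(
        np.asarray(p0x, float),
        np.asarray(p0y, float),
        np.asarray(p1x, float),
        np.asarray(p1y, float),
    )
    d = np.hypot(p1x - p0x, p1y - p0y)
    t = (np.arange(n_samp) + 0.5) / n_samp
    sx = p0x[..., None] + t * (p1x - p0x)[..., None]
    sy = p0y[..., None] + t * (p1y - p0y)[..., None]
    x0, y0 = grid.corner
    ix = np.floor((sx - x0) / grid.pixel_size).astype(np.intp)
    iy = np.floor((sy - y0) / grid.pixel_size).astype(np.intp)
    inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    ix = np.clip(ix, 0, grid.nx - 1)
    iy = np.clip(iy, 0, grid.ny - 1)
    vals = np.where(inside, mu2d[iy, ix], 0.0)
    return vals.mean(axis=-1) * d


def _coarsen_sum(slice2d: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = slice2d.shape
    return (
        slice2d.reshape(ny // factor, factor, nx // factor, factor)
        .sum(axis=(1, 3))
        .ravel()
    )


def _expand(flat_coarse: np.ndarray, nyc: int, nxc: int, factor: int) -> np.ndarray:
    img = flat_coarse.reshape(nyc, nxc)
    return np.repeat(np.repeat(img, factor, axis=0), factor, axis=1)


@dataclass
class ScatterKernel:
    """Sparse-in-structure scatter kernel with per-slice-pair blocks.

    ``blocks[(z_out, dz)]`` is an (n_rays x m_coarse) array mapping coarse
    emission-cell activity sums in slice ``z_out + dz`` to scatter counts in
    slice ``z_out``'s sinogram. The fine-pixel coefficient beta_ij is the
    block entry of pixel j's coarse cell, so SC stays exactly linear in f.
    """

    blocks: dict[tuple[int, int], np.ndarray]
    grid: GridSpec
    geometry: AcquisitionGeometry
    window: EnergyWindow
    energy: float = 140.0
    slab_mode: int = 1
    scale: float = 1.0
    grid_factor: int = 1

    def __post_init__(self) -> None:
        if self.slab_mode not in (1, 3):
            raise ValueError("slab_mode must be 1 or 3")

    @property
    def n_slices(self) -> int:
        return self.grid.nz

    @property
    def _coarse_shape(self) -> tuple[int, int]:
        return (self.grid.ny // self.grid_factor, self.grid.nx // self.grid_factor)

    def _fine_slices(self, f) -> np.ndarray:
        arr = f.flat if isinstance(f, ActivityImage) else np.asarray(f, float).ravel()
        nz, ny, nx = self.grid.nz, self.grid.ny, self.grid.nx
        if arr.size != nz * ny * nx:
            raise ValueError(
                f"activity size {arr.size} incompatible with grid {nz}x{ny}x{nx}"
            )
        return arr.reshape(nz, ny, nx)

    def estimate(self, f) -> np.ndarray:
        """Scatter sinogram SC from activity f; shape (nz, n_angles, n_bins)."""
        vol = self._fine_slices(f)
        fc = [_coarsen_sum(vol[z], self.grid_factor) for z in range(self.grid.nz)]
        geom = self.geometry
        out = np.zeros((self.grid.nz, geom.n_rays))
        for (z_out, dz), B in self.blocks.items():
            out[z_out] += self.scale * (B @ fc[z_out + dz])
        return out.reshape(self.grid.nz, geom.n_angles, geom.n_bins)

    def rmatvec(self, x) -> np.ndarray:
        """Adjoint product sum_i beta_ij x_i per fine pixel, flat (nz*ny*nx,)."""
        arr = np.asarray(x, float).ravel()
        geom = self.geometry
        nz = self.grid.nz
        if arr.size != nz * geom.n_rays:
            raise ValueError("sinogram-domain vector has wrong size")
        xs = arr.reshape(nz, geom.n_rays)
        nyc, nxc = self._coarse_shape
        out = np.zeros((nz, self.grid.ny, self.grid.nx))
        for (z_out, dz), B in self.blocks.items():
            coarse = self.scale * (B.T @ xs[z_out])
            out[z_out + dz] += _expand(coarse, nyc, nxc, self.grid_factor)
        return out.ravel()

    def column_sums(self) -> np.ndarray:
        """sum_i beta_ij per fine pixel j, flat."""
        return self.rmatvec(np.ones(self.grid.nz * self.geometry.n_rays))

    def dense(self) -> np.ndarray:
        """Full fine-pixel beta matrix (single-slice kernels only; tests)."""
        if self.grid.nz != 1:
            raise ValueError("dense() supports single-slice kernels only")
        B = self.scale * self.blocks[(0, 0)]
        _, nxc = self._coarse_shape
        iy, ix = np.divmod(np.arange(self.grid.n_pixels), self.grid.nx)
        mapping = (iy // self.grid_factor) * nxc + ix // self.grid_factor
        # beta_ij = B[i, cell(j)]
        return B[:, mapping]

    def to_slab1(self) -> "ScatterKernel":
        """In-plane-only kernel sharing this kernel's dz = 0 blocks."""
        blocks = {k: v for k, v in self.blocks.items() if k[1] == 0}
        return ScatterKernel(
            blocks,
            self.grid,
            self.geometry,
            self.window,
            self.energy,
            1,
            self.scale,
            self.grid_factor,
        )

    def with_scale(self, scale: float) -> "ScatterKernel":
        return ScatterKernel(
            self.blocks,
            self.grid,
            self.geometry,
            self.window,
            self.energy,
            self.slab_mode,
            scale,
            self.grid_factor,
        )


def estimate_scatter(kernel: ScatterKernel, f) -> np.ndarray:
    """SC_i = sum_j beta_ij f_j, shaped (nz, n_angles, n_bins)."""
    return kernel.estimate(f)


def _build_block(
    mu_c_flat: np.ndarray,
    grid_c: GridSpec,
    geom: AcquisitionGeometry,
    window: EnergyWindow,
    energy: float,
    dz_cm: float,
    dv_fine: float,
) -> np.ndarray:
    """One (n_rays x m_coarse) block for a given out-of-plane offset (cm)."""
    mc = grid_c.n_pixels
    ps_c = grid_c.pixel_size
    mu2d = mu_c_flat.reshape(grid_c.ny, grid_c.nx)
    cx, cy = (a.ravel() for a in grid_c.pixel_centers())
    mu_w0 = water_mu(min(max(energy, ENERGY_RANGE[0]), ENERGY_RANGE[1]))
    rho_e = RHO_E_WATER * mu_c_flat / mu_w0

    # pairwise in-plane distances and attenuation integrals between cell centres
    DX = cx[:, None] - cx[None, :]  # [site, emission] = s - j
    DY = cy[:, None] - cy[None, :]
    D2 = np.hypot(DX, DY)
    maxd = float(D2.max()) if mc > 1 else ps_c
    n_samp = max(2, int(math.ceil(maxd / (0.5 * ps_c))))
    I2 = np.empty((mc, mc))
    chunk = max(1, int(4e6 // (mc * n_samp)) or 1)
    for a0 in range(0, mc, chunk):
        a1 = min(mc, a0 + chunk)
        I2[a0:a1] = _line_integral_samples(
            mu2d,
            grid_c,
            cx[a0:a1, None],
            cy[a0:a1, None],
            cx[None, :],
            cy[None, :],
            n_samp,
        )

    D3 = np.hypot(D2, dz_cm)
    valid = D3 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        # first-leg attenuation: in-plane integral stretched to the 3-D path
        stretch = np.where(D2 > 1e-9 * ps_c, D3 / np.maximum(D2, 1e-300), 1.0)
        T0 = np.exp(-np.where(D2 > 1e-9 * ps_c, I2 * stretch, D3 * mu_c_flat[:, None]))
    GEO = np.where(valid, dv_fine / np.maximum(D3, ps_c) ** 2, 0.0)

    _, vdirs = geom.ray_directions()
    xmin, xmax, ymin, ymax = grid_c.extent
    B = np.zeros((geom.n_rays, mc))
    k0 = energy / ELECTRON_REST_ENERGY_KEV
    for ia in range(geom.n_angles):
        vx, vy = vdirs[ia]
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_t = np.where(valid, (DX * vx + DY * vy) / np.where(valid, D3, 1.0), 1.0)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        P = 1.0 / (1.0 + k0 * (1.0 - cos_t))
        E_prime = energy * P
        dsig = 0.5 * R_E2_CM2 * P**2 * (P + 1.0 / P - (1.0 - cos_t**2))
        W = window_acceptance(E_prime, window)
        M = T0 * GEO * dsig * W  # [site, emission]
        RATIO = _water_mu_vec(E_prime) / mu_w0
        active = M.max(axis=1) > 0.0
        for ib in range(geom.n_bins):
            p0, p1 = ray_endpoints(grid_c, geom, ia, ib)
            trace = ray_trace(grid_c, p0, p1)
            if not trace:
                continue
            sites = np.array([t[0] for t in trace], dtype=np.intp)
            lens = np.array([t[1] for t in trace])
            keep = active[sites] & (rho_e[sites] > 0)
            if not keep.any():
                continue
            sites, lens = sites[keep], lens[keep]
            # exit integral from each site centre along the ray direction
            tex = np.full(sites.shape, np.inf)
            for bound, comp, dcomp in (
                ((xmin, xmax), cx[sites], vx),
                ((ymin, ymax), cy[sites], vy),
            ):
                if dcomp != 0.0:
                    edge = bound[1] if dcomp > 0 else bound[0]
                    tex = np.minimum(tex, (edge - comp) / dcomp)
            i_exit = _line_integral_samples(
                mu2d,
                grid_c,
                cx[sites],
                cy[sites],
                cx[sites] + tex * vx,
                cy[sites] + tex * vy,
                n_samp,
            )
            contrib = (lens * rho_e[sites])[:, None] * M[sites] * np.exp(
                -RATIO[sites] * i_exit[:, None]
            )
            B[ia * geom.n_bins + ib] = contrib.sum(axis=0)
    return B


def build_scatter_kernel(
    grid: GridSpec,
    geom: AcquisitionGeometry,
    mu: AttenuationMap,
    window: EnergyWindow | None = None,
    slab_mode: int = 1,
    scatter_grid_factor: int = 1,
    scale: float = 1.0,
    energy: float | None = None,
) -> ScatterKernel:
    """Build the first-order scatter kernel for a grid/geometry/mu-map.

    Parameters
    ----------
    slab_mode : 1 or 3
        1: in-plane scatter only. 3: the slices directly above and below a
        slice also emit into its detection rays (requires nz >= 2; with the
        usual nz >= 3 every interior slice sees a full 3-slice slab).
    scatter_grid_factor : int
        Coarsen the scatter computation grid by this factor (1, 2 or 4);
        emission and scatter sites are taken at coarse-cell centres and the
        kernel is expanded back to fine pixels.
    scale : float
        Global calibration factor multiplying every entry.
    """
    window = window or EnergyWindow()
    if scatter_grid_factor not in (1, 2, 4):
        raise ValueError("scatter_grid_factor must be 1, 2 or 4")
    if slab_mode not in (1, 3):
        raise ValueError("slab_mode must be 1 or 3")
    if slab_mode == 3 and grid.nz < 2:
        raise ValueError("slab_mode 3 requires a multi-slice volume")
    E0 = energy if energy is not None else mu.reference_energy
    if mu.values.shape[-2:] != (grid.ny, grid.nx):
        raise ValueError("attenuation map does not match grid")
    vol = mu.values.reshape(grid.nz, grid.ny, grid.nx)

    grid_c = grid.coarsened(scatter_grid_factor)
    F = scatter_grid_factor
    dv_fine = grid.pixel_size**2 * grid.slice_thickness
    offsets = (0,) if slab_mode == 1 else (-1, 0, 1)
    blocks: dict[tuple[int, int], np.ndarray] = {}
    cache: dict[tuple, np.ndarray] = {}
    # identical mu slices (constant-profile slabs) share blocks across z
    uniform_z = all(np.array_equal(vol[z], vol[0]) for z in range(1, grid.nz))
    for z_out in range(grid.nz):
        mu_c = (
            vol[z_out]
            .reshape(grid.ny // F, F, grid.nx // F, F)
            .mean(axis=(1, 3))
            .ravel()
        )
        for dz in offsets:
            z_em = z_out + dz
            if not 0 <= z_em < grid.nz:
                continue
            key = (abs(dz),) if uniform_z else (z_out, abs(dz))
            if key not in cache:
                cache[key] = _build_block(
                    mu_c,
                    grid_c,
                    geom,
                    window,
                    E0,
                    abs(dz) * grid.slice_thickness,
                    dv_fine,
                )
            blocks[(z_out, dz)] = cache[key]
    return ScatterKernel(
        blocks, grid, geom, window, E0, slab_mode, scale, scatter_grid_factor
    )
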