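"""Independent brute-force oracles used by the scatter and MLEM tests.

The scatter oracle computes beta by an explicit double loop over
(detection-ray scatter site, emission pixel) pairs, with its own midpoint
sampler for every attenuation line integral — no shared code with the
vectorised kernel assembly beyond the elementary ray tracer.
"""

import math

import numpy as np

from spectrecon.ct import water_mu
from spectrecon.kn import ELECTRON_REST_ENERGY_KEV, R_E2_CM2, window_acceptance
from spectrecon.projector import ray_endpoints, ray_trace
from spectrecon.scatter import RHO_E_WATER


def brute_force_scatter_matrix(grid, geom, mu_map, window, energy=140.0):
    """Dense beta (n_rays x n_pixels) by direct summation (single slice)."""
    n = grid.nx
    ps = grid.pixel_size
    mu2d = mu_map.values
    X, Y = grid.pixel_centers()
    cx, cy = X.ravel(), Y.ravel()
    muf = mu2d.ravel()
    mu_w0 = water_mu(energy)
    rho = RHO_E_WATER * muf / mu_w0
    dv = ps * ps * grid.slice_thickness
    m = grid.n_pixels

    maxd = 0.0
    for a in range(m):
        maxd = max(maxd, float(np.hypot(cx - cx[a], cy - cy[a]).max()))
    n_samp = max(2, int(math.ceil(maxd / (0.5 * ps))))
    x0, y0 = grid.corner

    def sampled_integral(p0x, p0y, p1x, p1y):
        p0x, p0y, p1x, p1y = np.broadcast_arrays(
            np.atleast_1d(p0x * 1.0),
            np.atleast_1d(p0y * 1.0),
            np.atleast_1d(p1x * 1.0),
            np.atleast_1d(p1y * 1.0),
        )
        d = np.hypot(p1x - p0x, p1y - p0y)
        acc = np.zeros_like(d)
        for q in range(n_samp):
            t = (q + 0.5) / n_samp
            sx = p0x + t * (p1x - p0x)
            sy = p0y + t * (p1y - p0y)
            ix = np.floor((sx - x0) / ps).astype(int)
            iy = np.floor((sy - y0) / ps).astype(int)
            ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
            acc += np.where(
                ok, mu2d[np.clip(iy, 0, grid.ny - 1), np.clip(ix, 0, grid.nx - 1)], 0.0
            )
        return acc / n_samp * d

    _, vdirs = geom.ray_directions()
    xmin, xmax, ymin, ymax = grid.extent
    beta = np.zeros((geom.n_rays, m))
    for ia in range(geom.n_angles):
        vx, vy = vdirs[ia]
        for ib in range(geom.n_bins):
            p0, p1 = ray_endpoints(grid, geom, ia, ib)
            for s, rs in ray_trace(grid, p0, p1):
                if rho[s] <= 0:
                    continue
                tex = np.inf
                if vx > 0:
                    tex = min(tex, (xmax - cx[s]) / vx)
                elif vx < 0:
                    tex = min(tex, (xmin - cx[s]) / vx)
                if vy > 0:
                    tex = min(tex, (ymax - cy[s]) / vy)
                elif vy < 0:
                    tex = min(tex, (ymin - cy[s]) / vy)
                i_exit = sampled_integral(
                    cx[s], cy[s], cx[s] + tex * vx, cy[s] + tex * vy
                )[0]
                dx, dy = cx[s] - cx, cy[s] - cy
                d3 = np.hypot(dx, dy)
                valid = d3 > 0
                t0 = np.exp(
                    -sampled_integral(cx, cy, np.full(m, cx[s]), np.full(m, cy[s]))
                )
                geo = np.where(valid, dv / np.maximum(d3, ps) ** 2, 0.0)
                cos_t = np.where(
                    valid, (dx * vx + dy * vy) / np.where(valid, d3, 1.0), 1.0
                )
                P = 1.0 / (1.0 + (energy / ELECTRON_REST_ENERGY_KEV) * (1.0 - cos_t))
                Ep = energy * P
                dsig = 0.5 * R_E2_CM2 * P**2 * (P + 1.0 / P - (1.0 - cos_t**2))
                W = window_acceptance(Ep, window)
                ratio = (
                    np.array([water_mu(min(max(e, 50.0), 160.0)) for e in Ep]) / mu_w0
                )
                beta[ia * geom.n_bins + ib] += (
                    rs * rho[s] * t0 * geo * dsig * W * np.exp(-ratio * i_exit)
                )
    return beta
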