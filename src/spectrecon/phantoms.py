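"""Digital phantoms and the SPECT acquisition simulator.

Two phantoms are provided:

* the NEMA IEC body (image-quality) phantom: an elliptical water body with
  six fillable spheres (inner diameters 10, 13, 17, 22, 28, 37 mm) on a
  ring and a low-density cylindrical insert in the centre.  The four
  smallest spheres are hot at an 8:1 activity-concentration ratio to the
  background, the two largest are cold;
* a geometric torso surrogate in the spirit of the NURBS anthropomorphic
  (NCAT/XCAT) phantom: body ellipse, two lungs, myocardial ring,
  gallbladder, liver and spleen with activity ratios
  100 : 100 : 40 : 22 : 6 : 6 (myocardium, gallbladder, liver, spleen,
  lung, background) and a 140 keV attenuation map.  It is built from
  ellipses and annuli, not NURBS surfaces — a deliberately simple stand-in
  whose per-organ means are exact by construction.

The simulator draws Poisson counts around the single-scatter forward model
E(g) = A^mu f + beta f, scaled to a total count budget, and also returns the
primary-only and scatter expectations plus a "reference" sinogram of
unattenuated primaries (the comparator a reconstruction without any
correction can meaningfully be judged against).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct import MU_WATER_140KEV
from .geometry import ActivityImage, AttenuationMap, GridSpec
from .projector import SystemMatrix
from .scatter import ScatterKernel

__all__ = [
    "MU_LUNG_140KEV",
    "MU_SOFT_140KEV",
    "PhantomSpec",
    "SimulatedAcquisition",
    "make_nema_iq_phantom",
    "make_ncat_surrogate",
    "simulate_acquisition",
]

#: lung at 140 keV (~0.26 g/cm^3 inflated lung)
MU_LUNG_140KEV = 0.040
#: soft tissue approximated as water at 140 keV
MU_SOFT_140KEV = MU_WATER_140KEV

#: NEMA sphere inner diameters, mm (hot: 10-22; cold: 28, 37)
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description used in experiment manifests."""

    kind: str = "nema_iq"
    hot_background_ratio: float = 8.0
    body_semi_axes_cm: tuple[float, float] = (15.0, 11.5)
    sphere_ring_radius_cm: float = 5.72
    insert_radius_cm: float = 2.5
    activities: dict = field(default_factory=dict)


def _disk(X, Y, cx, cy, r):
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


def _ellipse(X, Y, cx, cy, a, b):
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0


def make_nema_iq_phantom(
    grid: GridSpec,
    ratio: float = 8.0,
    body_semi_axes: tuple[float, float] = (15.0, 11.5),
    ring_radius: float = 5.72,
    insert_radius: float = 2.5,
    background_activity: float = 1.0,
) -> tuple[ActivityImage, AttenuationMap, dict[str, np.ndarray]]:
    """NEMA IQ phantom slice: activity, 140 keV mu-map and region masks.

    Returns masks for ``body``, ``background``, ``insert`` and each sphere
    (``sphere_10`` ... ``sphere_37``, named by diameter in mm). Pixels
    belong to a region when their centre falls inside it; the 8:1 hot
    contrast is therefore exact on the voxelised image.
    """
    X, Y = grid.pixel_centers()
    a, b = body_semi_axes
    xmin, xmax, ymin, ymax = grid.extent
    if a * 2 > (xmax - xmin) or b * 2 > (ymax - ymin):
        raise ValueError("grid too small to contain the body ellipse")

    body = _ellipse(X, Y, 0.0, 0.0, a, b)
    insert = _disk(X, Y, 0.0, 0.0, insert_radius)
    masks: dict[str, np.ndarray] = {"body": body, "insert": insert & body}

    activity = np.where(body & ~insert, background_activity, 0.0)
    mu = np.where(body, MU_SOFT_140KEV, 0.0)
    mu = np.where(insert & body, MU_LUNG_140KEV, mu)

    sphere_angles = np.deg2rad(np.arange(6) * 60.0)
    taken = insert.copy()
    for d_mm, ang in zip(NEMA_SPHERE_DIAMETERS_MM, sphere_angles):
        r = 0.05 * d_mm  # mm diameter -> cm radius
        cx, cy = ring_radius * np.cos(ang), ring_radius * np.sin(ang)
        sph = _disk(X, Y, cx, cy, r) & body & ~taken
        masks[f"sphere_{int(d_mm)}"] = sph
        hot = d_mm <= 22.0
        activity = np.where(sph, ratio * background_activity if hot else 0.0, activity)
        taken |= sph
    masks["background"] = body & ~taken & ~insert
    return (
        ActivityImage(activity, grid),
        AttenuationMap(mu, grid, reference_energy=140.0),
        masks,
    )


#: organ activity ratios of the standard myocardial-perfusion torso distribution
NCAT_ACTIVITIES = {
    "myocardium": 100.0,
    "gallbladder": 100.0,
    "liver": 40.0,
    "spleen": 22.0,
    "lung": 6.0,
    "background": 6.0,
}


def make_ncat_surrogate(
    grid: GridSpec,
    n_slices: int = 3,
    body_semi_axes: tuple[float, float] = (17.0, 11.0),
) -> tuple[ActivityImage, AttenuationMap, dict[str, np.ndarray]]:
    """Geometric torso surrogate volume with the standard organ activity ratios.

    All ``n_slices`` trans-axial slices share the same cross-section (a
    constant-profile slab), which keeps every per-organ mean exact and gives
    the 3-slice scatter mode a fully populated slab. Masks are per-organ
    ownership masks (later organs in the assignment order win overlaps), so
    mask-weighted means reproduce the activity table exactly.
    """
    if n_slices < 3:
        raise ValueError("n_slices must be >= 3")
    X, Y = grid.pixel_centers()
    a, b = body_semi_axes
    xmin, xmax, ymin, ymax = grid.extent
    if a * 2 > (xmax - xmin) or b * 2 > (ymax - ymin):
        raise ValueError("grid too small to contain the torso ellipse")

    body = _ellipse(X, Y, 0.0, 0.0, a, b)
    lung_l = _ellipse(X, Y, -8.0, 2.5, 4.8, 6.0) & body
    lung_r = _ellipse(X, Y, 8.5, 2.5, 4.6, 6.0) & body
    heart_outer = _disk(X, Y, -2.5, 3.0, 3.4)
    heart_inner = _disk(X, Y, -2.5, 3.0, 2.2)
    myocardium = heart_outer & ~heart_inner & body
    liver = _ellipse(X, Y, 5.5, -4.0, 6.5, 4.0) & body
    gallbladder = _disk(X, Y, 1.5, -6.5, 1.3) & body
    spleen = _ellipse(X, Y, -9.5, -4.5, 2.6, 2.0) & body

    # assignment order: later regions override earlier ones
    label = np.zeros(body.shape, dtype=int)
    order = [
        ("lung", lung_l | lung_r),
        ("spleen", spleen),
        ("liver", liver),
        ("gallbladder", gallbladder),
        ("myocardium", myocardium),
    ]
    names = ["background"] + [n for n, _ in order]
    for idx, (_, region) in enumerate(order, start=1):
        label[region] = idx

    activity = np.zeros(body.shape)
    activity[body] = NCAT_ACTIVITIES["background"]
    masks: dict[str, np.ndarray] = {"body": body}
    for idx, name in enumerate(names):
        own = (label == idx) & body
        masks[name] = own
        activity[own] = NCAT_ACTIVITIES[name]

    mu = np.where(body, MU_SOFT_140KEV, 0.0)
    mu[masks["lung"]] = MU_LUNG_140KEV

    grid3 = GridSpec(
        grid.nx, grid.ny, n_slices, grid.pixel_size, grid.slice_thickness, grid.origin
    )
    act_vol = np.repeat(activity[None], n_slices, axis=0)
    mu_vol = np.repeat(mu[None], n_slices, axis=0)
    return (
        ActivityImage(act_vol, grid3),
        AttenuationMap(mu_vol, grid3, reference_energy=140.0),
        masks,
    )


@dataclass
class SimulatedAcquisition:
    """Photopeak sinogram plus the pieces of its expectation.

    ``g`` is the (noisy unless ``noise=False``) total sinogram,
    ``primary`` the attenuated primary-only sinogram, ``reference`` the
    unattenuated primary sinogram (or attenuated, per ``reference_mode``),
    and ``sc_true`` the noise-free scatter expectation. ``primary_mean`` /
    ``reference_mean`` / ``total_mean`` carry the exact expectations.
    """

    g: np.ndarray
    primary: np.ndarray
    reference: np.ndarray
    sc_true: np.ndarray
    total_mean: np.ndarray
    primary_mean: np.ndarray
    reference_mean: np.ndarray
    seed: int
    total_counts: float
    scale: float


def simulate_acquisition(
    f: ActivityImage,
    A: SystemMatrix,
    A_mu: SystemMatrix,
    kernel: ScatterKernel | None = None,
    total_counts: float = 5e5,
    seed: int = 0,
    reference_mode: str = "no_attenuation",
    noise: bool = True,
) -> SimulatedAcquisition:
    """Simulate a photopeak acquisition of activity ``f``.

    The activity is globally rescaled so the expected total counts in the
    photopeak sinogram equal ``total_counts`` (per volume). With
    ``noise=False`` the exact expectations are returned in place of Poisson
    draws. All randomness comes from one seeded generator, so outputs are
    bit-identical for a fixed seed.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    if reference_mode not in ("no_attenuation", "attenuated"):
        raise ValueError("reference_mode must be 'no_attenuation' or 'attenuated'")
    nz = f.grid.nz
    fv = f.flat
    m = A_mu.shape[1]

    def _project(mat: SystemMatrix) -> np.ndarray:
        if nz == 1:
            return np.asarray(mat.matrix @ fv)
        vol = fv.reshape(nz, m)
        return np.concatenate([np.asarray(mat.matrix @ vol[z]) for z in range(nz)])

    primary = _project(A_mu)
    unatt = _project(A)
    sc = kernel.estimate(fv).ravel() if kernel is not None else np.zeros_like(primary)
    total = primary + sc
    tot_sum = float(total.sum())
    if tot_sum <= 0:
        scale = 0.0
    else:
        scale = total_counts / tot_sum
    total_mean = scale * total
    primary_mean = scale * primary
    reference_mean = scale * (unatt if reference_mode == "no_attenuation" else primary)
    sc_true = scale * sc

    rng = np.random.default_rng(seed)
    if noise:
        g = rng.poisson(total_mean).astype(float)
        prim = rng.poisson(primary_mean).astype(float)
        ref = rng.poisson(reference_mean).astype(float)
    else:
        g, prim, ref = total_mean.copy(), primary_mean.copy(), reference_mean.copy()
    return SimulatedAcquisition(
        g=g,
        primary=prim,
        reference=ref,
        sc_true=sc_true,
        total_mean=total_mean,
        primary_mean=primary_mean,
        reference_mean=reference_mean,
        seed=seed,
        total_counts=total_counts,
        scale=scale,
    )
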