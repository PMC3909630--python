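"""Core domain types: image grids, acquisition geometry, images and sinograms.

Coordinate conventions
----------------------
The image grid lies in the (x, y) plane. With the default centred origin the
grid corner is at ``(-nx*ps/2, -ny*ps/2)`` so the grid midpoint is the origin
of the world frame; pixel ``(ix, iy)`` has its centre at
``((ix + 0.5)*ps + x0, (iy + 0.5)*ps + y0)``.  Arrays are indexed
``values[iy, ix]`` and flattened in C order, so flat pixel index
``j = iy*nx + ix``.

Projection rays for view angle ``theta`` (degrees, camera rotating
counter-clockwise) travel along ``v = (-sin t, cos t)`` towards the detector;
detector bins are laid out along ``u = (cos t, sin t)``, so at ``theta = 0``
bins line up with image columns. Sinograms are stored ``counts[angle, bin]``
and flatten angle-major / bin-fastest: flat bin index
``i = angle_index * n_bins + bin_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "AcquisitionGeometry",
    "ActivityImage",
    "AttenuationMap",
    "Sinogram",
]


@dataclass(frozen=True)
class GridSpec:
    """Pixelised reconstruction grid.

    Parameters
    ----------
    nx, ny : int
        Pixels per row / column (``m = nx * ny`` unknowns per slice).
    nz : int
        Number of axial slices (1 for a single trans-axial slice).
    pixel_size : float
        In-plane pixel side, cm.
    slice_thickness : float
        Axial slice thickness, cm.
    origin : str
        ``"center"`` (grid midpoint at the world origin) or ``"corner"``
        (grid corner at the origin).
    """

    nx: int
    ny: int
    nz: int = 1
    pixel_size: float = 0.625
    slice_thickness: float = 0.625
    origin: str = "center"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nz < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be > 0")
        if self.origin not in ("center", "corner"):
            raise ValueError(f"unknown origin convention {self.origin!r}")

    @property
    def n_pixels(self) -> int:
        """Pixels per slice."""
        return self.nx * self.ny

    @property
    def corner(self) -> tuple[float, float]:
        """World coordinates (x, y) of the grid's low corner."""
        if self.origin == "center":
            return (
                -0.5 * self.nx * self.pixel_size,
                -0.5 * self.ny * self.pixel_size,
            )
        return (0.0, 0.0)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid bounding box, cm."""
        x0, y0 = self.corner
        return (
            x0,
            x0 + self.nx * self.pixel_size,
            y0,
            y0 + self.ny * self.pixel_size,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (ny, nx) of pixel-centre x and y world coordinates."""
        x0, y0 = self.corner
        xs = x0 + (np.arange(self.nx) + 0.5) * self.pixel_size
        ys = y0 + (np.arange(self.ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def coarsened(self, factor: int) -> "GridSpec":
        """Grid coarsened by an integer factor (dimensions must divide)."""
        if self.nx % factor or self.ny % factor:
            raise ValueError(
                f"coarsening factor {factor} does not divide {self.nx}x{self.ny}"
            )
        return GridSpec(
            self.nx // factor,
            self.ny // factor,
            self.nz,
            self.pixel_size * factor,
            self.slice_thickness,
            self.origin,
        )


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Parallel-beam SPECT acquisition: detector bins and view angles.

    Default: 64 bins, 60 views over 360 deg at 6 deg increments, mirroring a
    standard single-head gamma-camera orbit.
    """

    n_bins: int = 64
    bin_width: float = 0.625
    angles: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.arange(60) * 6.0)
    )

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        ang = np.asarray(self.angles, dtype=float)
        if ang.ndim != 1 or ang.size < 1:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if np.any(ang < 0) or np.any(ang >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", tuple(float(a) for a in ang))

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_rays(self) -> int:
        """Total detection bins n = n_bins * n_angles (per slice)."""
        return self.n_bins * self.n_angles

    def bin_offsets(self) -> np.ndarray:
        """Signed lateral offsets of bin centres along the detector axis, cm."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_width

    def ray_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) unit vectors per angle: u detector axis, v ray direction."""
        t = np.deg2rad(self.angles)
        u = np.stack([np.cos(t), np.sin(t)], axis=1)
        v = np.stack([-np.sin(t), np.cos(t)], axis=1)
        return u, v


def _check_image(values: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    expected_2d = (grid.ny, grid.nx)
    expected_3d = (grid.nz, grid.ny, grid.nx)
    if arr.shape == expected_2d and grid.nz == 1:
        pass
    elif arr.shape == expected_3d:
        pass
    else:
        raise ValueError(
            f"{name} shape {arr.shape} does not match grid {expected_3d}"
        )
    if np.any(arr < 0):
        raise ValueError(f"{name} values must be nonnegative")
    return arr


@dataclass
class ActivityImage:
    """Pixelised radiotracer activity distribution f_j (arbitrary units)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _check_image(self.values, self.grid, "activity")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class AttenuationMap:
    """Per-pixel linear attenuation coefficients mu_k (1/cm) at a reference energy."""

    values: np.ndarray
    grid: GridSpec
    reference_energy: float = 140.0

    def __post_init__(self) -> None:
        self.values = _check_image(self.values, self.grid, "attenuation")
        if self.reference_energy <= 0:
            raise ValueError("reference_energy must be > 0 keV")


@dataclass
class Sinogram:
    """Detected counts g_i indexed by (view angle, detector bin)."""

    counts: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        na, nb = self.geometry.n_angles, self.geometry.n_bins
        if arr.shape not in ((na, nb),) and not (
            arr.ndim == 3 and arr.shape[1:] == (na, nb)
        ):
            raise ValueError(
                f"sinogram shape {arr.shape} does not match geometry "
                f"({na} angles x {nb} bins)"
            )
        if np.any(arr < 0):
            raise ValueError("sinogram counts must be nonnegative")
        self.counts = arr

    @property
    def flat(self) -> np.ndarray:
        """Angle-major / bin-fastest flattening (slice-major for volumes)."""
        return self.counts.ravel()
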