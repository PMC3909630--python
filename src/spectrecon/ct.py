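"""CT (Hounsfield unit) to linear-attenuation-coefficient conversion.

Uses the standard bilinear calibration: below the breakpoint (default 0 HU)
tissues are modelled as water/air mixtures, above it as water/bone mixtures
whose effective atomic number raises attenuation faster per HU. A small
built-in water mu(E) table supports rescaling maps between photon energies
(needed for the down-scattered photon leg of the scatter model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AttenuationMap, GridSpec

__all__ = [
    "WATER_MU_TABLE",
    "MU_WATER_140KEV",
    "MU_BONE_140KEV",
    "BilinearCalibration",
    "water_mu",
    "hu_to_mu",
    "rescale_mu_energy",
]

# Linear attenuation of liquid water (1.000 g/cm^3), cm^-1, NIST XCOM
# mass-attenuation values times density. Queried by log-linear interpolation.
WATER_MU_TABLE: dict[float, float] = {
    50.0: 0.2269,
    60.0: 0.2059,
    80.0: 0.1837,
    100.0: 0.1707,
    150.0: 0.1505,
    200.0: 0.1370,
}

_TABLE_E = np.array(sorted(WATER_MU_TABLE))
_TABLE_MU = np.array([WATER_MU_TABLE[e] for e in _TABLE_E])

#: valid query range for energy rescaling, keV
ENERGY_RANGE = (50.0, 160.0)


def water_mu(E_keV: float) -> float:
    """Linear attenuation coefficient of water at E_keV (cm^-1), log-linear interp."""
    lo, hi = ENERGY_RANGE
    if not lo <= E_keV <= hi:
        raise ValueError(f"energy {E_keV} keV outside table range {lo}-{hi} keV")
    return float(
        np.exp(np.interp(np.log(E_keV), np.log(_TABLE_E), np.log(_TABLE_MU)))
    )


#: water at the Tc-99m photopeak (from the table above)
MU_WATER_140KEV = water_mu(140.0)
#: cortical bone at 140 keV: 1.92 g/cm^3 times NIST mass attenuation
MU_BONE_140KEV = 0.295


@dataclass(frozen=True)
class BilinearCalibration:
    """Bilinear HU -> mu calibration at a target photon energy.

    ``slope_bone`` is chosen so HU = 1000 lands near cortical bone at
    140 keV; both segments meet continuously at the breakpoint.
    """

    mu_water: float = MU_WATER_140KEV
    slope_bone: float = (MU_BONE_140KEV - MU_WATER_140KEV) / 1000.0
    breakpoint_hu: float = 0.0
    energy: float = 140.0

    def __post_init__(self) -> None:
        if self.mu_water <= 0 or self.slope_bone <= 0:
            raise ValueError("mu_water and slope_bone must be > 0")


def hu_to_mu(
    ct: np.ndarray,
    calib: BilinearCalibration | None = None,
    grid: GridSpec | None = None,
) -> AttenuationMap | np.ndarray:
    """Convert a CT image in Hounsfield units to an attenuation map.

    HU <= breakpoint: mu = mu_water * (HU + 1000) / 1000, floored at 0
    (air at -1000 HU maps to 0). HU > breakpoint: mu = mu at breakpoint
    plus ``slope_bone`` per HU above it, making the map continuous and
    monotone. Input is clamped below at -1024 HU.

    Returns an :class:`AttenuationMap` when ``grid`` is given, else a bare
    array of the same shape as ``ct``.
    """
    calib = calib or BilinearCalibration()
    hu = np.clip(np.asarray(ct, dtype=float), -1024.0, None)
    bp = calib.breakpoint_hu
    mu_bp = calib.mu_water * (bp + 1000.0) / 1000.0
    soft = calib.mu_water * (hu + 1000.0) / 1000.0
    bone = mu_bp + calib.slope_bone * (hu - bp)
    mu = np.where(hu <= bp, soft, bone)
    mu = np.maximum(mu, 0.0)
    if grid is None:
        return mu
    return AttenuationMap(mu, grid, reference_energy=calib.energy)


def rescale_mu_energy(mu: AttenuationMap, E_target: float) -> AttenuationMap:
    """Rescale an attenuation map to another photon energy.

    Scales all coefficients by the water ratio mu_w(E_target)/mu_w(E_source);
    adequate for soft tissue and lung where attenuation tracks water across
    50-160 keV.
    """
    factor = water_mu(E_target) / water_mu(mu.reference_energy)
    return AttenuationMap(mu.values * factor, mu.grid, reference_energy=E_target)
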