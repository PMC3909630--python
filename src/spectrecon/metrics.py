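"""Image-quality metrics: contrast, MSE, SNR, CNR/CRC/CoV and profiles.

Conventions: all region statistics are simple pixel means over boolean
masks; standard deviations use the population convention (divide by n).
Contrast follows Ctr = (hot mean / background mean) - 1, the contrast
recovery coefficient CRC = (m_l - m_b) / (m_b (C - 1)) with C the true
phantom contrast ratio, the coefficient of variation CoV = background
stdev / background mean, and CNR = CRC / CoV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ROISet",
    "MetricsReport",
    "make_rois",
    "contrast",
    "mse",
    "snr",
    "cnr",
    "profile",
]


@dataclass
class ROISet:
    """Named boolean masks over the image grid.

    ``hot`` and ``background`` must be disjoint; ``signal`` defaults to the
    hot mask.
    """

    hot: np.ndarray
    background: np.ndarray
    signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hot = np.asarray(self.hot, bool)
        self.background = np.asarray(self.background, bool)
        if self.hot.shape != self.background.shape:
            raise ValueError("hot and background masks must share a shape")
        if not self.hot.any() or not self.background.any():
            raise ValueError("hot and background masks must be non-empty")
        if np.any(self.hot & self.background):
            raise ValueError("hot and background masks must be disjoint")
        if self.signal is None:
            self.signal = self.hot
        else:
            self.signal = np.asarray(self.signal, bool)


def make_rois(
    hot_mask: np.ndarray,
    body_mask: np.ndarray,
    exclude: np.ndarray | None = None,
    erode_hot: int = 1,
    dilate_exclude: int = 2,
) -> ROISet:
    """Build evaluation ROIs from phantom label masks.

    The hot ROI is the region mask eroded by ``erode_hot`` pixels to limit
    partial-volume edge effects (erosion is skipped when it would empty the
    mask). The background ROI is the body minus the dilated union of the
    hot region and ``exclude`` (other lesions, inserts, organs).
    """
    hot = np.asarray(hot_mask, bool)
    if erode_hot > 0:
        eroded = ndimage.binary_erosion(hot, iterations=erode_hot)
        if eroded.any():
            hot = eroded
    excl = np.asarray(hot_mask, bool)
    if exclude is not None:
        excl = excl | np.asarray(exclude, bool)
    excl = ndimage.binary_dilation(excl, iterations=dilate_exclude)
    background = np.asarray(body_mask, bool) & ~excl
    return ROISet(hot=hot, background=background)


def contrast(img: np.ndarray, roi: ROISet) -> float:
    """Ctr = mean(hot) / mean(background) - 1 (negative for cold regions)."""
    img = np.asarray(img, float)
    mb = img[roi.background].mean()
    if mb == 0:
        raise ValueError("zero background mean")
    return float(img[roi.hot].mean() / mb - 1.0)


def mse(P: np.ndarray, T: np.ndarray) -> float:
    """Mean of squared pixel differences between an image and a reference."""
    P = np.asarray(P, float)
    T = np.asarray(T, float)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {T.shape}")
    return float(np.mean((P - T) ** 2))


def snr(img: np.ndarray, roi: ROISet) -> float:
    """Mean signal over population stdev of the background ROI."""
    img = np.asarray(img, float)
    if roi.background.sum() < 2:
        raise ValueError("background ROI needs >= 2 pixels")
    sd = img[roi.background].std()
    if sd == 0:
        raise ValueError("zero background standard deviation (noise-free input?)")
    return float(img[roi.signal].mean() / sd)


def cnr(img: np.ndarray, roi: ROISet, C_true: float) -> tuple[float, float, float]:
    """(CNR, CRC, CoV) for a hot lesion with true contrast ratio C_true."""
    if C_true == 1.0:
        raise ValueError("C_true = 1 makes CRC undefined")
    img = np.asarray(img, float)
    m_l = img[roi.hot].mean()
    m_b = img[roi.background].mean()
    if m_b == 0:
        raise ValueError("zero background mean")
    crc = (m_l - m_b) / (m_b * (C_true - 1.0))
    cov = img[roi.background].std() / m_b
    cnr_val = crc / cov if cov > 0 else np.inf
    return float(cnr_val), float(crc), float(cov)


def profile(img: np.ndarray, row_index: int) -> np.ndarray:
    """Horizontal profile: pixel values of one image row, column order."""
    img = np.asarray(img, float)
    if not 0 <= row_index < img.shape[0]:
        raise IndexError(f"row {row_index} out of range for {img.shape}")
    return img[row_index].copy()


@dataclass
class MetricsReport:
    """All evaluation parameters for one reconstructed image."""

    method: str
    ctr: float
    mse: float
    snr: float
    cnr: float
    crc: float
    cov: float
    profile: np.ndarray
    seconds_per_iteration: float = float("nan")
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "contrast": self.ctr,
            "mse": self.mse,
            "snr": self.snr,
            "cnr": self.cnr,
            "crc": self.crc,
            "cov": self.cov,
            "s_per_iter": self.seconds_per_iteration,
        }
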