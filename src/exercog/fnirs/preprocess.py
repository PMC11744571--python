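"""fNIRS preprocessing: channel QC, filtering, PCA denoising, ROI averaging.

The connectivity branch of the pipeline band-passes concentration series to
the low-frequency hemodynamic band (0.01-0.08 Hz), removing cardiac (~1 Hz),
respiratory (~0.3 Hz), Mayer-wave (~0.1 Hz) and slow-drift content, then
regresses out leading spatial principal components to suppress remaining
global systemic physiology, and finally averages retained channels within
each ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage

__all__ = [
    "QualityReport",
    "RoiTimeSeries",
    "channel_quality_check",
    "bandpass",
    "pca_denoise",
    "roi_average",
]

CV_THRESHOLD = 0.15  # exclude a channel if sd/mean >= 15% at either wavelength


@dataclass
class QualityReport:
    """Outcome of the coefficient-of-variation channel screen."""

    retained: list[str]
    excluded: list[str]
    cv: pd.DataFrame  # channels x wavelengths
    threshold: float = CV_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "excluded": self.excluded,
            "threshold": self.threshold,
            "cv": {
                ch: {str(wl): float(v) for wl, v in row.items()}
                for ch, row in self.cv.iterrows()
            },
        }


@dataclass
class RoiTimeSeries:
    """Per-ROI chromophore series at a fixed sampling rate."""

    data: pd.DataFrame  # T x ROIs
    fs: float
    chromophore: str  # "hbo" or "hbr"
    segment: str = "resting"
    retained_channels: dict[str, int] = field(default_factory=dict)
    dropped_rois: list[str] = field(default_factory=list)

    @property
    def rois(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def channel_quality_check(
    intensity: np.ndarray,
    channel_names: list[str],
    fs: float,
    threshold: float = CV_THRESHOLD,
    wavelengths: tuple[int, int] = (760, 850),
) -> QualityReport:
    """Screen channels by intensity coefficient of variation.

    ``intensity`` has shape (n_channels, n_wavelengths, T).  A channel is
    excluded iff CV = sd/mean reaches the threshold (inclusive) at *either*
    wavelength.  Requires at least 10 s of data.
    """
    inten = np.asarray(intensity, dtype=float)
    if inten.ndim != 3 or inten.shape[0] != len(channel_names):
        raise ValueError("intensity must be (n_channels, n_wavelengths, T)")
    if inten.shape[-1] < 10 * fs:
        raise ValueError("quality check requires at least 10 s of data")
    mean = inten.mean(axis=-1)
    sd = inten.std(axis=-1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    bad = (cv >= threshold).any(axis=1)
    retained = [ch for ch, b in zip(channel_names, bad) if not b]
    excluded = [ch for ch, b in zip(channel_names, bad) if b]
    cv_df = pd.DataFrame(cv, index=channel_names, columns=list(wavelengths))
    return QualityReport(retained, excluded, cv_df, threshold)


def bandpass(
    series: np.ndarray,
    fs: float,
    low: float = 0.01,
    high: float = 0.08,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A 3rd-order Butterworth is applied forward and backward (``sosfiltfilt``)
    so the filter contributes no phase lag -- important because phase
    distortion would corrupt lag-based connectivity estimates downstream.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for high edge {high} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # forward-backward pass needs enough samples to settle the edge padding
    padlen = 3 * (2 * order + 1)
    min_len = 3 * padlen
    if x.shape[-1] <= min_len:
        raise ValueError(
            f"series too short for zero-phase filtering ({x.shape[-1]} <= {min_len})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def pca_denoise(series: np.ndarray, n_components: int = 1) -> np.ndarray:
    """Regress leading *spatial* principal components out of every channel.

    ``series`` is (n_channels, T).  Channels are temporally centered, the
    top ``n_components`` spatial eigenvectors of the channel covariance are
    projected out, and channel means restored.  With ``n_components=0`` the
    input is returned unchanged.  The cleaned data are exactly orthogonal to
    the removed components.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be (n_channels, T)")
    n_ch = x.shape[0]
    if n_ch < 2:
        raise ValueError("PCA denoising needs at least 2 channels")
    if n_components >= n_ch:
        raise ValueError(
            f"cannot remove {n_components} components from {n_ch} channels"
        )
    if n_components == 0:
        return x.copy()
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    # spatial components = left singular vectors of the channels x time matrix
    u, _, _ = np.linalg.svd(xc, full_matrices=False)
    basis = u[:, :n_components]  # (n_channels, k)
    cleaned = xc - basis @ (basis.T @ xc)
    return cleaned + mean


def roi_average(
    channel_series: dict[str, np.ndarray],
    montage: Montage,
    retained: list[str] | None = None,
    fs: float | None = None,
    chromophore: str = "hbo",
    segment: str = "resting",
) -> RoiTimeSeries:
    """Unweighted mean of retained member channels per ROI.

    ROIs whose channels were all excluded by QC are dropped from the output
    and listed in ``dropped_rois`` (a warning condition propagated to the
    run report rather than an error).
    """
    retained_set = set(retained) if retained is not None else set(channel_series)
    unknown = retained_set - set(channel_series)
    if unknown:
        raise ValueError(f"retained channels missing from data: {sorted(unknown)}")
    cols: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    dropped: list[str] = []
    for roi in montage.rois:
        members = [
            ch for ch in montage.roi_channels[roi]
            if ch in retained_set and ch in channel_series
        ]
        if not members:
            dropped.append(roi)
            continue
        cols[roi] = np.mean([channel_series[ch] for ch in members], axis=0)
        counts[roi] = len(members)
    if not cols:
        raise ValueError("every ROI lost all channels; nothing to average")
    return RoiTimeSeries(
        data=pd.DataFrame(cols),
        fs=fs if fs is not None else montage.fs_hz,
        chromophore=chromophore,
        segment=segment,
        retained_channels=counts,
        dropped_rois=dropped,
    )
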