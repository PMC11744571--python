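"""Forward model for two-wavelength fNIRS intensity recordings.

The latent cortical signal is a stable vector autoregression over the nine
ROIs (the ground-truth effective-connectivity network).  Task blocks add a
canonical-HRF-convolved boxcar response to the active ROIs.  The ROI HbO
series (µM) are copied to member channels with independent channel noise,
HbR is a scaled anticorrelated copy, both are projected to 760/850 nm
optical densities through the forward Beer-Lambert relation, and
physiological nuisance (cardiac, respiratory, Mayer waves, linear drift,
white noise) is added in OD space before converting to light intensities.
Running the package's inverse pipeline on a noise-free recording recovers
the latent concentrations exactly (up to the unobservable mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..fnirs.mbll import MbllParams, hemoglobin_to_od
from ..fnirs.montage import Montage, default_montage
from ..glm import canonical_hrf

__all__ = [
    "VarGroundTruth",
    "NoiseProfile",
    "FnirsRecording",
    "generate_fnirs_recording",
    "default_ground_truth",
]

STREAM_FNIRS = 5
HBR_RATIO = -0.35  # HbR tracks HbO with inverted sign and reduced amplitude


class StationarityError(ValueError):
    """The ground-truth VAR is not stable."""


@dataclass
class VarGroundTruth:
    """Latent VAR network: per-lag coefficient tensor and innovation SDs."""

    coefs: np.ndarray  # (p, n, n); coefs[l, i, j]: x_j(t-l-1) -> x_i(t)
    innovation_sd: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.coefs.ndim == 2:
            self.coefs = self.coefs[None]
        self.innovation_sd = np.broadcast_to(
            np.asarray(self.innovation_sd, dtype=float), (self.n_nodes,)
        ).copy()
        if (self.innovation_sd < 0).any():
            raise ValueError("innovation SDs must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.coefs.shape[1]

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        """Directed true couplings (source, target), excluding self-lags."""
        edges = set()
        for l in range(self.order):
            src, tgt = np.nonzero(self.coefs[l].T)
            for s, t in zip(src, tgt):
                if s != t:
                    edges.add((int(s), int(t)))
        return edges

    @property
    def spectral_radius(self) -> float:
        p, n = self.order, self.n_nodes
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coefs), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    @property
    def stable(self) -> bool:
        return self.spectral_radius < 1

    def simulate(self, n_samples: int, rng: np.random.Generator,
                 burn_in: int = 200) -> np.ndarray:
        if not self.stable:
            raise StationarityError(
                f"ground-truth VAR spectral radius {self.spectral_radius:.3f} >= 1"
            )
        p, n = self.order, self.n_nodes
        total = n_samples + burn_in
        innov = rng.standard_normal((total, n)) * self.innovation_sd
        x = np.zeros((total, n))
        for t in range(total):
            acc = innov[t].copy()
            for l in range(min(p, t)):
                acc += self.coefs[l] @ x[t - l - 1]
            x[t] = acc
        return x[burn_in:]


@dataclass
class NoiseProfile:
    """Physiological and instrumental nuisance amplitudes (OD units)."""

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.01
    respiration_hz: float = 0.3
    respiration_amp: float = 0.005
    mayer_hz: float = 0.1
    mayer_amp: float = 0.005
    drift_od_per_min: float = 0.002
    white_od_sd: float = 0.002
    channel_white_um: float = 0.01  # concentration-space channel noise (µM)

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiration_amp", "mayer_amp",
                     "white_od_sd", "channel_white_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cardiac_hz", "respiration_hz", "mayer_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def silent(cls) -> "NoiseProfile":
        return cls(cardiac_amp=0.0, respiration_amp=0.0, mayer_amp=0.0,
                   drift_od_per_min=0.0, white_od_sd=0.0, channel_white_um=0.0)


@dataclass
class FnirsRecording:
    """A synthetic two-wavelength recording plus its ground truth."""

    intensity: np.ndarray  # (n_channels, 2, T)
    channel_names: list[str]
    wavelengths_nm: tuple[int, int]
    fs: float
    montage: Montage
    latent_hbo: pd.DataFrame  # T x ROIs, µM (VAR + task response)
    latent_hbr: pd.DataFrame
    schedule: list[tuple[str, float, float]]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[-1]

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-matrix layout: time plus one column per channel/wavelength."""
        t = np.arange(self.n_samples) / self.fs
        cols = {"time_s": t}
        for i, ch in enumerate(self.channel_names):
            for w, wl in enumerate(self.wavelengths_nm):
                cols[f"{ch}_{wl}"] = self.intensity[i, w]
        return pd.DataFrame(cols)


def default_ground_truth(
    coupling: float = 0.25, n_nodes: int = 9, order: int = 1,
    innovation_sd: float = 0.05, seed: int = 0,
) -> VarGroundTruth:
    """A sparse stable 9-node network with a few directed couplings.

    Self-lags at 0.3 for smoothness; four planted directed edges
    (1->3, 4->7, 2->9, 4->1 in 1-based ROI numbering) echoing the kind of
    frontal-parietal interactions the task-based analysis reports.
    """
    coefs = np.zeros((order, n_nodes, n_nodes))
    coefs[0] = np.eye(n_nodes) * 0.3
    for src, tgt in ((0, 2), (3, 6), (1, 8), (3, 0)):
        if src < n_nodes and tgt < n_nodes:
            coefs[0, tgt, src] = coupling
    truth = VarGroundTruth(coefs=coefs, innovation_sd=np.full(n_nodes, innovation_sd))
    if not truth.stable:
        raise StationarityError("default ground truth unstable; lower coupling")
    return truth


def generate_fnirs_recording(
    truth: VarGroundTruth,
    task_design: list[tuple[str, float, float]] | None = None,
    noise: NoiseProfile | None = None,
    duration_s: float = 300.0,
    fs: float = 10.2,
    seed: int = 0,
    montage: Montage | None = None,
    roi_amplitudes: dict[str, float] | None = None,
    mbll_params: MbllParams | None = None,
) -> FnirsRecording:
    """Simulate a recording; see the module docstring for the forward model.

    ``task_design`` lists ``(block_type, onset_s, duration_s)`` task blocks
    (empty/None for resting state); ``roi_amplitudes`` maps ROI names to
    evoked HbO amplitudes in µM (default 0.2 µM for frontal ROIs).
    """
    noise = noise or NoiseProfile()
    montage = montage or default_montage()
    mbll = mbll_params or MbllParams(distance_cm=montage.distance_cm)
    if fs <= 2 * noise.cardiac_hz:
        raise ValueError(
            f"fs={fs} Hz aliases the {noise.cardiac_hz} Hz cardiac component"
        )
    if duration_s < 60:
        raise ValueError("recordings must be at least 60 s long")
    if truth.n_nodes != len(montage.rois):
        raise ValueError(
            f"ground truth has {truth.n_nodes} nodes but montage has "
            f"{len(montage.rois)} ROIs"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAM_FNIRS,)))
    n_samples = int(round(duration_s * fs))
    rois = montage.rois

    hbo = truth.simulate(n_samples, rng)  # (T, n) µM
    schedule = list(task_design or [])
    if schedule:
        amps = roi_amplitudes or {
            r: 0.2 for r in rois if "frontal" in r
        }
        hrf = canonical_hrf(np.arange(0, 32.0, 1.0 / fs))
        boxcar = np.zeros(n_samples)
        for _, onset, dur in schedule:
            i0 = int(round(onset * fs))
            i1 = int(round((onset + dur) * fs))
            if i0 < 0 or i1 > n_samples:
                raise ValueError("task block exceeds the recording span")
            boxcar[i0:i1] = 1.0
        response = np.convolve(boxcar, hrf)[:n_samples] / fs
        for j, roi in enumerate(rois):
            hbo[:, j] += amps.get(roi, 0.0) * response
    hbr = HBR_RATIO * hbo

    channels = montage.channels
    n_ch = len(channels)
    od = np.empty((n_ch, 2, n_samples))
    t = np.arange(n_samples) / fs
    for i, ch in enumerate(channels):
        roi_idx = rois.index(montage.roi_of(ch))
        ch_hbo = hbo[:, roi_idx] + noise.channel_white_um * rng.standard_normal(
            n_samples
        )
        ch_hbr = hbr[:, roi_idx] + noise.channel_white_um * rng.standard_normal(
            n_samples
        )
        od_i = hemoglobin_to_od(ch_hbo, ch_hbr, mbll)  # (2, T)
        systemic = np.zeros(n_samples)
        for freq, amp in (
            (noise.cardiac_hz, noise.cardiac_amp),
            (noise.respiration_hz, noise.respiration_amp),
            (noise.mayer_hz, noise.mayer_amp),
        ):
            if amp > 0:
                systemic += amp * np.sin(
                    2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
                )
        systemic += noise.drift_od_per_min * (t / 60.0) * rng.normal(0.0, 1.0)
        od_i = od_i + systemic
        if noise.white_od_sd > 0:
            od_i = od_i + noise.white_od_sd * rng.standard_normal(od_i.shape)
        od[i] = od_i
    i0 = rng.uniform(0.5, 2.0, size=(n_ch, 1, 1))
    intensity = i0 * np.power(10.0, -od)
    return FnirsRecording(
        intensity=intensity,
        channel_names=channels,
        wavelengths_nm=mbll.wavelengths_nm,
        fs=fs,
        montage=montage,
        latent_hbo=pd.DataFrame(hbo, columns=rois),
        latent_hbr=pd.DataFrame(hbr, columns=rois),
        schedule=schedule,
    )
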