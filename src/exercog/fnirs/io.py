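"""CSV-matrix I/O for two-wavelength intensity recordings.

The on-disk layout is one wide CSV: a ``time_s`` column plus one column
per channel/wavelength named ``<channel>_<wavelength>`` (e.g. ``C10_760``).
The montage travels separately as YAML (see :class:`~exercog.fnirs.montage.Montage`).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["write_intensity_csv", "read_intensity_csv"]

_COL_RE = re.compile(r"^(?P<ch>.+)_(?P<wl>\d{3,4})$")


def write_intensity_csv(
    intensity: np.ndarray,
    channel_names: list[str],
    wavelengths_nm: tuple[int, int],
    fs: float,
    path,
) -> None:
    """Write an (n_channels, n_wavelengths, T) intensity array."""
    t = np.arange(intensity.shape[-1]) / fs
    cols = {"time_s": t}
    for i, ch in enumerate(channel_names):
        for w, wl in enumerate(wavelengths_nm):
            cols[f"{ch}_{wl}"] = intensity[i, w]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")


def read_intensity_csv(path) -> tuple[np.ndarray, list[str], tuple[int, ...], float]:
    """Read a recording; returns (intensity, channels, wavelengths, fs)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("recording CSV must contain a time_s column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("recording too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    parsed = []
    for col in df.columns:
        if col == "time_s":
            continue
        m = _COL_RE.match(col)
        if not m:
            raise ValueError(f"cannot parse channel column {col!r}")
        parsed.append((m["ch"], int(m["wl"]), col))
    channels = list(dict.fromkeys(ch for ch, _, _ in parsed))
    wavelengths = tuple(sorted({wl for _, wl, _ in parsed}))
    inten = np.empty((len(channels), len(wavelengths), len(df)))
    for ch, wl, col in parsed:
        inten[channels.index(ch), wavelengths.index(wl)] = df[col].to_numpy()
    return inten, channels, wavelengths, fs
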