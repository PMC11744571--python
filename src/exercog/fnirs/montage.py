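"""Channel montage and region-of-interest (ROI) layout.

The packaged default montage reflects a 16-source / 16-detector prefrontal-
parietal layout sampled at 10.2 Hz with ~3 cm inter-optode separation and
760/850 nm sources, grouped into nine ROIs:

==== ======================== ==========
ROI  name                     channels
==== ======================== ==========
1    medial frontal           3
2    left superior frontal    8
3    left middle frontal      5
4    left precentral          3
5    left parietal            7
6    right superior frontal   8
7    right middle frontal     5
8    right precentral         3
9    right parietal           7
==== ======================== ==========

Every analysis channel maps to exactly one ROI; channels absent from the
ROI lists are treated as unassigned and ignored by ROI averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["Montage", "default_montage", "ROI_CHANNELS", "ROI_NAMES"]

ROI_NAMES = [
    "medial_frontal",
    "left_superior_frontal",
    "left_middle_frontal",
    "left_precentral",
    "left_parietal",
    "right_superior_frontal",
    "right_middle_frontal",
    "right_precentral",
    "right_parietal",
]

ROI_CHANNELS: dict[str, list[str]] = {
    "medial_frontal": ["C10", "C12", "C14"],
    "left_superior_frontal": ["C2", "C7", "C8", "C9", "C13", "C37", "C39", "C40"],
    "left_middle_frontal": ["C1", "C3", "C4", "C5", "C6"],
    "left_precentral": ["C38", "C47", "C48"],
    "left_parietal": ["C41", "C42", "C43", "C44", "C45", "C46", "C49"],
    "right_superior_frontal": ["C11", "C15", "C16", "C17", "C19", "C31", "C32", "C34"],
    "right_middle_frontal": ["C18", "C20", "C21", "C22", "C23"],
    "right_precentral": ["C24", "C26", "C33"],
    "right_parietal": ["C25", "C27", "C28", "C29", "C30", "C35", "C36"],
}


@dataclass
class Montage:
    """Channel layout: ROI membership, optode geometry, wavelengths."""

    roi_channels: dict[str, list[str]]
    distance_cm: float = 3.0
    wavelengths_nm: tuple[int, int] = (760, 850)
    fs_hz: float = 10.2

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for roi, chans in self.roi_channels.items():
            for ch in chans:
                if ch in seen:
                    raise ValueError(
                        f"channel {ch} assigned to both {seen[ch]} and {roi}"
                    )
                seen[ch] = roi
        if self.distance_cm <= 0:
            raise ValueError("inter-optode distance must be positive")

    @property
    def rois(self) -> list[str]:
        return list(self.roi_channels)

    @property
    def channels(self) -> list[str]:
        return [ch for chans in self.roi_channels.values() for ch in chans]

    def roi_of(self, channel: str) -> str | None:
        for roi, chans in self.roi_channels.items():
            if channel in chans:
                return roi
        return None

    def to_yaml(self, path) -> None:
        payload = {
            "roi_channels": self.roi_channels,
            "distance_cm": self.distance_cm,
            "wavelengths_nm": list(self.wavelengths_nm),
            "fs_hz": self.fs_hz,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["wavelengths_nm"] = tuple(payload["wavelengths_nm"])
        return cls(**payload)


def default_montage() -> Montage:
    """The packaged nine-ROI montage (10.2 Hz, 3 cm, 760/850 nm)."""
    return Montage(roi_channels={k: list(v) for k, v in ROI_CHANNELS.items()})
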