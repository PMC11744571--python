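"""Optical density and the modified Beer-Lambert law (MBLL).

Continuous-wave fNIRS measures light intensity attenuation at two
wavelengths.  Changes in optical density relative to the recording mean,

    dOD(t) = -log10( I(t) / mean_t I ),

are linearly related to changes in oxy-/deoxyhemoglobin concentration via

    dOD(lambda) = ( eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR ) * d * DPF,

where ``eps`` are molar extinction coefficients (1/(mM cm)), ``d`` the
inter-optode distance (cm) and ``DPF`` the differential pathlength factor
(dimensionless, 6 here).  Inverting the 2x2 extinction system per sample
yields concentration changes; because the reference is the recording mean,
absolute baselines are unobservable and all outputs are changes (µM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EXTINCTION_COEFFS",
    "MbllParams",
    "intensity_to_od",
    "od_to_hemoglobin",
    "hemoglobin_to_od",
]

# Molar extinction coefficients in 1/(mM cm), compiled from the W.B. Gratzer
# / M. Cope spectra that CW-NIRS toolchains conventionally use.  Overridable
# through MbllParams.
EXTINCTION_COEFFS: dict[int, dict[str, float]] = {
    760: {"hbo": 1.4866, "hbr": 3.8437},
    850: {"hbo": 2.5264, "hbr": 1.7986},
}


@dataclass
class MbllParams:
    """Constants of the MBLL inversion."""

    dpf: float = 6.0
    distance_cm: float = 3.0
    wavelengths_nm: tuple[int, int] = (760, 850)
    extinction: dict[int, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.dpf <= 0:
            raise ValueError("differential pathlength factor must be positive")
        if self.distance_cm <= 0:
            raise ValueError("inter-optode distance must be positive")
        if self.extinction is None:
            self.extinction = {
                wl: dict(EXTINCTION_COEFFS[wl]) for wl in self.wavelengths_nm
            }
        cond = np.linalg.cond(self.extinction_matrix)
        if not np.isfinite(cond) or cond >= 100:
            raise ValueError(
                f"extinction matrix is ill-conditioned (cond={cond:.3g}); "
                "wavelength pair cannot separate HbO from HbR"
            )

    @property
    def extinction_matrix(self) -> np.ndarray:
        """(n_wavelengths x 2) matrix E with columns (HbO, HbR)."""
        return np.array(
            [
                [self.extinction[wl]["hbo"], self.extinction[wl]["hbr"]]
                for wl in self.wavelengths_nm
            ]
        )


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical-density change relative to the per-channel temporal mean.

    ``intensity`` has time on the last axis (any leading channel/wavelength
    axes); all values must be strictly positive.
    """
    inten = np.asarray(intensity, dtype=float)
    bad = ~(inten > 0)
    if bad.any():
        where = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at index {tuple(int(i) for i in where)}"
        )
    ref = inten.mean(axis=-1, keepdims=True)
    return -np.log10(inten / ref)


def od_to_hemoglobin(
    od: np.ndarray, params: MbllParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL: OD changes -> (dHbO, dHbR) in µM.

    ``od`` has shape ``(..., n_wavelengths, T)`` with the wavelength axis
    ordered as ``params.wavelengths_nm``.
    """
    params = params or MbllParams()
    od = np.asarray(od, dtype=float)
    n_wl = len(params.wavelengths_nm)
    if od.shape[-2] != n_wl:
        raise ValueError(
            f"expected {n_wl} wavelengths on axis -2, got shape {od.shape}"
        )
    e_inv = np.linalg.inv(params.extinction_matrix)
    # concentrations in mM, scaled to µM
    conc = np.einsum("cw,...wt->...ct", e_inv, od) / (
        params.distance_cm * params.dpf
    )
    conc_um = conc * 1e3
    return conc_um[..., 0, :], conc_um[..., 1, :]


def hemoglobin_to_od(
    hbo_um: np.ndarray, hbr_um: np.ndarray, params: MbllParams | None = None
) -> np.ndarray:
    """Forward MBLL: concentration changes (µM) -> OD changes.

    Exact inverse of :func:`od_to_hemoglobin`; used by the synthetic forward
    model and for round-trip checks.
    """
    params = params or MbllParams()
    conc_mm = np.stack([np.asarray(hbo_um), np.asarray(hbr_um)], axis=-2) * 1e-3
    return np.einsum(
        "wc,...ct->...wt", params.extinction_matrix, conc_mm
    ) * (params.distance_cm * params.dpf)
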