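"""Summary calibers of the retinal microvasculature.

The central retinal arteriolar equivalent (CRAE) and central retinal venular
equivalent (CRVE) condense the widths of the six largest arterioles and six
largest venules crossing a peripapillary measurement zone into a single
caliber per vessel type, using the revised Knudtson/Parr-Hubbard formulas.
Two branches of width ``w1`` and ``w2`` are combined into the equivalent
caliber of their parent trunk as ``k * sqrt(w1**2 + w2**2)``, with branching
coefficient ``k = 0.88`` for arterioles and ``k = 0.95`` for venules.  The
list of measured widths is reduced iteratively -- largest paired with
smallest, middle element carried when the count is odd -- until one value
remains.  The arteriole-to-venule ratio (AVR) is CRAE/CRVE and is
dimensionless; a lower AVR indicates relative arteriolar narrowing.

Widths are expected in micrometers (µm), although the formulas are
scale-equivariant so any consistent unit works.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "K_ARTERIOLE",
    "K_VENULE",
    "VesselMeasurementSet",
    "RetinalIndices",
    "pair_equivalent",
    "iterative_reduce",
    "compute_indices",
    "indices_table",
    "icc_agreement",
]

#: Branching coefficients linking parent trunk calibers to branch calibers.
K_ARTERIOLE = 0.88
K_VENULE = 0.95

#: Standard number of vessels of each type entering the calculation.
STANDARD_VESSEL_COUNT = 6


class IncompleteMeasurementError(ValueError):
    """Raised when a measurement set lacks arterioles or venules entirely."""


@dataclass
class VesselMeasurementSet:
    """Widths of the largest arterioles and venules for one eye/timepoint.

    The standard grading protocol measures exactly six vessels of each type;
    fewer are tolerated (a quality flag is set on the output) but at least
    one of each type is required.
    """

    arteriole_widths: list[float]
    venule_widths: list[float]
    subject: str | None = None
    condition: str | None = None
    timepoint: str | None = None
    eye: str = "right"

    def __post_init__(self) -> None:
        for name in ("arteriole_widths", "venule_widths"):
            widths = [float(w) for w in getattr(self, name)]
            if any(w <= 0 or not math.isfinite(w) for w in widths):
                raise ValueError(f"{name} must be positive and finite, got {widths}")
            setattr(self, name, widths)


@dataclass
class RetinalIndices:
    """CRAE/CRVE (µm) and the AVR under a recorded ratio convention."""

    crae: float
    crve: float
    avr: float
    avr_convention: str = "standard"
    quality_flag: bool = False
    n_arterioles: int = STANDARD_VESSEL_COUNT
    n_venules: int = STANDARD_VESSEL_COUNT


def pair_equivalent(w1: float, w2: float, k: float) -> float:
    """Caliber of the parent trunk implied by two branch widths.

    Parameters
    ----------
    w1, w2 : float
        Branch widths (µm), strictly positive.
    k : float
        Branching coefficient (0.88 arterioles, 0.95 venules).
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"vessel widths must be positive, got ({w1}, {w2})")
    return k * math.hypot(w1, w2)


def iterative_reduce(widths, k: float) -> float:
    """Reduce a list of vessel widths to a single central equivalent.

    Each round sorts the current values, pairs the largest with the smallest
    (second largest with second smallest, and so on) through
    :func:`pair_equivalent`, and carries the middle value forward unpaired
    when the count is odd.  Rounds repeat until one value remains.  A
    single-element input is returned unchanged.
    """
    current = sorted(float(w) for w in widths)
    if not current:
        raise ValueError("at least one vessel width is required")
    if any(w <= 0 for w in current):
        raise ValueError("vessel widths must be positive")
    while len(current) > 1:
        nxt = []
        n = len(current)
        for i in range(n // 2):
            nxt.append(pair_equivalent(current[n - 1 - i], current[i], k))
        if n % 2 == 1:
            nxt.append(current[n // 2])
        current = sorted(nxt)
    return current[0]


def compute_indices(
    measurement: VesselMeasurementSet, convention: str = "standard"
) -> RetinalIndices:
    """CRAE, CRVE, and AVR for one measurement set.

    ``convention="standard"`` reports AVR = CRAE/CRVE (the
    arteriole-to-venule ratio); ``convention="paper_literal"`` reports
    CRVE/CRAE.  The convention used is recorded on the result.
    """
    if convention not in ("standard", "paper_literal"):
        raise ValueError(f"unknown AVR convention: {convention!r}")
    arts = measurement.arteriole_widths
    vens = measurement.venule_widths
    if not arts or not vens:
        raise IncompleteMeasurementError(
            "both arteriole and venule widths are required"
        )
    quality = len(arts) != STANDARD_VESSEL_COUNT or len(vens) != STANDARD_VESSEL_COUNT
    if quality:
        warnings.warn(
            f"non-standard vessel counts (A={len(arts)}, V={len(vens)}); "
            "indices computed with a quality flag",
            stacklevel=2,
        )
    crae = iterative_reduce(arts, K_ARTERIOLE)
    crve = iterative_reduce(vens, K_VENULE)
    avr = crae / crve if convention == "standard" else crve / crae
    return RetinalIndices(
        crae=crae,
        crve=crve,
        avr=avr,
        avr_convention=convention,
        quality_flag=quality,
        n_arterioles=len(arts),
        n_venules=len(vens),
    )


def indices_table(widths: pd.DataFrame, convention: str = "standard") -> pd.DataFrame:
    """Per-cell retinal indices from a long-format vessel-width table.

    Expects columns ``subject, condition, timepoint, vessel_type, width_um``
    with ``vessel_type`` in {"arteriole", "venule"}; returns one row per
    (subject, condition, timepoint) with crae/crve/avr and quality flag.
    """
    required = {"subject", "condition", "timepoint", "vessel_type", "width_um"}
    missing = required - set(widths.columns)
    if missing:
        raise ValueError(f"width table is missing columns: {sorted(missing)}")
    rows = []
    for (subj, cond, tp), grp in widths.groupby(
        ["subject", "condition", "timepoint"], sort=True
    ):
        m = VesselMeasurementSet(
            arteriole_widths=grp.loc[grp.vessel_type == "arteriole", "width_um"].tolist(),
            venule_widths=grp.loc[grp.vessel_type == "venule", "width_um"].tolist(),
            subject=str(subj),
            condition=str(cond),
            timepoint=str(tp),
        )
        idx = compute_indices(m, convention=convention)
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "timepoint": tp,
                "crae": idx.crae,
                "crve": idx.crve,
                "avr": idx.avr,
                "avr_convention": idx.avr_convention,
                "quality_flag": idx.quality_flag,
            }
        )
    return pd.DataFrame(rows)


def icc_agreement(replicates: np.ndarray | pd.DataFrame) -> float:
    """Two-way mixed, absolute-agreement, single-measure ICC, i.e. ICC(A,1).

    Parameters
    ----------
    replicates
        ``(n_subjects, k_raters)`` array (or DataFrame) of repeated gradings
        of the same index; at least two replicates per subject.

    Returns
    -------
    float
        ICC in [-1, 1]; 1 for identical replicates.

    Notes
    -----
    Mean-squares form of McGraw & Wong's ICC(A,1):
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects x replicates) table with >= 2 replicates")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:  # all values identical
        return 1.0
    return float((msr - mse) / denom)
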