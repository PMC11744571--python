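"""Synthetic retinal vessel widths with exact summary-caliber targets.

The generator works backwards from the quantity the pipeline estimates:
for each subject x condition x timepoint cell it draws a target CRAE and
CRVE (population mean + subject intercept + injected condition x time
effect + residual noise, all in µm), jitters a six-vessel width template
multiplicatively for realism, and rescales the template so that the
Knudtson iterative reduction of the emitted widths reproduces the target
exactly (the reduction is scale-equivariant).  The AVR is emergent.

Two design modes exist: ``"full"`` (SIT/MIC/VIC with the marginal-means
difference-in-differences of the profile) and ``"reduced"`` (a
two-condition sitting-vs-exercise design whose single condition x time
interaction equals the profile's ``interaction_um``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..retina import K_ARTERIOLE, K_VENULE, iterative_reduce
from .profiles import EffectProfile

__all__ = ["generate_vessel_widths", "REDUCED_CONDITIONS"]

STREAM_VESSELS = 2
TIMEPOINTS = ("pre", "post")
REDUCED_CONDITIONS = ("SIT", "EX")

# relative width templates for the six largest vessels of each type
_ARTERIOLE_TEMPLATE = np.array([0.78, 0.88, 0.95, 1.02, 1.10, 1.22])
_VENULE_TEMPLATE = np.array([0.80, 0.90, 0.97, 1.03, 1.10, 1.20])
_JITTER_LOG_SD = 0.05


def _cell_widths(
    rng: np.random.Generator, template: np.ndarray, k: float, target: float
) -> np.ndarray:
    jittered = template * np.exp(rng.normal(0.0, _JITTER_LOG_SD, size=len(template)))
    return jittered * (target / iterative_reduce(jittered, k))


def generate_vessel_widths(
    profile: EffectProfile,
    covariates: pd.DataFrame,
    seed: int = 0,
    design: str = "full",
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Long-format width table (6 arterioles + 6 venules per cell)."""
    ret = profile.retinal
    if design == "reduced":
        conditions = conditions or REDUCED_CONDITIONS
        shifts = {
            (c, "post"): {
                "crae": ret.interaction_um.get("crae", 0.0),
                "crve": ret.interaction_um.get("crve", 0.0),
            }
            for c in conditions
            if c != "SIT"
        }
    elif design == "full":
        conditions = conditions or ("SIT", "MIC", "VIC")
        shifts = {
            (c, "post"): dict(ret.dids.get(c, {}))
            for c in conditions
            if c in ret.dids
        }
    else:
        raise ValueError(f"unknown design: {design!r}")

    rows = []
    for subj_idx, row in enumerate(covariates.itertuples(index=False)):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(STREAM_VESSELS, subj_idx))
        )
        b_crae = rng.normal(0.0, ret.between_subject_sd_um)
        b_crve = rng.normal(0.0, ret.between_subject_sd_um)
        for condition in conditions:
            for timepoint in TIMEPOINTS:
                shift = shifts.get((condition, timepoint), {})
                target_crae = (
                    ret.crae_mean_um
                    + b_crae
                    + shift.get("crae", 0.0)
                    + rng.normal(0.0, ret.residual_sd_um)
                )
                target_crve = (
                    ret.crve_mean_um
                    + b_crve
                    + shift.get("crve", 0.0)
                    + rng.normal(0.0, ret.residual_sd_um)
                )
                arts = _cell_widths(rng, _ARTERIOLE_TEMPLATE, K_ARTERIOLE, target_crae)
                vens = _cell_widths(rng, _VENULE_TEMPLATE, K_VENULE, target_crve)
                for vt, widths in (("arteriole", arts), ("venule", vens)):
                    for w in widths:
                        rows.append(
                            {
                                "subject": row.subject,
                                "condition": condition,
                                "timepoint": timepoint,
                                "vessel_type": vt,
                                "width_um": float(w),
                            }
                        )
    return pd.DataFrame(rows)
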