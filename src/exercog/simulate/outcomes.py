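"""Direct per-cell generators for network-level summary outcomes.

Causal density enters the group-level models as one observation per
subject x condition x timepoint.  For effect-recovery experiments the
generator emits those observations directly as Gaussian cells (population
base + subject intercept + injected condition x time shift + residual),
which emulates the statistical structure of the pipeline's causal-density
estimates without the cost of simulating and re-estimating full
recordings.  Values are not clipped to [0, 1]: clipping would bias the
injected effects, and the Gaussian cell model is a statistical emulation
of the estimator's output, not a bounded density itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import CausalDensityParams, EffectProfile

__all__ = ["generate_causal_density_cells", "REDUCED_CONDITIONS"]

TIMEPOINTS = ("pre", "post")
REDUCED_CONDITIONS = ("SIT", "EX")
_STREAMS = {"resting": 3, "task": 4}


def generate_causal_density_cells(
    profile: EffectProfile,
    covariates: pd.DataFrame,
    state: str = "resting",
    seed: int = 0,
    design: str = "full",
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One causal-density observation per subject x condition x timepoint.

    ``state`` selects the resting-state or whole-task effect block of the
    profile; ``design`` works as in
    :func:`exercog.simulate.vessels.generate_vessel_widths`.
    """
    if state not in _STREAMS:
        raise ValueError(f"state must be 'resting' or 'task', got {state!r}")
    params: CausalDensityParams = (
        profile.cd_resting if state == "resting" else profile.cd_task
    )
    if design == "reduced":
        conditions = conditions or REDUCED_CONDITIONS
        shifts = {
            (c, "post"): params.interaction for c in conditions if c != "SIT"
        }
    elif design == "full":
        conditions = conditions or ("SIT", "MIC", "VIC")
        shifts = {
            (c, "post"): params.dids[c] for c in conditions if c in params.dids
        }
    else:
        raise ValueError(f"unknown design: {design!r}")

    rows = []
    for subj_idx, row in enumerate(covariates.itertuples(index=False)):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_STREAMS[state], subj_idx))
        )
        b_i = rng.normal(0.0, params.between_subject_sd)
        for condition in conditions:
            for timepoint in TIMEPOINTS:
                value = (
                    params.base
                    + b_i
                    + shifts.get((condition, timepoint), 0.0)
                    + rng.normal(0.0, params.residual_sd)
                )
                rows.append(
                    {
                        "subject": row.subject,
                        "condition": condition,
                        "timepoint": timepoint,
                        "state": state,
                        "causal_density": float(value),
                    }
                )
    return pd.DataFrame(rows)
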