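"""Trial-level generator for the dual-task Stroop blocks.

Each subject carries a lognormal speed multiplier (between-subject RT
heterogeneity) and a Beta-distributed error probability.  Per trial, RT is
lognormal (block-scaled median, truncated to the 200-3000 ms response
window) and correctness Bernoulli.  Condition x time effects are injected
at post-intervention cells: an additive ms shift for RT and a
multiplicative factor on the error probability, both derived from the
profile's z-unit effects by :mod:`exercog.simulate.calibration`.  The
congruency mix is exactly 50% congruent / 25% incongruent / 25% neutral
within every 12-trial sequence, and a fraction of error trials are
omissions (no keypress, no RT).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import BehavioralCalibration, calibrate_behavior
from .profiles import BLOCKS, EffectProfile

__all__ = ["generate_trials"]

STREAM_TRIALS = 1
TIMEPOINTS = ("pre", "post")
RT_WINDOW_MS = (200.0, 3000.0)


def _sequence_congruency(rng: np.random.Generator, n: int) -> np.ndarray:
    base = ["congruent"] * (n // 2) + ["incongruent"] * (n // 4) + ["neutral"] * (
        n - n // 2 - n // 4
    )
    arr = np.array(base)
    rng.shuffle(arr)
    return arr


def generate_trials(
    profile: EffectProfile,
    covariates: pd.DataFrame,
    conditions: tuple[str, ...] = ("SIT", "MIC", "VIC"),
    seed: int = 0,
    calibration: BehavioralCalibration | None = None,
) -> pd.DataFrame:
    """Generate the full trial table for every subject x condition x time.

    ``covariates`` must hold one row per subject with columns
    ``subject, sex, age, bmi`` (see :func:`exercog.simulate.study.generate_covariates`);
    sex is coded 0 = male, 1 = female.
    """
    beh = profile.behavioral
    cov = profile.covariates
    calib = calibration or calibrate_behavior(beh, cov)
    alpha, beta = beh.beta_params
    n_seq = beh.sequences_per_block
    n_per_seq = beh.trials_per_sequence
    mu_log = np.log(beh.rt_median_ms)

    frames = []
    for subj_idx, row in enumerate(covariates.itertuples(index=False)):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(STREAM_TRIALS, subj_idx))
        )
        u_i = (
            beh.rt_sex_effect_log * (row.sex - cov.female_prop)
            + beh.rt_age_effect_log_per_yr * (row.age - cov.age_mean)
            + rng.normal(0.0, calib.subject_resid_log_sd)
            - calib.log_center
        )
        p_i = rng.beta(alpha, beta)
        for condition in conditions:
            for timepoint in TIMEPOINTS:
                shifted = timepoint == "post" and condition in calib.delta_rt_ms
                gamma = calib.gamma_er[condition] if shifted else 1.0
                p_err = min(gamma * p_i, 1.0 - 1e-12)
                for block in BLOCKS:
                    delta = calib.delta_rt_ms[condition][block] if shifted else 0.0
                    scale = beh.block_rt_scale[block]
                    n_total = n_seq * n_per_seq
                    congruency = np.concatenate(
                        [_sequence_congruency(rng, n_per_seq) for _ in range(n_seq)]
                    )
                    correct = rng.random(n_total) >= p_err
                    rt = (
                        scale
                        * np.exp(mu_log + u_i + beh.rt_sigma_log * rng.standard_normal(n_total))
                        + delta
                    )
                    rt = np.clip(rt, *RT_WINDOW_MS)
                    omitted = (~correct) & (
                        rng.random(n_total) < beh.omission_fraction
                    )
                    rt[omitted] = np.nan
                    frames.append(
                        pd.DataFrame(
                            {
                                "subject": row.subject,
                                "condition": condition,
                                "timepoint": timepoint,
                                "block": block,
                                "sequence": np.repeat(
                                    np.arange(1, n_seq + 1), n_per_seq
                                ),
                                "trial": np.arange(1, n_total + 1),
                                "congruency": congruency,
                                "rt_ms": rt,
                                "correct": correct,
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True)
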