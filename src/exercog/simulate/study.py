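"""Whole-study generation: covariates, trials, vessels, densities, fNIRS.

One call produces every input of the downstream pipeline for an
``n_subjects`` x conditions x {pre, post} crossover, with the effect
profile's condition x time shifts injected.  The master seed is split into
independent per-subject, per-domain streams keyed by a counter scheme, so
regenerating any one subject (or domain) is independent of iteration
order, and identical (profile, seed) inputs reproduce bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import generate_trials
from .calibration import BehavioralCalibration, calibrate_behavior
from .fnirsgen import (
    FnirsRecording,
    NoiseProfile,
    VarGroundTruth,
    default_ground_truth,
    generate_fnirs_recording,
)
from .outcomes import generate_causal_density_cells
from .profiles import EffectProfile
from .vessels import generate_vessel_widths

__all__ = ["StudyDataset", "generate_covariates", "generate_study"]

STREAM_COV = 0
STREAM_FNIRS_STUDY = 7


@dataclass
class StudyDataset:
    """All synthetic inputs for one study run."""

    covariates: pd.DataFrame
    trials: pd.DataFrame
    vessel_widths: pd.DataFrame
    causal_density: pd.DataFrame
    profile_name: str
    seed: int
    conditions: tuple[str, ...]
    calibration: BehavioralCalibration
    fnirs: dict[tuple[str, str, str], FnirsRecording] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "profile": self.profile_name,
            "seed": self.seed,
            "n_subjects": len(self.covariates),
            "conditions": list(self.conditions),
            "n_trials": len(self.trials),
            "n_vessel_rows": len(self.vessel_widths),
            "n_cd_cells": len(self.causal_density),
            "n_fnirs_recordings": len(self.fnirs),
        }


def generate_covariates(profile: EffectProfile, seed: int = 0) -> pd.DataFrame:
    """Per-subject sex (0 = male, 1 = female), age (yr) and BMI (kg/m^2)."""
    cov = profile.covariates
    rows = []
    for i in range(profile.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(STREAM_COV, i))
        )
        rows.append(
            {
                "subject": f"S{i + 1:03d}",
                "sex": float(rng.random() < cov.female_prop),
                "age": float(rng.normal(cov.age_mean, cov.age_sd)),
                "bmi": float(max(rng.normal(cov.bmi_mean, cov.bmi_sd), 14.0)),
            }
        )
    return pd.DataFrame(rows)


def generate_study(
    profile: EffectProfile,
    seed: int = 0,
    conditions: tuple[str, ...] = ("SIT", "MIC", "VIC"),
    include_fnirs: bool = False,
    fnirs_duration_s: float = 120.0,
    fnirs_truth: VarGroundTruth | None = None,
    fnirs_noise: NoiseProfile | None = None,
) -> StudyDataset:
    """Generate the full study dataset for the given effect profile.

    fNIRS recordings (optional; they dominate run time) are resting-state
    segments whose VAR coupling is scaled up post-exercise, providing
    qualitatively -- not calibration-exactly -- enhanced connectivity; the
    calibrated causal-density observations come from
    :func:`generate_causal_density_cells`.
    """
    unknown = [c for c in conditions if c not in ("SIT", "MIC", "VIC", "EX")]
    if unknown:
        raise ValueError(f"unknown conditions: {unknown}")
    covariates = generate_covariates(profile, seed)
    calibration = calibrate_behavior(profile.behavioral, profile.covariates)
    trials = generate_trials(
        profile, covariates, conditions=conditions, seed=seed,
        calibration=calibration,
    )
    vessels = generate_vessel_widths(
        profile, covariates, seed=seed, design="full", conditions=conditions
    )
    cd = pd.concat(
        [
            generate_causal_density_cells(
                profile, covariates, state=state, seed=seed, design="full",
                conditions=conditions,
            )
            for state in ("resting", "task")
        ],
        ignore_index=True,
    )
    fnirs: dict[tuple[str, str, str], FnirsRecording] = {}
    if include_fnirs:
        base_truth = fnirs_truth or default_ground_truth()
        noise = fnirs_noise or NoiseProfile()
        for i, subject in enumerate(covariates["subject"]):
            for condition in conditions:
                for timepoint in ("pre", "post"):
                    boost = (
                        1.25
                        if timepoint == "post" and condition != "SIT"
                        else 1.0
                    )
                    truth = VarGroundTruth(
                        coefs=_boost_off_diagonal(base_truth.coefs, boost),
                        innovation_sd=base_truth.innovation_sd,
                    )
                    rec_seed = int(
                        np.random.SeedSequence(
                            seed,
                            spawn_key=(
                                STREAM_FNIRS_STUDY,
                                i,
                                conditions.index(condition),
                                0 if timepoint == "pre" else 1,
                            ),
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    fnirs[(subject, condition, timepoint)] = (
                        generate_fnirs_recording(
                            truth,
                            noise=noise,
                            duration_s=fnirs_duration_s,
                            seed=rec_seed,
                        )
                    )
    return StudyDataset(
        covariates=covariates,
        trials=trials,
        vessel_widths=vessels,
        causal_density=cd,
        profile_name=profile.name,
        seed=seed,
        conditions=tuple(conditions),
        calibration=calibration,
        fnirs=fnirs,
    )


def _boost_off_diagonal(coefs: np.ndarray, factor: float) -> np.ndarray:
    out = coefs.copy()
    for l in range(out.shape[0]):
        diag = np.diag(np.diag(out[l]))
        out[l] = diag + factor * (out[l] - diag)
    return out
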