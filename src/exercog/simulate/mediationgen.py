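"""Generator for mediation change-score triples (X, M, Y).

Emulates per-subject change scores -- exposure X (e.g. change in AVR),
mediator M (e.g. change in task-based causal density), outcome Y (e.g.
change in z-RT) -- from the structural model

    M = a X + e1,    Y = c' X + b M + e2,

with X standard normal and independent Gaussian noise of a common SD.
Optional small covariate effects (sex, age, BMI) are added to M and Y;
because the fitting stage adjusts for the same covariates, path recovery
is unaffected.  The generating total effect is c' + a*b by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import CovariateParams, MediationPaths

__all__ = ["generate_mediation_dataset"]

STREAM_MEDIATION = 6

# small covariate effects used when covariates=True
_COV_EFFECTS_M = {"sex": 0.05, "age": 0.01, "bmi": -0.01}
_COV_EFFECTS_Y = {"sex": -0.04, "age": 0.015, "bmi": 0.01}


def generate_mediation_dataset(
    paths: MediationPaths,
    n: int = 71,
    noise_sd: float | None = None,
    covariates: bool = True,
    seed: int = 0,
    covariate_params: CovariateParams | None = None,
) -> pd.DataFrame:
    """Tidy (subject, x, m, y, sex, age, bmi) table of n change scores."""
    if n < 10:
        raise ValueError(f"mediation generator requires n >= 10, got {n}")
    sd = paths.noise_sd if noise_sd is None else float(noise_sd)
    if sd <= 0:
        raise ValueError("noise_sd must be positive")
    cp = covariate_params or CovariateParams()
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STREAM_MEDIATION,))
    )
    sex = (rng.random(n) < cp.female_prop).astype(float)
    age = rng.normal(cp.age_mean, cp.age_sd, n)
    bmi = rng.normal(cp.bmi_mean, cp.bmi_sd, n)
    x = rng.standard_normal(n)
    m = paths.a * x + rng.normal(0.0, sd, n)
    y = paths.c_prime * x + paths.b * m + rng.normal(0.0, sd, n)
    if covariates:
        zc = {
            "sex": sex - cp.female_prop,
            "age": age - cp.age_mean,
            "bmi": bmi - cp.bmi_mean,
        }
        for name, eff in _COV_EFFECTS_M.items():
            m = m + eff * zc[name]
        for name, eff in _COV_EFFECTS_Y.items():
            y = y + eff * zc[name]
    return pd.DataFrame(
        {
            "subject": [f"S{i + 1:03d}" for i in range(n)],
            "x": x,
            "m": m,
            "y": y,
            "sex": sex,
            "age": age,
            "bmi": bmi,
        }
    )
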