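"""Effect-recovery experiments: generator -> pipeline -> estimate -> compare.

Each experiment generates synthetic data from the packaged effect profile,
runs the corresponding pipeline estimator over a set of seeds, and returns
seed-averaged estimates of the injected effects.  These are the package's
reproduction harness: the same functions back the acceptance script and
the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import LmmSpec, condition_did, emmeans_contrasts, fit_lmm
from .mediation import fit_mediation
from .retina import indices_table
from .simulate import (
    EffectProfile,
    generate_causal_density_cells,
    generate_covariates,
    generate_mediation_dataset,
    generate_study,
    generate_vessel_widths,
    paper_effects,
)
from .stroop import summarize_trials, zscore_measures

__all__ = [
    "mediation_recovery",
    "behavioral_recovery",
    "retinal_recovery",
    "causal_density_recovery",
]


def _interaction_coef(fit) -> float:
    """The single condition x time interaction coefficient (2x2 design)."""
    hits = [n for n in fit.coef.index if n.count("C(") == 2]
    if len(hits) != 1:
        raise ValueError(f"expected one interaction term, found {hits}")
    return float(fit.coef.loc[hits[0], "beta"])


def mediation_recovery(
    seeds,
    profile: EffectProfile | None = None,
    n: int = 71,
    noise_sd: float = 0.1,
    n_boot: int = 10_000,
) -> dict:
    """Fit the mediation stage on profile-generated change scores per seed.

    Returns seed means of the total, direct, and indirect effects, and
    whether the bias-corrected bootstrap CI of the indirect effect excluded
    zero in every seed.
    """
    profile = profile or paper_effects()
    totals, directs, indirects, sig = [], [], [], []
    for seed in seeds:
        df = generate_mediation_dataset(
            profile.mediation, n=n, noise_sd=noise_sd, seed=seed,
            covariate_params=profile.covariates,
        )
        res = fit_mediation(df, n_boot=n_boot, seed=seed)
        totals.append(res.c.estimate)
        directs.append(res.c_prime.estimate)
        indirects.append(res.indirect)
        sig.append(res.significant)
    return {
        "total": float(np.mean(totals)),
        "direct": float(np.mean(directs)),
        "indirect": float(np.mean(indirects)),
        "all_ci_exclude_zero": bool(all(sig)),
        "per_seed": {
            "total": totals, "direct": directs, "indirect": indirects,
        },
        "n": n,
    }


def behavioral_recovery(
    seeds,
    profile: EffectProfile | None = None,
    conditions: tuple[str, ...] = ("SIT", "MIC"),
) -> dict:
    """Score, z-score, and LMM-contrast the behavioral generator's output.

    Returns the seed-averaged (MIC - SIT) post-minus-pre marginal-means
    contrast for each z-scored measure.
    """
    profile = profile or paper_effects()
    out: dict[str, list[float]] = {"z_rt": [], "z_er": [], "z_ies": []}
    for seed in seeds:
        ds = generate_study(profile, seed=seed, conditions=conditions)
        z = zscore_measures(summarize_trials(ds.trials)).merge(
            ds.covariates, on="subject"
        )
        for measure in out:
            fit = fit_lmm(z, LmmSpec(outcome=measure))
            contrasts = emmeans_contrasts(fit)
            out[measure].append(condition_did(contrasts, "MIC", "SIT"))
    return {
        **{m: float(np.mean(v)) for m, v in out.items()},
        "per_seed": out,
        "n": profile.n_subjects,
    }


def retinal_recovery(seeds, profile: EffectProfile | None = None) -> dict:
    """Reduced-design CRAE/CRVE interaction recovery through Knudtson + LMM."""
    profile = profile or paper_effects()
    out: dict[str, list[float]] = {"crae": [], "crve": []}
    for seed in seeds:
        cov = generate_covariates(profile, seed=seed)
        widths = generate_vessel_widths(profile, cov, seed=seed, design="reduced")
        indices = indices_table(widths).merge(cov, on="subject")
        for index in out:
            fit = fit_lmm(indices, LmmSpec(outcome=index))
            out[index].append(_interaction_coef(fit))
    return {
        **{k: float(np.mean(v)) for k, v in out.items()},
        "per_seed": out,
        "n": profile.n_subjects,
    }


def causal_density_recovery(
    seeds, state: str = "resting", profile: EffectProfile | None = None
) -> dict:
    """Reduced-design causal-density interaction recovery through the LMM."""
    profile = profile or paper_effects()
    vals = []
    for seed in seeds:
        cov = generate_covariates(profile, seed=seed)
        cells = generate_causal_density_cells(
            profile, cov, state=state, seed=seed, design="reduced"
        ).merge(cov, on="subject")
        cells = cells.rename(columns={"causal_density": "cd"})
        fit = fit_lmm(cells, LmmSpec(outcome="cd"))
        vals.append(_interaction_coef(fit))
    return {
        "interaction": float(np.mean(vals)),
        "per_seed": vals,
        "n": profile.n_subjects,
    }
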