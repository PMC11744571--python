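"""Raw-scale calibration of the behavioral z-score effects.

The profile states condition x time effects in *z-score units* of the
scored measures (RT, ER, IES), while the generator works at the trial
level (lognormal RTs with a lognormal subject speed multiplier, Bernoulli
errors with a Beta-distributed subject error probability).  A z-unit shift
``theta`` translates to a raw shift ``theta * S``, where ``S`` is the
standard deviation of the normalisation pool -- all subjects'
pre-intervention cell summaries for that measure and block.  This module
computes those pool moments exactly (numerical integration over the Beta
error mixture and the binomial trial count; closed forms for the lognormal
parts) and solves for the one free variance parameter.

Why a solve is needed: IES = RT / (1 - ER) is a deterministic function of
the other two measures, so the triple of injected z-effects (rt, er, ies)
cannot be chosen independently.  Injecting the RT effect (additive, ms)
and the ER effect (multiplicative on the subject error probability) fixes
the IES shift in ms; what remains free is how that shift *scales* to
z-units, which depends on the between-subject RT spread.
:func:`calibrate_behavior` solves for the subject log-variance that makes
the implied z-IES effect of the calibration condition equal its profile
value.  Other conditions' RT and ER effects are honored exactly; their
IES effects are emergent and reported back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .profiles import BehavioralParams, CovariateParams, ProfileError

__all__ = ["BehavioralCalibration", "calibrate_behavior", "error_moments"]

_GRID = 801  # Beta-mixture integration grid


@dataclass
class ErrorMoments:
    """Moments of one cell's error rate / correct count under the mixture.

    ER = K/n with K ~ Binomial(n, gamma * p), p ~ Beta(alpha, beta);
    W = 1/(1-ER) and n_corr = n - K (the all-error cell K = n carries
    negligible mass and is excluded from the W moments).
    """

    e_er: float
    var_er: float
    e_w: float
    e_w2: float
    e_inv_ncorr: float
    e_w2_inv_ncorr: float


def error_moments(
    alpha: float, beta: float, n_trials: int, gamma: float = 1.0
) -> ErrorMoments:
    if gamma <= 0:
        raise ProfileError(
            f"error-rate multiplier must stay positive, got gamma={gamma:.4f}; "
            "the requested z-ER effect is too large for the error-rate model"
        )
    p = np.linspace(0.0, 1.0, _GRID)[1:-1]
    w = stats.beta.pdf(p, alpha, beta)
    w = w / np.trapezoid(w, p)
    q = np.minimum(gamma * p, 1.0 - 1e-12)
    k = np.arange(n_trials + 1)
    pmf = stats.binom.pmf(k[None, :], n_trials, q[:, None])  # (grid, n+1)

    def mix(vals: np.ndarray, upto: int) -> float:
        inner = pmf[:, :upto] @ vals[:upto]
        return float(np.trapezoid(w * inner, p))

    er = k / n_trials
    e_er = mix(er, n_trials + 1)
    e_er2 = mix(er**2, n_trials + 1)
    with np.errstate(divide="ignore"):
        wk = np.where(k < n_trials, n_trials / (n_trials - k), 0.0)
        invn = np.where(k < n_trials, 1.0 / (n_trials - k), 0.0)
    return ErrorMoments(
        e_er=e_er,
        var_er=e_er2 - e_er**2,
        e_w=mix(wk, n_trials),
        e_w2=mix(wk**2, n_trials),
        e_inv_ncorr=mix(invn, n_trials),
        e_w2_inv_ncorr=mix(wk**2 * invn, n_trials),
    )


@dataclass
class BehavioralCalibration:
    """Raw-scale injection parameters implied by a behavioral profile."""

    s_er: float  # pool SD of cell error rate
    s_rt_ms: dict[str, float]  # pool SD of cell mean RT, per block
    s_ies_ms: dict[str, float]  # pool SD of cell IES, per block
    sigma_u2: float  # subject speed-multiplier log-variance (total)
    subject_resid_log_sd: float  # after removing covariate contributions
    log_center: float  # kappa such that E[exp(u)] = 1
    delta_rt_ms: dict[str, dict[str, float]]  # condition -> block -> ms shift
    gamma_er: dict[str, float]  # condition -> error-probability multiplier
    implied_z_ies: dict[str, float]  # condition -> z-IES DiD in expectation
    trial_mean_ms: dict[str, float]
    trial_var_ms2: dict[str, float]


def _trial_moments(beh: BehavioralParams) -> tuple[dict, dict]:
    mu = np.log(beh.rt_median_ms)
    s2 = beh.rt_sigma_log**2
    m1, v1 = {}, {}
    for block, scale in beh.block_rt_scale.items():
        m1[block] = scale * np.exp(mu + s2 / 2)
        v1[block] = scale**2 * (np.exp(s2) - 1) * np.exp(2 * mu + s2)
    return m1, v1


def _covariate_log_variance(beh: BehavioralParams, cov: CovariateParams) -> float:
    pq = cov.female_prop * (1 - cov.female_prop)
    return beh.rt_sex_effect_log**2 * pq + (
        beh.rt_age_effect_log_per_yr * cov.age_sd
    ) ** 2


def _log_center(beh: BehavioralParams, cov: CovariateParams, resid_var: float) -> float:
    """kappa with E[exp(covariate part + N(0, resid))] = exp(kappa)."""
    p = cov.female_prop
    bs = beh.rt_sex_effect_log
    sex_mgf = np.exp(-bs * p) * (1 - p + p * np.exp(bs))
    age_mgf = np.exp((beh.rt_age_effect_log_per_yr * cov.age_sd) ** 2 / 2)
    return float(np.log(sex_mgf) + np.log(age_mgf) + resid_var / 2)


def calibrate_behavior(
    beh: BehavioralParams, cov: CovariateParams
) -> BehavioralCalibration:
    """Solve the pool moments and return raw-scale injection parameters."""
    alpha, beta = beh.beta_params
    n = beh.trials_per_block
    base = error_moments(alpha, beta, n, gamma=1.0)
    s_er = float(np.sqrt(base.var_er))
    m1, v1 = _trial_moments(beh)
    blocks = list(beh.block_rt_scale)
    covvar = _covariate_log_variance(beh, cov)

    theta = beh.dids.get(beh.calibration_condition, {})
    th_rt = float(theta.get("rt", 0.0))
    th_er = float(theta.get("er", 0.0))
    th_ies = float(theta.get("ies", 0.0))

    def gamma_for(t_er: float) -> float:
        return 1.0 + t_er * s_er / base.e_er

    def pool_sds(sigma_u2: float) -> tuple[dict, dict]:
        eu = np.exp(sigma_u2)
        s_rt = {
            b: float(np.sqrt(m1[b] ** 2 * (eu - 1) + eu * v1[b] * base.e_inv_ncorr))
            for b in blocks
        }
        s_ies = {
            b: float(
                np.sqrt(
                    eu * (m1[b] ** 2 * base.e_w2 + v1[b] * base.e_w2_inv_ncorr)
                    - m1[b] ** 2 * base.e_w**2
                )
            )
            for b in blocks
        }
        return s_rt, s_ies

    def implied_ies(sigma_u2: float, t_rt: float, t_er: float) -> float:
        mg = error_moments(alpha, beta, n, gamma=gamma_for(t_er))
        s_rt, s_ies = pool_sds(sigma_u2)
        zs = []
        for b in blocks:
            delta = t_rt * s_rt[b]
            d_ies = (m1[b] + delta) * mg.e_w - m1[b] * base.e_w
            zs.append(d_ies / s_ies[b])
        return float(np.mean(zs))

    if th_rt == 0.0 and th_er == 0.0 and th_ies == 0.0:
        sigma_u2 = 0.25**2  # ~25% between-subject speed spread
    else:
        lo, hi = 1e-8, 4.0
        f_lo = implied_ies(lo, th_rt, th_er) - th_ies
        f_hi = implied_ies(hi, th_rt, th_er) - th_ies
        if f_lo * f_hi > 0:
            raise ProfileError(
                "behavioral.dids: the (rt, er, ies) z-effect triple for "
                f"{beh.calibration_condition} is unattainable; the implied "
                f"z-IES effect ranges ({f_hi + th_ies:.3f}, {f_lo + th_ies:.3f})"
            )
        sigma_u2 = optimize.brentq(
            lambda s: implied_ies(s, th_rt, th_er) - th_ies, lo, hi, xtol=1e-10
        )

    resid_var = sigma_u2 - covvar
    if resid_var <= 0:
        raise ProfileError(
            "covariate RT effects exceed the calibrated between-subject variance"
        )

    s_rt_ms, s_ies_ms = pool_sds(sigma_u2)
    delta_rt: dict[str, dict[str, float]] = {}
    gamma_er: dict[str, float] = {}
    implied: dict[str, float] = {}
    for cond, d in beh.dids.items():
        t_rt = float(d.get("rt", 0.0))
        t_er = float(d.get("er", 0.0))
        delta_rt[cond] = {b: t_rt * s_rt_ms[b] for b in blocks}
        gamma_er[cond] = gamma_for(t_er)
        implied[cond] = implied_ies(sigma_u2, t_rt, t_er)
    return BehavioralCalibration(
        s_er=s_er,
        s_rt_ms=s_rt_ms,
        s_ies_ms=s_ies_ms,
        sigma_u2=float(sigma_u2),
        subject_resid_log_sd=float(np.sqrt(resid_var)),
        log_center=_log_center(beh, cov, resid_var),
        delta_rt_ms=delta_rt,
        gamma_er=gamma_er,
        implied_z_ies=implied,
        trial_mean_ms={b: float(m1[b]) for b in blocks},
        trial_var_ms2={b: float(v1[b]) for b in blocks},
    )
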