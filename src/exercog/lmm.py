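"""Linear mixed models, marginal-means contrasts, and assumption checks.

Every outcome of the crossover study (behavioral z-scores, retinal
calibers, activation betas, causal density) is modelled as

    y ~ condition * timepoint [* block] + sex + age + bmi + (1 | subject)

with maximum-likelihood estimation, treatment coding, and the reference
levels sitting-control / pre-intervention / baseline-block, so interaction
coefficients read directly as difference-in-differences (DiD).  Post-hoc
condition contrasts are computed on the estimated-marginal-means grid
(model-implied cell means with covariates at their sample means) as
post-minus-pre differences between conditions, FDR-adjusted within the
contrast family of one outcome.

Assumption diagnostics (Shapiro-Wilk normality, Breusch-Pagan
homoscedasticity, Durbin-Watson independence) run on the conditional
residuals; failures trigger a variance-stabilising transformation refit
and, if still failing, subject-level bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.formula.api import mixedlm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_lmm",
    "emmeans_contrasts",
    "condition_did",
    "check_assumptions",
    "fit_with_remediation",
]


@dataclass
class LmmSpec:
    """Model specification for one outcome."""

    outcome: str
    condition_ref: str = "SIT"
    timepoint_ref: str = "pre"
    block: str | None = None  # None, "additive", or "full" (3-way structure)
    block_ref: str = "baseline"
    covariates: tuple[str, ...] = ("sex", "age", "bmi")
    subject_col: str = "subject"

    def formula(self, data: pd.DataFrame) -> str:
        cond = f"C(condition, Treatment('{self.condition_ref}'))"
        time = f"C(timepoint, Treatment('{self.timepoint_ref}'))"
        blk = f"C(block, Treatment('{self.block_ref}'))"
        if self.block == "full":
            rhs = [f"{cond} * {time} * {blk}"]
        elif self.block == "additive":
            rhs = [f"{cond} * {time} + {blk}"]
        else:
            rhs = [f"{cond} * {time}"]
        rhs += [c for c in self.covariates if c in data.columns]
        return f"{self.outcome} ~ " + " + ".join(rhs)


@dataclass
class LmmFit:
    """Fitted mixed model plus everything downstream stages consume."""

    spec: LmmSpec
    result: object  # statsmodels MixedLMResults
    coef: pd.DataFrame
    aic: float
    bic: float
    var_subject: float
    var_residual: float
    data: pd.DataFrame
    converged: bool
    singular: bool
    remediation: str = "none"
    diagnostics: dict = field(default_factory=dict)
    bootstrap_ci: pd.DataFrame | None = None

    def coefficient(self, pattern: str) -> float:
        """The (single) fixed-effect coefficient whose name contains ``pattern``."""
        hits = [n for n in self.coef.index if pattern in n]
        if len(hits) != 1:
            raise KeyError(f"pattern {pattern!r} matches {hits}")
        return float(self.coef.loc[hits[0], "beta"])


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """ML-estimated random-intercept mixed model for one outcome."""
    missing = {spec.outcome, spec.subject_col, "condition", "timepoint"} - set(
        data.columns
    )
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    df = data.dropna(subset=[spec.outcome]).copy()
    counts = df.groupby(spec.subject_col).size()
    if (counts < 2).all():
        raise ValueError("need >= 2 observations for at least some participants")
    formula = spec.formula(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = mixedlm(formula, df, groups=df[spec.subject_col])
        result = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if result is None:  # last resort: Nelder-Mead
            result = model.fit(reml=False, method="nm")
    fe = result.fe_params
    k_fe = len(fe)
    sub = result.bse[: k_fe]
    coef = pd.DataFrame(
        {
            "beta": fe.to_numpy(),
            "se": sub.to_numpy(),
            "t": (fe / sub).to_numpy(),
            "p": 2 * stats.norm.sf(np.abs((fe / sub).to_numpy())),
        },
        index=list(fe.index),
    )
    n_params = k_fe + 2  # + random-intercept variance + residual variance
    aic = float(-2 * result.llf + 2 * n_params)
    bic = float(-2 * result.llf + np.log(len(df)) * n_params)
    var_subject = float(result.cov_re.iloc[0, 0] * result.scale)
    var_resid = float(result.scale)
    singular = var_subject < 1e-8 * max(var_resid, 1e-12)
    return LmmFit(
        spec=spec,
        result=result,
        coef=coef,
        aic=aic,
        bic=bic,
        var_subject=var_subject,
        var_residual=var_resid,
        data=df,
        converged=bool(result.converged),
        singular=singular,
    )


def _emmeans_grid(fit: LmmFit) -> tuple[pd.DataFrame, np.ndarray]:
    """Reference grid rows and their fixed-effect design matrix.

    Factor cells are crossed; covariates sit at their sample means; when the
    model contains a block factor the grid rows average over block levels.
    """
    df = fit.data
    conditions = sorted(df["condition"].unique())
    timepoints = sorted(df["timepoint"].unique())
    blocks = sorted(df["block"].unique()) if fit.spec.block else [None]
    cov_means = {c: df[c].mean() for c in fit.spec.covariates if c in df.columns}
    design_info = fit.result.model.data.design_info

    rows, designs = [], []
    for cond in conditions:
        for tp in timepoints:
            cell_rows = []
            for blk in blocks:
                rec = {"condition": cond, "timepoint": tp, **cov_means}
                if blk is not None:
                    rec["block"] = blk
                cell_rows.append(rec)
            (dm,) = patsy.build_design_matrices(
                [design_info], pd.DataFrame(cell_rows)
            )
            designs.append(np.asarray(dm).mean(axis=0))
            rows.append({"condition": cond, "timepoint": tp})
    return pd.DataFrame(rows), np.vstack(designs)


def emmeans_contrasts(
    fit: LmmFit,
    family: str = "condition_time_did",
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Estimated-marginal-means difference-in-differences contrasts.

    For every ordered condition pair (A, B) with A != reference-or-earlier,
    the contrast is (A, post - pre) - (B, post - pre) on the model scale.
    Returns estimates, SEs, z/p, and FDR-adjusted p within the family.
    """
    if family != "condition_time_did":
        raise ValueError(f"unknown contrast family: {family!r}")
    grid, D = _emmeans_grid(fit)
    fe = fit.result.fe_params.to_numpy()
    fe_names = list(fit.result.fe_params.index)
    cov_all = fit.result.cov_params()
    cov = cov_all.loc[fe_names, fe_names].to_numpy()

    conditions = list(dict.fromkeys(grid["condition"]))
    timepoints = sorted(grid["timepoint"].unique())
    if len(timepoints) != 2:
        raise ValueError("DiD contrasts need exactly two timepoints")
    pre, post = (
        (fit.spec.timepoint_ref,
         [t for t in timepoints if t != fit.spec.timepoint_ref][0])
    )

    def row(cond, tp):
        mask = (grid["condition"] == cond) & (grid["timepoint"] == tp)
        if not mask.any():
            return None
        return D[mask.to_numpy()][0]

    out = []
    for b_i, b in enumerate(conditions):
        for a in conditions[b_i + 1:]:
            vecs = [row(a, post), row(a, pre), row(b, post), row(b, pre)]
            if any(v is None for v in vecs):
                out.append({"contrast": f"({a}-{b}) post-pre", "estimate": np.nan,
                            "se": np.nan, "z": np.nan, "p": np.nan,
                            "estimable": False})
                continue
            L = vecs[0] - vecs[1] - vecs[2] + vecs[3]
            est = float(L @ fe)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se if se > 0 else np.nan
            out.append(
                {
                    "contrast": f"({a}-{b}) post-pre",
                    "condition_a": a,
                    "condition_b": b,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": float(2 * stats.norm.sf(abs(z))),
                    "estimable": True,
                }
            )
    table = pd.DataFrame(out)
    ok = table["estimable"] & table["p"].notna()
    p_adj = np.full(len(table), np.nan)
    if ok.any():
        _, adj, *_ = multipletests(table.loc[ok, "p"], alpha=fdr_q, method="fdr_bh")
        p_adj[ok.to_numpy()] = adj
    table["p_fdr"] = p_adj
    return table


def condition_did(contrasts: pd.DataFrame, a: str, b: str) -> float:
    """The (a - b) post-minus-pre estimate from a contrast table.

    Handles either ordering of the stored pair by flipping the sign.
    """
    hit = contrasts[
        (contrasts["condition_a"] == a) & (contrasts["condition_b"] == b)
    ]
    if len(hit):
        return float(hit.iloc[0]["estimate"])
    hit = contrasts[
        (contrasts["condition_a"] == b) & (contrasts["condition_b"] == a)
    ]
    if not len(hit):
        raise KeyError(f"no contrast for pair ({a}, {b})")
    return -float(hit.iloc[0]["estimate"])


def check_assumptions(fit: LmmFit, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk, Breusch-Pagan, and Durbin-Watson on residuals."""
    resid = np.asarray(fit.result.resid, dtype=float)
    fitted = np.asarray(fit.result.fittedvalues, dtype=float)
    sw_sample = resid if len(resid) <= 5000 else np.random.default_rng(0).choice(
        resid, 5000, replace=False
    )
    sw_stat, sw_p = stats.shapiro(sw_sample)
    exog = np.column_stack([np.ones_like(fitted), fitted])
    bp_stat, bp_p, *_ = het_breuschpagan(resid, exog)
    order = fit.data.sort_values([fit.spec.subject_col]).index
    dw = float(durbin_watson(pd.Series(resid, index=fit.data.index).loc[order]))
    return {
        "shapiro_w": float(sw_stat),
        "shapiro_p": float(sw_p),
        "breusch_pagan": float(bp_stat),
        "breusch_pagan_p": float(bp_p),
        "durbin_watson": dw,
        "normality_ok": sw_p >= alpha,
        "homoscedastic_ok": bp_p >= alpha,
    }


def _rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def fit_with_remediation(
    data: pd.DataFrame,
    spec: LmmSpec,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> LmmFit:
    """Fit, check assumptions, and remediate if they fail.

    Remediation ladder: (1) variance-stabilising transform -- natural log
    for strictly positive outcomes, rank-based inverse normal otherwise --
    then refit; (2) if diagnostics still fail, nonparametric subject-level
    (case-resampling) bootstrap percentile CIs for the fixed effects.  The
    path taken is recorded on the returned fit.
    """
    fit = fit_lmm(data, spec)
    diag = check_assumptions(fit, alpha=alpha)
    fit.diagnostics = diag
    if diag["normality_ok"] and diag["homoscedastic_ok"]:
        return fit

    df = data.copy()
    y = df[spec.outcome].to_numpy(dtype=float)
    transform = "log" if np.all(y > 0) else "rank_inverse_normal"
    df[spec.outcome] = np.log(y) if transform == "log" else _rank_inverse_normal(y)
    fit2 = fit_lmm(df, spec)
    diag2 = check_assumptions(fit2, alpha=alpha)
    fit2.diagnostics = diag2
    fit2.remediation = f"transformed:{transform}"
    if diag2["normality_ok"] and diag2["homoscedastic_ok"]:
        return fit2

    # bootstrap on the original-scale model
    rng = np.random.default_rng(seed)
    subjects = data[spec.subject_col].unique()
    boot = []
    for _ in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        parts = []
        for new_id, s in enumerate(pick):
            part = data[data[spec.subject_col] == s].copy()
            part[spec.subject_col] = f"b{new_id}"
            parts.append(part)
        bdf = pd.concat(parts, ignore_index=True)
        try:
            bfit = fit_lmm(bdf, spec)
            boot.append(bfit.coef["beta"])
        except Exception:
            continue
    bmat = pd.DataFrame(boot)
    ci = pd.DataFrame(
        {
            "ci_low": bmat.quantile(alpha / 2),
            "ci_high": bmat.quantile(1 - alpha / 2),
        }
    )
    fit.remediation = "bootstrapped"
    fit.bootstrap_ci = ci
    return fit
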