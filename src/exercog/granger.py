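"""VAR modelling and pairwise-conditional Granger causality over ROIs.

A vector autoregression of order ``p`` over the ROI series,

    x(t) = c + A_1 x(t-1) + ... + A_p x(t-p) + e(t),

is estimated by per-equation least squares (conditional maximum likelihood
under Gaussian innovations), with ``p`` chosen by the Bayesian Information
Criterion.  For each ordered ROI pair (i -> j) the Granger-causality
magnitude is the log ratio of residual variances of the *reduced* model for
equation j (all lags except those of i, conditioning on every other ROI)
to the *full* model:

    GC(i -> j) = ln( RSS_reduced / RSS_full )  >= 0.

An F-test on the same nested comparison provides significance;
Benjamini-Hochberg correction runs across all n(n-1) ordered pairs.  Causal
density summarises the network as the significant-edge fraction
(unweighted) and the mean GC magnitude (weighted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VarModel",
    "GcResult",
    "fit_var",
    "pairwise_conditional_gc",
    "causal_density",
    "edges_table",
]


class StationarityError(ValueError):
    """Selected VAR model is unstable (companion spectral radius >= 1)."""


@dataclass
class VarModel:
    """Fitted VAR: coefficients, innovations, order-selection diagnostics."""

    order: int
    coefs: np.ndarray  # (p, n, n): coefs[l, i, j] = effect of x_j(t-l-1) on x_i(t)
    intercept: np.ndarray
    sigma_u: np.ndarray  # innovation covariance (ML)
    aic: float
    bic: float
    stable: bool
    spectral_radius: float
    whiteness_p: np.ndarray  # Ljung-Box p per equation
    n_obs: int

    def companion(self) -> np.ndarray:
        p, n, _ = self.coefs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate([self.coefs[l] for l in range(p)], axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp


@dataclass
class GcResult:
    """Directed GC magnitudes, tests, and causal-density summaries."""

    gc: np.ndarray  # (n, n): gc[i, j] = GC(i -> j); diagonal NaN
    fstat: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray  # boolean
    order: int
    rois: list[str]
    model: VarModel
    fdr_q: float = 0.05

    @property
    def n_pairs(self) -> int:
        n = len(self.rois)
        return n * (n - 1)

    @property
    def causal_density_unweighted(self) -> float:
        return float(np.nansum(self.significant) / self.n_pairs)

    @property
    def causal_density_weighted(self) -> float:
        return float(np.nanmean(self.gc))


def _lag_matrix(x: np.ndarray, p: int, t0: int) -> np.ndarray:
    """Regressors [1, x(t-1), ..., x(t-p)] for t = t0..T-1."""
    T, n = x.shape
    cols = [np.ones(T - t0)]
    for lag in range(1, p + 1):
        cols.append(x[t0 - lag:T - lag])
    return np.column_stack(cols)


def _rss(Z: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    return np.sum(resid**2, axis=0), beta


def fit_var(
    series: np.ndarray | pd.DataFrame,
    max_order: int = 20,
    order: int | None = None,
    check_stability: bool = True,
) -> VarModel:
    """Fit a VAR with BIC order selection and stability/whiteness checks.

    Order candidates 1..max_order are compared on a common estimation
    sample (first ``max_order`` observations held out); the selected order
    is refitted on its full usable sample.  An unstable selected model
    raises :class:`StationarityError` (consider a lower order or more data).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be (T, n_series)")
    T, n = x.shape
    if T <= n * max_order + 10:
        raise ValueError(
            f"series length {T} too short for {n} nodes at max order {max_order}"
        )
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < n:
        raise ValueError("collinear or constant series; VAR regressors singular")

    if order is None:
        t0 = max_order
        T_eff = T - t0
        best = (np.inf, 1)
        for p in range(1, max_order + 1):
            Z = _lag_matrix(x, p, t0)
            rss, _ = _rss(Z, x[t0:])
            sigma = (x[t0:] - Z @ np.linalg.lstsq(Z, x[t0:], rcond=None)[0])
            sig = sigma.T @ sigma / T_eff
            sign, logdet = np.linalg.slogdet(sig)
            if sign <= 0:
                continue
            k = p * n * n + n
            bic = logdet + k * np.log(T_eff) / T_eff
            if bic < best[0]:
                best = (bic, p)
        order = best[1]

    p = order
    t0 = p
    Z = _lag_matrix(x, p, t0)
    Y = x[t0:]
    T_eff = Y.shape[0]
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    sigma_u = resid.T @ resid / T_eff
    sign, logdet = np.linalg.slogdet(sigma_u)
    k = p * n * n + n
    bic = float(logdet + k * np.log(T_eff) / T_eff)
    aic = float(logdet + 2 * k / T_eff)

    intercept = beta[0]
    coefs = np.stack(
        [beta[1 + l * n:1 + (l + 1) * n].T for l in range(p)], axis=0
    )
    model = VarModel(
        order=p,
        coefs=coefs,
        intercept=intercept,
        sigma_u=sigma_u,
        aic=aic,
        bic=bic,
        stable=True,
        spectral_radius=0.0,
        whiteness_p=np.empty(0),
        n_obs=T_eff,
    )
    radius = float(np.max(np.abs(np.linalg.eigvals(model.companion()))))
    model.spectral_radius = radius
    model.stable = radius < 1
    if check_stability and not model.stable:
        raise StationarityError(
            f"selected VAR({p}) is unstable (spectral radius {radius:.3f}); "
            "try a lower order or a longer series"
        )
    lb_lags = min(20, T_eff // 5)
    model.whiteness_p = np.array(
        [
            float(acorr_ljungbox(resid[:, i], lags=[lb_lags]).iloc[0]["lb_pvalue"])
            for i in range(n)
        ]
    )
    return model


def pairwise_conditional_gc(
    series: np.ndarray | pd.DataFrame,
    order: int | None = None,
    max_order: int = 20,
    fdr_q: float = 0.05,
    rois: list[str] | None = None,
    check_stability: bool = True,
) -> GcResult:
    """Pairwise-conditional Granger causality over all ordered ROI pairs.

    The reduced model for (i -> j) drops only source i's lags from
    equation j, keeping every other ROI as a conditioning variable, so
    indirect influences routed through third regions are not double-counted.
    """
    if isinstance(series, pd.DataFrame):
        rois = rois or [str(c) for c in series.columns]
    x = np.asarray(series, dtype=float)
    T, n = x.shape
    rois = rois or [f"roi{i + 1}" for i in range(n)]
    model = fit_var(x, max_order=max_order, order=order,
                    check_stability=check_stability)
    p = model.order

    Z = _lag_matrix(x, p, p)
    Y = x[p:]
    T_eff = Y.shape[0]
    k_full = Z.shape[1]
    rss_full, _ = _rss(Z, Y)

    gc = np.full((n, n), np.nan)
    fstat = np.full((n, n), np.nan)
    pmat = np.full((n, n), np.nan)
    dof = T_eff - k_full
    if dof <= 0:
        raise ValueError("not enough observations for the full model F-test")
    for src in range(n):
        keep = [0] + [
            1 + l * n + j for l in range(p) for j in range(n) if j != src
        ]
        rss_red, _ = _rss(Z[:, keep], Y)
        for tgt in range(n):
            if tgt == src:
                continue
            gc[src, tgt] = np.log(max(rss_red[tgt], 1e-300) / rss_full[tgt])
            f = ((rss_red[tgt] - rss_full[tgt]) / p) / (rss_full[tgt] / dof)
            fstat[src, tgt] = f
            pmat[src, tgt] = stats.f.sf(max(f, 0.0), p, dof)

    off = ~np.eye(n, dtype=bool)
    reject, p_adj, *_ = multipletests(pmat[off], alpha=fdr_q, method="fdr_bh")
    p_fdr = np.full((n, n), np.nan)
    signif = np.zeros((n, n), dtype=bool)
    p_fdr[off] = p_adj
    signif[off] = reject
    return GcResult(gc, fstat, pmat, p_fdr, signif, p, rois, model, fdr_q)


def causal_density(result: GcResult) -> dict[str, float]:
    """Unweighted (significant fraction) and weighted (mean GC) density."""
    return {
        "unweighted": result.causal_density_unweighted,
        "weighted": result.causal_density_weighted,
    }


def edges_table(result: GcResult) -> pd.DataFrame:
    """Long-format directed-edge table (one row per ordered ROI pair)."""
    rows = []
    n = len(result.rois)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append(
                {
                    "from_roi": result.rois[i],
                    "to_roi": result.rois[j],
                    "gc": result.gc[i, j],
                    "f_stat": result.fstat[i, j],
                    "p": result.p[i, j],
                    "p_fdr": result.p_fdr[i, j],
                    "significant": bool(result.significant[i, j]),
                }
            )
    return pd.DataFrame(rows)


def plot_adjacency(result: GcResult, path) -> None:
    """Save a simple GC-magnitude heatmap with significance markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(result.gc.T, cmap="viridis")
    n = len(result.rois)
    for i in range(n):
        for j in range(n):
            if i != j and result.significant[i, j]:
                ax.plot(i, j, "r.", markersize=8)
    ax.set_xticks(range(n), result.rois, rotation=90, fontsize=7)
    ax.set_yticks(range(n), result.rois, fontsize=7)
    ax.set_xlabel("from ROI")
    ax.set_ylabel("to ROI")
    fig.colorbar(im, ax=ax, label="GC magnitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
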