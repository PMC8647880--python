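"""Shared GWAS plumbing: result container, fast covariate-adjusted marker
regression, and the eigendecomposition-based REML core used by both the MLM
engine and the FarmCPU random-effect step."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ThresholdRecord",
    "GWASResult",
    "marker_regression",
    "eigen_reml",
]


@dataclass
class ThresholdRecord:
    """How significance was decided: type in {fdr, bonferroni, empirical}."""

    type: str
    level: float
    value: float | None = None

    def __post_init__(self) -> None:
        if self.type not in ("fdr", "bonferroni", "empirical"):
            raise ValueError(f"unknown threshold type {self.type!r}")


@dataclass
class GWASResult:
    """Per-marker association table plus engine provenance.

    ``table`` columns always include marker, chrom, pos, effect, se, stat,
    p (or importance for the SVR engine) and ``significant``.
    """

    table: pd.DataFrame
    engine: str
    threshold: ThresholdRecord
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.engine not in ("mlm", "farmcpu", "svr"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if "p" in self.table.columns:
            p = self.table["p"].dropna()
            if ((p <= 0) | (p > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")

    def significant_markers(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def marker_regression(
    y: np.ndarray,
    covariates: np.ndarray,
    markers: np.ndarray,
    weights: np.ndarray | None = None,
    warn: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker least squares of y on [covariates, marker], vectorised.

    ``weights`` (optional) are inverse-standard-deviation row weights for
    GLS in a rotated basis.  Residual variance is estimated per marker, so
    with identity weights the p-values equal ordinary t-test p-values.

    Returns (effect, se, t, p); collinear or constant markers yield NaN.
    """
    y = np.asarray(y, float)
    X = np.asarray(covariates, float)
    M = np.asarray(markers, float)
    if M.ndim == 1:
        M = M[:, None]
    n = len(y)
    if weights is not None:
        w = weights[:, None]
        X = X * w
        M = M * w
        y = y * weights
    # residualise y and markers against covariates
    Q, _ = np.linalg.qr(X)
    p_cov = X.shape[1]
    y_perp = y - Q @ (Q.T @ y)
    M_perp = M - Q @ (Q.T @ M)
    mm = np.einsum("ij,ij->j", M_perp, M_perp)
    my = M_perp.T @ y_perp
    yy = float(y_perp @ y_perp)
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough observations for the marker test")
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.einsum("ij,ij->j", M, M)
        ok = mm > 1e-10 * np.maximum(scale, 1.0)
        beta = np.where(ok, my / np.where(ok, mm, 1.0), np.nan)
        rss = yy - beta**2 * mm
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / np.where(ok, mm, np.nan))
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvals[~ok] = np.nan
    if warn and (~ok).any():
        warnings.warn(f"{int((~ok).sum())} constant/collinear marker(s) -> NaN p")
    return beta, se, tstat, pvals


@dataclass
class EigenRemlFit:
    var_u: float
    var_e: float
    delta: float            # var_e / var_u
    log_restricted_likelihood: float
    eigenvalues: np.ndarray
    rotation: np.ndarray    # Q such that K = Q diag(lambda) Q'
    y_rot: np.ndarray
    X_rot: np.ndarray


def eigen_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> EigenRemlFit:
    """REML of y = Xb + u + e with u ~ N(0, var_u K), via eigendecomposition
    of K and a 1-D search over log(delta), delta = var_e/var_u."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = len(y)
    lam, Q = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise ValueError(
            f"kinship is not PSD within tolerance (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    y_rot = Q.T @ y
    X_rot = Q.T @ X
    p = X.shape[1]
    nm_p = n - p

    def neg2_profiled(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = lam + delta
        wi = 1.0 / w
        Xw = X_rot * wi[:, None]
        XtWX = X_rot.T @ Xw
        XtWy = Xw.T @ y_rot
        sign, logdetX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        ypy = float(y_rot @ (wi * y_rot) - XtWy @ beta)
        ypy = max(ypy, 1e-300)
        return float(np.sum(np.log(w)) + logdetX + nm_p * np.log(ypy))

    res = minimize_scalar(neg2_profiled, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    delta = float(np.exp(res.x))
    w = lam + delta
    wi = 1.0 / w
    Xw = X_rot * wi[:, None]
    XtWX = X_rot.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y_rot)
    resid = y_rot - X_rot @ beta
    ypy = float(resid @ (wi * resid))
    var_u = ypy / nm_p
    var_e = delta * var_u
    # -2lR = sum log w + log|X'WX| + (n-p) log var_u + ypy/var_u + (n-p) log 2pi
    loglik = -0.5 * (
        float(np.sum(np.log(w)))
        + float(np.linalg.slogdet(XtWX)[1])
        + nm_p * np.log(var_u)
        + ypy / var_u
        + nm_p * np.log(2.0 * np.pi)
    )
    return EigenRemlFit(
        var_u=var_u,
        var_e=var_e,
        delta=delta,
        log_restricted_likelihood=float(loglik),
        eigenvalues=lam,
        rotation=Q,
        y_rot=y_rot,
        X_rot=X_rot,
    )
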