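"""SVR-mediated GWAS: variable-importance association scores with a
permutation-based global empirical threshold.

Importance is either permutation importance (held-out score drop when a
marker column is shuffled — the default, kernel-agnostic metric) or, for
the linear kernel, |weight| as a fast alternative.  The global empirical
threshold is the (1 - alpha) quantile of the maximum raw importance over
phenotype permutations; comparisons are made on the raw scale and the
reported threshold is mapped onto the 0-100 scale of the observed run, so
the family-wise false-positive rate is alpha by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVR, LinearSVR

from hypwas._gwas_core import GWASResult, ThresholdRecord
from hypwas.geno import GenotypeMatrix
from hypwas.rfe import scale_importance

__all__ = ["SVRConfig", "svr_importance", "empirical_threshold", "svr_gwas"]


@dataclass
class SVRConfig:
    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.1
    cv_folds: int = 5
    cv_repeats: int = 10
    n_repetitions: int = 1000       # importance-aggregation reseeds
    n_permutations: int = 1000      # phenotype permutations for the null
    perm_cv_repeats: int = 1        # reduced repeats inside the null
    alpha: float = 0.05
    importance: str = "permutation"  # or "weights" (linear kernel only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.importance not in ("permutation", "weights"):
            raise ValueError(f"unknown importance metric {self.importance!r}")
        if self.importance == "weights" and self.kernel != "linear":
            raise ValueError("weight importance requires the linear kernel")


def _dosage_matrix(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        if (G.dosage == -1).any():
            raise ValueError("genotypes must be imputed")
        return G.dosage.astype(float)
    return np.asarray(G, float)


def _fit_svr(X, y, cfg: SVRConfig):
    if cfg.kernel == "linear":
        # primal solver with the squared epsilon-insensitive loss: same
        # epsilon-tube geometry, far better convergence when p is large
        model = LinearSVR(
            C=cfg.C, epsilon=cfg.epsilon, loss="squared_epsilon_insensitive",
            dual=False, max_iter=3_000, tol=1e-3, random_state=0,
        )
    else:
        model = SVR(kernel="rbf", C=cfg.C, epsilon=cfg.epsilon)
    model.fit(X, y)
    return model


def _r2(y, pred) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def _fold_importance(model, X_te, y_te, cfg: SVRConfig, rng) -> np.ndarray:
    """Per-marker importance on one held-out fold."""
    if cfg.importance == "weights":
        return np.abs(model.coef_).ravel()
    pred = model.predict(X_te)
    base_sse = float(np.sum((y_te - pred) ** 2))
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    if ss_tot == 0:
        return np.zeros(X_te.shape[1])
    perm = rng.permutation(len(y_te))
    if cfg.kernel == "linear":
        # shuffling column j shifts predictions by w_j * (x_perm - x);
        # the R2 drop follows in closed form without re-predicting
        w = np.asarray(model.coef_).ravel()
        resid = y_te - pred
        dX = X_te[perm] - X_te
        sse_perm = (
            base_sse
            + w**2 * np.einsum("ij,ij->j", dX, dX)
            - 2.0 * w * (resid @ dX)
        )
        return (sse_perm - base_sse) / ss_tot
    drops = np.empty(X_te.shape[1])
    for j in range(X_te.shape[1]):
        Xp = X_te.copy()
        Xp[:, j] = Xp[perm, j]
        drops[j] = (float(np.sum((y_te - model.predict(Xp)) ** 2)) - base_sse) / ss_tot
    return drops


def _raw_importance(y, X, cfg: SVRConfig, cv_repeats: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Mean raw importance over folds x repeats; also the per-repeat means."""
    n = len(y)
    folds = min(cfg.cv_folds, n)
    rkf = RepeatedKFold(
        n_splits=folds, n_repeats=cv_repeats,
        random_state=int(rng.integers(2**31 - 1)),
    )
    per_fold = np.zeros((folds * cv_repeats, X.shape[1]))
    for k, (tr, te) in enumerate(rkf.split(X)):
        model = _fit_svr(X[tr], y[tr], cfg)
        per_fold[k] = _fold_importance(model, X[te], y[te], cfg, rng)
    per_repeat = per_fold.reshape(cv_repeats, folds, -1).mean(axis=1)
    return per_fold.mean(axis=0), per_repeat


def svr_importance(y, G, cfg: SVRConfig | None = None) -> np.ndarray:
    """Per-marker importance on the 0-100 scale (mean over folds/repeats)."""
    cfg = cfg or SVRConfig()
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    X = _dosage_matrix(G)
    rng = np.random.default_rng(cfg.seed)
    raw, _ = _raw_importance(y, X, cfg, cfg.cv_repeats, rng)
    return scale_importance(raw)


def _perm_maxima(y, X, cfg: SVRConfig, rng) -> np.ndarray:
    maxima = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        y_perm = rng.permutation(y)
        raw, _ = _raw_importance(y_perm, X, cfg, cfg.perm_cv_repeats, rng)
        maxima[b] = raw.max()
    return maxima


def _threshold_from_maxima(maxima: np.ndarray, alpha: float) -> float:
    """(1 - alpha) empirical quantile as an order statistic: the
    ceil((1 - alpha) * B)-th smallest maximum."""
    B = len(maxima)
    k = max(1, math.ceil((1.0 - alpha) * B))
    return float(np.sort(maxima)[k - 1])


def empirical_threshold(y, G, cfg: SVRConfig | None = None) -> tuple[float, np.ndarray]:
    """Global empirical threshold on the raw importance scale.

    Returns ``(threshold_raw, per-permutation maxima)``.  Use
    :func:`svr_gwas` for the version mapped onto the 0-100 scale of the
    observed run.
    """
    cfg = cfg or SVRConfig()
    if cfg.n_permutations < 20:
        raise ValueError("need >= 20 permutations")
    if cfg.alpha < 1.0 / cfg.n_permutations:
        raise ValueError(
            f"alpha {cfg.alpha} is below 1/n_permutations; increase permutations"
        )
    y = np.asarray(y, float)
    X = _dosage_matrix(G)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    maxima = _perm_maxima(y, X, cfg, rng)
    return _threshold_from_maxima(maxima, cfg.alpha), maxima


def svr_gwas(y, G, cfg: SVRConfig | None = None) -> GWASResult:
    """Full SVR engine: aggregated importance, empirical threshold, flags.

    The result table carries scaled importance (0-100), its per-repetition
    mean/SD, the selection frequency (fraction of repetitions whose raw
    importance exceeds the raw threshold), and the significance flag.
    """
    cfg = cfg or SVRConfig()
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    X = _dosage_matrix(G)
    rng = np.random.default_rng(cfg.seed)
    # per-repetition storage: n_repetitions CV reseeds (scalable via config)
    raw, per_repeat = _raw_importance(y, X, cfg, cfg.n_repetitions, rng)
    thr_raw, maxima = empirical_threshold(y, G, cfg)

    scaled = scale_importance(raw)
    lo, hi = raw.min(), raw.max()
    thr_scaled = 100.0 * (thr_raw - lo) / (hi - lo) if hi > lo else np.inf
    sel_freq = (per_repeat > thr_raw).mean(axis=0)
    rep_mean = per_repeat.mean(axis=0)
    rep_sd = per_repeat.std(axis=0, ddof=1) if per_repeat.shape[0] > 1 else np.zeros(X.shape[1])

    if isinstance(G, GenotypeMatrix):
        marker, chrom, pos = (
            G.markers["marker"], G.markers["chrom"], G.markers["pos"]
        )
    else:
        marker = [f"m{j}" for j in range(X.shape[1])]
        chrom, pos = ["NA"] * X.shape[1], np.zeros(X.shape[1], int)
    table = pd.DataFrame(
        {
            "marker": marker,
            "chrom": chrom,
            "pos": pos,
            "importance": scaled,
            "importance_raw": raw,
            "rep_mean_raw": rep_mean,
            "rep_sd_raw": rep_sd,
            "selection_frequency": sel_freq,
            "significant": raw > thr_raw,
        }
    )
    return GWASResult(
        table=table,
        engine="svr",
        threshold=ThresholdRecord("empirical", cfg.alpha, float(thr_scaled)),
        extra={
            "threshold_raw": thr_raw,
            "perm_maxima": maxima,
            "config": cfg,
        },
    )
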