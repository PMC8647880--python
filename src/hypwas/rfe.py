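"""Recursive feature elimination of reflectance bands against a response
trait, with cross-validated subset sizing and 0-100 importance scaling.

The inner learner is a random-forest regressor by default (impurity
importance) or a standardised linear SVR (|weight| importance).  Candidate
subset sizes are scored by repeated k-fold CV; the optimal size is the best
mean R-squared with a one-standard-error tie-break toward fewer bands.
"Significant" bands are defined by membership in the CV-optimal subset —
the selected-band scores are not separable by any single importance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

__all__ = ["RFEProfile", "rfe_select", "scale_importance"]


@dataclass
class RFEProfile:
    """Outcome of one RFE run.

    ``importance`` is the 0-100 scaled importance of every band from the
    full-band fit on all data (comparable across bands); ``refit_importance``
    re-scores only the selected subset from the final refit at the optimal
    size.  ``cv_profile`` has one row per candidate subset size with mean /
    SD of R-squared and RMSE.
    """

    bands: pd.DataFrame                # band, wavelength, importance, refit_importance, selected
    cv_profile: pd.DataFrame           # size, mean_r2, sd_r2, mean_rmse, sd_rmse
    optimal_size: int
    selected: list[int]                # column indices into the input matrix
    learner: str
    elimination_order: list[int]       # first-eliminated first
    significant: bool
    best_cv_r2: float
    min_r2: float = 0.1

    def __post_init__(self) -> None:
        imp = self.bands["importance"].to_numpy()
        if np.nanmin(imp) < -1e-9 or np.nanmax(imp) > 100 + 1e-9:
            raise ValueError("importance must lie in [0, 100]")


def scale_importance(raw) -> np.ndarray:
    """Linear min-max map onto [0, 100]; max -> 100, min -> 0.

    A constant (or single-value) vector maps to all-100 with a warning in
    the constant case.
    """
    raw = np.asarray(raw, float)
    if raw.size == 0:
        raise ValueError("empty importance vector")
    if not np.all(np.isfinite(raw)):
        raise ValueError("importance values must be finite")
    if raw.size == 1:
        return np.array([100.0])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("constant importance vector; scaling everything to 100")
        return np.full(raw.shape, 100.0)
    return 100.0 * (raw - lo) / (hi - lo)


def _make_learner(learner: str, seed: int):
    if learner == "rf":
        return RandomForestRegressor(
            n_estimators=100, random_state=seed, n_jobs=1, min_samples_leaf=2
        )
    if learner == "svr":
        return make_pipeline(
            StandardScaler(), LinearSVR(C=1.0, epsilon=0.0, max_iter=20_000, random_state=seed)
        )
    raise ValueError(f"unknown learner {learner!r} (use 'rf' or 'svr')")


def _importances(model, learner: str) -> np.ndarray:
    if learner == "rf":
        return model.feature_importances_
    return np.abs(model[-1].coef_).ravel()


def _elimination_path(X, y, sizes_desc, learner, seed):
    """Backward elimination: returns {size: column-index array} plus the
    full elimination order (first-dropped first)."""
    current = np.arange(X.shape[1])
    keep_at: dict[int, np.ndarray] = {X.shape[1]: current.copy()}
    order: list[int] = []
    for size in sizes_desc:
        if size >= len(current):
            keep_at[size] = current.copy()
            continue
        model = _make_learner(learner, seed)
        model.fit(X[:, current], y)
        imp = _importances(model, learner)
        rank = np.argsort(imp)            # ascending: least important first
        dropped = current[rank[: len(current) - size]]   # ascending importance
        order.extend(dropped.tolist())
        current = np.sort(current[rank[len(current) - size:]])
        keep_at[size] = current.copy()
    return keep_at, order


def rfe_select(
    X: np.ndarray,
    y: np.ndarray,
    learner: str = "rf",
    subset_sizes: list[int] | None = None,
    cv: int = 5,
    repeats: int = 5,
    seed: int = 0,
    min_r2: float = 0.1,
    wavelengths: np.ndarray | None = None,
) -> RFEProfile:
    """Cross-validated recursive feature elimination.

    Parameters mirror a caret-style ``rfe``: the learner is refit at each
    candidate subset size inside every CV split; the reported importances
    come from full-data fits.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with >= 1 band")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    n, m = X.shape
    if subset_sizes is None:
        subset_sizes = sorted(set(range(1, min(20, m) + 1)) | {m})
    subset_sizes = sorted(set(int(s) for s in subset_sizes))
    if subset_sizes[-1] > m or subset_sizes[0] < 1:
        raise ValueError(f"subset sizes must lie in [1, {m}]")
    sizes_desc = sorted(subset_sizes, reverse=True)

    rkf = RepeatedKFold(n_splits=cv, n_repeats=repeats, random_state=seed)
    r2_scores = {s: [] for s in subset_sizes}
    rmse_scores = {s: [] for s in subset_sizes}
    for split_i, (tr, te) in enumerate(rkf.split(X)):
        keep_at, _ = _elimination_path(X[tr], y[tr], sizes_desc, learner, seed + split_i)
        for s in subset_sizes:
            cols = keep_at[s]
            model = _make_learner(learner, seed + split_i)
            model.fit(X[tr][:, cols], y[tr])
            pred = model.predict(X[te][:, cols])
            ss_res = float(np.sum((y[te] - pred) ** 2))
            ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
            r2_scores[s].append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
            rmse_scores[s].append(float(np.sqrt(ss_res / len(te))))

    profile = pd.DataFrame(
        {
            "size": subset_sizes,
            "mean_r2": [np.mean(r2_scores[s]) for s in subset_sizes],
            "sd_r2": [np.std(r2_scores[s], ddof=1) if len(r2_scores[s]) > 1 else 0.0 for s in subset_sizes],
            "mean_rmse": [np.mean(rmse_scores[s]) for s in subset_sizes],
            "sd_rmse": [np.std(rmse_scores[s], ddof=1) if len(rmse_scores[s]) > 1 else 0.0 for s in subset_sizes],
        }
    )
    best_i = int(profile["mean_r2"].idxmax())
    best_r2 = float(profile.loc[best_i, "mean_r2"])
    se_best = float(profile.loc[best_i, "sd_r2"]) / np.sqrt(cv * repeats)
    within = profile[profile["mean_r2"] >= best_r2 - se_best]
    optimal_size = int(within["size"].min())

    # full-data fits: importances on the complete band set, then the refit
    full_model = _make_learner(learner, seed)
    full_model.fit(X, y)
    full_imp = scale_importance(_importances(full_model, learner))

    keep_at, elim_order = _elimination_path(X, y, sizes_desc, learner, seed)
    selected = sorted(keep_at[optimal_size].tolist())
    refit_model = _make_learner(learner, seed)
    refit_model.fit(X[:, selected], y)
    refit_imp = scale_importance(_importances(refit_model, learner))

    wl = np.asarray(wavelengths, float) if wavelengths is not None else np.arange(m, dtype=float)
    refit_col = np.full(m, np.nan)
    refit_col[selected] = refit_imp
    bands = pd.DataFrame(
        {
            "band": np.arange(m),
            "wavelength": wl,
            "importance": full_imp,
            "refit_importance": refit_col,
            "selected": np.isin(np.arange(m), selected),
        }
    )
    return RFEProfile(
        bands=bands,
        cv_profile=profile,
        optimal_size=optimal_size,
        selected=selected,
        learner=learner,
        elimination_order=elim_order,
        significant=best_r2 > min_r2,
        best_cv_r2=best_r2,
        min_r2=min_r2,
    )
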