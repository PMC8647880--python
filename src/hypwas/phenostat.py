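"""Multi-environment mixed model: REML variance components, BLUPs,
entry-mean heritability, and trait-band correlations.

Model: value = environment (fixed) + genotype (random, var_g)
        + genotype x environment (random, var_int) + residual (var_e).

REML is a direct 2-D optimisation of the profiled restricted log-likelihood
over the variance ratios (var_g/var_e, var_int/var_e) in log space, using a
Woodbury identity so each evaluation costs one Cholesky of a
(q_g + q_ge) square matrix.  Robustness over speed: the problems here are
hundreds of genotypes, not tens of thousands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "PlotTable",
    "VarianceComponents",
    "BLUPResult",
    "read_plot_table",
    "fit_blup",
    "heritability",
    "correlate",
]

_REQUIRED_COLS = ["genotype", "environment", "replicate", "trait", "value"]


@dataclass
class PlotTable:
    """Long-format plot observations: genotype / environment / replicate /
    trait / value.  Missing values are NaN and are excluded from fits."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plot table lacks columns: {missing}")
        keys = self.data[["genotype", "environment", "replicate", "trait"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate observation key: {dup}")
        vals = self.data["value"]
        if np.isinf(vals.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("plot values must be finite or missing")

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        return sub.dropna(subset=["value"]).reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_plot_table(path) -> PlotTable:
    return PlotTable(pd.read_csv(path, sep="\t"))


@dataclass
class VarianceComponents:
    var_g: float
    var_int: float
    var_e: float

    def __post_init__(self) -> None:
        if min(self.var_g, self.var_int, self.var_e) < -1e-12:
            raise ValueError("variance components must be >= 0")


@dataclass
class BLUPResult:
    """REML fit of the multi-environment model."""

    fixed_effects: pd.Series          # per-environment means
    genotype_effects: pd.Series       # BLUPs of g
    gxe_effects: pd.Series            # BLUPs of i, (genotype, environment) index
    vc: VarianceComponents
    log_restricted_likelihood: float
    trait: str
    converged: bool = True

    def genotype_values(self) -> pd.Series:
        """Genotype BLUP plus the grand fixed-effect mean (entry means)."""
        return self.genotype_effects + self.fixed_effects.mean()


class _RemlProblem:
    """Profiled restricted log-likelihood machinery for one trait.

    Writing H = I + g1 Z1 Z1' + g2 Z2 Z2' (Z1 genotype incidence, Z2 cell
    incidence), the Woodbury capacitance matrix has diagonal blocks
    (both Z1'Z1 and Z2'Z2 are count diagonals) coupled only within each
    genotype, so its Schur complement is diagonal and every likelihood
    evaluation is closed-form O(n) — no matrix factorisation at all.
    Cell-indexed vectors are stored as (n_genotypes, n_envs) arrays.
    """

    def __init__(self, df: pd.DataFrame, with_gxe: bool):
        self.genotypes = pd.Index(sorted(df["genotype"].unique()))
        self.envs = pd.Index(sorted(df["environment"].unique()))
        g_idx = self.genotypes.get_indexer(df["genotype"])
        e_idx = self.envs.get_indexer(df["environment"])
        n = len(df)
        n_g, n_e = len(self.genotypes), len(self.envs)
        self.n, self.p = n, n_e
        self.n_g, self.n_e = n_g, n_e
        self.q1, self.q2 = n_g, (n_g * n_e if with_gxe else 0)
        self.with_gxe = with_gxe
        y = df["value"].to_numpy(float)
        self.y = y
        # sufficient statistics
        self.c_cell = np.zeros((n_g, n_e))
        np.add.at(self.c_cell, (g_idx, e_idx), 1.0)
        self.c_g = self.c_cell.sum(axis=1)
        self.c_e = self.c_cell.sum(axis=0)
        self.s_cell = np.zeros((n_g, n_e))
        np.add.at(self.s_cell, (g_idx, e_idx), y)
        self.s_g = self.s_cell.sum(axis=1)
        self.Xty = self.s_cell.sum(axis=0)
        self.yty = float(y @ y)

    # -- capacitance-matrix algebra ------------------------------------
    def _prep(self, g1: float, g2: float):
        if not self.with_gxe:
            g2 = 0.0
        A22 = 1.0 + g2 * self.c_cell                       # (n_g, n_e)
        S = 1.0 + g1 * self.c_g - g1 * g2 * np.sum(
            self.c_cell**2 / A22, axis=1
        )                                                  # (n_g,)
        logdetA = float(np.sum(np.log(A22)) + np.sum(np.log(S)))
        return A22, S, logdetA

    def _solve(self, g1, g2, A22, S, v1, v2):
        """A^{-1} [v1; v2]; v1 (n_g, k), v2 (n_g, n_e, k)."""
        sq = np.sqrt(g1 * g2) if self.with_gxe else 0.0
        if self.with_gxe and sq > 0:
            Bv2 = sq * np.einsum("ge,gek->gk", self.c_cell / A22, v2)
        else:
            Bv2 = 0.0
        x1 = (v1 - Bv2) / S[:, None]
        if self.with_gxe:
            Btx1 = sq * self.c_cell[:, :, None] * x1[:, None, :]
            x2 = (v2 - Btx1) / A22[:, :, None]
        else:
            x2 = np.zeros_like(v2)
        return x1, x2

    def _rhs_blocks(self, g1: float, g2: float):
        """D^{1/2} Z' [X | y] as structured arrays."""
        d1, d2 = np.sqrt(g1), (np.sqrt(g2) if self.with_gxe else 0.0)
        k = self.n_e + 1
        v1 = np.empty((self.n_g, k))
        v1[:, : self.n_e] = d1 * self.c_cell               # Z1'X columns
        v1[:, self.n_e] = d1 * self.s_g                    # Z1'y
        v2 = np.zeros((self.n_g, self.n_e, k))
        if self.with_gxe:
            for e in range(self.n_e):                      # Z2'X col e: c_ge on env e
                v2[:, e, e] = d2 * self.c_cell[:, e]
            v2[:, :, self.n_e] = d2 * self.s_cell          # Z2'y
        return v1, v2

    def _core(self, g1: float, g2: float):
        A22, S, logdetA = self._prep(g1, g2)
        v1, v2 = self._rhs_blocks(g1, g2)
        x1, x2 = self._solve(g1, g2, A22, S, v1, v2)
        # Gram matrix of [X | y] under H^{-1}
        cross = v1.T @ x1 + np.einsum("gek,gel->kl", v2, x2)
        full = np.zeros((self.n_e + 1, self.n_e + 1))
        full[: self.n_e, : self.n_e] = np.diag(self.c_e)
        full[: self.n_e, self.n_e] = self.Xty
        full[self.n_e, : self.n_e] = self.Xty
        full[self.n_e, self.n_e] = self.yty
        full -= cross
        XtHiX = full[: self.n_e, : self.n_e]
        XtHiy = full[: self.n_e, self.n_e]
        ytHiy = full[self.n_e, self.n_e]
        sign, logdetXHX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return np.inf, None
        beta = np.linalg.solve(XtHiX, XtHiy)
        ypy = max(float(ytHiy - XtHiy @ beta), 1e-300)
        nm_p = self.n - self.p
        neg2 = logdetA + logdetXHX + nm_p * np.log(ypy)
        return neg2, (A22, S, beta, ypy, logdetA, logdetXHX)

    def neg2_reml(self, log_g1: float, log_g2: float) -> float:
        return self._core(np.exp(log_g1), np.exp(log_g2))[0]

    def solve(self, g1: float, g2: float):
        """Variance components, effects and restricted log-likelihood."""
        _, cache = self._core(g1, g2)
        A22, S, beta, ypy, logdetA, logdetXHX = cache
        nm_p = self.n - self.p
        sigma_e2 = ypy / nm_p
        # residual summaries r = y - X beta
        z1r = self.s_g - self.c_cell @ beta                # Z1'r
        z2r = self.s_cell - self.c_cell * beta[None, :]    # Z2'r
        d1, d2 = np.sqrt(g1), (np.sqrt(g2) if self.with_gxe else 0.0)
        x1, x2 = self._solve(
            g1, g2, A22, S, (d1 * z1r)[:, None], (d2 * z2r)[:, :, None]
        )
        x1, x2 = x1[:, 0], x2[:, :, 0]
        # Z' H^{-1} r = Z'r - Z'Z D^{1/2} x
        zz1 = self.c_g * d1 * x1 + d2 * np.sum(self.c_cell * x2, axis=1)
        u_g = g1 * (z1r - zz1)
        if self.with_gxe:
            zz2 = self.c_cell * (d1 * x1)[:, None] + d2 * self.c_cell * x2
            u_cell = g2 * (z2r - zz2)
        else:
            u_cell = np.zeros_like(z2r)
        neg2_unprof = (
            logdetA + logdetXHX + nm_p * np.log(sigma_e2) + ypy / sigma_e2
        )
        loglik = -0.5 * (neg2_unprof + nm_p * np.log(2.0 * np.pi))
        return sigma_e2, beta, u_g, u_cell, loglik

    def unprofiled_neg2(self, g1: float, g2: float, sigma_e2: float) -> float:
        _, cache = self._core(g1, g2)
        _, _, _, ypy, logdetA, logdetXHX = cache
        nm_p = self.n - self.p
        return logdetA + logdetXHX + nm_p * np.log(sigma_e2) + ypy / sigma_e2


def restricted_loglik(tbl: PlotTable, trait: str, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at given variance components (for sanity
    checks of the optimum)."""
    df = tbl.for_trait(trait)
    with_gxe = df["environment"].nunique() > 1
    prob = _RemlProblem(df, with_gxe)
    ve = max(vc.var_e, 1e-10)
    g1 = max(vc.var_g, 1e-12) / ve
    g2 = (max(vc.var_int, 1e-12) / ve) if with_gxe else 0.0
    const = (prob.n - prob.p) * np.log(2.0 * np.pi)
    return -0.5 * (prob.unprofiled_neg2(g1, g2, ve) + const)


def fit_blup(tbl: PlotTable, trait: str = "yield") -> BLUPResult:
    """REML fit of environment (fixed) + genotype + GxE (random) + residual.

    With a single environment the GxE term is fixed at zero.  Raises when
    GxE and residual are confounded (multiple environments, no replication
    in any genotype x environment cell).
    """
    df = tbl.for_trait(trait)
    if df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    n_env = df["environment"].nunique()
    with_gxe = n_env > 1
    if with_gxe:
        cell_counts = df.groupby(["genotype", "environment"]).size()
        if cell_counts.max() == 1:
            raise ValueError(
                "GxE interaction and residual variance are confounded: no "
                "genotype x environment cell has replication; drop the GxE "
                "term or supply replicated data"
            )

    # degenerate: constant trait
    if np.ptp(df["value"].to_numpy(float)) == 0:
        genotypes = pd.Index(sorted(df["genotype"].unique()))
        envs = pd.Index(sorted(df["environment"].unique()))
        val = float(df["value"].iloc[0])
        mi = pd.MultiIndex.from_product([genotypes, envs], names=["genotype", "environment"])
        return BLUPResult(
            fixed_effects=pd.Series(val, index=envs, name="fixed"),
            genotype_effects=pd.Series(0.0, index=genotypes, name="g"),
            gxe_effects=pd.Series(0.0, index=mi, name="i"),
            vc=VarianceComponents(0.0, 0.0, 0.0),
            log_restricted_likelihood=np.inf,
            trait=trait,
        )

    prob = _RemlProblem(df, with_gxe)

    lo, hi = -14.0, 10.0
    if with_gxe:
        def objective(x):
            return prob.neg2_reml(*np.clip(x, lo, hi))
        x0 = np.array([0.0, -1.0])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
        g1, g2 = np.exp(np.clip(res.x, lo, hi))
    else:
        def objective1(x):
            return prob.neg2_reml(float(np.clip(x[0], lo, hi)), lo)
        res = minimize(objective1, np.array([0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200})
        g1, g2 = float(np.exp(np.clip(res.x[0], lo, hi))), np.exp(lo)

    sigma_e2, beta, u_g, u_cell, loglik = prob.solve(g1, g2)
    floor = np.exp(lo) * 2.0
    var_g = g1 * sigma_e2 if g1 > floor else 0.0
    var_int = g2 * sigma_e2 if (with_gxe and g2 > floor) else 0.0
    vc = VarianceComponents(var_g, var_int, sigma_e2)

    fixed = pd.Series(beta, index=prob.envs, name="fixed")
    g_eff = pd.Series(u_g, index=prob.genotypes, name="g")
    mi = pd.MultiIndex.from_product(
        [prob.genotypes, prob.envs], names=["genotype", "environment"]
    )
    i_eff = pd.Series(u_cell.ravel(), index=mi, name="i")
    return BLUPResult(
        fixed_effects=fixed,
        genotype_effects=g_eff,
        gxe_effects=i_eff,
        vc=vc,
        log_restricted_likelihood=float(loglik),
        trait=trait,
        converged=bool(res.success),
    )


def heritability(v: VarianceComponents, n_env: int, n_rep: int) -> float:
    """Entry-mean heritability: var_g / (var_g + var_int/n + var_e/(n*r))."""
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    denom = v.var_g + v.var_int / n_env + v.var_e / (n_env * n_rep)
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return v.var_g / denom


def correlate(bands: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """Per-band Pearson correlation between genotype-level band values and a
    genotype-level trait, pairwise-complete over shared genotypes.

    Zero-variance inputs yield NaN with a warning.
    """
    shared = bands.index.intersection(trait.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genotypes to correlate")
    B = bands.loc[shared]
    t = trait.loc[shared]
    out = {}
    for col in B.columns:
        x = B[col]
        ok = x.notna() & t.notna()
        if ok.sum() < 3 or x[ok].std() == 0 or t[ok].std() == 0:
            warnings.warn(f"correlation undefined for band {col}; reported as NaN")
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x[ok], t[ok])[0, 1])
    return pd.Series(out, name="pearson_r")
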