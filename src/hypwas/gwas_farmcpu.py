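"""Iterative fixed/random-model scan with pseudo-QTN covariates.

Each iteration (i) tests every marker in a fixed-effect model that carries
the current pseudo-QTNs as covariates, (ii) bins markers by genomic
position and ranks the bin representatives by p-value, and (iii) picks the
pseudo-QTN set and bin size whose pseudo-QTN-derived relationship matrix
maximises the restricted likelihood of y = u + e.  The loop stops when the
pseudo-QTN set repeats or ``max_iter`` is hit; pseudo-QTNs receive the
p-value of their own covariate coefficient in the final fixed-effect model.

Default bin-size grid {50 kb, 500 kb, 5 Mb} and max pseudo-QTN count
ceil(sqrt(n)); only markers with a fixed-model p below ``qtn_p_threshold``
are eligible for promotion, which keeps the scan calibrated under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hypwas._gwas_core import GWASResult, ThresholdRecord, eigen_reml, marker_regression
from hypwas.geno import GenotypeMatrix, StructureCovariates
from hypwas.postgwas import bh_fdr

__all__ = ["FarmCPUState", "farmcpu_scan", "DEFAULT_BIN_SIZES"]

DEFAULT_BIN_SIZES = (50_000, 500_000, 5_000_000)


@dataclass
class FarmCPUState:
    """Iteration log: pseudo-QTN history and per-iteration p-vectors."""

    pseudo_qtns: list[int] = field(default_factory=list)
    effects: dict[int, float] = field(default_factory=dict)
    iteration: int = 0
    history: list[list[int]] = field(default_factory=list)
    p_history: list[np.ndarray] = field(default_factory=list)
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES
    max_qtn: int = 0
    converged: bool = False
    chosen_bin_size: int | None = None

    def check_bin_exclusivity(self, positions, chroms, bin_size: int) -> None:
        bins = {
            (chroms[j], positions[j] // bin_size) for j in self.pseudo_qtns
        }
        if len(bins) != len(self.pseudo_qtns):
            raise AssertionError("two pseudo-QTNs share one genomic bin")


def _design(n: int, covariates) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is None:
        return X
    C = covariates.values if isinstance(covariates, StructureCovariates) else np.asarray(covariates, float)
    if C.size == 0:
        return X
    return np.hstack([X, np.atleast_2d(C)])


def _fem_scan(y, X, qtn_dosage, M):
    """Fixed-effect model: every marker tested with pseudo-QTNs as covariates."""
    covs = X if qtn_dosage is None else np.hstack([X, qtn_dosage])
    # pseudo-QTN self-collinearity is expected; their p is filled in later
    return marker_regression(y, covs, M, warn=qtn_dosage is None)


def _qtn_pvalues(y, X, qtn_dosage):
    """p-value of each pseudo-QTN's own coefficient, conditioning on the
    other pseudo-QTNs (leave-one-in test)."""
    t = qtn_dosage.shape[1]
    pvals = np.empty(t)
    effects = np.empty(t)
    for k in range(t):
        others = np.delete(qtn_dosage, k, axis=1)
        covs = np.hstack([X, others]) if others.size else X
        b, _, _, p = marker_regression(y, covs, qtn_dosage[:, k])
        pvals[k], effects[k] = p[0], b[0]
    return effects, pvals


def _bin_representatives(pvals, chroms, positions, bin_size):
    """Best (lowest-p) marker index per genomic bin, ordered by p."""
    order = np.lexsort((positions, chroms, pvals))
    seen_bins = set()
    reps = []
    for j in order:
        if np.isnan(pvals[j]):
            continue
        b = (chroms[j], positions[j] // bin_size)
        if b in seen_bins:
            continue
        seen_bins.add(b)
        reps.append(j)
    return reps


def _rem_loglik(y, X, qtn_dosage) -> float:
    """Restricted likelihood of y = u + e with cov(u) from the candidate
    pseudo-QTN dosages (cross-product relationship matrix)."""
    S = qtn_dosage.astype(float)
    S = S - S.mean(axis=0)
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    S = S / sd
    Kq = S @ S.T / S.shape[1]
    return eigen_reml(y, X, Kq).log_restricted_likelihood


def farmcpu_scan(
    y: np.ndarray,
    covariates,
    G: GenotypeMatrix,
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
    max_iter: int = 10,
    max_qtn: int | None = None,
    qtn_p_threshold: float = 0.01,
    fdr_level: float = 0.05,
) -> GWASResult:
    """Run the iterative scan; significance by BH FDR on the final p-values."""
    y = np.asarray(y, float)
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete")
    M = G.dosage.astype(float)
    if (G.dosage == -1).any():
        raise ValueError("genotypes must be imputed")
    n = len(y)
    X = _design(n, covariates)
    chroms = pd.factorize(G.markers["chrom"])[0]
    positions = G.markers["pos"].to_numpy()
    if max_qtn is None:
        max_qtn = int(np.ceil(np.sqrt(n)))

    state = FarmCPUState(bin_sizes=tuple(bin_sizes), max_qtn=max_qtn)
    qtn_set: list[int] = []
    effects = ses = stats_ = pvals = None

    for it in range(1, max_iter + 1):
        state.iteration = it
        qtn_dosage = M[:, qtn_set] if qtn_set else None
        effects, ses, stats_, pvals = _fem_scan(y, X, qtn_dosage, M)
        if qtn_set:
            q_eff, q_p = _qtn_pvalues(y, X, qtn_dosage)
            for k, j in enumerate(qtn_set):
                effects[j], pvals[j] = q_eff[k], q_p[k]
                ses[j] = np.nan
                stats_[j] = np.nan
            state.effects = {j: float(effects[j]) for j in qtn_set}
        state.p_history.append(pvals.copy())

        if max_qtn == 0:
            state.converged = True
            break

        new_set, chosen_bin = _select_pseudo_qtns(
            y, X, M, pvals, chroms, positions,
            bin_sizes, max_qtn, qtn_p_threshold,
        )
        state.history.append(list(new_set))
        state.chosen_bin_size = chosen_bin
        if sorted(new_set) == sorted(qtn_set) or list(new_set) in state.history[:-1]:
            state.converged = True
            qtn_set = new_set
            state.pseudo_qtns = list(qtn_set)
            if qtn_set and chosen_bin:
                state.check_bin_exclusivity(positions, chroms, chosen_bin)
            break
        qtn_set = new_set
        state.pseudo_qtns = list(qtn_set)
        if qtn_set and chosen_bin:
            state.check_bin_exclusivity(positions, chroms, chosen_bin)

    flags, qvals = bh_fdr(pvals, fdr_level)
    table = pd.DataFrame(
        {
            "marker": G.markers["marker"],
            "chrom": G.markers["chrom"],
            "pos": positions,
            "effect": effects,
            "se": ses,
            "stat": stats_,
            "p": pvals,
            "fdr_q": qvals,
            "significant": flags,
            "pseudo_qtn": np.isin(np.arange(G.n_markers), qtn_set),
        }
    )
    return GWASResult(
        table=table,
        engine="farmcpu",
        threshold=ThresholdRecord("fdr", fdr_level),
        extra={"state": state, "converged": state.converged},
    )


def _select_pseudo_qtns(
    y, X, M, pvals, chroms, positions, bin_sizes, max_qtn, qtn_p_threshold
):
    """Choose the (bin size, candidate count) pair maximising the REM
    restricted likelihood; returns the winning marker index list."""
    best_ll = -np.inf
    best_set: list[int] = []
    best_bin = None
    for bin_size in bin_sizes:
        reps = _bin_representatives(pvals, chroms, positions, bin_size)
        reps = [j for j in reps if pvals[j] < qtn_p_threshold][:max_qtn]
        if not reps:
            continue
        counts = sorted({min(c, len(reps)) for c in (1, 2, 4, 8, 16, 32, len(reps))})
        for c in counts:
            cand = reps[:c]
            ll = _rem_loglik(y, X, M[:, cand])
            if ll > best_ll + 1e-9:
                best_ll = ll
                best_set = cand
                best_bin = bin_size
    return best_set, best_bin
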