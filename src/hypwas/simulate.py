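"""Synthetic genotypes, reflectance spectra, and multi-environment trials
with known ground truth.

The generative model is an artifact convention (no such model is published
for the emulated data): genotypes come from a Gaussian-copula first-order
chain on latent gamete alleles, spectra are a smooth vegetation-like
baseline plus genotype signals at causal bands, and plot yields follow an
environment + genotype + GxE + residual decomposition.  A single global seed
drives everything through deterministic per-generator substreams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from hypwas.geno import GenotypeMatrix
from hypwas.spectra import SpectraMatrix
from hypwas.phenostat import PlotTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_spectra",
    "simulate_trial",
    "simulate_qtn_phenotype",
    "default_band_grid",
    "write_truth",
]


def default_band_grid() -> np.ndarray:
    """250 band centers at 3-nm spacing starting at 350 nm (350..1097)."""
    return 350.0 + 3.0 * np.arange(250)


@dataclass
class SimConfig:
    """Ground-truth configuration for all three generators.

    ``causal_snps`` holds ``(marker_index, effect)`` pairs.  When
    ``causal_bands`` is non-empty, causal SNP *k* acts on the band of causal
    band ``k % len(causal_bands)`` (effect in reflectance units per alt
    allele), and each causal band ``(band_index, effect)`` feeds the trait —
    this routes genetic signal genotype -> band -> yield.  With no causal
    bands, SNP effects act on the trait directly.
    """

    n_genotypes: int = 200
    n_markers: int = 500
    n_chromosomes: int = 5
    ld_decay_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    band_grid: np.ndarray = field(default_factory=default_band_grid)
    causal_bands: list[tuple[int, float]] = field(default_factory=list)
    var_g: float = 1.0
    var_int: float = 0.5
    var_e: float = 1.0
    n_env: int = 4
    n_rep: int = 2
    seed: int = 0
    marker_spacing_bp: int = 10_000
    spectra_noise_sd: float = 0.005
    route_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.band_grid = np.asarray(self.band_grid, dtype=float)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie in (0, 0.5]")
        if not 0 <= self.ld_decay_rho < 1:
            raise ValueError("ld_decay_rho must lie in [0, 1)")
        if min(self.var_g, self.var_int, self.var_e) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")
        if np.any(np.diff(self.band_grid) <= 0):
            raise ValueError("band_grid must be strictly increasing")
        for idx, _ in self.causal_snps:
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"causal SNP index {idx} out of range")
        for idx, _ in self.causal_bands:
            if not 0 <= idx < len(self.band_grid):
                raise ValueError(f"causal band index {idx} outside the grid")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream derived from the global seed.

        Uses a stable (process-independent) hash of the stream name.
        """
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    genotype_effects: dict[str, float]
    causal_markers: list[dict]
    causal_bands: list[dict]
    realized_heritability: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json() + "\n")


def _genotype_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genotypes))
    return [f"G{i + 1:0{width}d}" for i in range(cfg.n_genotypes)]


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Biallelic dosages with tunable positional LD.

    Per chromosome and per haplotype, a latent standard-normal AR(1) chain
    with coefficient ``ld_decay_rho`` is thresholded at the marker's allele
    frequency quantile (Gaussian copula), so adjacent-marker correlation
    decays geometrically with marker distance.
    """
    rng = cfg.rng("genotypes")
    n, m = cfg.n_genotypes, cfg.n_markers
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    # alt allele may be major or minor
    flip = rng.random(m) < 0.5
    freqs = np.where(flip, 1.0 - freqs, freqs)
    thresholds = norm.ppf(freqs)

    chrom_of = np.array_split(np.arange(m), cfg.n_chromosomes)
    dosage = np.zeros((n, m), dtype=np.int8)
    rho = cfg.ld_decay_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    for markers in chrom_of:
        L = len(markers)
        if L == 0:
            continue
        for _hap in range(2):
            z = np.empty((n, L))
            z[:, 0] = rng.standard_normal(n)
            eps = rng.standard_normal((n, L - 1)) * innov_sd if L > 1 else None
            for j in range(1, L):
                z[:, j] = rho * z[:, j - 1] + eps[:, j - 1]
            dosage[:, markers] += (z < thresholds[markers]).astype(np.int8)

    chrom_names = []
    positions = []
    for c, markers in enumerate(chrom_of, start=1):
        chrom_names += [f"Chr{c}"] * len(markers)
        positions += [cfg.marker_spacing_bp * (j + 1) for j in range(len(markers))]
    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.choice(alleles, size=m)
    alt = np.array([rng.choice([a for a in alleles if a != r]) for r in ref])
    markers_df = pd.DataFrame(
        {
            "marker": [f"{c}_{p}" for c, p in zip(chrom_names, positions)],
            "chrom": chrom_names,
            "pos": positions,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeMatrix(_genotype_ids(cfg), markers_df, dosage)


def _baseline(band_grid: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like reflectance baseline on [0, 1]."""
    w = band_grid
    green = 0.08 * np.exp(-0.5 * ((w - 550) / 40.0) ** 2)
    red_edge = 0.35 / (1.0 + np.exp(-(w - 715) / 18.0))
    base = 0.05 + green + red_edge
    return np.clip(base, 0.0, 1.0)


def _band_genetic_signal(cfg: SimConfig, G: GenotypeMatrix) -> np.ndarray:
    """Genotype x band matrix of causal-SNP contributions to reflectance."""
    signal = np.zeros((G.n_samples, len(cfg.band_grid)))
    if not cfg.causal_bands:
        return signal
    for k, (snp_idx, eff) in enumerate(cfg.causal_snps):
        band_idx = cfg.causal_bands[k % len(cfg.causal_bands)][0]
        signal[:, band_idx] += eff * G.dosage[:, snp_idx].astype(float)
    return signal


def simulate_spectra(cfg: SimConfig, G: GenotypeMatrix) -> SpectraMatrix:
    """Plot-level spectra: baseline + genotype causal-band signal + noise.

    One spectrum per plot of the ``n_env x n_rep`` design; plot ids are
    ``<genotype>:<env>:<rep>`` matching :func:`simulate_trial`.
    """
    rng = cfg.rng("spectra")
    base = _baseline(cfg.band_grid)
    signal = _band_genetic_signal(cfg, G)
    plot_ids = []
    rows = []
    for gi, gid in enumerate(G.sample_ids):
        for e in range(cfg.n_env):
            for r in range(cfg.n_rep):
                plot_ids.append(f"{gid}:E{e + 1}:R{r + 1}")
                noise = (
                    rng.standard_normal(len(cfg.band_grid)) * cfg.spectra_noise_sd
                    if cfg.spectra_noise_sd > 0
                    else 0.0
                )
                rows.append(base + signal[gi] + noise)
    values = np.clip(np.asarray(rows), 0.0, 1.0)
    return SpectraMatrix(plot_ids, cfg.band_grid.copy(), values, band_width_nm=float(np.median(np.diff(cfg.band_grid))) if len(cfg.band_grid) > 1 else 1.0)


def _genotype_effects(cfg: SimConfig, G: GenotypeMatrix) -> tuple[np.ndarray, list[dict], list[dict]]:
    """Total genetic values with realized variance var_g.

    When causal bands exist, a fraction ``route_fraction`` of var_g flows
    through the band signal (standardised empirically so realized variance
    matches); the remainder — or all of it, absent causal bands but with
    causal SNPs acting directly; else a pure polygenic draw — is direct.
    """
    rng = cfg.rng("trial-genetics")
    n = G.n_samples
    causal_marker_log: list[dict] = []
    causal_band_log: list[dict] = []

    routed = np.zeros(n)
    route_var = 0.0
    if cfg.causal_bands and cfg.causal_snps:
        signal = _band_genetic_signal(cfg, G)
        raw = np.zeros(n)
        for band_idx, band_eff in cfg.causal_bands:
            raw += band_eff * signal[:, band_idx]
        sd = raw.std()
        route_var = cfg.route_fraction * cfg.var_g
        if sd > 0 and route_var > 0:
            scale = np.sqrt(route_var) / sd
            routed = (raw - raw.mean()) * scale
        else:
            route_var = 0.0
            scale = 0.0
        for k, (snp_idx, eff) in enumerate(cfg.causal_snps):
            band_idx, band_eff = cfg.causal_bands[k % len(cfg.causal_bands)]
            causal_marker_log.append(
                {
                    "marker": G.markers["marker"].iloc[snp_idx],
                    "index": int(snp_idx),
                    "band_index": int(band_idx),
                    "effect_on_band": float(eff),
                    "effect_on_trait": float(eff * band_eff * scale),
                }
            )
        for band_idx, band_eff in cfg.causal_bands:
            causal_band_log.append(
                {
                    "band_index": int(band_idx),
                    "wavelength_nm": float(cfg.band_grid[band_idx]),
                    "effect_on_trait": float(band_eff * scale),
                }
            )
        direct_var = max(cfg.var_g - route_var, 0.0)
    elif cfg.causal_snps:
        raw = np.zeros(n)
        for snp_idx, eff in cfg.causal_snps:
            raw += eff * G.dosage[:, snp_idx].astype(float)
            causal_marker_log.append(
                {
                    "marker": G.markers["marker"].iloc[snp_idx],
                    "index": int(snp_idx),
                    "band_index": None,
                    "effect_on_band": 0.0,
                    "effect_on_trait": float(eff),
                }
            )
        routed = raw - raw.mean()
        route_var = float(routed.var())
        direct_var = max(cfg.var_g - route_var, 0.0)
    else:
        direct_var = cfg.var_g

    direct = rng.standard_normal(n) * np.sqrt(direct_var) if direct_var > 0 else np.zeros(n)
    if direct_var > 0 and n > 1:
        # standardise empirically so realized var matches the requested var_g
        direct = (direct - direct.mean()) / direct.std() * np.sqrt(direct_var)
    g = routed + direct
    return g, causal_marker_log, causal_band_log


def simulate_trial(cfg: SimConfig, G: GenotypeMatrix) -> tuple[PlotTable, SimTruth]:
    """Balanced RCBD-style multi-environment trial.

    yield = env effect (fixed draw) + genotype effect + GxE + residual.
    """
    rng = cfg.rng("trial-noise")
    g, marker_log, band_log = _genotype_effects(cfg, G)
    n = G.n_samples
    env_effects = cfg.rng("environments").standard_normal(cfg.n_env)

    def _draw(shape, var):
        """Gaussian draw standardised so the realized variance equals var."""
        if var <= 0:
            return np.zeros(shape)
        x = rng.standard_normal(shape)
        sd = x.std()
        if sd == 0:
            return np.zeros(shape)
        return (x - x.mean()) / sd * np.sqrt(var)

    gxe = _draw((n, cfg.n_env), cfg.var_int)
    resid = _draw((n, cfg.n_env, cfg.n_rep), cfg.var_e)
    rows = []
    for gi, gid in enumerate(G.sample_ids):
        for e in range(cfg.n_env):
            for r in range(cfg.n_rep):
                rows.append(
                    {
                        "genotype": gid,
                        "environment": f"E{e + 1}",
                        "replicate": f"R{r + 1}",
                        "trait": "yield",
                        "value": env_effects[e] + g[gi] + gxe[gi, e] + resid[gi, e, r],
                    }
                )
    table = PlotTable(pd.DataFrame(rows))
    var_g_real = float(np.var(g))
    h2 = var_g_real / (
        var_g_real + cfg.var_int / cfg.n_env + cfg.var_e / (cfg.n_env * cfg.n_rep)
    ) if var_g_real + cfg.var_int + cfg.var_e > 0 else float("nan")
    truth = SimTruth(
        genotype_effects={gid: float(v) for gid, v in zip(G.sample_ids, g)},
        causal_markers=marker_log,
        causal_bands=band_log,
        realized_heritability=h2,
    )
    return table, truth


def simulate_qtn_phenotype(
    G: GenotypeMatrix,
    marker_index: int,
    h2_qtn: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample-level phenotype in which one marker explains ``h2_qtn`` of the
    variance and the rest is iid noise.  Utility for power studies."""
    if not 0 <= h2_qtn < 1:
        raise ValueError("h2_qtn must be in [0, 1)")
    x = G.dosage[:, marker_index].astype(float)
    sd = x.std()
    if sd == 0:
        raise ValueError("causal marker is monomorphic")
    x = (x - x.mean()) / sd
    y = np.sqrt(h2_qtn) * x + np.sqrt(1.0 - h2_qtn) * rng.standard_normal(G.n_samples)
    return y
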