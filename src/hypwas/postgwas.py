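"""Post-GWAS processing: FDR control, peak flanking regions, LD decay,
allelic effects, and gene-interval overlap.

All coordinates are 1-based inclusive (HapMap/GFF3 convention); overlap
means at least one shared base.  BED-style exports convert to 0-based
half-open at write time only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from hypwas.geno import GenotypeMatrix

__all__ = [
    "QTLRegion",
    "GeneAnnotation",
    "bh_fdr",
    "flanking_region",
    "regions_from_result",
    "ld_decay",
    "allelic_effect",
    "read_gff3_genes",
    "overlap_genes",
    "write_regions_bed",
]


@dataclass
class QTLRegion:
    """1-based inclusive interval around a peak marker."""

    chrom: str
    start: int
    end: int
    peak_marker: str
    peak_pos: int
    engine: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.peak_pos <= self.end):
            raise ValueError(
                f"require 1 <= start <= peak <= end, got "
                f"[{self.start}, {self.peak_pos}, {self.end}]"
            )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    attributes: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``.

    NaN p-values propagate as unflagged NaN q-values.  Returns
    ``(flags, q_values)`` in input order.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    ok = ~np.isnan(p)
    if ((p[ok] <= 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    flags = np.zeros(p.shape, bool)
    qvals = np.full(p.shape, np.nan)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        flags[ok] = rej
        qvals[ok] = qv
    return flags, qvals


def flanking_region(
    chrom: str,
    pos: int,
    marker: str = "",
    window_bp: int = 150_000,
    chrom_length: int | None = None,
    engine: str = "",
    trait: str = "",
) -> QTLRegion:
    """Symmetric window around a peak SNP, clipped to [1, chrom_length]."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    start = max(1, pos - window_bp)
    end = pos + window_bp
    if chrom_length is not None:
        if pos > chrom_length:
            raise ValueError(f"peak position {pos} beyond {chrom} length {chrom_length}")
        end = min(end, chrom_length)
    return QTLRegion(chrom, start, end, marker or f"{chrom}_{pos}", pos, engine, trait)


def regions_from_result(
    table: pd.DataFrame,
    window_bp: int = 150_000,
    chrom_lengths: dict | None = None,
    engine: str = "",
    trait: str = "",
) -> list[QTLRegion]:
    """One region per significant marker; overlapping windows on the same
    chromosome merge into one region keeping the strongest peak."""
    sig = table[table["significant"].fillna(False)].copy()
    if sig.empty:
        return []
    if chrom_lengths is not None:
        unknown = set(sig["chrom"]) - set(chrom_lengths)
        if unknown:
            raise ValueError(f"no chromosome length for: {sorted(unknown)}")
    strength = -np.log10(sig["p"]) if "p" in sig.columns else sig.get("importance", 0)
    sig = sig.assign(_strength=strength).sort_values(["chrom", "pos"])
    regions: list[QTLRegion] = []
    for _, row in sig.iterrows():
        length = chrom_lengths.get(row["chrom"]) if chrom_lengths else None
        r = flanking_region(
            row["chrom"], int(row["pos"]), str(row["marker"]),
            window_bp, length, engine, trait,
        )
        if regions and regions[-1].chrom == r.chrom and r.start <= regions[-1].end:
            prev = regions[-1]
            keep_prev_peak = True
            if "_strength" in sig.columns:
                prev_strength = sig.loc[sig["marker"] == prev.peak_marker, "_strength"]
                keep_prev_peak = bool(
                    len(prev_strength) and prev_strength.iloc[0] >= row["_strength"]
                )
            peak_marker = prev.peak_marker if keep_prev_peak else r.peak_marker
            peak_pos = prev.peak_pos if keep_prev_peak else r.peak_pos
            regions[-1] = QTLRegion(
                prev.chrom, prev.start, max(prev.end, r.end),
                peak_marker, peak_pos, engine, trait,
            )
        else:
            regions.append(r)
    return regions


def ld_decay(
    G: GenotypeMatrix, max_dist_bp: int = 1_000_000, bin_bp: int = 10_000
) -> tuple[pd.DataFrame, dict]:
    """Distance-binned mean r-squared between same-chromosome marker pairs.

    The decay summary reports the distance at which a moving-average smooth
    of the binned means first falls below half its maximum (NaN when never
    reached).
    """
    if (G.dosage == -1).any():
        raise ValueError("LD decay requires imputed genotypes")
    maf = G.maf()
    poly = maf > 0
    n_mono = int((~poly).sum())
    if n_mono:
        warnings.warn(f"excluding {n_mono} monomorphic marker(s) from LD decay")
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    any_pair = False
    for chrom, grp in G.markers[poly].groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        pos = grp["pos"].to_numpy()
        X = G.dosage[:, idx].astype(float)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        X /= sd
        R = (X.T @ X) / X.shape[0]
        iu, ju = np.triu_indices(len(idx), k=1)
        d = pos[ju] - pos[iu]
        keep = d <= max_dist_bp
        if keep.any():
            any_pair = True
            dists.append(d[keep])
            r2s.append(R[iu[keep], ju[keep]] ** 2)
    if not any_pair:
        raise ValueError("no polymorphic marker pairs within max_dist on any chromosome")
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    bins = (d // bin_bp).astype(int)
    df = (
        pd.DataFrame({"bin": bins, "dist": d, "r2": r2})
        .groupby("bin")
        .agg(distance_bp=("dist", "mean"), mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        .reset_index(drop=True)
        .sort_values("distance_bp")
        .reset_index(drop=True)
    )
    smooth = df["mean_r2"].rolling(3, center=True, min_periods=1).mean()
    half = smooth.max() / 2.0
    below = np.nonzero(smooth.to_numpy() < half)[0]
    half_dist = float(df["distance_bp"].iloc[below[0]]) if below.size else float("nan")
    summary = {
        "max_mean_r2": float(smooth.max()),
        "half_max_distance_bp": half_dist,
        "half_max_reached": bool(below.size),
        "n_pairs": int(len(d)),
    }
    return df, summary


def allelic_effect(y: np.ndarray, G: GenotypeMatrix, marker: str) -> dict:
    """Mean trait value per homozygote class at one marker.

    Heterozygotes are reported separately; an empty homozygote class is
    reported as NaN with a warning.
    """
    idx = G.markers.index[G.markers["marker"] == marker]
    if len(idx) == 0:
        raise ValueError(f"marker {marker!r} not found")
    y = np.asarray(y, float)
    d = G.dosage[:, idx[0]]
    out = {"marker": marker}
    for name, code in (("ref", 0), ("het", 1), ("alt", 2)):
        sel = d == code
        out[f"n_{name}"] = int(sel.sum())
        if sel.any():
            out[f"mean_{name}"] = float(y[sel].mean())
        else:
            out[f"mean_{name}"] = float("nan")
            if name != "het":
                warnings.warn(f"no dosage-{code} samples at {marker}; {name} mean is NaN")
    if np.isnan(out["mean_ref"]) or np.isnan(out["mean_alt"]):
        out["difference"] = float("nan")
    else:
        out["difference"] = out["mean_alt"] - out["mean_ref"]
    return out


def read_gff3_genes(path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file."""
    names = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names, dtype=str)
    genes = []
    for _, row in df[df["type"] == "gene"].iterrows():
        attrs = dict(
            kv.split("=", 1) for kv in row["attributes"].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name") or f"{row['seqid']}:{row['start']}"
        genes.append(
            GeneAnnotation(
                gene_id, row["seqid"], int(row["start"]), int(row["end"]),
                row["strand"], row["attributes"],
            )
        )
    return genes


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Shared bases between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def overlap_genes(
    regions: list[QTLRegion], genes: list[GeneAnnotation]
) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 base, with overlap length."""
    if regions and genes:
        region_chroms = {r.chrom for r in regions}
        gene_chroms = {g.chrom for g in genes}
        if not region_chroms & gene_chroms:
            raise ValueError(
                "no shared chromosome names between regions "
                f"({sorted(region_chroms)[:5]}) and annotation "
                f"({sorted(gene_chroms)[:5]}); supply a rename map"
            )
    rows = []
    for r in regions:
        for g in genes:
            if g.chrom != r.chrom:
                continue
            ov = _overlap(r.start, r.end, g.start, g.end)
            if ov > 0:
                rows.append(
                    {
                        "region_chrom": r.chrom,
                        "region_start": r.start,
                        "region_end": r.end,
                        "peak_marker": r.peak_marker,
                        "gene_id": g.gene_id,
                        "gene_start": g.start,
                        "gene_end": g.end,
                        "strand": g.strand,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "region_chrom", "region_start", "region_end", "peak_marker",
            "gene_id", "gene_start", "gene_end", "strand", "overlap_bp",
        ],
    )


def write_regions_bed(regions: list[QTLRegion], path) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.peak_marker}\n")
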