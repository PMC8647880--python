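"""Genotype I/O (HapMap / VCF), filtering, imputation, kinship and
population-structure covariates.

Conventions: coordinates are 1-based inclusive; heterozygotes are coded as
dosage 1 (no dominance coding); missing dosage is ``-1`` internally and is
removed by :func:`impute_missing` before any kinship or GWAS step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "StructureCovariates",
    "read_hapmap",
    "write_hapmap",
    "read_vcf",
    "read_q_matrix",
    "filter_maf",
    "impute_missing",
    "kinship_vanraden",
    "structure_pcs",
]

MISSING = -1

_HAPMAP_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_IUPAC_HET = {
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"},
    "W": {"A", "T"}, "K": {"G", "T"}, "M": {"A", "C"},
}


@dataclass
class GenotypeMatrix:
    """Sample x marker dosage matrix with a marker map.

    ``dosage`` holds alt-allele counts in {0, 1, 2} with ``-1`` for missing,
    shaped ``(n_samples, n_markers)``.  ``markers`` is a DataFrame with
    columns ``marker``, ``chrom``, ``pos``, ``ref``, ``alt`` (pos 1-based).
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    imputed_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        legal = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not legal.all():
            raise ValueError("dosage contains codes outside {0,1,2,missing}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        pos = self.markers["pos"].to_numpy()
        if (pos < 0).any():
            raise ValueError("negative marker positions")
        for _, grp in self.markers.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) < 0):
                raise ValueError("positions not sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per marker from non-missing calls."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.markers.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask[:, mask],
        )


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix aligned to a sample id order."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be n x n")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class StructureCovariates:
    """n x k structure covariates (PCA scores or Q-matrix memberships)."""

    values: np.ndarray
    sample_ids: list[str]
    source: str = "pca"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = np.empty((len(self.sample_ids), 0))
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("covariate rows must align with sample ids")

    @property
    def k(self) -> int:
        return self.values.shape[1]


def _call_to_dosage(call: str, ref: str, alt: str) -> int:
    call = call.strip().upper()
    if call in ("N", "NN", "--", ".", "./.", ""):
        return MISSING
    if len(call) == 1:
        if call == ref:
            return 0
        if call == alt:
            return 2
        het = _IUPAC_HET.get(call)
        if het == {ref, alt}:
            return 1
        return MISSING
    if len(call) == 2:
        a, b = call[0], call[1]
        n_alt = sum(1 for x in (a, b) if x == alt)
        n_ref = sum(1 for x in (a, b) if x == ref)
        if n_alt + n_ref == 2:
            return n_alt
        return MISSING
    return MISSING


def read_hapmap(path) -> GenotypeMatrix:
    """Parse a HapMap ``.hmp.txt`` file into dosages.

    The 11 standard metadata columns are expected before the sample columns.
    Diploid calls may be single-letter IUPAC or two-letter; unknown codes map
    to missing.  Alt allele is the second allele of the ``alleles`` column.
    """
    records = []
    sample_ids: list[str] = []
    dosage_rows = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12:
            raise ValueError("HapMap header has fewer than 12 columns")
        sample_ids = header[11:]
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"ragged row at line {lineno}: {len(fields)} columns, expected {n_cols}"
                )
            marker = fields[0]
            if marker in seen:
                raise ValueError(f"duplicated marker id {marker!r}")
            seen.add(marker)
            alleles = fields[1].upper().split("/")
            ref = alleles[0] if alleles else "N"
            alt = alleles[1] if len(alleles) > 1 else "N"
            records.append((marker, fields[2], int(fields[3]), ref, alt))
            dosage_rows.append(
                [_call_to_dosage(c, ref, alt) for c in fields[11:]]
            )
    markers = pd.DataFrame(records, columns=["marker", "chrom", "pos", "ref", "alt"])
    dosage = np.array(dosage_rows, dtype=np.int8).T if dosage_rows else np.empty((len(sample_ids), 0), np.int8)
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].astype(str).to_numpy()))
    if not np.array_equal(order, np.arange(len(markers))):
        markers = markers.iloc[order].reset_index(drop=True)
        dosage = dosage[:, order]
    return GenotypeMatrix(sample_ids, markers, dosage)


_DOSAGE_TO_CALL = {0: lambda r, a: r + r, 1: lambda r, a: r + a, 2: lambda r, a: a + a}


def write_hapmap(G: GenotypeMatrix, path) -> None:
    """Write the HapMap dialect read by :func:`read_hapmap` (round-trips dosages)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_COLS + list(G.sample_ids)) + "\n")
        for j in range(G.n_markers):
            m = G.markers.iloc[j]
            ref, alt = m["ref"], m["alt"]
            meta = [
                str(m["marker"]), f"{ref}/{alt}", str(m["chrom"]), str(int(m["pos"])),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            calls = [
                "NN" if d == MISSING else _DOSAGE_TO_CALL[int(d)](ref, alt)
                for d in G.dosage[:, j]
            ]
            fh.write("\t".join(meta + calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; multiallelic records are skipped
    with a warning carrying the skip count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records = []
    dosage_cols = []
    n_skipped = 0
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise ValueError(f"record at {var.CHROM}:{var.POS} lacks GT field")
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotype.array()[:, :2]
        d = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        records.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                        var.REF, var.ALT[0]))
        dosage_cols.append(d.astype(np.int8))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic record(s)")
    markers = pd.DataFrame(records, columns=["marker", "chrom", "pos", "ref", "alt"])
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0), np.int8)
    return GenotypeMatrix(sample_ids, markers, dosage)


def read_q_matrix(path) -> StructureCovariates:
    """Read a user-supplied Q matrix (TSV, first column sample id)."""
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    return StructureCovariates(df.iloc[:, 1:].to_numpy(float), ids, source="file")


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers with minor allele frequency below ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    maf = G.maf()
    keep = ~np.isnan(maf) & (maf >= min_maf)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("MAF filter removed all markers")
    out = G.subset_markers(keep)
    out.markers.attrs["maf_removed"] = n_removed
    return out


def impute_missing(
    G: GenotypeMatrix, strategy: str = "mode", max_missing: float = 0.5
) -> GenotypeMatrix:
    """Fill missing dosages per marker.

    ``mode`` uses the most frequent non-missing dosage (ties to the smaller
    code); ``mean-round`` rounds the marker mean to the nearest legal code.
    Markers whose missing fraction exceeds ``max_missing`` abort the call.
    """
    if strategy not in ("mode", "mean-round"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    d = G.dosage.copy()
    miss = d == MISSING
    frac = miss.mean(axis=0)
    bad = np.nonzero(frac > max_missing)[0]
    if bad.size:
        names = G.markers["marker"].iloc[bad].tolist()
        raise ValueError(
            f"{bad.size} marker(s) exceed the missing-fraction cap {max_missing}: {names[:10]}"
        )
    for j in np.nonzero(miss.any(axis=0))[0]:
        col = d[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            fill = 0
        elif strategy == "mode":
            counts = np.bincount(obs, minlength=3)
            fill = int(np.argmax(counts))
        else:
            fill = int(np.clip(np.rint(obs.mean()), 0, 2))
        col[col == MISSING] = fill
    out = GenotypeMatrix(list(G.sample_ids), G.markers.copy(), d, imputed_mask=miss)
    return out


def kinship_vanraden(G: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix: centered cross-product scaled by
    ``2 * sum(p * (1 - p))`` over markers."""
    if (G.dosage == MISSING).any():
        raise ValueError("kinship requires imputed (no-missing) genotypes")
    p = G.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic markers for kinship")
    M = G.dosage[:, poly].astype(float)
    p = p[poly]
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = Z @ Z.T / denom
    return KinshipMatrix(K, list(G.sample_ids))


def structure_pcs(G: GenotypeMatrix, k: int = 3) -> StructureCovariates:
    """First ``k`` principal-component scores of the centered dosage matrix."""
    if k >= G.n_samples:
        raise ValueError("k must be < number of samples")
    if k == 0:
        return StructureCovariates(np.empty((G.n_samples, 0)), list(G.sample_ids))
    if (G.dosage == MISSING).any():
        raise ValueError("PCA requires imputed genotypes")
    X = G.dosage.astype(float)
    X -= X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    return StructureCovariates(scores, list(G.sample_ids), source="pca")
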