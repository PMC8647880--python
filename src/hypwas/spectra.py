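"""Hyperspectral reflectance matrices: I/O, trimming, rebinning, smoothing,
and PCA-based outlier screening.

The canonical preprocessing order is trim -> rebin -> smooth; the CLI preset
enforces it.  Scaling/centering is applied only inside the PCA outlier
screen, never to exported spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectraMatrix",
    "read_spectra",
    "write_spectra",
    "trim_bands",
    "rebin_bands",
    "savgol_smooth",
    "detect_outliers_pca",
]


@dataclass
class SpectraMatrix:
    """Plot x band reflectance with its wavelength grid.

    Attributes
    ----------
    plot_ids
        One identifier per row.
    wavelengths_nm
        Strictly increasing band centers in nanometres.
    reflectance
        Array of shape ``(n_plots, n_bands)``; unitless fractions.
    band_width_nm
        Nominal bandwidth. For a freshly read file this is inferred from the
        grid spacing.
    """

    plot_ids: list[str]
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    band_width_nm: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (plots x bands)")
        if self.reflectance.shape != (len(self.plot_ids), len(self.wavelengths_nm)):
            raise ValueError(
                f"shape mismatch: {self.reflectance.shape} vs "
                f"{len(self.plot_ids)} plots x {len(self.wavelengths_nm)} bands"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if np.isnan(self.band_width_nm) and len(self.wavelengths_nm) > 1:
            self.band_width_nm = float(np.median(np.diff(self.wavelengths_nm)))

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths_nm)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance,
            columns=[format(w, "g") for w in self.wavelengths_nm],
        )
        df.insert(0, "plot_id", self.plot_ids)
        return df


def read_spectra(path) -> SpectraMatrix:
    """Read a tab-delimited spectra file.

    First column is the plot id; remaining column names are wavelength
    centers in nm.
    """
    df = pd.read_csv(path, sep="\t")
    plot_ids = df.iloc[:, 0].astype(str).tolist()
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return SpectraMatrix(plot_ids, wavelengths, values)


def write_spectra(S: SpectraMatrix, path) -> None:
    S.to_frame().to_csv(path, sep="\t", index=False)


def trim_bands(S: SpectraMatrix, keep_min_nm: float, keep_max_nm: float) -> SpectraMatrix:
    """Keep only bands whose center lies in ``[keep_min_nm, keep_max_nm]``."""
    if not keep_min_nm < keep_max_nm:
        raise ValueError("keep_min_nm must be < keep_max_nm")
    mask = (S.wavelengths_nm >= keep_min_nm) & (S.wavelengths_nm <= keep_max_nm)
    if not mask.any():
        raise ValueError(
            f"no bands with centers in [{keep_min_nm}, {keep_max_nm}] nm"
        )
    return SpectraMatrix(
        list(S.plot_ids),
        S.wavelengths_nm[mask],
        S.reflectance[:, mask],
        band_width_nm=S.band_width_nm,
    )


def rebin_bands(S: SpectraMatrix, target_width_nm: float) -> SpectraMatrix:
    """Average native bands into wider bins of ``target_width_nm``.

    New centers start at the first retained center and step by the target
    width until the last native center is covered (the final center may
    overshoot the last native center by less than one step).  Each new value
    is the mean of native bands whose centers fall in
    ``[c - w/2, c + w/2)`` — half-open on the upper side so adjacent bins
    never share a native band.
    """
    native = S.wavelengths_nm
    spacing = float(np.min(np.diff(native))) if len(native) > 1 else target_width_nm
    if target_width_nm < spacing:
        raise ValueError(
            f"target width {target_width_nm} nm is below native spacing {spacing} nm"
        )
    first, last = native[0], native[-1]
    n_new = int(np.ceil((last - first) / target_width_nm)) + 1
    centers = first + target_width_nm * np.arange(n_new)
    half = target_width_nm / 2.0
    cols = []
    kept = []
    for c in centers:
        sel = (native >= c - half) & (native < c + half)
        if not sel.any():
            continue  # trailing center overshot the grid by more than half a width
        kept.append(c)
        cols.append(S.reflectance[:, sel].mean(axis=1))
    centers = np.array(kept)
    values = np.column_stack(cols)
    return SpectraMatrix(
        list(S.plot_ids), centers, values, band_width_nm=float(target_width_nm)
    )


def savgol_smooth(S: SpectraMatrix, window: int = 11, polyorder: int = 2) -> SpectraMatrix:
    """Savitzky-Golay smoothing along the band axis of every spectrum.

    Edges are handled by fitting the polynomial on the truncated window
    (``mode='interp'``), which reproduces polynomial spectra exactly.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window > S.n_bands:
        raise ValueError(
            f"window {window} exceeds number of bands {S.n_bands}"
        )
    smoothed = savgol_filter(S.reflectance, window, polyorder, axis=1, mode="interp")
    return SpectraMatrix(
        list(S.plot_ids), S.wavelengths_nm.copy(), smoothed, band_width_nm=S.band_width_nm
    )


def detect_outliers_pca(
    S: SpectraMatrix, n_components: int = 2, z_threshold: float = 4.0
) -> list[str]:
    """Flag plots that are outlying on any leading principal component.

    Scores are robust-standardised per component (median / MAD); a plot is
    flagged when any |standardised score| exceeds ``z_threshold``.  The input
    matrix is not modified and flagged plots are only reported, never
    dropped.
    """
    if n_components >= min(S.n_plots, S.n_bands):
        raise ValueError("n_components must be < min(n_plots, n_bands)")
    X = S.reflectance - S.reflectance.mean(axis=0)
    col_sd = X.std(axis=0)
    if np.all(col_sd == 0):
        warnings.warn("all spectra identical; no outliers can be detected")
        return []
    nz = col_sd > 0
    X = X[:, nz] / col_sd[nz]
    # plots x bands SVD; scores = U * s
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    flagged: set[str] = set()
    for j in range(scores.shape[1]):
        col = scores[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        scale = 1.4826 * mad
        if scale == 0:
            # fall back to SD so a single extreme point is still detectable
            scale = col.std()
        if scale == 0:
            continue
        z = np.abs(col - med) / scale
        for i in np.nonzero(z > z_threshold)[0]:
            flagged.add(S.plot_ids[i])
    return sorted(flagged)
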