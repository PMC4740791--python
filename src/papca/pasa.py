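"""Photoacoustic spectral analysis (PASA).

The dB power spectrum of an RF photoacoustic record is fit to a straight
line over an analysis band, yielding three parameters: slope (dB/MHz),
intercept (dB at 0 MHz) and midband-fit (dB at the band center).  Only two
are independent — the midband-fit is the intercept plus slope times the band
center by construction.  Slope encodes the frequency extension of the
spectrum (absorber size / tissue heterogeneity) and is invariant under
uniform dB offsets, which makes it robust to optical-fluence uncertainty;
intercept and midband-fit track spectral magnitude (chromophore
concentration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .pcs import PCSMatrix, PowerSpectrum, power_spectrum

DEFAULT_BAND_MHZ = (0.1, 8.0)
DEFAULT_WAVELENGTHS_NM = (700.0, 1220.0, 1370.0)
FEATURE_COLUMNS = ("slope700", "slope1220", "slope1370", "mid700", "mid1220", "mid1370")


@dataclass(frozen=True)
class PASAResult:
    """Linear spectral-fit parameters over a stated band."""

    slope: float  # dB/MHz
    intercept: float  # dB at 0 MHz
    midband_fit: float  # dB at the band center
    band: tuple[float, float]
    r2: float

    @classmethod
    def from_fit(cls, slope: float, intercept: float, band: tuple[float, float],
                 r2: float) -> "PASAResult":
        center = 0.5 * (band[0] + band[1])
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            midband_fit=float(intercept + slope * center),
            band=(float(band[0]), float(band[1])),
            r2=float(r2),
        )


def linear_fit_spectrum(
    spectrum: PowerSpectrum,
    band: tuple[float, float] = DEFAULT_BAND_MHZ,
) -> PASAResult:
    """Ordinary least squares of power (dB) against frequency over ``band``."""
    sub = spectrum.band(*band)
    f = sub.f_MHz
    y = sub.power_dB
    if f.size < 3:
        raise ValueError(f"need at least 3 in-band bins, got {f.size}")
    if np.ptp(f) == 0:
        raise ValueError("all in-band frequencies are equal")
    slope, intercept = np.polyfit(f, y, 1)
    resid = y - (intercept + slope * f)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PASAResult.from_fit(slope, intercept, band, r2)


def pasa_at_wavelengths(
    pcs: PCSMatrix,
    wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    band: tuple[float, float] = DEFAULT_BAND_MHZ,
    tol_nm: float = 5.0,
) -> np.ndarray:
    """Slope and midband-fit features at the analysis wavelengths.

    Returns the ordered vector (slope_λ1, …, slope_λk, mid_λ1, …, mid_λk);
    with the default wavelengths that is (slope₇₀₀, slope₁₂₂₀, slope₁₃₇₀,
    mid₇₀₀, mid₁₂₂₀, mid₁₃₇₀).  Intercept is excluded: as a fluence-sensitive
    magnitude it duplicates the midband-fit without its robustness.
    """
    fits = [linear_fit_spectrum(pcs.row(lam, tol_nm=tol_nm), band) for lam in wavelengths_nm]
    return np.array([r.slope for r in fits] + [r.midband_fit for r in fits])


@dataclass(frozen=True)
class ParameterMap:
    """Windowed PASA parameters over a beamformed image.

    Arrays are (axial window × lateral line); ``mask`` is True where the
    window's peak intensity falls below the overlay threshold.
    """

    slope: np.ndarray
    midband_fit: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    axial_mm: np.ndarray
    lateral_mm: np.ndarray
    mask: np.ndarray
    band: tuple[float, float]


def parameter_map(
    beamformed: np.ndarray,
    fs_MHz: float,
    window_len: int = 128,
    overlap: float = 0.5,
    band: tuple[float, float] = DEFAULT_BAND_MHZ,
    intensity_threshold: float = 0.1,
    window_fn: str = "hann",
    v_s_mm_per_us: float = 1.5,
    lateral_pitch_mm: float = 0.1,
    t0_us: float = 0.0,
) -> ParameterMap:
    """Localized PASA over segmented A-lines of a beamformed frame.

    ``beamformed`` is (n_lines, n_samples).  Each A-line is tiled with
    windows of ``window_len`` samples advanced by ``window_len·(1−overlap)``;
    each window's tapered periodogram is fit over ``band``.  Windows whose
    peak amplitude is below ``intensity_threshold`` times the image maximum
    are masked from the overlay.
    """
    lines = np.atleast_2d(np.asarray(beamformed, dtype=float))
    n_lines, n_samples = lines.shape
    if window_len < 64:
        raise ValueError("window_len must be at least 64 samples")
    if window_len > n_samples:
        raise ValueError("window longer than the A-line")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = max(1, int(round(window_len * (1.0 - overlap))))
    starts = np.arange(0, n_samples - window_len + 1, step)
    n_win = starts.size

    taper = get_window(window_fn, window_len, fftbins=True)
    peak_global = float(np.max(np.abs(lines)))
    shape = (n_win, n_lines)
    slope = np.empty(shape)
    mid = np.empty(shape)
    icpt = np.empty(shape)
    r2 = np.empty(shape)
    mask = np.zeros(shape, dtype=bool)
    f = np.fft.rfftfreq(window_len, d=1.0 / fs_MHz)
    sel = (f >= band[0]) & (f <= band[1])
    if sel.sum() < 3:
        raise ValueError("analysis band holds fewer than 3 bins at this window length")
    for j in range(n_lines):
        for i, s0 in enumerate(starts):
            seg = lines[j, s0 : s0 + window_len]
            ps = power_spectrum(taper * seg, fs_MHz=fs_MHz, window_fn="boxcar")
            fit = linear_fit_spectrum(ps, band)
            slope[i, j] = fit.slope
            mid[i, j] = fit.midband_fit
            icpt[i, j] = fit.intercept
            r2[i, j] = fit.r2
            mask[i, j] = np.max(np.abs(seg)) < intensity_threshold * peak_global
    centers_us = t0_us + (starts + window_len / 2.0) / fs_MHz
    return ParameterMap(
        slope=slope,
        midband_fit=mid,
        intercept=icpt,
        r2=r2,
        axial_mm=centers_us * v_s_mm_per_us,
        lateral_mm=np.arange(n_lines) * lateral_pitch_mm,
        mask=mask,
        band=(float(band[0]), float(band[1])),
    )


def summarize_groups(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Box-plot statistics per condition group and feature.

    For every (group, feature): mean, 25th/75th percentiles (linear
    interpolation between order statistics), whisker extremes excluding
    outliers, and the outliers themselves under the 1.5·IQR rule.
    """
    if isinstance(features, pd.DataFrame):
        frame = features.copy()
        if labels is not None:
            frame = frame.assign(_group=list(labels))
        elif "condition" in frame.columns:
            frame = frame.rename(columns={"condition": "_group"})
        else:
            raise ValueError("labels required when the DataFrame has no 'condition' column")
        value_cols = [c for c in frame.columns if c != "_group"]
    else:
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if labels is None:
            raise ValueError("labels are required with array input")
        names = list(columns) if columns is not None else [f"f{i}" for i in range(arr.shape[1])]
        frame = pd.DataFrame(arr, columns=names).assign(_group=list(labels))
        value_cols = names

    rows = []
    for group, sub in frame.groupby("_group", sort=True):
        for col in value_cols:
            v = sub[col].to_numpy(dtype=float)
            q25, q75 = np.percentile(v, [25, 75])
            iqr = q75 - q25
            lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
            inliers = v[(v >= lo_fence) & (v <= hi_fence)]
            outliers = v[(v < lo_fence) | (v > hi_fence)]
            rows.append(
                {
                    "group": group,
                    "feature": col,
                    "n": v.size,
                    "mean": float(v.mean()),
                    "q25": float(q25),
                    "q75": float(q75),
                    "whisker_lo": float(inliers.min()),
                    "whisker_hi": float(inliers.max()),
                    "n_outliers": int(outliers.size),
                    "outliers": outliers.tolist(),
                }
            )
    return pd.DataFrame(rows)


def features_table(
    pcs_by_specimen: Mapping[str, tuple[str, PCSMatrix]],
    wavelengths_nm: Sequence[float] = DEFAULT_WAVELENGTHS_NM,
    band: tuple[float, float] = DEFAULT_BAND_MHZ,
) -> pd.DataFrame:
    """Feature rows (one per specimen) in the standard CSV layout."""
    rows = []
    for specimen_id, (condition, pcs) in pcs_by_specimen.items():
        feats = pasa_at_wavelengths(pcs, wavelengths_nm, band)
        rows.append({"specimen_id": specimen_id, "condition": condition,
                     **dict(zip(FEATURE_COLUMNS, feats))})
    return pd.DataFrame(rows)
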