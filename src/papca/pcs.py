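"""Physio-chemical spectrogram (PCS) assembly.

A PCS is a two-dimensional map of calibrated radio-frequency power (dB)
indexed by optical wavelength (the chemistry axis) and ultrasonic frequency
(the microstructure axis).  Each row is the power spectrum of the averaged
photoacoustic record at one laser wavelength after energy normalization,
attenuation compensation and system-response deconvolution; the whole matrix
is referenced to its global maximum (0 dB).

Vertical stripes at a chromophore's absorption band — "fingerprints" — carry
both that chromophore's concentration (stripe magnitude) and the spatial
heterogeneity of its distribution (stripe extension toward high ultrasonic
frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import get_window

from . import calibrate as _cal
from .synth import RFFrame

#: linear power floor, relative to the spectrum maximum, used when
#: converting to dB so that empty bins map to a finite level (−150 dB)
_DB_FLOOR_REL = 1e-15


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum with a stated 0 dB reference.

    ``power_dB = 10·log10(power_linear / reference_linear)``, floored at
    −150 dB relative to the spectrum maximum.
    """

    f_MHz: np.ndarray
    power_linear: np.ndarray
    reference_linear: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.f_MHz, dtype=float)
        p = np.asarray(self.power_linear, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequency grid and power must be 1-D and equal length")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("power_linear must be finite and non-negative")
        if not self.reference_linear > 0:
            raise ValueError("reference_linear must be positive")
        object.__setattr__(self, "f_MHz", f)
        object.__setattr__(self, "power_linear", p)

    @property
    def power_dB(self) -> np.ndarray:
        floor = max(float(np.max(self.power_linear)), np.finfo(float).tiny) * _DB_FLOOR_REL
        return 10.0 * np.log10(np.maximum(self.power_linear, floor) / self.reference_linear)

    def scaled_dB(self, gain_dB: np.ndarray) -> "PowerSpectrum":
        """Apply a per-frequency gain given in power dB."""
        factor = 10.0 ** (np.asarray(gain_dB, dtype=float) / 10.0)
        return PowerSpectrum(self.f_MHz, self.power_linear * factor, self.reference_linear)

    def scaled_linear(self, factor: np.ndarray) -> "PowerSpectrum":
        """Apply a per-frequency gain given as a linear power factor."""
        return PowerSpectrum(self.f_MHz, self.power_linear * np.asarray(factor, float),
                             self.reference_linear)

    def band(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        sel = (self.f_MHz >= f_lo) & (self.f_MHz <= f_hi)
        if not np.any(sel):
            raise ValueError(f"band [{f_lo}, {f_hi}] MHz contains no bins")
        return PowerSpectrum(self.f_MHz[sel], self.power_linear[sel], self.reference_linear)


def power_spectrum(
    frame: RFFrame | np.ndarray,
    fs_MHz: float | None = None,
    window_fn: str = "hann",
    band: tuple[float, float] | None = None,
) -> PowerSpectrum:
    """Tapered one-sided periodogram of an RF record.

    Normalized so that the total one-sided linear power equals the energy of
    the tapered time series, ``Σ_k P_k = Σ_n (w_n x_n)²`` (Parseval).  Pass
    ``window_fn='boxcar'`` for the plain periodogram.
    """
    if isinstance(frame, RFFrame):
        x = frame.samples
        fs = frame.fs_MHz
    else:
        x = np.asarray(frame, dtype=float)
        if fs_MHz is None:
            raise ValueError("fs_MHz is required when passing a raw sample array")
        fs = float(fs_MHz)
    n = x.size
    if n < 64:
        raise ValueError("record too short for spectral estimation (need >= 64 samples)")
    w = get_window(window_fn, n, fftbins=True)
    spec = np.fft.rfft(w * x)
    power = np.abs(spec) ** 2 / n
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    ps = PowerSpectrum(f, power)
    if band is not None:
        f_lo, f_hi = band
        if f_lo < 0 or f_hi > fs / 2:
            raise ValueError(f"band [{f_lo}, {f_hi}] MHz outside [0, {fs / 2}]")
        ps = ps.band(f_lo, f_hi)
    return ps


@dataclass(frozen=True)
class PCSMatrix:
    """Calibrated power (dB) over optical wavelength × ultrasonic frequency."""

    wavelengths_nm: np.ndarray
    f_MHz: np.ndarray
    power_dB: np.ndarray
    reference_dB: float = 0.0
    calibration_record: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        f = np.asarray(self.f_MHz, dtype=float)
        p = np.asarray(self.power_dB, dtype=float)
        if p.shape != (wl.size, f.size):
            raise ValueError(
                f"power_dB shape {p.shape} does not match "
                f"{wl.size} wavelengths x {f.size} frequencies"
            )
        if np.any(np.isnan(p)):
            raise ValueError("power_dB contains NaN")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "f_MHz", f)
        object.__setattr__(self, "power_dB", p)

    def row(self, wavelength_nm: float, tol_nm: float = 5.0) -> PowerSpectrum:
        """The spectrum at the nearest grid wavelength within ``tol_nm``."""
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[idx] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"wavelength {wavelength_nm} nm is more than {tol_nm} nm from the grid"
            )
        return PowerSpectrum(self.f_MHz, 10.0 ** (self.power_dB[idx] / 10.0))


def assemble_pcs(
    frames: Sequence[RFFrame],
    calibration: _cal.CalibrationConfig | None = None,
    window_fn: str = "hann",
) -> PCSMatrix:
    """Assemble calibrated per-wavelength spectra into a PCS.

    Each frame is energy-normalized, transformed to a tapered periodogram,
    attenuation-compensated (unless the calibration is in in-situ mode) and
    system-deconvolved.  Rows are sorted by wavelength and the matrix is
    re-referenced so its global maximum sits at 0 dB.
    """
    if not frames:
        raise ValueError("no frames supplied")
    calibration = calibration or _cal.CalibrationConfig()
    lams = np.array([fr.wavelength_nm for fr in frames], dtype=float)
    if np.unique(lams).size != lams.size:
        raise ValueError("duplicate wavelengths in frame set")
    fss = {fr.fs_MHz for fr in frames}
    if len(fss) != 1:
        raise ValueError(f"inconsistent sampling rates across frames: {sorted(fss)}")

    order = np.argsort(lams)
    rows = []
    record: dict[str, object] = {
        "energy_normalized": True,
        "window": window_fn,
        "attenuation": None,
        "deconvolved": calibration.response is not None,
        "mode": calibration.mode,
    }
    for i in order:
        ps = power_spectrum(_cal.energy_normalize(frames[i]), window_fn=window_fn)
        if calibration.attenuation is not None and calibration.mode == "ex_vivo":
            ps = _cal.attenuation_compensate(ps, calibration.attenuation)
            record["attenuation"] = {
                "alpha0": calibration.attenuation.alpha0,
                "y": calibration.attenuation.y,
                "path_cm": calibration.attenuation.path_cm,
            }
        if calibration.response is not None:
            ps = _cal.system_deconvolve(ps, calibration.response, calibration.floor_frac)
        rows.append(ps)

    f = rows[0].f_MHz
    dB = np.stack([r.power_dB for r in rows])
    ref = float(np.max(dB))
    return PCSMatrix(
        wavelengths_nm=lams[order],
        f_MHz=f,
        power_dB=dB - ref,
        reference_dB=ref,
        calibration_record=record,
    )


def absorption_proxy(
    pcs: PCSMatrix,
    band: tuple[float, float] = (0.1, 8.0),
    scale: str = "amplitude",
) -> np.ndarray:
    """Optical-absorption proxy: per-wavelength in-band spectral sum.

    Summing the linear-scale spectral amplitudes of each PCS column block
    recovers the sample's relative optical absorption spectrum.  With
    ``scale='amplitude'`` (default) the square root of the linear power is
    summed; ``scale='power'`` sums linear power instead.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ValueError("empty frequency band")
    sel = (pcs.f_MHz >= f_lo) & (pcs.f_MHz <= f_hi)
    if not np.any(sel):
        raise ValueError(f"band [{f_lo}, {f_hi}] MHz contains no bins")
    linear = 10.0 ** (pcs.power_dB[:, sel] / 10.0)
    if scale == "amplitude":
        return np.sqrt(linear).sum(axis=1)
    if scale == "power":
        return linear.sum(axis=1)
    raise ValueError("scale must be 'amplitude' or 'power'")


def extract_fingerprint(
    pcs: PCSMatrix,
    wavelength_band: tuple[float, float] | float,
) -> PowerSpectrum:
    """Mean spectrum over a chromophore's absorption band.

    The fingerprint bands of interest are hemoglobin (700 nm), lipid
    (1200–1240 nm) and collagen (1350–1390 nm).  A scalar band selects the
    single nearest row; otherwise rows with wavelength inside the closed
    interval are averaged in dB.
    """
    if np.isscalar(wavelength_band):
        return pcs.row(float(wavelength_band))
    lo, hi = wavelength_band
    sel = (pcs.wavelengths_nm >= lo) & (pcs.wavelengths_nm <= hi)
    if not np.any(sel):
        raise ValueError(f"wavelength band [{lo}, {hi}] nm misses the PCS grid")
    mean_dB = pcs.power_dB[sel].mean(axis=0)
    return PowerSpectrum(pcs.f_MHz, 10.0 ** (mean_dB / 10.0))
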