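"""Instrument and propagation calibration for photoacoustic spectra.

Three multiplicative corrections are removed from each per-wavelength
record before spectrogram assembly:

* pulse-energy normalization — the photoacoustic amplitude is linear in the
  delivered optical energy, so samples are divided by the monitored per-shot
  energy;
* frequency-dependent acoustic attenuation over the propagation path,
  modelled as the usual soft-tissue power law ``alpha(f) = alpha0 · f^y``
  (dB/cm) and compensated in the power domain;
* the measurement chain's frequency response ``|H(f)|``, estimated from a
  sub-resolution target (an impulse to the system) and divided out with a
  regularizing floor.

All three are multiplicative in the linear signal, so the corrections
commute and may be applied in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pcs import PowerSpectrum
    from .synth import RFFrame


@dataclass(frozen=True)
class AttenuationModel:
    """Power-law acoustic attenuation along a fixed path.

    ``alpha0`` in dB·cm⁻¹·MHz⁻ʸ; ``path_cm`` is the one-way acoustic path
    (sensor face to sample center).
    """

    alpha0: float = 0.5
    y: float = 1.0
    path_cm: float = 1.2

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be non-negative")
        if self.path_cm < 0:
            raise ValueError("path_cm must be non-negative")

    def power_gain_dB(self, f_MHz: np.ndarray) -> np.ndarray:
        """dB added to the *power* spectrum at each frequency.

        One-way amplitude attenuation is ``alpha0·path·f^y`` dB; power is
        amplitude squared, hence the factor 2.
        """
        f = np.asarray(f_MHz, dtype=float)
        return 2.0 * self.alpha0 * self.path_cm * np.abs(f) ** self.y


@dataclass(frozen=True)
class SystemResponse:
    """Relative magnitude response |H(f)| of the acquisition chain."""

    f_MHz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f_MHz, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if m.shape != f.shape or np.any(m < 0):
            raise ValueError("magnitude must be non-negative and match the grid")
        object.__setattr__(self, "f_MHz", f)
        object.__setattr__(self, "magnitude", m)

    def at(self, f_MHz: np.ndarray) -> np.ndarray:
        """|H| interpolated onto ``f_MHz`` (edge-held outside the grid)."""
        return np.interp(np.asarray(f_MHz, dtype=float), self.f_MHz, self.magnitude)

    @classmethod
    def from_csv(cls, path) -> "SystemResponse":
        table = pd.read_csv(path)
        for col in ("f_MHz", "magnitude"):
            if col not in table.columns:
                raise ValueError(f"system-response CSV missing column {col!r}")
        return cls(table["f_MHz"].to_numpy(float), table["magnitude"].to_numpy(float))


@dataclass(frozen=True)
class CalibrationConfig:
    """The corrections applied during spectrogram assembly.

    ``mode='in_situ'`` disables attenuation compensation (probe in contact
    with the tissue, negligible intervening path); ``mode='ex_vivo'`` applies
    it.
    """

    attenuation: AttenuationModel | None = None
    response: SystemResponse | None = None
    floor_frac: float = 0.01
    mode: str = "ex_vivo"

    def __post_init__(self) -> None:
        if self.mode not in ("ex_vivo", "in_situ"):
            raise ValueError("mode must be 'ex_vivo' or 'in_situ'")
        if not self.floor_frac > 0:
            raise ValueError("floor_frac must be positive")


def energy_normalize(frame: "RFFrame") -> "RFFrame":
    """Scale an RF frame to unit pulse energy."""
    if frame.pulse_energy is None or not frame.pulse_energy > 0:
        raise ValueError("frame has no positive pulse-energy record")
    return replace(
        frame, samples=frame.samples / frame.pulse_energy, pulse_energy=1.0
    )


def attenuation_compensate(spectrum: "PowerSpectrum", model: AttenuationModel) -> "PowerSpectrum":
    """Undo power-law acoustic attenuation on a power spectrum (dB domain)."""
    gain_dB = model.power_gain_dB(spectrum.f_MHz)
    return spectrum.scaled_dB(gain_dB)


def apply_attenuation(spectrum: "PowerSpectrum", model: AttenuationModel) -> "PowerSpectrum":
    """Forward attenuation (the inverse of :func:`attenuation_compensate`)."""
    return spectrum.scaled_dB(-model.power_gain_dB(spectrum.f_MHz))


def estimate_system_response(
    impulse_frame: "RFFrame",
    window_samples: int | None = None,
    min_snr: float = 8.0,
) -> SystemResponse:
    """Estimate |H(f)| from the record of a sub-resolution (impulse) target.

    The dominant transient is located, a Hann-tapered window centered on it
    is transformed, and the magnitude spectrum is peak-normalized to 1.
    Raises if no transient stands above the noise floor (peak below
    ``min_snr`` times the record's median absolute amplitude).
    """
    from scipy.signal.windows import hann

    x = impulse_frame.samples
    peak = int(np.argmax(np.abs(x)))
    floor = float(np.median(np.abs(x)))
    if np.abs(x[peak]) <= min_snr * max(floor, np.finfo(float).tiny):
        raise ValueError("no transient above the noise floor in the impulse record")
    n = window_samples or min(256, x.size)
    half = n // 2
    lo = max(0, peak - half)
    hi = min(x.size, lo + n)
    lo = max(0, hi - n)
    seg = x[lo:hi] * hann(hi - lo, sym=False)
    mag = np.abs(np.fft.rfft(seg))
    f = np.fft.rfftfreq(hi - lo, d=1.0 / impulse_frame.fs_MHz)
    return SystemResponse(f, mag / mag.max())


def system_deconvolve(
    spectrum: "PowerSpectrum",
    response: SystemResponse,
    floor_frac: float = 0.01,
) -> "PowerSpectrum":
    """Divide out the squared system response with a regularizing floor.

    Power is divided by ``max(|H|², (floor_frac·max|H|)²)``, capping the
    maximum power gain at ``1/floor_frac²`` where the response vanishes.
    """
    if not floor_frac > 0:
        raise ValueError("floor_frac must be positive")
    h = response.at(spectrum.f_MHz)
    h_floor = floor_frac * float(np.max(response.magnitude))
    denom = np.maximum(h, h_floor) ** 2
    return spectrum.scaled_linear(1.0 / denom)


def apply_system_response(spectrum: "PowerSpectrum", response: SystemResponse) -> "PowerSpectrum":
    """Multiply a power spectrum by |H(f)|² (forward system filtering)."""
    return spectrum.scaled_linear(response.at(spectrum.f_MHz) ** 2)
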