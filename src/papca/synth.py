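"""Tissue-phantom forward simulator for photoacoustic spectral analysis.

Emulates multi-wavelength photoacoustic acquisitions of liver-like tissue:
ensembles of spherical optical absorbers (lipid- or collagen-rich droplets in
a hemoglobin background) are excited by a nanosecond laser pulse and radiate
broadband pressure transients recorded by a point sensor.  Three conditions
are modelled — normal, steatosis (lipid infiltration) and fibrosis (collagen
deposition) — differing in absorber chemistry, size and number density as
well as in background hemoglobin content.

The per-absorber acoustic kernel is the classic far-field N-wave of an
impulsively and uniformly heated sphere, whose amplitude spectrum is

    |S(f)| ∝ |sin x − x cos x| / x²,   x = 2π f R / v_s,

so sphere radius maps directly onto ultrasonic-frequency content: small
absorbers (heterogeneous tissue) extend the spectrum to high frequency.
Frames are synthesised band-limited in the frequency domain, which keeps the
sampled record free of aliasing and exactly consistent with the analytic
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CHROMOPHORES = ("hemoglobin", "lipid", "collagen", "water")
CONDITIONS = ("normal", "steatosis", "fibrosis")

#: default optical grid: hemoglobin window plus lipid/collagen/water overtone
#: window, 10 nm tuning step
DEFAULT_WAVELENGTHS_NM = tuple(range(680, 951, 10)) + tuple(range(1200, 1701, 10))


# --------------------------------------------------------------------------
# chromophore spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Absorption spectrum of one chromophore.

    ``mu_a`` is the absorption coefficient (1/mm) contributed per unit
    volume fraction of the chromophore.
    """

    name: str
    wavelength_nm: np.ndarray
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if mu.shape != wl.shape:
            raise ValueError(f"{self.name}: mu_a and wavelength grids differ in length")
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise ValueError(f"{self.name}: mu_a must be finite and non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "mu_a", mu)

    def mu_at(self, wavelength_nm: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated absorption coefficient at ``wavelength_nm``."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"{self.name}: query wavelength outside tabulated range "
                f"[{lo:g}, {hi:g}] nm"
            )
        out = np.interp(lam, self.wavelength_nm, self.mu_a)
        return float(out) if np.isscalar(wavelength_nm) else out


def load_chromophore_table(path) -> dict[str, ChromophoreSpectrum]:
    """Read a chromophore absorption table from CSV.

    Layout: a ``wavelength_nm`` column followed by one column per
    chromophore, all on a common strictly increasing grid.
    """
    table = pd.read_csv(path)
    if "wavelength_nm" not in table.columns:
        raise ValueError("chromophore CSV must contain a 'wavelength_nm' column")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    spectra = {}
    for name in table.columns:
        if name == "wavelength_nm":
            continue
        spectra[name] = ChromophoreSpectrum(name, wl, table[name].to_numpy(dtype=float))
    if not spectra:
        raise ValueError("chromophore CSV contains no chromophore columns")
    return spectra


def _gauss(lam: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((lam - center) / width) ** 2)


def default_chromophores() -> dict[str, ChromophoreSpectrum]:
    """Bundled liver chromophore table.

    Qualitative near-infrared features: hemoglobin dominates below 950 nm;
    lipid peaks at 1210 nm with a secondary peak at 1450 nm; collagen peaks
    at 1370 nm; water absorbs broadly over 1400–1600 nm.  Magnitudes are
    plausible for soft tissue but only the peak positions are contractual.
    """
    lam = np.asarray(DEFAULT_WAVELENGTHS_NM, dtype=float)
    hemoglobin = 0.35 * np.exp(-(lam - 680.0) / 150.0)
    hemoglobin[lam > 1000] = 0.35 * np.exp(-(950.0 - 680.0) / 150.0) * 0.15
    lipid = (
        0.004
        + _gauss(lam, 930.0, 20.0, 0.015)
        + _gauss(lam, 1210.0, 25.0, 0.120)
        + _gauss(lam, 1450.0, 40.0, 0.070)
    )
    collagen = (
        0.004
        + _gauss(lam, 1370.0, 30.0, 0.100)
        + _gauss(lam, 1700.0, 80.0, 0.040)
    )
    water = (
        0.002
        + _gauss(lam, 970.0, 25.0, 0.010)
        + _gauss(lam, 1450.0, 75.0, 0.110)
    )
    cols = {"hemoglobin": hemoglobin, "lipid": lipid, "collagen": collagen, "water": water}
    return {k: ChromophoreSpectrum(k, lam, v) for k, v in cols.items()}


def bundled_chromophore_path():
    """Path-like handle to the shipped chromophore CSV."""
    return resources.files("papca").joinpath("data/chromophores.csv")


def absorption_coefficient(
    composition: Mapping[str, float],
    spectra: Mapping[str, ChromophoreSpectrum],
    wavelength_nm: float,
) -> float:
    """Absorption coefficient (1/mm) of a chromophore mixture.

    Linear mixing: ``mu_a = Σ_k fraction_k · mu_a_k(λ)``.
    """
    mu = 0.0
    for name, fraction in composition.items():
        if name not in spectra:
            raise KeyError(f"unknown chromophore {name!r}")
        mu += float(fraction) * spectra[name].mu_at(wavelength_nm)
    return mu


def _validate_composition(composition: Mapping[str, float], what: str) -> dict[str, float]:
    comp = {k: float(v) for k, v in composition.items()}
    if any(v < 0 for v in comp.values()):
        raise ValueError(f"{what}: volume fractions must be non-negative")
    if sum(comp.values()) > 1.0 + 1e-9:
        raise ValueError(f"{what}: volume fractions must sum to at most 1")
    return comp


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Absorber:
    """A spherical absorber: position, radius and chromophore make-up."""

    center_mm: np.ndarray
    radius_mm: float
    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.center_mm, dtype=float)
        if c.shape != (3,):
            raise ValueError("center_mm must be a 3-vector")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")
        object.__setattr__(self, "center_mm", c)
        object.__setattr__(
            self, "composition", _validate_composition(self.composition, "absorber")
        )


@dataclass(frozen=True)
class Phantom:
    """Labeled sphere-ensemble tissue model in a box ``[0, extent]³``."""

    condition: str
    background_composition: Mapping[str, float]
    absorbers: tuple[Absorber, ...]
    extent_mm: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        ext = np.asarray(self.extent_mm, dtype=float)
        if ext.shape != (3,) or np.any(ext <= 0):
            raise ValueError("extent_mm must be a positive 3-vector")
        object.__setattr__(self, "extent_mm", ext)
        object.__setattr__(self, "absorbers", tuple(self.absorbers))
        object.__setattr__(
            self,
            "background_composition",
            _validate_composition(self.background_composition, "background"),
        )
        for a in self.absorbers:
            if np.any(a.center_mm < 0) or np.any(a.center_mm > ext):
                raise ValueError("absorber center outside phantom extent")


@dataclass(frozen=True)
class ConditionProfile:
    """Generator defaults for one liver condition."""

    density_per_mm3: float
    radius_median_mm: float
    radius_sigma_ln: float
    absorber_composition: Mapping[str, float]
    background_composition: Mapping[str, float]


# Normal liver: well-perfused, homogeneous — few discrete absorbers above a
# hemoglobin-rich background.  Steatosis: dense lipid droplets at the
# hundred-micron scale with reduced background hemoglobin (distorted
# sinusoids carry less blood).  Fibrosis: dense collagen-rich deposits,
# likewise with reduced background hemoglobin.  Diseased absorbers carry a
# trace hemoglobin fraction (residual blood trapped between deposits), which
# fragments the hemoglobin signal and extends the 700 nm fingerprint.
CONDITION_PROFILES: dict[str, ConditionProfile] = {
    "normal": ConditionProfile(
        density_per_mm3=0.5,
        radius_median_mm=0.15,
        radius_sigma_ln=0.25,
        absorber_composition={"hemoglobin": 0.50, "water": 0.50},
        background_composition={
            "hemoglobin": 0.12, "lipid": 0.03, "collagen": 0.02, "water": 0.70,
        },
    ),
    "steatosis": ConditionProfile(
        density_per_mm3=5.0,
        radius_median_mm=0.08,
        radius_sigma_ln=0.30,
        absorber_composition={"lipid": 0.75, "water": 0.20, "hemoglobin": 0.05},
        background_composition={
            "hemoglobin": 0.07, "lipid": 0.08, "collagen": 0.02, "water": 0.70,
        },
    ),
    "fibrosis": ConditionProfile(
        density_per_mm3=5.0,
        radius_median_mm=0.08,
        radius_sigma_ln=0.30,
        absorber_composition={"collagen": 0.65, "water": 0.30, "hemoglobin": 0.05},
        background_composition={
            "hemoglobin": 0.07, "lipid": 0.03, "collagen": 0.08, "water": 0.70,
        },
    ),
}


def generate_phantom(
    condition: str,
    extent_mm: Sequence[float] = (4.0, 4.0, 4.0),
    density_per_mm3: float | None = None,
    radius_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    *,
    profile: ConditionProfile | None = None,
) -> Phantom:
    """Draw a reproducible sphere-ensemble phantom for one condition.

    The absorber count is Poisson(density × volume), centers are uniform in
    the box, radii follow the condition's lognormal size distribution unless
    ``radius_dist`` is supplied, and per-absorber compositions carry mild
    multiplicative jitter around the condition's chemistry.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    ext = np.asarray(extent_mm, dtype=float)
    if ext.shape != (3,) or np.any(ext <= 0):
        raise ValueError("extent_mm must be a positive 3-vector")
    prof = profile or CONDITION_PROFILES[condition]
    density = prof.density_per_mm3 if density_per_mm3 is None else float(density_per_mm3)
    if density < 0:
        raise ValueError("density_per_mm3 must be non-negative")

    rng = np.random.default_rng(seed)
    volume = float(np.prod(ext))
    n = int(rng.poisson(density * volume))
    centers = rng.uniform(0.0, ext, size=(n, 3))
    if radius_dist is not None:
        radii = np.asarray(radius_dist(rng, n), dtype=float)
    else:
        radii = prof.radius_median_mm * np.exp(
            rng.normal(0.0, prof.radius_sigma_ln, size=n)
        )
    absorbers = []
    for i in range(n):
        comp = {}
        total = 0.0
        for name, frac in prof.absorber_composition.items():
            f = frac * float(np.exp(rng.normal(0.0, 0.10)))
            comp[name] = f
            total += f
        if total > 1.0:  # renormalize rare overshoots of the volume budget
            comp = {k: v / total for k, v in comp.items()}
        absorbers.append(Absorber(centers[i], float(radii[i]), comp))
    return Phantom(
        condition=condition,
        background_composition=dict(prof.background_composition),
        absorbers=tuple(absorbers),
        extent_mm=ext,
        seed=int(seed),
    )


def generate_cohort(condition: str, n_specimens: int, seed: int = 0) -> list[Phantom]:
    """A cohort of phantoms with specimen-to-specimen biological variability.

    Between-specimen variation (lognormal jitter on absorber density, droplet
    size and background hemoglobin) emulates animal-to-animal differences;
    within-specimen randomness comes from :func:`generate_phantom`.
    """
    rng = np.random.default_rng([int(seed), CONDITIONS.index(condition)])
    base = CONDITION_PROFILES[condition]
    phantoms = []
    for _ in range(n_specimens):
        background = dict(base.background_composition)
        background["hemoglobin"] *= float(np.exp(rng.normal(0.0, 0.15)))
        profile = ConditionProfile(
            density_per_mm3=base.density_per_mm3 * float(np.exp(rng.normal(0.0, 0.15))),
            radius_median_mm=base.radius_median_mm * float(np.exp(rng.normal(0.0, 0.10))),
            radius_sigma_ln=base.radius_sigma_ln,
            absorber_composition=base.absorber_composition,
            background_composition=background,
        )
        phantoms.append(
            generate_phantom(
                condition,
                seed=int(rng.integers(0, 2**31 - 1)),
                profile=profile,
            )
        )
    return phantoms


# --------------------------------------------------------------------------
# acquisition and forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSettings:
    """Emulated scanning-system settings.

    Defaults mirror the modeled acquisition: 10 nm optical tuning step over
    680–950 and 1200–1700 nm, 15–20 mJ pulses, 30 averaged shots per frame,
    and a point sensor 10 mm below the sample.
    """

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    fs_MHz: float = 50.0
    n_samples: int = 2048
    n_averages: int = 30
    v_s_mm_per_us: float = 1.5
    noise_sigma: float = 1e-3
    energy_range_mJ: tuple[float, float] = (15.0, 20.0)
    mu_eff_per_mm: Callable[[float], float] | None = None
    mu_s_prime_per_mm: float = 1.0
    sensor_position_mm: tuple[float, float, float] = (2.0, 2.0, -10.0)
    t0_us: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_MHz <= 0 or self.n_samples < 2:
            raise ValueError("fs_MHz must be positive and n_samples >= 2")
        if self.n_averages < 1:
            raise ValueError("n_averages must be at least 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        lo, hi = self.energy_range_mJ
        if not 0 < lo <= hi:
            raise ValueError("energy_range_mJ must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class RFFrame:
    """One optical wavelength's averaged RF record."""

    wavelength_nm: float
    pulse_energy: float  # mJ, mean of the monitored per-shot energies
    samples: np.ndarray
    fs_MHz: float
    t0_us: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if not self.pulse_energy > 0:
            raise ValueError("pulse_energy must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def times_us(self) -> np.ndarray:
        return self.t0_us + np.arange(self.samples.size) / self.fs_MHz


def nwave_spectrum(R_mm: float, v_s_mm_per_us: float, f_MHz) -> np.ndarray:
    """Relative amplitude spectrum of the N-wave from a heated sphere.

    ``|sin x − x cos x| / x²`` with ``x = 2π f R / v_s``; continuous at
    ``x = 0`` where it behaves as ``x/3`` (linear rise in frequency).  Nulls
    sit at the roots of ``tan x = x``, so halving the radius doubles every
    null frequency.
    """
    if R_mm <= 0:
        raise ValueError("R_mm must be positive")
    f = np.asarray(f_MHz, dtype=float)
    x = 2.0 * np.pi * f * R_mm / v_s_mm_per_us
    return np.abs(_sphere_shape(x))


def _sphere_shape(x: np.ndarray) -> np.ndarray:
    """Signed (sin x − x cos x)/x², series-expanded near the origin."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 30.0
    xl = x[~small]
    out[~small] = (np.sin(xl) - xl * np.cos(xl)) / xl**2
    return out


def nwave_first_null_MHz(R_mm: float, v_s_mm_per_us: float) -> float:
    """Frequency of the first spectral null: x* · v_s / (2πR), tan x* = x*."""
    from scipy.optimize import brentq

    x_star = brentq(lambda x: np.tan(x) - x, np.pi + 1e-6, 1.5 * np.pi - 1e-6)
    return x_star * v_s_mm_per_us / (2.0 * np.pi * R_mm)


def default_mu_eff(
    background_composition: Mapping[str, float],
    spectra: Mapping[str, ChromophoreSpectrum],
    mu_s_prime_per_mm: float = 1.0,
) -> Callable[[float], float]:
    """Diffusion-theory effective attenuation of the background medium.

    ``mu_eff = sqrt(3 · mu_a · (mu_a + mu_s'))`` with the background mixture's
    absorption and a wavelength-independent reduced scattering coefficient.
    """

    def mu_eff(lam: float) -> float:
        mu_a = absorption_coefficient(background_composition, spectra, lam)
        return float(np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime_per_mm)))

    return mu_eff


def _frame_rng(phantom_seed: int, wavelength_nm: float) -> np.random.Generator:
    # one stream per (phantom, wavelength): bit-identical replay per frame
    return np.random.default_rng([int(phantom_seed) & 0x7FFFFFFF, int(round(wavelength_nm * 10))])


def _absorber_geometry(phantom: Phantom, settings: AcquisitionSettings):
    """Ranges, depths and radii of all sources including the background blob.

    The diffuse background is represented by one large effective sphere of
    radius ``min(extent)/2`` at the box center, radiating the low-frequency
    bulk signal.
    """
    sensor = np.asarray(settings.sensor_position_mm, dtype=float)
    if np.all(sensor >= 0) and np.all(sensor <= phantom.extent_mm):
        raise ValueError("sensor must be outside the phantom volume")
    centers = [a.center_mm for a in phantom.absorbers]
    radii = [a.radius_mm for a in phantom.absorbers]
    comps = [a.composition for a in phantom.absorbers]
    # background blob
    centers.append(phantom.extent_mm / 2.0)
    radii.append(float(np.min(phantom.extent_mm)) / 2.0)
    comps.append(phantom.background_composition)
    centers = np.asarray(centers)
    radii = np.asarray(radii, dtype=float)
    ranges = np.linalg.norm(centers - sensor[None, :], axis=1)
    depths = centers[:, 2]  # illumination along +z from the z=0 face
    return ranges, depths, radii, comps


def _spectral_kernel(
    ranges: np.ndarray,
    radii: np.ndarray,
    settings: AcquisitionSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-source complex spectrum on the rfft grid, without chemistry.

    Source ``k`` contributes ``(R_k/r_k) · 2a_k · i · g(x)/x² · e^{−iωτ_k}``
    with ``a_k = R_k/v_s`` and arrival time ``τ_k = r_k/v_s``; the chemistry
    weight (absorption × fluence) multiplies this kernel per wavelength.
    """
    f = np.fft.rfftfreq(settings.n_samples, d=1.0 / settings.fs_MHz)  # MHz
    omega = 2.0 * np.pi * f
    a = radii / settings.v_s_mm_per_us  # µs
    tau = ranges / settings.v_s_mm_per_us
    x = omega[None, :] * a[:, None]
    shape = _sphere_shape(x)
    amp = (radii / ranges)[:, None] * (2.0 * a)[:, None] * shape
    kernel = 1j * amp * np.exp(-1j * omega[None, :] * (tau - settings.t0_us)[:, None])
    # DFT synthesis: divide by the sample interval so irfft reproduces the
    # continuous-time amplitudes
    kernel /= 1.0 / settings.fs_MHz
    return f, kernel


def _check_window(ranges, radii, settings):
    a = radii / settings.v_s_mm_per_us
    tau = ranges / settings.v_s_mm_per_us
    t_end = settings.t0_us + (settings.n_samples - 1) / settings.fs_MHz
    if np.any(tau - a < settings.t0_us) or np.any(tau + a > t_end):
        raise ValueError(
            "sampling window too short: acoustic arrivals fall outside "
            f"[{settings.t0_us:g}, {t_end:g}] us"
        )


def simulate_frames(
    phantom: Phantom,
    settings: AcquisitionSettings | None = None,
    spectra: Mapping[str, ChromophoreSpectrum] | None = None,
    wavelengths_nm: Sequence[float] | None = None,
) -> list[RFFrame]:
    """Forward-simulate averaged RF frames at each optical wavelength.

    Per wavelength λ, source k contributes with weight
    ``mu_a(comp_k, λ) · exp(−mu_eff(λ)·depth_k)``; the noise-free signal
    scales linearly with pulse energy.  Averaging the ``n_averages`` shots
    (energies E_i, independent sensor noise) is carried out in closed form:
    the averaged frame is ``mean(E_i)·s(t)`` plus Gaussian noise of standard
    deviation ``noise_sigma/√n_averages``.
    """
    settings = settings or AcquisitionSettings()
    spectra = spectra or default_chromophores()
    lams = tuple(wavelengths_nm) if wavelengths_nm is not None else settings.wavelengths_nm

    ranges, depths, radii, comps = _absorber_geometry(phantom, settings)
    _check_window(ranges, radii, settings)
    _, kernel = _spectral_kernel(ranges, radii, settings)

    mu_eff = settings.mu_eff_per_mm or default_mu_eff(
        phantom.background_composition, spectra, settings.mu_s_prime_per_mm
    )

    frames = []
    for lam in lams:
        rng = _frame_rng(phantom.seed, lam)
        fluence = np.exp(-mu_eff(lam) * np.maximum(depths, 0.0))
        mu = np.array([absorption_coefficient(c, spectra, lam) for c in comps])
        weights = mu * fluence
        spectrum = weights @ kernel
        signal = np.fft.irfft(spectrum, n=settings.n_samples)
        energies = rng.uniform(*settings.energy_range_mJ, size=settings.n_averages)
        mean_energy = float(np.mean(energies))
        noise = rng.normal(
            0.0,
            settings.noise_sigma / np.sqrt(settings.n_averages),
            size=settings.n_samples,
        )
        samples = mean_energy * signal + noise
        frames.append(
            RFFrame(
                wavelength_nm=float(lam),
                pulse_energy=mean_energy,
                samples=samples,
                fs_MHz=settings.fs_MHz,
                t0_us=settings.t0_us,
            )
        )
    return frames


def simulate_rf(
    phantom: Phantom,
    settings: AcquisitionSettings | None = None,
    wavelength_nm: float = 700.0,
    spectra: Mapping[str, ChromophoreSpectrum] | None = None,
) -> RFFrame:
    """Single-wavelength convenience wrapper around :func:`simulate_frames`."""
    return simulate_frames(phantom, settings, spectra, wavelengths_nm=[wavelength_nm])[0]
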