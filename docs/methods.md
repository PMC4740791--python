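# Methods

This note records the models, numerical choices and known limitations behind
`papca`, in the order data flows through the pipeline.

## Forward model

**Acoustic kernel.**  Each absorber is a sphere heated impulsively and
uniformly.  Its far-field pressure is the classic N-wave — a linear bipolar
ramp of half-duration a = R/v_s — whose amplitude spectrum is
|sin x − x cos x|/x², x = 2πfR/v_s (continuous at x = 0, rising as x/3).
Nulls sit at the roots of tan x = x; the first, x* ≈ 4.4934, puts the
first null of a 0.1 mm sphere in 1.5 mm/µs tissue at 10.73 MHz.  An
absorber at range r contributes with amplitude μ_a(comp, λ)·Φ(depth, λ)·R/r.

**Band-limited synthesis.**  Frames are synthesized in the frequency domain:
the analytic spectrum (with the arrival-time phase e^{−iωr/v_s}) is sampled
on the rfft grid of the record and inverse-transformed.  The sampled record
is therefore alias-free and exactly consistent with the analytic spectrum —
which is what makes the periodogram-vs-analytic-spectrum oracle test
meaningful at the 1% level.  The cost is mild sinc ringing around the
compact pulse support in the time domain.

**Fluence.**  1-D Beer–Lambert depth weighting Φ = exp(−μ_eff(λ)·z), with
μ_eff = √(3 μ_a(μ_a + μ_s′)) computed from the background mixture and a
wavelength-independent μ_s′ = 1 mm⁻¹.  This is the simplest model that
produces wavelength-dependent depth weighting; real fluence fields in
scattering tissue are not reproduced.

**Averaged acquisition.**  Each frame averages n = 30 shots with per-shot
energies drawn uniformly from 15–20 mJ and independent Gaussian sensor
noise.  Because the signal is linear in energy, the average equals
mean(E)·s(t) plus noise of standard deviation σ/√n; the simulator draws the
n energies and a single reduced-σ noise vector, which is distributionally
identical to the per-shot loop and much cheaper.  Per-(phantom, wavelength)
RNG streams make frames bit-reproducible.

**Background.**  The diffuse background mixture is represented by one large
effective sphere (radius = half the box edge) at the phantom center,
radiating the low-frequency bulk term.  Defaults: 4×4×4 mm box, sensor
10 mm below the illuminated face, fs = 50 MHz, 2048 samples, v_s = 1.5
mm/µs, per-shot noise σ = 10⁻³ (arbitrary linear units, signal peaks are
of order 10⁻²·E).

## Conditions

No quantitative per-condition absorber size distribution is established for
this kind of model; the profiles below were chosen once as a plausible
rendering of "hundred-micron level" histology and are configuration, not
asserted biology.

| condition | density (mm⁻³) | radius (lognormal median / σln) | absorber chemistry | background Hb |
|---|---|---|---|---|
| normal    | 0.5 | 0.15 mm / 0.25 | Hb 0.50, water 0.50 | 0.12 |
| steatosis | 5.0 | 0.08 mm / 0.30 | lipid 0.75, water 0.20, Hb 0.05 | 0.07 |
| fibrosis  | 5.0 | 0.08 mm / 0.30 | collagen 0.65, water 0.30, Hb 0.05 | 0.07 |

Diseased conditions carry reduced background hemoglobin (distorted sinusoids
perfuse poorly) and a trace hemoglobin fraction inside the deposits, which
fragments the hemoglobin signal and extends the 700 nm fingerprint.
Cohorts add between-specimen lognormal jitter (15% on density and background
Hb, 10% on droplet size) to emulate animal-to-animal variability;
within-phantom jitter (10% per absorber composition) emulates local
heterogeneity.  The generator itself is exactly Poisson in absorber count so
its statistics are testable in closed form.

**Chromophore table.**  The bundled CSV has qualitatively correct NIR
features — hemoglobin dominant below 950 nm, lipid peaks at 1210 and
1450 nm, collagen at 1370 nm, water broad over 1400–1600 nm — with
magnitudes plausible for soft tissue (10⁻³–10⁻¹ mm⁻¹ per unit volume
fraction).  Only the peak positions are contractual; values are not
literature data.

## Calibration

All three corrections are multiplicative in the linear signal, so they
commute and their order is immaterial (tested).  Attenuation follows the
soft-tissue power law with defaults α₀ = 0.5 dB·cm⁻¹·MHz⁻¹, y = 1, path
1.2 cm; the compensation adds 2·α₀·d·f^y dB to the power spectrum.  The
in-situ mode flag skips attenuation compensation (probe in contact with the
tissue).  System-response deconvolution divides power by
max(|H|², (0.01·max|H|)²); the 1% floor caps the gain at 10⁴ and prevents
noise blow-up where the response rolls off.  The response estimator windows
the dominant transient (Hann, 256 samples by default) and requires the peak
to exceed 8× the record's median absolute amplitude — the peak/median ratio
of pure Gaussian noise is ≈ 5 at these record lengths, so this rejects
no-transient records without rejecting genuine impulses.

## Spectrogram and spectral parameters

The spectral estimator is a single Hann-tapered periodogram of the
time-averaged record (averaging happens in the time domain before the
transform), normalized so the one-sided power sums to the tapered record's
energy (Parseval, tested to 1e−6).  Welch-style averaging is available
through `power_spectrum` on segmented records but is not the default.

The PCS reference is its own global maximum (0 dB at the peak).  Slopes are
reference-invariant; intercept and midband-fit are therefore *relative*
magnitudes within a specimen's spectrogram.  The absorption proxy sums
linear-scale *amplitudes* (√power) over 0.1–8 MHz per wavelength; a config
flag switches to power sums.  Rows in 1400–1600 nm are retained in the PCS
but excluded from feature extraction, since lipid and water absorption
overlap there and the two cannot be separated from a single band.

PASA is ordinary least squares of dB power against frequency over a config
band (default 0.1–8 MHz, inside the sub-10 MHz probe band).  The midband
identity mid = intercept + slope·(f_lo+f_hi)/2 holds by construction to
1e−9 dB.  On the default acquisition grid the analysis band holds 323 bins;
with 1 dB Gaussian spectral noise OLS theory gives a slope standard error of
σ/√S_xx ≈ 0.024 dB/MHz, so the ±0.05 dB/MHz band corresponds to ≈ 2σ and
empirical coverage ≈ 96% — the acceptance check asserts ≥ 95% at 1000
trials.  (With only 100 bins over the same band the predicted coverage is
74%; the stated precision is a property of the full spectral grid.)

Parameter maps tile each A-line with 128-sample Hann windows at 50%
overlap and mask windows below 10% of the image peak; percentiles in group
summaries interpolate linearly between order statistics, with outliers by
the 1.5·IQR rule.  Off-grid wavelength lookups snap to the nearest row
within 5 nm (half the tuning step).

## Classification

The kernel is strictly homogeneous, (γ⟨u,v⟩)³ with no constant term.  The
quadratic program is solved by scikit-learn's `SVC` (`kernel='poly'`,
`coef0=0`, `degree=3` is exactly this kernel); an explicit dual-QP solve on
the same Gram matrix serves as an independent oracle in the tests.
One-vs-one voting is re-implemented on the pairwise decision values so the
tie rule is explicit and logged: tied votes (including zero decisions) fall
to the lowest class index.

Min–max normalization to [0, 1] is computed per parameter *type* — one
affine map for all three slope columns, another for the midband columns —
preserving relative differences among wavelengths.  The default fits the
transform on the training folds only and applies it unchanged to the test
fold (no leakage); a `global` mode normalizes the full table first, for
feature files that were pre-normalized as a whole.  Degenerate constant
groups map to 0; held-out values are not clipped.

Cross-validation draws seeded stratified thirds (counts must be equal per
class and divisible by 3; 12 per condition gives 24 train / 12 test per
cycle) and averages the three cycle accuracies.  Grid search scans
exponential grids (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³) by mean cross-validated
testing accuracy by default — per-cycle selection on training accuracy is
selectable — with ties to the smallest C, then smallest γ.  Default
operating point C = 10, γ = 1/6.

## Problem sizes and what the synthetic results show

The end-to-end staging study uses 12 phantoms per condition on the full
79-wavelength grid and 10 cross-validation fold seeds; the directional
fingerprint contrasts use 20 matched phantom seeds per condition at the
three analysis wavelengths.  Under the default conditions the combined
slope+midband feature set stages the synthetic cohorts at ≥ 80% mean
testing accuracy and is at least as accurate as either parameter type
alone; steatosis exceeds normal in slope and midband at 1220 nm, and
fibrosis exceeds normal at 1370 nm, each beyond 2σ on the cohort mean.
These demonstrate internal consistency of the pipeline on a generator whose
effect sizes are set by the profiles above — they are not evidence about
real livers, where fluence heterogeneity, acoustic scattering, probe
directivity and biological variability are all richer than the simulator.

## Known limitations

* Single-scattering-free acoustics: no full-wave propagation, attenuation
  inside the phantom, nonlinearity, or array directivity; beamformed
  A-lines are an input, not something the package computes.
* Sphere-only microstructure; fibrous strands are rendered as equivalent
  sphere ensembles, so only spectral statistics — not morphology — are
  meaningful.
* Midband-fit and intercept are relative to the per-specimen PCS maximum;
  absolute cross-instrument magnitudes are out of scope.
* The attenuation coefficients actually present in any given measurement
  are configuration; no claim of equivalence with any specific instrument's
  calibrated magnitudes is made.
* No spectral unmixing: chromophore concentrations are read off fingerprint
  bands, not solved for; the lipid/water overlap band is excluded.
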