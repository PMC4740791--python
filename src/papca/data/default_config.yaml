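# Default run configuration.  Values are plain YAML so a study can be
# reproduced by archiving this single document together with the seed.
seed: 0

acquisition:
  fs_MHz: 50.0              # sampling rate of the digitizer
  n_samples: 2048           # record length per frame
  n_averages: 30            # shots averaged per wavelength
  v_s_mm_per_us: 1.5        # speed of sound
  noise_sigma: 0.001        # per-shot additive sensor noise (linear units)
  wavelengths_nm: null      # null = full 680-950 & 1200-1700 nm grid, 10 nm step
  sensor_position_mm: [2.0, 2.0, -10.0]
  energy_range_mJ: [15.0, 20.0]   # per-pulse laser energy window

phantom:
  extent_mm: [4.0, 4.0, 4.0]

calibration:
  alpha0: 0.5               # dB cm^-1 MHz^-y, generic soft tissue
  y: 1.0                    # attenuation power-law exponent
  path_cm: 1.2              # sensor-to-sample acoustic path
  floor_frac: 0.01          # deconvolution floor, fraction of peak |H|
  mode: ex_vivo             # in_situ disables attenuation compensation

analysis:
  band_MHz: [0.1, 8.0]      # spectral-fit and proxy-sum band
  wavelengths_nm: [700.0, 1220.0, 1370.0]   # hemoglobin / lipid / collagen
  wavelength_tol_nm: 5.0    # off-grid lookup tolerance (half the tuning step)
  proxy_scale: amplitude    # absorption proxy sums amplitudes, not powers
  fingerprint_bands_nm:
    hemoglobin: [700.0, 700.0]
    lipid: [1200.0, 1240.0]
    collagen: [1350.0, 1390.0]
  excluded_band_nm: [1400.0, 1600.0]  # lipid/water overlap, kept out of features

map:
  window_len: 128           # samples per axial window
  overlap: 0.5
  intensity_threshold: 0.1  # overlay mask, fraction of image maximum

svm:
  C: 10.0
  gamma: 0.16666666666666666
  degree: 3
  normalization: train-fold # fit the min-max transform on training folds only
  C_grid: [0.03125, 0.125, 0.5, 2.0, 8.0, 32.0, 128.0, 512.0, 2048.0, 8192.0, 32768.0]
  gamma_grid: [3.0517578125e-05, 0.0001220703125, 0.00048828125, 0.001953125, 0.0078125, 0.03125, 0.125, 0.5, 2.0, 8.0]
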