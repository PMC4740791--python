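import numpy as np
import pytest

from papca import calibrate, pasa, pcs, synth


@pytest.fixture(scope="session")
def chromophores():
    return synth.default_chromophores()


@pytest.fixture(scope="session")
def quiet_settings():
    """Noise-free acquisition with flat fluence, for physics oracles."""
    return synth.AcquisitionSettings(noise_sigma=0.0, mu_eff_per_mm=lambda lam: 0.0)


def single_sphere_phantom(radius_mm=0.1, composition=None, center=(2.0, 2.0, 2.0)):
    return synth.Phantom(
        condition="normal",
        background_composition={},
        absorbers=(synth.Absorber(np.array(center), radius_mm,
                                  composition or {"lipid": 1.0}),),
        extent_mm=np.array([4.0, 4.0, 4.0]),
        seed=0,
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    return single_sphere_phantom()


def cohort_features(n_per_condition, seed, wavelengths=None):
    """Simulate cohorts and extract PASA features; shared by staging tests."""
    calibration = calibrate.CalibrationConfig(attenuation=calibrate.AttenuationModel())
    X, y = [], []
    for cond in synth.CONDITIONS:
        for ph in synth.generate_cohort(cond, n_per_condition, seed=seed):
            frames = synth.simulate_frames(ph, wavelengths_nm=wavelengths)
            matrix = pcs.assemble_pcs(frames, calibration)
            lams = wavelengths if wavelengths is not None else pasa.DEFAULT_WAVELENGTHS_NM
            X.append(pasa.pasa_at_wavelengths(matrix, lams))
            y.append(cond)
    return np.array(X), np.array(y)


@pytest.fixture(scope="session")
def staging_features():
    """12 specimens per condition on the full optical grid (default config)."""
    return cohort_features(12, seed=1)
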