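import numpy as np
import pytest

import cinnaprint as cp
from cinnaprint.quantify import (
    DEFAULT_CALIBRATION,
    ReferenceCalibration,
    estimate_noise_floor,
    integrate_region,
    quantify_metabolite,
    quantify_sample,
)
from cinnaprint.simulate import EXTRACT_VOLUME_L, SAMPLE_MASS_G, GroundTruth, mg_per_g_to_molar


def lorentzian(ppm, center, fwhm, area=1.0):
    hwhm = fwhm / 2.0
    return area * (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm**2)


def test_zero_spectrum_integrates_to_zero():
    s = cp.Spectrum(np.linspace(0, 12, 1000), np.zeros(1000))
    assert integrate_region(s, (2.0, 3.0)) == 0.0


def test_unit_lorentzian_area_in_wide_window():
    # analytic check: a window 20 FWHM wide captures 2/pi * arctan(20) ~ 0.968
    ppm = np.linspace(0, 12, 200_001)
    fwhm = 0.01
    s = cp.Spectrum(ppm, lorentzian(ppm, 6.0, fwhm))
    area = integrate_region(s, (6.0 - 10 * fwhm, 6.0 + 10 * fwhm))
    assert 0.95 <= area <= 1.0
    assert area == pytest.approx(2 / np.pi * np.arctan(20), rel=1e-3)


def test_integration_additive_over_adjacent_windows(rng):
    ppm = np.linspace(0, 12, 10_001)
    s = cp.Spectrum(ppm, np.abs(rng.normal(size=ppm.size)))
    total = integrate_region(s, (2.0, 4.0))
    split = integrate_region(s, (2.0, 3.1)) + integrate_region(s, (3.1, 4.0))
    assert split == pytest.approx(total, rel=1e-12)


def test_window_outside_grid_rejected():
    s = cp.Spectrum(np.linspace(1, 10, 100), np.zeros(100))
    with pytest.raises(ValueError, match="outside"):
        integrate_region(s, (9.5, 11.0))


def test_zero_signal_reports_nd(quiet_params):
    # all-zero concentrations: reference + solvent only, no analyte signal
    truth = GroundTruth("x", "C. verum", {m: 0.0 for m in cp.list_metabolites()})
    s = cp.simulate_spectrum(truth, quiet_params)
    value, nd = quantify_metabolite(s, "Coumarin")
    assert value == 0.0 and nd


def test_invalid_calibration_rejected():
    s = cp.Spectrum(np.linspace(-0.5, 12.5, 4096), np.zeros(4096))
    with pytest.raises(ValueError, match="invalid calibration"):
        quantify_metabolite(s, "Coumarin")


def test_reference_window_must_avoid_quant_windows():
    with pytest.raises(ValueError, match="overlaps"):
        ReferenceCalibration(ref_window=(7.9, 8.0))


def test_coumarin_round_trip_within_one_percent(quiet_params):
    truth = GroundTruth("Cin_cass_20", "C. cassia", {"Coumarin": 9.2})
    s = cp.simulate_spectrum(truth, quiet_params)
    value, nd = quantify_metabolite(s, "Coumarin")
    assert not nd
    assert value == pytest.approx(9.2, rel=0.01)


def test_doubling_analyte_area_doubles_result(quiet_params):
    s1 = cp.simulate_spectrum(GroundTruth("a", "C. cassia", {"Alanine": 1.7}), quiet_params)
    s2 = cp.simulate_spectrum(GroundTruth("a", "C. cassia", {"Alanine": 3.4}), quiet_params)
    v1, _ = quantify_metabolite(s1, "Alanine")
    v2, _ = quantify_metabolite(s2, "Alanine")
    assert v2 == pytest.approx(2 * v1, rel=1e-6)


def test_scale_equivariance(quiet_params):
    s = cp.simulate_spectrum(GroundTruth("a", "C. cassia", {"Coumarin": 4.0}), quiet_params)
    scaled = cp.Spectrum(s.ppm, 17.0 * s.intensity, dict(s.meta))
    v, _ = quantify_metabolite(s, "Coumarin")
    v_scaled, _ = quantify_metabolite(scaled, "Coumarin")
    assert v_scaled == pytest.approx(v, rel=1e-12)


def test_units_identity():
    # mg/g -> molar -> mg/g is the identity: the quantifier inverts the
    # simulator's concentration mapping dimensionally
    for mg_g, mw in [(9.2, 146.14), (0.05, 89.09), (42.0, 180.16)]:
        c = mg_per_g_to_molar(mg_g, mw)
        back = c * EXTRACT_VOLUME_L * mw * 1000.0 / SAMPLE_MASS_G
        assert back == pytest.approx(mg_g, rel=1e-12)


def test_identical_noise_free_replicates_have_zero_sd(quiet_params):
    truth = GroundTruth("Cin_veru_01", "C. verum", {"Coumarin": 0.8, "Eugenol": 6.44})
    reps = [cp.simulate_spectrum(truth, quiet_params) for _ in range(3)]
    result = quantify_sample(reps, metabolites=["Coumarin", "Eugenol"])
    assert result.sd["Coumarin"] == 0.0
    assert result.mean["Coumarin"] == pytest.approx(0.8, abs=0.01)


def test_single_replicate_rejected(quiet_params):
    s = cp.simulate_spectrum(GroundTruth("a", "C. verum", {"Coumarin": 1.0}), quiet_params)
    with pytest.raises(ValueError, match="replicate"):
        quantify_sample([s])


def test_inconsistent_replicate_grids_rejected(quiet_params):
    s1 = cp.simulate_spectrum(GroundTruth("a", "C. verum", {"Coumarin": 1.0}), quiet_params)
    s2 = cp.simulate_spectrum(
        GroundTruth("a", "C. verum", {"Coumarin": 1.0}),
        cp.SimulationParams(noise_sd=0.0, n_points=16384),
    )
    with pytest.raises(ValueError, match="inconsistent"):
        quantify_sample([s1, s2])


def test_triplicate_recovery_of_reference_row(ref_table):
    # simulate the triplicate measurement of one tabulated sample at low
    # noise and recover its generating concentrations
    row = ref_table.mean_filled(0.0).loc["Cin_veru_01"].to_dict()
    truth = GroundTruth("Cin_veru_01", "C. verum", row)
    reps = [
        cp.simulate_spectrum(truth, cp.SimulationParams(noise_sd=0.005, seed=s)) for s in (1, 2, 3)
    ]
    result = quantify_sample(reps)
    for name, true in row.items():
        if true >= 0.05:
            assert result.mean[name] == pytest.approx(true, rel=0.05), name


def test_noise_floor_estimate_matches_generator(quiet_params):
    params = cp.SimulationParams(noise_sd=0.02, seed=11)
    s = cp.simulate_spectrum(GroundTruth("a", "C. verum", {"Coumarin": 1.0}), params)
    assert estimate_noise_floor(s) == pytest.approx(0.02, rel=0.15)
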