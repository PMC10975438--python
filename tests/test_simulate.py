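import numpy as np
import pytest

import cinnaprint as cp
from cinnaprint.catalogue import UnknownMetaboliteError
from cinnaprint.io import bundled_table_path
from cinnaprint.quantify import integrate_region
from cinnaprint.simulate import (
    LINE_SUPPORT_PPM,
    GroundTruth,
    SimulationParams,
    cohort_to_table,
    generate_cohort,
    species_profiles_from_table,
    _draw_truncated_normal,
)


def test_same_seed_gives_bit_identical_spectra(quiet_params):
    truth = GroundTruth("Cin_cass_01", "C. cassia", {"Coumarin": 2.0})
    params = SimulationParams(noise_sd=0.02, seed=99)
    a = cp.simulate_spectrum(truth, params)
    b = cp.simulate_spectrum(truth, params)
    np.testing.assert_array_equal(a.intensity, b.intensity)
    c = cp.simulate_spectrum(truth, SimulationParams(noise_sd=0.02, seed=100))
    assert not np.array_equal(a.intensity, c.intensity)


def test_zero_concentrations_leave_only_reference_and_solvent(quiet_params):
    truth = GroundTruth("Cin_veru_01", "C. verum", {m: 0.0 for m in cp.list_metabolites()})
    s = cp.simulate_spectrum(truth, quiet_params)
    peaks = [0.0] + [c for c, _ in quiet_params.solvent_peaks]
    away = np.ones(s.ppm.size, dtype=bool)
    for center in peaks:
        away &= np.abs(s.ppm - center) > LINE_SUPPORT_PPM
    assert np.all(s.intensity[away] == 0.0)
    assert np.any(s.intensity[~away] > 0.0)


def test_area_linearity_doubling_concentrations(quiet_params):
    met = cp.get_metabolite("Eugenol")
    low = cp.simulate_spectrum(GroundTruth("Cin_veru_01", "C. verum", {"Eugenol": 3.0}), quiet_params)
    high = cp.simulate_spectrum(GroundTruth("Cin_veru_01", "C. verum", {"Eugenol": 6.0}), quiet_params)
    ref = integrate_region(low, (-0.05, 0.05))
    a_low = integrate_region(low, met.quant_signal.window)
    a_high = integrate_region(high, met.quant_signal.window)
    assert a_high == pytest.approx(2 * a_low, rel=1e-9)
    assert integrate_region(high, (-0.05, 0.05)) == pytest.approx(ref, rel=1e-12)


def test_unknown_metabolite_rejected(quiet_params):
    with pytest.raises(UnknownMetaboliteError):
        cp.simulate_spectrum(GroundTruth("x", "C. verum", {"caffeine": 1.0}), quiet_params)


def test_coarse_grid_records_warning_note():
    params = SimulationParams(n_points=4096, noise_sd=0.0)  # ~0.8 points per linewidth
    s = cp.simulate_spectrum(GroundTruth("x", "C. verum", {"Coumarin": 1.0}), params)
    assert "too coarse" in s.meta.get("notes", "")


def test_truncated_normal_never_negative(rng):
    draws = _draw_truncated_normal(rng, loc=0.1, scale=2.0, size=10_000)
    assert draws.min() >= 0.0
    assert _draw_truncated_normal(rng, 5.0, 0.0, 3).tolist() == [5.0, 5.0, 5.0]


def test_species_profiles_moments(ref_table, profiles):
    by_species = {p.species: p for p in profiles}
    # independent oracle: direct summation over the raw CSV text
    text = bundled_table_path().read_text(encoding="utf-8").splitlines()
    cols = text[0].split(",")
    idx = cols.index("Coumarin_mean")
    sums = {"Cin_cass": [], "Cin_veru": []}
    for line in text[1:]:
        cells = line.split(",")
        for prefix in sums:
            if cells[0].startswith(prefix):
                sums[prefix].append(0.0 if cells[idx] == "ND" else float(cells[idx]))
    assert by_species["C. cassia"].location["Coumarin"] == pytest.approx(np.mean(sums["Cin_cass"]))
    assert by_species["C. verum"].location["Coumarin"] == pytest.approx(np.mean(sums["Cin_veru"]))
    assert by_species["C. cassia"].location["Coumarin"] > by_species["C. verum"].location["Coumarin"]


def test_single_sample_species_has_zero_scale(ref_table):
    one_each = ref_table.mean.groupby(ref_table.species).head(1).index
    sub = cp.ConcentrationTable(
        mean=ref_table.mean.loc[one_each],
        sd=ref_table.sd.loc[one_each],
        nd_mask=ref_table.nd_mask.loc[one_each],
        species=ref_table.species.loc[one_each],
    )
    for p in species_profiles_from_table(sub):
        assert all(v == 0.0 for v in p.scale.values())


def test_cohort_counts_and_determinism(profiles):
    params = SimulationParams(n_points=8192, noise_sd=0.01)
    spectra, truths = generate_cohort(profiles, 1, params, seed=5)
    assert len(truths) == 3
    assert sum(len(reps) for reps in spectra) == 9
    spectra2, truths2 = generate_cohort(profiles, 1, params, seed=5)
    assert [t.conc_mg_per_g for t in truths] == [t.conc_mg_per_g for t in truths2]
    np.testing.assert_array_equal(spectra[0][0].intensity, spectra2[0][0].intensity)


def test_zero_scale_profiles_reproduce_location(profiles):
    degenerate = [
        cp.SpeciesProfile(p.species, p.location, {m: 0.0 for m in p.scale}) for p in profiles
    ]
    _, truths = generate_cohort(degenerate, 2, SimulationParams(n_points=4096), seed=0)
    for t in truths:
        loc = next(p.location for p in degenerate if p.species == t.species)
        assert t.conc_mg_per_g == pytest.approx(loc)


def test_ground_truth_table_round_trip(profiles):
    _, truths = generate_cohort(profiles, 2, SimulationParams(n_points=4096), seed=3)
    table = cohort_to_table(truths, lod_mg_per_g=0.05)
    assert table.n_samples == 6
    assert (table.nd_mask.to_numpy() == (np.nan_to_num(table.mean.to_numpy()) == 0)).all()
    truth0 = truths[0]
    for m, v in truth0.conc_mg_per_g.items():
        if v >= 0.05:
            assert table.mean.loc[truth0.sample_id, m] == pytest.approx(v)
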