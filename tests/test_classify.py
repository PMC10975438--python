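import numpy as np
import pandas as pd
import pytest

import cinnaprint as cp
from cinnaprint.classify import (
    MetaboliteOrdination,
    NearestCentroidSpecies,
    loo_accuracy,
    nearest_centroid_classify,
    pca_ordination,
    ratio_features,
    scale_matrix,
)


def test_planar_data_explained_by_two_components(rng):
    # points in a 2-D plane embedded in 6-D: two components carry everything
    basis = rng.normal(size=(2, 6))
    coeff = rng.normal(size=(30, 2))
    X = coeff @ basis + rng.normal(size=6)
    res = pca_ordination(pd.DataFrame(X), scaling="center")
    assert res.two_component_variance() == pytest.approx(100.0, abs=1e-8)


def test_variance_percentages_non_increasing(ref_table):
    res = pca_ordination(ref_table)
    v = res.var_explained_pct
    assert np.all(np.diff(v) <= 1e-9)
    assert v.sum() <= 100 + 1e-6


def test_row_permutation_leaves_variance_unchanged(ref_table, rng):
    res = pca_ordination(ref_table)
    perm = rng.permutation(ref_table.n_samples)
    shuffled = cp.ConcentrationTable(
        mean=ref_table.mean.iloc[perm],
        sd=ref_table.sd.iloc[perm],
        nd_mask=ref_table.nd_mask.iloc[perm],
        species=ref_table.species.iloc[perm],
    )
    res_p = pca_ordination(shuffled)
    np.testing.assert_allclose(res.var_explained_pct, res_p.var_explained_pct, atol=1e-9)


def test_reconstruction_from_all_components(ref_table):
    X = ref_table.mean_filled(0.0).to_numpy()
    Xs, keep = scale_matrix(X, "autoscale")
    est = MetaboliteOrdination(scaling="autoscale").fit(X)
    recon = est.scores_ @ est.components_ + Xs.mean(axis=0)
    np.testing.assert_allclose(recon, Xs, atol=1e-8)


def test_zero_variance_column_dropped_with_warning():
    X = np.column_stack([np.arange(10.0), np.full(10, 3.0), np.arange(10.0) ** 2])
    with pytest.warns(UserWarning, match="zero-variance"):
        Xs, keep = scale_matrix(X, "autoscale")
    assert Xs.shape[1] == 2 and not keep[1]


def test_component_sign_is_fixed(ref_table):
    res = pca_ordination(ref_table)
    for pc in res.loadings.columns:
        col = res.loadings[pc]
        assert col.iloc[np.abs(col.to_numpy()).argmax()] > 0


def test_fewer_than_three_samples_rejected(ref_table):
    sub = ref_table.mean_filled(0.0).iloc[:2]
    with pytest.raises(ValueError, match="at least 3"):
        MetaboliteOrdination().fit(sub.to_numpy())


def test_training_sample_classified_as_own_species():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.2, (6, 4)), rng.normal(5, 0.2, (6, 4))])
    y = ["C. cassia"] * 6 + ["C. verum"] * 6
    clf = NearestCentroidSpecies().fit(X, y)
    assert list(clf.predict(X)) == y


def test_species_with_too_few_samples_rejected():
    X = np.zeros((3, 2))
    with pytest.raises(ValueError, match="fewer than"):
        NearestCentroidSpecies().fit(X, ["a", "a", "b"])


def test_tie_breaks_to_lexicographically_first_species():
    X = np.array([[0.0, 0], [0, 1], [2, 0], [2, 1], [1.0, 0.5]])
    y = np.array(["b_species", "b_species", "a_species", "a_species", "b_species"])
    clf = NearestCentroidSpecies().fit(X[:4], y[:4])
    # the probe sits exactly between both centroids
    assert clf.predict(X[4:5])[0] == "a_species"


def test_classification_invariant_to_feature_rescaling(ref_table):
    calls = nearest_centroid_classify(ref_table)
    scaled_mean = ref_table.mean * 7.5 + 0.0  # per-metabolite affine (positive scale)
    scaled = cp.ConcentrationTable(
        mean=scaled_mean, sd=ref_table.sd * 7.5, nd_mask=ref_table.nd_mask, species=ref_table.species
    )
    calls_scaled = nearest_centroid_classify(scaled)
    assert [c.predicted for c in calls] == [c.predicted for c in calls_scaled]


def test_loo_accuracy_on_separated_data():
    rng = np.random.default_rng(2)
    ids = [f"Cin_cass_{i:02d}" for i in range(5)] + [f"Cin_veru_{i:02d}" for i in range(5)]
    mean = pd.DataFrame(
        np.vstack([rng.normal(0, 0.1, (5, 3)) + 1, rng.normal(8, 0.1, (5, 3))]),
        index=ids, columns=["Coumarin", "Eugenol", "Alanine"],
    )
    table = cp.ConcentrationTable(
        mean=mean, sd=mean * 0, nd_mask=mean.isna(),
        species=pd.Series([cp.io.species_from_sample_id(i) for i in ids], index=ids),
    )
    assert loo_accuracy(table) == 1.0


def test_ratio_features_from_reference_row(ref_table):
    ratios = ratio_features(ref_table.mean.loc["Cin_cass_20"])
    assert ratios["coumarin_to_cinnamaldehyde"] == pytest.approx(9.2 / 0.35, rel=1e-6)
    assert ratios["coumarin_to_cinnamaldehyde"] == pytest.approx(26.29, abs=0.01)


def test_ratio_with_nd_denominator_is_undefined(ref_table):
    # Cin_cass_07: cinnamaldehyde and coumarin both ND
    ratios = ratio_features(ref_table.mean.loc["Cin_cass_07"])
    assert ratios["coumarin_to_cinnamaldehyde"] is None
    assert ratios["methoxycinnamaldehyde_to_coumarin"] is None


def test_equal_values_give_unit_ratios():
    row = {m: 2.0 for m in cp.list_metabolites()}
    ratios = ratio_features(row)
    defined = [v for k, v in ratios.items() if k != "eugenol_level"]
    assert all(v == pytest.approx(1.0) for v in defined)
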