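"""Multivariate ordination and species calling from metabolite profiles.

A principal component analysis of the samples x metabolites concentration
matrix summarizes between-species structure; the two leading components are
the usual 2-D ordination plot.  Species assignment uses a nearest-centroid
rule in the autoscaled concentration space, and a set of diagnostic
metabolite ratios (coumarin:cinnamaldehyde and friends) supports rule-of-
thumb authentication.  Not-detected entries are zero-imputed by default:
ND means "below the limit of detection", which is numerically near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .io import ConcentrationTable

__all__ = [
    "OrdinationResult",
    "SpeciesCall",
    "SCALING_OPTIONS",
    "scale_matrix",
    "pca_ordination",
    "MetaboliteOrdination",
    "NearestCentroidSpecies",
    "nearest_centroid_classify",
    "loo_accuracy",
    "ratio_features",
]

SCALING_OPTIONS = ("none", "center", "autoscale", "pareto")


@dataclass
class OrdinationResult:
    """PCA scores, loadings and per-component variance percentages."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained_pct: np.ndarray
    scaling: str = "autoscale"

    def __post_init__(self) -> None:
        v = np.asarray(self.var_explained_pct, dtype=float)
        if (v < 0).any() or v.sum() > 100 + 1e-6:
            raise ValueError("variance percentages must be >= 0 and sum to <= 100")
        self.var_explained_pct = v

    def two_component_variance(self) -> float:
        """Percent variance captured by the 2-D ordination plot."""
        return float(self.var_explained_pct[:2].sum())


@dataclass
class SpeciesCall:
    """One sample's species assignment with the evidence behind it."""

    sample_id: str
    predicted: str
    centroid_distances: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float | None] = field(default_factory=dict)
    tie: bool = False


def _table_matrix(table: ConcentrationTable | pd.DataFrame, nd_policy: str = "zero") -> pd.DataFrame:
    if isinstance(table, ConcentrationTable):
        if nd_policy == "zero":
            return table.mean_filled(0.0)
        if nd_policy == "drop":
            return table.mean.dropna(axis=1)
        raise ValueError(f"unknown nd_policy {nd_policy!r}")
    return pd.DataFrame(table)


def scale_matrix(X: np.ndarray, scaling: str = "autoscale") -> tuple[np.ndarray, np.ndarray]:
    """Apply one of the standard chemometric scalings column-wise.

    Returns (scaled matrix, keep-mask): under autoscale/pareto, zero-variance
    columns carry no usable signal and are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    keep = np.ones(X.shape[1], dtype=bool)
    if scaling == "none":
        return X.copy(), keep
    centered = X - X.mean(axis=0)
    if scaling == "center":
        return centered, keep
    sd = X.std(axis=0, ddof=1)
    if scaling in ("autoscale", "pareto"):
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s) under {scaling}")
        denom = sd[keep] if scaling == "autoscale" else np.sqrt(sd[keep])
        return centered[:, keep] / denom, keep
    raise ValueError(f"unknown scaling {scaling!r}; options: {SCALING_OPTIONS}")


class MetaboliteOrdination(TransformerMixin, BaseEstimator):
    """PCA ordination of concentration matrices, sklearn style.

    Parameters
    ----------
    scaling : {"none", "center", "autoscale", "pareto"}
        Column pretreatment before PCA; autoscale (unit variance) is the
        default so each metabolite gets equal prior weight.
    n_components : int or None
        Components to keep (None = all).

    Attributes (after fit)
    ----------------------
    components_ : loadings, shape (n_components, n_metabolites_kept)
    explained_variance_pct_ : per-component percent variance
    """

    def __init__(self, scaling: str = "autoscale", n_components: int | None = None):
        self.scaling = scaling
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need at least 3 samples for ordination")
        Xs, keep = scale_matrix(X, self.scaling)
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = self._pca.fit_transform(Xs)
        # fix component sign: the largest-magnitude loading is made positive
        flips = np.ones(self._pca.components_.shape[0])
        for i, comp in enumerate(self._pca.components_):
            j = int(np.abs(comp).argmax())
            if comp[j] < 0:
                flips[i] = -1.0
        self.components_ = self._pca.components_ * flips[:, None]
        self.scores_ = scores * flips[None, :]
        self.keep_mask_ = keep
        self.explained_variance_pct_ = self._pca.explained_variance_ratio_ * 100.0
        self.mean_ = Xs.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        Xs, _ = scale_matrix(np.asarray(X, dtype=float), self.scaling)
        return (Xs - self._pca.mean_) @ self.components_.T


def pca_ordination(
    table: ConcentrationTable | pd.DataFrame,
    scaling: str = "autoscale",
    nd_policy: str = "zero",
    n_components: int | None = None,
) -> OrdinationResult:
    """PCA of a concentration table; returns scores, loadings, variance %."""
    M = _table_matrix(table, nd_policy)
    est = MetaboliteOrdination(scaling=scaling, n_components=n_components).fit(M.to_numpy())
    kept = [c for c, k in zip(M.columns, est.keep_mask_) if k]
    comp_names = [f"PC{i+1}" for i in range(est.components_.shape[0])]
    return OrdinationResult(
        scores=pd.DataFrame(est.scores_, index=M.index, columns=comp_names),
        loadings=pd.DataFrame(est.components_.T, index=kept, columns=comp_names),
        var_explained_pct=est.explained_variance_pct_,
        scaling=scaling,
    )


class NearestCentroidSpecies(ClassifierMixin, BaseEstimator):
    """Nearest-centroid species classifier in autoscaled concentration space.

    The training matrix is autoscaled (centre, unit variance); each species'
    centroid is the mean of its training rows; prediction assigns the nearest
    centroid by Euclidean distance, breaking exact ties toward the
    lexicographically first species.
    """

    def __init__(self, min_per_class: int = 2):
        self.min_per_class = min_per_class

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if (counts < self.min_per_class).any():
            small = classes[counts < self.min_per_class]
            raise ValueError(f"species with fewer than {self.min_per_class} training samples: {list(small)}")
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.sigma_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mu_) / self.sigma_
        self.classes_ = classes
        self.centroids_ = np.vstack([Xs[y == c].mean(axis=0) for c in classes])
        return self

    def _distances(self, X):
        Xs = (np.asarray(X, dtype=float) - self.mu_) / self.sigma_
        return np.linalg.norm(Xs[:, None, :] - self.centroids_[None, :, :], axis=2)

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        d = self._distances(X)
        # argmin returns the first (lexicographically smallest class) on ties
        return self.classes_[d.argmin(axis=1)]


def nearest_centroid_classify(
    table: ConcentrationTable,
    train_labels: Mapping[str, str] | Sequence[str] | None = None,
    nd_policy: str = "zero",
) -> list[SpeciesCall]:
    """Classify every sample of a table against species centroids.

    ``train_labels`` defaults to the table's own species labels (parsed from
    sample ids); centroids are fit on all rows and each row is then assigned,
    with centroid distances and diagnostic ratios recorded as evidence.
    """
    M = _table_matrix(table, nd_policy)
    if train_labels is None:
        y = table.species.to_numpy()
    elif isinstance(train_labels, Mapping):
        y = np.asarray([train_labels[s] for s in M.index])
    else:
        y = np.asarray(list(train_labels))
    clf = NearestCentroidSpecies().fit(M.to_numpy(), y)
    d = clf._distances(M.to_numpy())
    calls = []
    for i, sid in enumerate(M.index):
        row_d = d[i]
        best = int(row_d.argmin())
        tie = bool((row_d == row_d[best]).sum() > 1)
        calls.append(
            SpeciesCall(
                sample_id=str(sid),
                predicted=str(clf.classes_[best]),
                centroid_distances={str(c): float(v) for c, v in zip(clf.classes_, row_d)},
                ratios=ratio_features(table.mean.loc[sid]),
                tie=tie,
            )
        )
    return calls


def loo_accuracy(table: ConcentrationTable, nd_policy: str = "zero") -> float:
    """Leave-one-out nearest-centroid accuracy over a labelled table."""
    M = _table_matrix(table, nd_policy).to_numpy()
    y = table.species.to_numpy()
    hits = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = NearestCentroidSpecies().fit(M[mask], y[mask])
        hits += int(clf.predict(M[i : i + 1])[0] == y[i])
    return hits / len(y)


#: named diagnostic ratios: numerator, denominator
_RATIOS = {
    "coumarin_to_cinnamaldehyde": ("Coumarin", "Cinnamaldehyde"),
    "methoxycinnamaldehyde_to_coumarin": ("Methoxy cinnamaldehyde", "Coumarin"),
    "cinnamic_acid_to_coumarin": ("Cinnamic acid", "Coumarin"),
}


def ratio_features(row: Mapping[str, float] | pd.Series) -> dict[str, float | None]:
    """Diagnostic metabolite ratios for one sample.

    Ratios with an ND (NaN) or zero denominator come back as ``None`` rather
    than raising; the eugenol level is passed through as-is.
    """
    def val(name):
        v = row.get(name) if hasattr(row, "get") else row[name]
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    out: dict[str, float | None] = {}
    for key, (num, den) in _RATIOS.items():
        n, d = val(num), val(den)
        out[key] = None if n is None or not d else n / d
    out["eugenol_level"] = val("Eugenol")
    return out
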