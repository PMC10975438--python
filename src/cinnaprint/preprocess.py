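"""Spectral bucketing, solvent exclusion and fingerprint normalization.

A spectrum is reduced to rectangular buckets of positive intensity over
1-12 ppm at 0.01 ppm width, residual-solvent regions (water 4.75-5.06,
methanol 3.16-3.45, TMS/TMSP -0.05-0.05 ppm) are discarded, and the
surviving bucket areas are mapped to integer levels: at or below the
spectrum mean -> 0, above the mean -> 1..100 by min-max scaling.  The
resulting fingerprint is what gets clustered and compared across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import Spectrum

__all__ = [
    "BucketVector",
    "Fingerprint",
    "DEFAULT_EXCLUSIONS",
    "bucket_spectrum",
    "apply_exclusions",
    "normalize_fingerprint",
    "fingerprint_spectrum",
    "SpectrumBucketer",
    "FingerprintNormalizer",
]

#: water, methanol and TMS/TMSP residual regions, in ppm
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (4.75, 5.06),
    (3.16, 3.45),
    (-0.05, 0.05),
)


@dataclass
class BucketVector:
    """Rectangular-bucket integrals of one spectrum.

    ``bucket_edges`` has one more entry than ``values``; bucket *i* is the
    half-open cell ``[edges[i], edges[i+1])``.  ``retained_mask`` marks
    buckets that survived solvent exclusion.
    """

    bucket_edges: np.ndarray
    values: np.ndarray
    retained_mask: np.ndarray

    def __post_init__(self) -> None:
        self.bucket_edges = np.asarray(self.bucket_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.bucket_edges.size != self.values.size + 1:
            raise ValueError("need one more edge than bucket values")
        if self.values.shape != self.retained_mask.shape:
            raise ValueError("values and retained_mask must be congruent")
        if np.any(np.diff(self.bucket_edges) <= 0):
            raise ValueError("bucket edges must strictly increase")
        if np.any(self.values < -1e-12):
            raise ValueError("bucket values must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bucket_edges[:-1] + self.bucket_edges[1:])

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def retained_values(self) -> np.ndarray:
        return self.values[self.retained_mask]


@dataclass
class Fingerprint:
    """Normalized integer fingerprint over the retained buckets."""

    centers: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        if self.centers.shape != self.levels.shape:
            raise ValueError("centers and levels must be congruent")
        bad = (self.levels != 0) & ((self.levels < 1) | (self.levels > 100))
        if bad.any():
            raise ValueError("levels must be 0 or in [1, 100]")


def bucket_spectrum(
    spectrum: Spectrum,
    range_lo: float = 1.0,
    range_hi: float = 12.0,
    width: float = 0.01,
) -> BucketVector:
    """Integrate positive intensity into uniform half-open buckets.

    Each bucket value is the trapezoidal integral of ``max(intensity, 0)``
    over its cell; no scaling is applied.  The spectrum grid must cover the
    full bucketing range.
    """
    if width <= 0:
        raise ValueError("bucket width must be positive")
    if not spectrum.covers(range_lo, range_hi):
        raise ValueError(
            f"spectrum grid [{spectrum.ppm[0]:g}, {spectrum.ppm[-1]:g}] does not cover "
            f"the bucketing range [{range_lo:g}, {range_hi:g}]"
        )
    n_buckets = int(round((range_hi - range_lo) / width))
    edges = range_lo + width * np.arange(n_buckets + 1)

    clipped = np.clip(spectrum.intensity, 0.0, None)
    # exact trapezoid on the union of grid points and bucket edges: interpolate
    # intensity at the edges, cumulative-integrate, difference at the edges
    grid = np.union1d(spectrum.ppm, edges)
    grid = grid[(grid >= range_lo) & (grid <= edges[-1])]
    vals = np.interp(grid, spectrum.ppm, clipped)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    at_edges = np.interp(edges, grid, cum)
    values = np.maximum(np.diff(at_edges), 0.0)
    return BucketVector(edges, values, np.ones(n_buckets, dtype=bool))


def apply_exclusions(
    bucket_vector: BucketVector,
    windows=DEFAULT_EXCLUSIONS,
) -> BucketVector:
    """Drop every bucket whose cell overlaps a solvent window.

    Overlap means a nonzero-length intersection; sharing a single boundary
    point does not exclude a bucket.  Idempotent.
    """
    lo = bucket_vector.bucket_edges[:-1]
    hi = bucket_vector.bucket_edges[1:]
    mask = bucket_vector.retained_mask.copy()
    for w_lo, w_hi in windows:
        mask &= ~((lo < w_hi) & (hi > w_lo))
    return BucketVector(bucket_vector.bucket_edges, bucket_vector.values, mask)


def normalize_fingerprint(bucket_vector: BucketVector) -> Fingerprint:
    """Map retained bucket areas to the 0 / 1..100 integer scale.

    Values at or below the spectrum-wise mean of the retained buckets become
    0; values above it are min-max scaled onto 1..100 (round half up).  A
    constant vector maps entirely to 0; if all above-mean values coincide
    they map to 100.
    """
    if bucket_vector.n_retained == 0:
        raise ValueError("no retained buckets to normalize")
    v = bucket_vector.retained_values()
    mu = v.mean()
    above = v > mu
    levels = np.zeros(v.size, dtype=int)
    if above.any():
        hi = v[above]
        vmin, vmax = hi.min(), hi.max()
        if vmax == vmin:
            levels[above] = 100
        else:
            scaled = 1.0 + 99.0 * (hi - vmin) / (vmax - vmin)
            levels[above] = np.floor(scaled + 0.5).astype(int)  # round half up
    return Fingerprint(bucket_vector.centers[bucket_vector.retained_mask], levels)


def fingerprint_spectrum(
    spectrum: Spectrum,
    range_lo: float = 1.0,
    range_hi: float = 12.0,
    width: float = 0.01,
    exclusions=DEFAULT_EXCLUSIONS,
) -> Fingerprint:
    """Bucket, exclude and normalize in one call."""
    return normalize_fingerprint(
        apply_exclusions(bucket_spectrum(spectrum, range_lo, range_hi, width), exclusions)
    )


class SpectrumBucketer(TransformerMixin, BaseEstimator):
    """Transformer: list of spectra -> matrix of retained bucket areas.

    Parameters
    ----------
    range_lo, range_hi, width : float
        Bucketing grid (defaults 1-12 ppm at 0.01 ppm).
    exclusions : sequence of (lo, hi)
        Solvent windows whose overlapping buckets are dropped.
    """

    def __init__(self, range_lo=1.0, range_hi=12.0, width=0.01, exclusions=DEFAULT_EXCLUSIONS):
        self.range_lo = range_lo
        self.range_hi = range_hi
        self.width = width
        self.exclusions = exclusions

    def fit(self, X, y=None):
        if self.width <= 0:
            raise ValueError("bucket width must be positive")
        n_buckets = int(round((self.range_hi - self.range_lo) / self.width))
        edges = self.range_lo + self.width * np.arange(n_buckets + 1)
        probe = BucketVector(edges, np.zeros(n_buckets), np.ones(n_buckets, dtype=bool))
        probe = apply_exclusions(probe, self.exclusions)
        self.bucket_edges_ = edges
        self.retained_mask_ = probe.retained_mask
        self.centers_ = probe.centers[probe.retained_mask]
        self.n_features_out_ = int(probe.retained_mask.sum())
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_mask_")
        rows = []
        for s in X:
            bv = bucket_spectrum(s, self.range_lo, self.range_hi, self.width)
            rows.append(bv.values[self.retained_mask_])
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "centers_")
        return np.asarray([f"ppm_{c:.3f}" for c in self.centers_], dtype=object)


class FingerprintNormalizer(TransformerMixin, BaseEstimator):
    """Row-wise 0 / 1..100 fingerprint normalization of bucket-area matrices.

    Stateless: each row is normalized against its own mean, mirroring
    per-spectrum processing.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D bucket-area matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape, dtype=int)
        for i, row in enumerate(X):
            edges = np.arange(row.size + 1, dtype=float)
            bv = BucketVector(edges, np.clip(row, 0, None), np.ones(row.size, dtype=bool))
            out[i] = normalize_fingerprint(bv).levels
        return out
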