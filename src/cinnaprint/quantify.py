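"""Absolute qNMR quantification against an external reference signal.

The quantifier implements the standard external-calibration ratio: the molar
concentration of an analyte follows from the ratio of its signal integral to
the integral of a calibration signal of known equivalent concentration,
corrected for the proton counts of the two signals,

    C_met = (A_met / A_ref) * (n_ref / n_met) * C_ref ,

and is converted to mg of analyte per gram of sample through the extraction
constants (extract volume, sample mass) and the molecular weight.  Samples
are measured in triplicate; the report carries the replicate mean and sample
standard deviation, rounded to two decimals, with a signal-to-noise based
not-detected (ND) flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import catalogue as cat
from .catalogue import MetaboliteDef
from .io import ConcentrationTable, Spectrum
from .simulate import EXTRACT_VOLUME_L, SAMPLE_MASS_G

__all__ = [
    "ReferenceCalibration",
    "QuantResult",
    "integrate_region",
    "estimate_noise_floor",
    "quantify_metabolite",
    "quantify_sample",
    "quantify_cohort",
    "QNMRQuantifier",
    "DEFAULT_CALIBRATION",
]


@dataclass(frozen=True)
class ReferenceCalibration:
    """The external calibration signal: where it is and what it is worth.

    The default reference window is 0.10 ppm wide, matching the width of
    every catalogued quantification window, so the fraction of a Lorentzian
    line captured inside the integration region cancels in the analyte/
    reference area ratio.
    """

    ref_window: tuple[float, float] = (-0.05, 0.05)
    ref_conc_molar: float = 0.01
    ref_n_protons: int = 1

    def __post_init__(self) -> None:
        if self.ref_conc_molar <= 0:
            raise ValueError("reference concentration must be positive")
        if self.ref_n_protons < 1:
            raise ValueError("reference proton count must be at least 1")
        for met in cat.catalogue():
            lo, hi = met.quant_signal.window
            if min(hi, self.ref_window[1]) > max(lo, self.ref_window[0]):
                raise ValueError(
                    f"reference window overlaps quantification window of {met.name!r}"
                )


DEFAULT_CALIBRATION = ReferenceCalibration()


@dataclass
class QuantResult:
    """Triplicate quantification report for one sample (mg/g)."""

    sample_id: str
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    replicates: dict[str, list[float]] = field(default_factory=dict)
    nd: dict[str, bool] = field(default_factory=dict)


def integrate_region(spectrum: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over a closed ppm window."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must have positive width")
    if not spectrum.covers(lo, hi):
        raise ValueError(f"window [{lo:g}, {hi:g}] outside spectrum grid")
    inside = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    x = spectrum.ppm[inside]
    y = spectrum.intensity[inside]
    # add interpolated endpoints so the integral covers exactly [lo, hi]
    if x.size == 0 or x[0] > lo:
        x = np.concatenate([[lo], x])
        y = np.concatenate([[np.interp(lo, spectrum.ppm, spectrum.intensity)], y])
    if x[-1] < hi:
        x = np.concatenate([x, [hi]])
        y = np.concatenate([y, [np.interp(hi, spectrum.ppm, spectrum.intensity)]])
    return float(np.trapezoid(y, x))


def estimate_noise_floor(spectrum: Spectrum, region: tuple[float, float] = (11.5, 12.0)) -> float:
    """Noise level as the intensity SD over a signal-free region."""
    inside = (spectrum.ppm >= region[0]) & (spectrum.ppm <= region[1])
    if inside.sum() < 2:
        raise ValueError(f"noise region {region} not covered by the spectrum")
    return float(np.std(spectrum.intensity[inside]))


def quantify_metabolite(
    spectrum: Spectrum,
    metabolite: MetaboliteDef | str,
    calibration: ReferenceCalibration = DEFAULT_CALIBRATION,
    extract_volume_l: float = EXTRACT_VOLUME_L,
    sample_mass_g: float = SAMPLE_MASS_G,
    snr_limit: float = 3.0,
) -> tuple[float, bool]:
    """Quantify one metabolite; returns (mg per g of sample, nd_flag).

    The ND flag is raised when the peak's signal-to-noise ratio (maximum
    intensity in the quantification window over the noise floor) falls below
    ``snr_limit``; the numeric estimate is still returned.
    """
    if isinstance(metabolite, str):
        metabolite = cat.get_metabolite(metabolite)
    a_ref = integrate_region(spectrum, calibration.ref_window)
    if a_ref <= 0:
        raise ValueError("invalid calibration: non-positive reference integral")
    sig = metabolite.quant_signal
    a_met = integrate_region(spectrum, sig.window)
    if a_met <= 0:
        return 0.0, True

    c_molar = (a_met / a_ref) * (calibration.ref_n_protons / sig.n_protons) * calibration.ref_conc_molar
    mg_per_g = c_molar * extract_volume_l * metabolite.mol_weight * 1000.0 / sample_mass_g

    noise = estimate_noise_floor(spectrum)
    lo, hi = sig.window
    inside = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    peak_height = float(spectrum.intensity[inside].max()) if inside.any() else 0.0
    nd = bool(noise > 0 and peak_height / noise < snr_limit)
    return mg_per_g, nd


def quantify_sample(
    replicates: Sequence[Spectrum],
    calibration: ReferenceCalibration = DEFAULT_CALIBRATION,
    metabolites: Sequence[str] | None = None,
    **kwargs,
) -> QuantResult:
    """Quantify all catalogued metabolites over replicate spectra.

    Reports the replicate mean and sample SD per metabolite, rounded to two
    decimals (replicate values keep full precision); a metabolite is ND only
    if every replicate flags it ND.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicate spectra")
    grids = {(s.ppm[0], s.ppm[-1], s.n_points) for s in replicates}
    if len(grids) != 1:
        raise ValueError("replicate spectra are on inconsistent grids")
    names = list(metabolites) if metabolites is not None else cat.list_metabolites()
    sample_id = str(replicates[0].meta.get("sample_id", "sample"))
    result = QuantResult(sample_id=sample_id)
    for name in names:
        vals, flags = zip(*(quantify_metabolite(s, name, calibration, **kwargs) for s in replicates))
        result.replicates[name] = list(vals)
        result.nd[name] = all(flags)
        result.mean[name] = round(float(np.mean(vals)), 2)
        result.sd[name] = round(float(np.std(vals, ddof=1)), 2)
    return result


def quantify_cohort(
    cohort: Sequence[Sequence[Spectrum]],
    calibration: ReferenceCalibration = DEFAULT_CALIBRATION,
    **kwargs,
) -> ConcentrationTable:
    """Quantify a list of replicate groups into a concentration table."""
    results = [quantify_sample(reps, calibration, **kwargs) for reps in cohort]
    names = cat.list_metabolites()
    ids = [r.sample_id for r in results]
    mean = pd.DataFrame([[r.mean[n] for n in names] for r in results], index=ids, columns=names)
    sd = pd.DataFrame([[r.sd[n] for n in names] for r in results], index=ids, columns=names)
    nd = pd.DataFrame([[r.nd[n] for n in names] for r in results], index=ids, columns=names)
    mean, sd = mean.mask(nd), sd.mask(nd)
    from .io import species_from_sample_id

    species = pd.Series([species_from_sample_id(i) for i in ids], index=ids, name="species")
    return ConcentrationTable(mean=mean, sd=sd, nd_mask=nd, species=species)


class QNMRQuantifier(TransformerMixin, BaseEstimator):
    """Transformer: replicate spectrum groups -> mg/g concentration matrix.

    ``transform`` accepts a sequence of replicate groups (each a sequence of
    :class:`Spectrum`) and returns the (n_samples, 16) matrix of replicate
    means with ND entries as NaN.  The full table is kept on ``table_``.
    """

    def __init__(self, calibration: ReferenceCalibration = DEFAULT_CALIBRATION,
                 extract_volume_l: float = EXTRACT_VOLUME_L,
                 sample_mass_g: float = SAMPLE_MASS_G):
        self.calibration = calibration
        self.extract_volume_l = extract_volume_l
        self.sample_mass_g = sample_mass_g

    def fit(self, X, y=None):
        self.metabolites_ = cat.list_metabolites()
        return self

    def transform(self, X):
        check_is_fitted(self, "metabolites_")
        self.table_ = quantify_cohort(
            X, self.calibration,
            extract_volume_l=self.extract_volume_l,
            sample_mass_g=self.sample_mass_g,
        )
        return self.table_.mean.to_numpy()
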