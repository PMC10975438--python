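"""Synthetic 1-D proton NMR spectra with known metabolite content.

Emulates 400 MHz one-dimensional spectra of cinnamon extracts: 32 K points
over -0.5..12.5 ppm, Lorentzian lines at the catalogued metabolite signals,
a calibration reference line at 0.0 ppm, residual water and methanol lines
inside the standard exclusion regions, and additive Gaussian noise.  Peak
areas follow quantitative NMR physics: area is proportional to molar
concentration times the number of equivalent protons, with the molar
concentration derived from the sample's mg/g content through the extraction
constants (300 mg sample into 2.0 mL of solvent).

Species-level cohorts are drawn from per-metabolite truncated normal
distributions whose location/scale come straight from a reference
concentration table, so every downstream stage can be exercised against a
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import catalogue as cat
from .io import ConcentrationTable, Spectrum

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SpeciesProfile",
    "SAMPLE_MASS_G",
    "EXTRACT_VOLUME_L",
    "simulate_spectrum",
    "species_profiles_from_table",
    "generate_cohort",
    "cohort_to_table",
]

#: extraction constants: 300 mg of homogenized sample in 2.0 mL of solvent
SAMPLE_MASS_G = 0.300
EXTRACT_VOLUME_L = 0.002

#: half-width of the truncated Lorentzian support, ppm
LINE_SUPPORT_PPM = 0.2


@dataclass(frozen=True)
class SimulationParams:
    """Acquisition and lineshape parameters of the simulated spectrometer.

    ``reference_area`` is the integrated area assigned to the calibration
    line per unit (molar) reference concentration per proton; it fixes the
    instrument sensitivity that converts molar concentration x proton count
    into peak area for every line in the spectrum.
    """

    field_mhz: float = 400.0
    n_points: int = 32768
    ppm_range: tuple[float, float] = (-0.5, 12.5)
    linewidth_hz: float = 1.0
    noise_sd: float = 0.01
    solvent_peaks: tuple[tuple[float, float], ...] = ((4.90, 200.0), (3.31, 50.0))
    reference_area: float = 100.0
    ref_conc_molar: float = 0.01
    ref_n_protons: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if not (self.ppm_range[0] <= 1.0 and self.ppm_range[1] >= 12.0):
            raise ValueError("ppm_range must span the bucketing range [1, 12]")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def linewidth_ppm(self) -> float:
        return self.linewidth_hz / self.field_mhz

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)


@dataclass(frozen=True)
class GroundTruth:
    """True metabolite content of one simulated sample."""

    sample_id: str
    species: str
    conc_mg_per_g: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.conc_mg_per_g.items():
            if value < 0:
                raise ValueError(f"negative concentration for {name!r}")


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species location/scale of each metabolite's mg/g distribution."""

    species: str
    location: Mapping[str, float]
    scale: Mapping[str, float]

    def __post_init__(self) -> None:
        for m in self.location:
            if self.location[m] < 0 or self.scale.get(m, 0.0) < 0:
                raise ValueError(f"negative location/scale for {m!r}")


def _truncated_lorentzian(grid: np.ndarray, center: float, hwhm: float, area: float) -> np.ndarray:
    """Lorentzian of total mass ``area`` restricted to +/-LINE_SUPPORT_PPM.

    The shape is renormalized on its support so the numeric integral over the
    spectrum equals ``area`` exactly (up to grid resolution) and intensity is
    exactly zero far from the line.
    """
    out = np.zeros_like(grid)
    sel = np.abs(grid - center) <= LINE_SUPPORT_PPM
    if not sel.any():
        return out
    x = grid[sel] - center
    coverage = 2.0 / np.pi * np.arctan(LINE_SUPPORT_PPM / hwhm)
    out[sel] = area / coverage * (hwhm / np.pi) / (x**2 + hwhm**2)
    return out


def mg_per_g_to_molar(mg_per_g: float, mol_weight: float,
                      sample_mass_g: float = SAMPLE_MASS_G,
                      extract_volume_l: float = EXTRACT_VOLUME_L) -> float:
    """Molar concentration in the extract for a given tissue content."""
    grams = mg_per_g * sample_mass_g / 1000.0
    return grams / mol_weight / extract_volume_l


def simulate_spectrum(truth: GroundTruth, params: SimulationParams = SimulationParams()) -> Spectrum:
    """Render one noisy spectrum from a ground-truth concentration vector.

    Every catalogued signal of each metabolite contributes a Lorentzian whose
    area is sensitivity x molar concentration x proton count; the calibration
    reference sits at 0.0 ppm and solvent residuals at their usual shifts.
    The RNG is seeded from ``params.seed``, so identical inputs give
    bit-identical spectra.
    """
    known = set(cat.list_metabolites())
    unknown = set(truth.conc_mg_per_g) - known
    if unknown:
        raise cat.UnknownMetaboliteError(f"not in catalogue: {sorted(unknown)}")

    grid = params.grid
    hwhm = params.linewidth_ppm / 2.0
    sensitivity = params.reference_area  # area per molar per proton
    intensity = np.zeros_like(grid)

    for name, mg_g in truth.conc_mg_per_g.items():
        if mg_g == 0.0:
            continue
        met = cat.get_metabolite(name)
        c_molar = mg_per_g_to_molar(mg_g, met.mol_weight)
        for sig in met.signals:
            area = sensitivity * c_molar * sig.n_protons
            intensity += _truncated_lorentzian(grid, sig.center_ppm, hwhm, area)

    ref_area = sensitivity * params.ref_conc_molar * params.ref_n_protons
    intensity += _truncated_lorentzian(grid, 0.0, hwhm, ref_area)
    for center, rel_area in params.solvent_peaks:
        intensity += _truncated_lorentzian(grid, center, hwhm, rel_area * ref_area)

    meta = {
        "sample_id": truth.sample_id,
        "species": truth.species,
        "field_mhz": params.field_mhz,
        "n_points": params.n_points,
    }
    step = (params.ppm_range[1] - params.ppm_range[0]) / (params.n_points - 1)
    if params.linewidth_ppm / step < 3:
        meta["notes"] = "grid too coarse: fewer than 3 points per linewidth"

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=grid.size)
    return Spectrum(grid, intensity, meta)


def species_profiles_from_table(table: ConcentrationTable) -> list[SpeciesProfile]:
    """Estimate per-species concentration profiles from an observed table.

    Location is the species mean of the reported mg/g (ND counted as 0) and
    scale is the corresponding across-sample standard deviation.
    """
    mean0 = table.mean_filled(0.0)
    profiles = []
    for species in sorted(table.species.unique()):
        rows = mean0.loc[table.species == species]
        if rows.empty:
            raise ValueError(f"no samples for species {species!r}")
        loc = rows.mean(axis=0)
        scale = rows.std(axis=0, ddof=1).fillna(0.0) if len(rows) > 1 else loc * 0.0
        profiles.append(
            SpeciesProfile(species, loc.to_dict(), scale.to_dict())
        )
    return profiles


def _draw_truncated_normal(rng: np.random.Generator, loc: float, scale: float, size: int) -> np.ndarray:
    if scale == 0.0:
        return np.full(size, loc)
    a = (0.0 - loc) / scale  # truncate at zero: concentrations cannot be negative
    return stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=size,
                               random_state=rng)


def generate_cohort(
    profiles: Sequence[SpeciesProfile],
    n_per_species: int,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[list[list[Spectrum]], list[GroundTruth]]:
    """Draw a cohort and render replicate spectra per sample.

    Per species, ``n_per_species`` truth vectors are drawn from zero-truncated
    normals with the profile's location/scale; each sample is rendered as
    ``n_replicates`` spectra with independent noise.  Returns (spectra grouped
    by sample, ground truths).
    """
    if n_per_species < 1:
        raise ValueError("need at least one sample per species")
    rng = np.random.default_rng(seed)
    truths: list[GroundTruth] = []
    spectra: list[list[Spectrum]] = []
    counter = 0
    for profile in profiles:
        metabolites = list(profile.location)
        draws = {
            m: _draw_truncated_normal(rng, profile.location[m], profile.scale[m], n_per_species)
            for m in metabolites
        }
        for i in range(n_per_species):
            counter += 1
            short = profile.species.split(". ")[-1][:4]
            truth = GroundTruth(
                sample_id=f"Cin_{short}_{counter:02d}",
                species=profile.species,
                conc_mg_per_g={m: float(draws[m][i]) for m in metabolites},
            )
            truths.append(truth)
            reps = []
            for r in range(n_replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                rep_params = replace(params, seed=rep_seed)
                s = simulate_spectrum(truth, rep_params)
                s.meta["replicate"] = r + 1
                reps.append(s)
            spectra.append(reps)
    return spectra, truths


def cohort_to_table(truths: Sequence[GroundTruth], lod_mg_per_g: float = 0.05) -> ConcentrationTable:
    """Ground-truth table in the concentration-CSV layout.

    Concentrations below the limit of detection are flagged ND, mirroring how
    a real quantification report censors weak signals.
    """
    names = cat.list_metabolites()
    ids = [t.sample_id for t in truths]
    mean = pd.DataFrame(
        [[t.conc_mg_per_g.get(m, 0.0) for m in names] for t in truths],
        index=ids, columns=names, dtype=float,
    )
    nd = mean < lod_mg_per_g
    sd = pd.DataFrame(0.0, index=ids, columns=names)
    mean, sd = mean.mask(nd), sd.mask(nd)
    species = pd.Series([t.species for t in truths], index=ids, name="species")
    return ConcentrationTable(mean=mean, sd=sd, nd_mask=nd, species=species)
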