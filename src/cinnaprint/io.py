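"""Reading and writing of 1-D NMR spectra and metabolite concentration tables.

Spectra travel as plain two-column text (chemical shift in ppm, intensity),
optionally with ``#``-prefixed header lines carrying metadata, or as simple
JCAMP-DX ``XYDATA (X++(Y..Y))`` blocks.  Concentration tables follow the
layout of a quantification report: one row per sample, one (mean, sd)
column pair per metabolite, with the literal string ``ND`` marking
below-detection entries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ConcentrationTable",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "load_concentration_table",
    "write_concentration_table",
    "bundled_table_path",
    "SPECIES_PREFIXES",
]

#: Mapping of sample-id prefixes to canonical species names.
SPECIES_PREFIXES: Mapping[str, str] = {
    "Cin_veru": "C. verum",
    "Cin_cass": "C. cassia",
    "Cin_burm": "C. burmannii",
}


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; carries the line number."""


@dataclass
class Spectrum:
    """A 1-D proton NMR trace on a strictly increasing ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.ppm)
        if np.any(d <= 0):
            if np.all(d < 0):  # descending input: reorder ascending
                self.ppm = self.ppm[::-1].copy()
                self.intensity = self.intensity[::-1].copy()
            else:
                raise ValueError("ppm grid must be strictly monotone")

    @property
    def n_points(self) -> int:
        return int(self.ppm.size)

    def covers(self, lo: float, hi: float) -> bool:
        return self.ppm[0] <= lo and self.ppm[-1] >= hi


def read_spectrum(path) -> Spectrum:
    """Read a spectrum from two-column text or a minimal JCAMP-DX file.

    Descending ppm axes are reversed so the returned grid always ascends.
    Malformed rows raise :class:`SpectrumParseError` with the line number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("##"):
        return _read_jcamp(text, path.name)
    meta: dict = {}
    ppm, intensity = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*[:=]\s*(.*)", line)
            if m:
                meta[m.group(1)] = _coerce(m.group(2).strip())
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) != 2:
            raise SpectrumParseError(f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}")
        try:
            ppm.append(float(fields[0]))
            intensity.append(float(fields[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path.name}:{lineno}: non-numeric field ({exc})") from None
    if len(ppm) < 2:
        raise SpectrumParseError(f"{path.name}: fewer than 2 data points")
    return Spectrum(np.array(ppm), np.array(intensity), meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text with ``#key: value`` metadata header."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in spectrum.meta.items()]
    lines += [f"{float(p)!r} {float(i)!r}" for p, i in zip(spectrum.ppm, spectrum.intensity)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def _read_jcamp(text: str, name: str) -> Spectrum:
    """Minimal JCAMP-DX reader for AFFN ``XYDATA=(X++(Y..Y))`` blocks."""
    meta: dict = {}
    ydata: list[float] = []
    firstx = lastx = None
    in_xy = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key, val = key.strip().upper(), val.strip()
            if key == "XYDATA":
                in_xy = True
                continue
            in_xy = False
            if key == "FIRSTX":
                firstx = float(val)
            elif key == "LASTX":
                lastx = float(val)
            elif key == "END":
                break
            else:
                meta[key.lower()] = _coerce(val)
        elif in_xy and line:
            try:
                vals = [float(v) for v in re.split(r"[,\s]+", line)]
            except ValueError as exc:
                raise SpectrumParseError(f"{name}:{lineno}: bad XYDATA ({exc})") from None
            ydata.extend(vals[1:])  # first value on each line is the X ordinate
    if firstx is None or lastx is None or len(ydata) < 2:
        raise SpectrumParseError(f"{name}: incomplete JCAMP-DX (need FIRSTX/LASTX/XYDATA)")
    ppm = np.linspace(firstx, lastx, len(ydata))
    return Spectrum(ppm, np.array(ydata), meta)


# ---------------------------------------------------------------------------
# Concentration tables
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationTable:
    """Samples x metabolites mg/g table with SDs and not-detected flags.

    ``mean``/``sd`` are DataFrames indexed by sample id; ND entries hold NaN
    and are flagged in ``nd_mask``.  ND is "below the limit of detection",
    deliberately distinct from a measured zero; any zero-imputation is an
    explicit downstream choice.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    nd_mask: pd.DataFrame
    species: pd.Series

    def __post_init__(self) -> None:
        if not (self.mean.shape == self.sd.shape == self.nd_mask.shape):
            raise ValueError("mean, sd and nd_mask must be congruent")
        with np.errstate(invalid="ignore"):
            if (self.mean.to_numpy() < 0).any() or (self.sd.to_numpy() < 0).any():
                raise ValueError("concentrations and SDs must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mean.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def n_samples(self) -> int:
        return len(self.mean)

    def mean_filled(self, fill: float = 0.0) -> pd.DataFrame:
        """Mean matrix with ND entries imputed by ``fill`` (default 0)."""
        return self.mean.fillna(fill)


def species_from_sample_id(sample_id: str) -> str:
    for prefix, species in SPECIES_PREFIXES.items():
        if sample_id.startswith(prefix):
            return species
    raise ValueError(
        f"unknown species prefix in sample id {sample_id!r}; "
        f"expected one of {sorted(SPECIES_PREFIXES)}"
    )


def load_concentration_table(path=None) -> ConcentrationTable:
    """Load a concentration CSV (sample_id + 16 mean/sd column pairs).

    With no argument, loads the bundled 48-sample reference table.  ``ND``
    must appear in both members of a pair or neither; a half-ND pair is an
    error.
    """
    if path is None:
        path = bundled_table_path()
    raw = pd.read_csv(path, dtype=str).set_index("sample_id")
    mean_cols = [c for c in raw.columns if c.endswith("_mean")]
    names = [c[: -len("_mean")] for c in mean_cols]
    for n in names:
        if f"{n}_sd" not in raw.columns:
            raise ValueError(f"column {n}_mean has no matching {n}_sd")
    mean = pd.DataFrame(index=raw.index, columns=names, dtype=float)
    sd = pd.DataFrame(index=raw.index, columns=names, dtype=float)
    nd = pd.DataFrame(False, index=raw.index, columns=names)
    for n in names:
        m_nd = raw[f"{n}_mean"].str.upper().eq("ND")
        s_nd = raw[f"{n}_sd"].str.upper().eq("ND")
        if (m_nd != s_nd).any():
            bad = raw.index[m_nd != s_nd][0]
            raise ValueError(f"inconsistent ND pair for {n!r} in sample {bad!r}")
        nd[n] = m_nd
        mean.loc[~m_nd, n] = raw.loc[~m_nd, f"{n}_mean"].astype(float)
        sd.loc[~s_nd, n] = raw.loc[~s_nd, f"{n}_sd"].astype(float)
    species = pd.Series(
        [species_from_sample_id(s) for s in raw.index], index=raw.index, name="species"
    )
    return ConcentrationTable(mean=mean, sd=sd, nd_mask=nd, species=species)


def write_concentration_table(table: ConcentrationTable, path) -> None:
    """Write a table back to the CSV schema accepted by ``load_concentration_table``."""
    out = pd.DataFrame(index=table.mean.index)
    for n in table.metabolites:
        m = table.mean[n].map(lambda v: "ND" if pd.isna(v) else f"{v:g}")
        s = table.sd[n].map(lambda v: "ND" if pd.isna(v) else f"{v:g}")
        out[f"{n}_mean"], out[f"{n}_sd"] = m, s
    out.index.name = "sample_id"
    out.to_csv(path)


def bundled_table_path() -> Path:
    """Path of the bundled 48 x 16 reference concentration table."""
    return Path(resources.files("cinnaprint.data") / "reference_concentrations.csv")
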