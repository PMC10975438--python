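"""Static catalogue of the 16 quantified cinnamon metabolites.

Each entry carries the molecular formula and weight plus the proton signal
used for quantification (centre, integration window, number of equivalent
protons).  Quantification windows are pairwise disjoint and sit outside the
solvent-residual regions so the simulator and the quantifier can share one
consistent signal map.  Secondary signals are used only by the spectrum
simulator to give fingerprints realistic multi-peak structure.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "SignalDef",
    "MetaboliteDef",
    "UnknownMetaboliteError",
    "list_metabolites",
    "get_metabolite",
    "catalogue",
    "molecular_weight",
]

# IUPAC 2021 standard atomic weights (conventional values), g/mol
ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

PPM_BOUNDS = (-0.5, 12.5)


class UnknownMetaboliteError(KeyError):
    """Requested metabolite is not one of the 16 catalogued compounds."""


@dataclass(frozen=True)
class SignalDef:
    """One NMR resonance: where it sits and how many protons produce it."""

    center_ppm: float
    window: tuple[float, float]
    n_protons: int
    multiplicity_label: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo < hi):
            raise ValueError(f"empty signal window {self.window}")
        if not (lo <= self.center_ppm <= hi):
            raise ValueError(f"center {self.center_ppm} outside window {self.window}")
        if not (PPM_BOUNDS[0] <= lo and hi <= PPM_BOUNDS[1]):
            raise ValueError(f"window {self.window} outside plausible ppm range {PPM_BOUNDS}")
        if self.n_protons < 1:
            raise ValueError("a signal needs at least one proton")

    @property
    def width(self) -> float:
        return self.window[1] - self.window[0]


@dataclass(frozen=True)
class MetaboliteDef:
    name: str
    formula: str
    mol_weight: float
    quant_signal: SignalDef
    secondary_signals: tuple[SignalDef, ...] = ()

    def __post_init__(self) -> None:
        if self.mol_weight <= 0:
            raise ValueError("molecular weight must be positive")

    @property
    def signals(self) -> tuple[SignalDef, ...]:
        return (self.quant_signal, *self.secondary_signals)


def molecular_weight(formula: str) -> float:
    """Molecular weight in g/mol from a Hill-style formula such as ``C9H6O2``."""
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    weight = 0.0
    seen = ""
    for element, count in tokens:
        if not element:
            continue
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unsupported element {element!r} in formula {formula!r}")
        weight += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        seen += element + count
    if seen != formula:
        raise ValueError(f"cannot parse formula {formula!r}")
    return weight


def _parse_secondary(cell) -> tuple[SignalDef, ...]:
    # "7.45:1;6.70:1" -> singlet-like lines at those shifts with proton counts;
    # secondary windows are nominal +/-0.05 ppm and only used by the simulator.
    if pd.isna(cell) or not str(cell).strip():
        return ()
    out = []
    for part in str(cell).split(";"):
        center, protons = part.split(":")
        c = float(center)
        out.append(SignalDef(c, (c - 0.05, c + 0.05), int(protons), "secondary"))
    return tuple(out)


@lru_cache(maxsize=1)
def catalogue() -> tuple[MetaboliteDef, ...]:
    """The 16-entry metabolite catalogue, loaded once from bundled data."""
    path = resources.files("cinnaprint.data") / "metabolite_catalogue.csv"
    df = pd.read_csv(path)
    entries = []
    for row in df.itertuples(index=False):
        quant = SignalDef(
            center_ppm=float(row.center_ppm),
            window=(float(row.window_lo), float(row.window_hi)),
            n_protons=int(row.n_protons),
            multiplicity_label=str(row.multiplicity),
        )
        entries.append(
            MetaboliteDef(
                name=str(row.name),
                formula=str(row.formula),
                mol_weight=float(row.mol_weight),
                quant_signal=quant,
                secondary_signals=_parse_secondary(row.secondary),
            )
        )
    _validate(entries)
    return tuple(entries)


def _validate(entries: list[MetaboliteDef]) -> None:
    names = [m.name for m in entries]
    if len(entries) != 16 or len(set(names)) != 16:
        raise ValueError(f"catalogue must hold exactly 16 uniquely named entries, got {len(entries)}")
    windows = [(m.name, *m.quant_signal.window) for m in entries]
    for i, (ni, lo_i, hi_i) in enumerate(windows):
        for nj, lo_j, hi_j in windows[i + 1 :]:
            if min(hi_i, hi_j) > max(lo_i, lo_j):
                raise ValueError(f"quantification windows of {ni!r} and {nj!r} overlap")


def list_metabolites() -> list[str]:
    """Canonical names of the 16 quantified metabolites, in stable table order."""
    return [m.name for m in catalogue()]


def get_metabolite(name: str) -> MetaboliteDef:
    """Look up a catalogue entry by name (case-insensitive)."""
    lowered = {m.name.lower(): m for m in catalogue()}
    hit = lowered.get(name.strip().lower())
    if hit is not None:
        return hit
    close = difflib.get_close_matches(name.lower(), lowered, n=1, cutoff=0.0)
    suggestion = lowered[close[0]].name if close else "?"
    raise UnknownMetaboliteError(f"unknown metabolite {name!r}; nearest catalogue entry is {suggestion!r}")
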