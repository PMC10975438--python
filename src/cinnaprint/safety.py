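"""Coumarin exposure screening against the tolerable daily intake.

The European Food Safety Authority's tolerable daily intake (TDI) for
coumarin is 0.1 mg per kilogram of body weight per day.  For a product with
coumarin content c (mg per g of product) and a consumer of body weight w
(kg), the daily amount of product that reaches the TDI is

    max_daily_g = 0.1 * w / c ,

so a serving of s grams per day exceeds the TDI exactly when s * c > 0.1 * w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConcentrationTable

__all__ = [
    "TDI_MG_PER_KG",
    "DEFAULT_BODY_WEIGHT_KG",
    "DEFAULT_SERVING_G",
    "TDIReport",
    "tdi_max_daily_grams",
    "screen_tdi",
]

#: EFSA tolerable daily intake for coumarin, mg per kg body weight per day
TDI_MG_PER_KG = 0.1

DEFAULT_BODY_WEIGHT_KG = 60.0
DEFAULT_SERVING_G = 1.0


@dataclass
class TDIReport:
    """TDI screen outcome for one sample."""

    sample_id: str
    coumarin_mg_per_g: float | None
    body_weight_kg: float
    serving_g: float
    max_daily_g: float | None  # None when coumarin is ND/zero: no limit computable
    flagged: bool


def tdi_max_daily_grams(coumarin_mg_per_g: float, body_weight_kg: float) -> float:
    """Grams of product per day at which coumarin intake reaches the TDI."""
    if coumarin_mg_per_g <= 0:
        raise ValueError("coumarin content must be positive; ND/zero has no computable limit")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return TDI_MG_PER_KG * body_weight_kg / coumarin_mg_per_g


def screen_tdi(
    table: ConcentrationTable,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    serving_g: float = DEFAULT_SERVING_G,
) -> list[TDIReport]:
    """Screen every sample's coumarin content against the TDI.

    Returns one report per sample, ordered by decreasing coumarin content so
    the most exposing product comes first; samples whose daily serving
    exceeds the TDI are flagged.  ND coumarin yields an unflagged report with
    no computable limit.
    """
    if serving_g <= 0:
        raise ValueError("serving must be positive")
    coumarin = table.mean["Coumarin"]
    order = coumarin.fillna(-np.inf).sort_values(ascending=False).index
    reports = []
    for sid in order:
        c = coumarin.loc[sid]
        if pd.isna(c) or c <= 0:
            reports.append(TDIReport(str(sid), None, body_weight_kg, serving_g, None, False))
            continue
        limit = tdi_max_daily_grams(float(c), body_weight_kg)
        reports.append(
            TDIReport(
                sample_id=str(sid),
                coumarin_mg_per_g=float(c),
                body_weight_kg=body_weight_kg,
                serving_g=serving_g,
                max_daily_g=limit,
                flagged=bool(serving_g > limit),
            )
        )
    return reports
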