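"""Census arithmetic: residency proportions, fold changes, extrapolation.

The share of residents in a winter census is estimated as the ratio of
wintering individuals to breeding individuals, with breeding individuals
taken as twice the number of breeding pairs (each occupied nest holds two
adults).  When a breeding census is missing for a target year, pairs can be
extrapolated from earlier censuses by ordinary least squares — the mapping
of calendar years onto the regressor must be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResidencyEstimate",
    "resident_proportion",
    "fold_change",
    "extrapolate_pairs",
    "residency_trend",
]


@dataclass(frozen=True)
class ResidencyEstimate:
    year: int
    proportion: float
    wintering: int
    pairs: float
    extrapolated: bool

    @property
    def percent(self) -> int:
        """Headline value: nearest-integer percent."""
        return round(self.proportion * 100)


def resident_proportion(wintering: float, pairs: float) -> float:
    """Residents as a fraction of the breeding population: W / (2 B).

    Scaling both counts by the same factor leaves the proportion unchanged;
    values slightly above 1 are possible (non-breeders wintering).
    """
    if pairs <= 0:
        raise ValueError("pairs must be positive")
    if wintering < 0:
        raise ValueError("wintering count must be non-negative")
    return wintering / (2.0 * pairs)


def fold_change(early: float, late: float) -> float:
    """late / early, e.g. the 16-fold wintering increase 1995 -> 2020."""
    if early <= 0:
        raise ValueError("early count must be positive")
    return late / early


def extrapolate_pairs(
    census: pd.DataFrame,
    target_year: int,
    x_encoding: Mapping[int, float] | Callable[[int], float],
) -> tuple[float, float, float]:
    """OLS prediction of breeding pairs at ``target_year``.

    ``x_encoding`` maps calendar years to the regressor scale (it must be
    given explicitly: published fit coefficients are meaningless without
    it).  Uses the rows of ``census`` with non-missing ``breeding_pairs``.
    Returns (predicted_pairs, slope, intercept).
    """
    enc = x_encoding if callable(x_encoding) else x_encoding.__getitem__
    obs = census.dropna(subset=["breeding_pairs"])
    if len(obs) < 2:
        raise ValueError("need at least 2 breeding censuses to extrapolate")
    x = np.array([enc(int(y)) for y in obs["year"]], dtype=float)
    y = obs["breeding_pairs"].to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * enc(int(target_year)) + intercept
    return float(pred), float(slope), float(intercept)


def residency_trend(census: pd.DataFrame) -> pd.DataFrame:
    """Residency proportion for every census year with both counts.

    Breeding pairs are carried forward from the most recent breeding census
    (the minimum-estimate convention when breeding surveys are sparser than
    wintering ones); rows using carried-forward pairs are flagged.
    """
    df = census.sort_values("year").reset_index(drop=True)
    rows = []
    last_pairs = np.nan
    last_pairs_year = None
    for r in df.itertuples(index=False):
        pairs = r.breeding_pairs
        carried = False
        if pd.isna(pairs):
            pairs = last_pairs
            carried = True
        else:
            last_pairs = pairs
            last_pairs_year = r.year
        if pd.isna(r.wintering_individuals) or pd.isna(pairs):
            continue
        rows.append(
            {
                "year": int(r.year),
                "proportion": resident_proportion(r.wintering_individuals, pairs),
                "wintering": int(r.wintering_individuals),
                "pairs": float(pairs),
                "pairs_year": last_pairs_year,
                "pairs_carried_forward": carried,
            }
        )
    return pd.DataFrame(rows)
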