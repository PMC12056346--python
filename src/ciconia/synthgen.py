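"""Synthetic inputs with the statistical structure the analyses assume.

Four generators:

* neutral allele counts whose derived-count classes follow the standard
  neutral spectrum P(x = i) proportional to 1/i;
* sweep-distorted allele counts under the escape-probability hitchhiking
  model (each lineage escapes the sweep with probability
  p_e = 1 - exp(-alpha * d), escapees carry the derived allele with the
  pre-sweep frequency, non-escapees copy the swept haplotype), conditioned
  on polymorphism by rejection;
* GPS cohorts with an age-declining marginal migration probability
  (0.98 / 0.67 / 0.33 / 0.19 for ages 1, 2, 3, adult) and near-perfect
  adult consistency (per-year strategy flips at 0.027 ~ 3/113);
* linear-growth breeding/wintering census series.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .popstats import SFS

__all__ = [
    "SweepModelParams",
    "TrackSimParams",
    "DegenerateSweepError",
    "neutral_sfs",
    "sim_neutral_sites",
    "sim_sweep_sites",
    "split_pool",
    "sim_tracks",
    "sim_october_fixes",
    "sim_census",
]


class DegenerateSweepError(ValueError):
    """Polymorphism-conditioned sweep sampling has a vanishing acceptance rate."""


def neutral_sfs(n_chrom: int) -> SFS:
    """The 1/i neutral spectrum over derived counts 1..n-1, normalized."""
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    w = 1.0 / np.arange(1, n_chrom)
    return SFS(n_chrom, w / w.sum())


@dataclass(frozen=True)
class SweepModelParams:
    """Escape-probability hitchhiking model.

    alpha is the sweep intensity per base pair: a lineage at distance d from
    the sweep center recombines away ("escapes") with probability
    p_e = 1 - exp(-alpha * d).  background_sfs is the pre-sweep spectrum
    over derived counts 1..n_chrom-1.
    """

    alpha: float
    center_pos: int
    n_chrom: int
    background_sfs: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        # validates shape, positivity, unit sum
        object.__setattr__(
            self, "background_sfs", SFS(self.n_chrom, self.background_sfs).probs
        )

    @property
    def sfs(self) -> SFS:
        return SFS(self.n_chrom, self.background_sfs)


@dataclass(frozen=True)
class TrackSimParams:
    """Age-structured migratory-strategy simulator parameters.

    p_migrate_by_age holds the marginal migration probabilities for age
    classes 1, 2, 3 and adult (>= 4).  adult_flip_prob is the per-year
    probability that an adult switches strategy.  Latitude parameters are
    (mean, sd) in decimal degrees for each wintering destination; only the
    Gibraltar threshold (36 N) matters for classification.
    morocco_frac is the share of migrants wintering in Morocco rather than
    the Sahel (first-year split 13/87).
    """

    p_migrate_by_age: Sequence[float] = (0.98, 0.67, 0.33, 0.19)
    adult_flip_prob: float = 0.027
    latitude_means_sd: dict = field(
        default_factory=lambda: {
            "iberia": (39.0, 1.5),
            "morocco": (33.0, 1.0),
            "sahel": (15.0, 1.5),
        }
    )
    morocco_frac: float = 0.13

    def __post_init__(self) -> None:
        if len(self.p_migrate_by_age) == 0:
            raise ValueError("empty age schedule")
        p = np.asarray(self.p_migrate_by_age, float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("migration probabilities must be in [0, 1]")
        if not 0 <= self.adult_flip_prob <= 1:
            raise ValueError("adult_flip_prob must be in [0, 1]")
        if not 0 <= self.morocco_frac <= 1:
            raise ValueError("morocco_frac must be in [0, 1]")
        for dest, (_, sd) in self.latitude_means_sd.items():
            if sd <= 0:
                raise ValueError(f"latitude SD for {dest} must be > 0")


def sim_neutral_sites(
    n_chrom: int,
    n_sites: int,
    window_length: int,
    seed: int,
    scaffold: str = "scaf1",
    offset: int = 0,
) -> pd.DataFrame:
    """Neutral segregating sites: counts from the 1/i spectrum, uniform positions.

    Positions are 1-based, uniform on [offset+1, offset+window_length].
    """
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    sfs = neutral_sfs(n_chrom)
    x = rng.choice(np.arange(1, n_chrom), size=n_sites, p=sfs.probs)
    pos = np.sort(rng.integers(1, window_length + 1, size=n_sites)) + offset
    return pd.DataFrame(
        {"scaffold": scaffold, "pos": pos, "x": x.astype(int), "n": n_chrom}
    )


def _sweep_polymorphism_prob(pe: np.ndarray, freqs: np.ndarray, probs: np.ndarray, n: int):
    """P(0 < x < n) per site under the unconditioned sweep model (closed form)."""
    pe = pe[:, None]
    p = freqs[None, :]
    p0 = (1 - p) * (1 - pe * p) ** n + p * (pe * (1 - p)) ** n
    pn = p * (1 - pe * (1 - p)) ** n + (1 - p) * (pe * p) ** n
    return 1.0 - (probs[None, :] * (p0 + pn)).sum(axis=1)


def sim_sweep_sites(
    params: SweepModelParams,
    n_sites: int,
    window_length: int,
    seed: int,
    scaffold: str = "scaf1",
    offset: int = 0,
    acceptance_floor: float = 1e-3,
) -> pd.DataFrame:
    """Sweep-distorted segregating sites around ``params.center_pos``.

    Per site at distance d: draw the pre-sweep derived frequency from the
    background spectrum, let each of n lineages escape independently with
    p_e = 1 - exp(-alpha d); escapees are derived with the pre-sweep
    frequency, non-escapees copy the swept haplotype (derived with that same
    frequency).  Monomorphic outcomes are redrawn (rejection sampling).

    Raises DegenerateSweepError when the analytic acceptance probability of
    any site falls below ``acceptance_floor`` (e.g. the hard-sweep limit
    alpha -> 0, where every outcome is monomorphic).
    """
    rng = np.random.default_rng(seed)
    n = params.n_chrom
    sfs = params.sfs
    pos = np.sort(rng.integers(1, window_length + 1, size=n_sites)) + offset
    d = np.abs(pos - params.center_pos).astype(float)
    pe = 1.0 - np.exp(-params.alpha * d)
    acc = _sweep_polymorphism_prob(pe, sfs.freqs, sfs.probs, n)
    if n_sites and acc.min() < acceptance_floor:
        raise DegenerateSweepError(
            f"polymorphism acceptance probability {acc.min():.2e} below floor "
            f"{acceptance_floor:.0e}; sweep parameters are degenerate"
        )
    x = np.zeros(n_sites, dtype=int)
    todo = np.ones(n_sites, dtype=bool)
    classes = np.arange(1, n)
    while todo.any():
        m = int(todo.sum())
        p = classes[rng.choice(n - 1, size=m, p=sfs.probs)] / n
        j = rng.binomial(n, pe[todo])          # escapees
        b_esc = rng.binomial(j, p)             # derived among escapees
        swept_derived = rng.random(m) < p
        draw = b_esc + np.where(swept_derived, n - j, 0)
        x[todo] = draw
        todo[todo] = (draw <= 0) | (draw >= n)
    return pd.DataFrame({"scaffold": scaffold, "pos": pos, "x": x, "n": n})


def split_pool(sites: pd.DataFrame, n_total: int, n_group_a: int, seed: int) -> pd.DataFrame:
    """Split one panmictic pool into two groups by hypergeometric sampling.

    Group A receives ``n_group_a`` chromosomes drawn without replacement
    from the x derived among ``n_total``; group B gets the remainder, so
    x_a + x_b = x at every site and the expected between-group F_ST is 0.
    """
    if not 0 < n_group_a < n_total:
        raise ValueError("need 0 < n_group_a < n_total")
    x = sites["x"].to_numpy(int)
    if np.any(x > n_total) or np.any(sites["n"].to_numpy(int) != n_total):
        raise ValueError("site counts are not defined on n_total chromosomes")
    rng = np.random.default_rng(seed)
    x_a = rng.hypergeometric(x, n_total - x, n_group_a)
    out = sites.copy()
    out["x_a"] = x_a.astype(int)
    out["n_a"] = n_group_a
    out["x_b"] = (x - x_a).astype(int)
    out["n_b"] = n_total - n_group_a
    return out


def _draw_destination(rng, params: TrackSimParams, migrant: bool) -> str:
    if not migrant:
        return "iberia"
    return "morocco" if rng.random() < params.morocco_frac else "sahel"


def sim_tracks(
    params: TrackSimParams,
    n_birds: int,
    n_years: int,
    seed: int = 0,
    start_age: int = 1,
    first_year: int = 2016,
) -> pd.DataFrame:
    """Bird-year table with age-structured strategies and wintering latitudes.

    Birds enter at ``start_age`` and are followed ``n_years`` winters.  While
    immature (ages 1-3) the strategy is drawn each year from the marginal
    age schedule; on reaching adulthood a fixed strategy is drawn from the
    adult marginal and thereafter flips with ``adult_flip_prob`` per year.
    Adult migrants keep one destination (Morocco or Sahel) while migrant;
    the wintering latitude is drawn each year from that destination's
    normal distribution.
    """
    if n_birds <= 0:
        raise ValueError("n_birds must be positive")
    rng = np.random.default_rng(seed)
    sched = list(params.p_migrate_by_age)
    n_immature = len(sched) - 1  # last entry is the adult marginal
    rows = []
    for b in range(n_birds):
        adult_strategy: bool | None = None
        destination: str | None = None
        for t in range(n_years):
            age = start_age + t
            if age <= n_immature:
                migrant = rng.random() < sched[age - 1]
                destination = _draw_destination(rng, params, migrant)
            else:
                if adult_strategy is None:
                    adult_strategy = rng.random() < sched[-1]
                    destination = _draw_destination(rng, params, adult_strategy)
                elif rng.random() < params.adult_flip_prob:
                    # observed adult switches are short-distance: migrants
                    # settle in Iberia, lapsing residents go only to Morocco
                    adult_strategy = not adult_strategy
                    destination = "morocco" if adult_strategy else "iberia"
                migrant = adult_strategy
            mean, sd = params.latitude_means_sd[destination]
            # truncated to the strategy's side of the Gibraltar line so the
            # label and the latitude never disagree
            lat = rng.normal(mean, sd)
            while (lat < 36.0) != migrant:
                lat = rng.normal(mean, sd)
            rows.append(
                (
                    f"bird{b:05d}",
                    first_year + t,
                    age,
                    "adult" if age > n_immature else str(age),
                    lat,
                    "migrant" if migrant else "resident",
                )
            )
    return pd.DataFrame(
        rows, columns=["bird_id", "year", "age", "age_class", "winter_lat", "strategy"]
    )


def sim_october_fixes(
    bird_years: pd.DataFrame, fixes_per_bird: int = 12, lat_jitter: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """GPS fixes in October of each bird-year whose minimum latitude is
    exactly that row's ``winter_lat`` (the remaining fixes sit up to
    ``lat_jitter`` degrees further north)."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in bird_years.itertuples(index=False):
        lats = r.winter_lat + rng.uniform(0.0, lat_jitter, size=fixes_per_bird)
        lats[rng.integers(fixes_per_bird)] = r.winter_lat
        days = np.sort(rng.choice(np.arange(31), size=fixes_per_bird, replace=False))
        for day, lat in zip(days, lats):
            ts = pd.Timestamp(year=int(r.year), month=10, day=int(day) + 1, tz="UTC")
            rows.append((r.bird_id, ts, lat, -8.0 + rng.normal(0, 0.2)))
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "lat", "lon"])


def sim_census(
    base_pairs: int,
    pair_growth: float,
    base_winterers: int,
    winterer_growth: float,
    years: Sequence[int],
) -> pd.DataFrame:
    """Linear-growth census series (pairs and wintering individuals)."""
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    t = np.asarray(years) - years[0]
    pairs = base_pairs + pair_growth * t
    winter = base_winterers + winterer_growth * t
    if np.any(pairs < 0) or np.any(winter < 0):
        raise ValueError("requested negative census counts")
    return pd.DataFrame(
        {
            "year": years,
            "breeding_pairs": np.round(pairs).astype(int),
            "wintering_individuals": np.round(winter).astype(int),
        }
    )
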