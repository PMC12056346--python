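"""Site-frequency-spectrum statistics on derived-allele count tables.

The atomic observation is one polarized biallelic site: a derived-allele
count ``x`` out of ``n`` sampled chromosomes.  Everything here works on
pandas tables of such sites (columns ``scaffold, pos, x, n`` plus optional
per-group columns ``x_a, n_a, x_b, n_b``) and on non-overlapping genomic
windows tiled from position 0.

Statistics
----------
* per-site heterozygosity pi_site = 2 x (n-x) / (n (n-1)) (Nei's pairwise
  nucleotide diversity once summed over sites and divided by the number of
  callable sites);
* Watterson's theta S / a1;
* Tajima's D with the 1989 normalization constants;
* Fay & Wu's H = sum(pi_site) - sum(thetaH_site), thetaH_site =
  2 x^2 / (n (n-1)), unnormalized by default (``normalized=True`` gives the
  variance-standardized variant);
* Hudson's F_ST as a windowed ratio of averages.

Window conventions: 0-based half-open internally, BED-compatible on disk;
site positions are 1-based in allele-count tables (the SweepFinder dialect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SFS",
    "TajimaConstants",
    "tajima_constants",
    "site_pi",
    "site_theta_h",
    "window_sfs_stats",
    "hudson_fst",
    "global_sfs",
    "polarize",
    "make_windows",
    "assign_windows",
    "window_stats_table",
    "subsample_one_allele",
    "read_site_counts",
    "write_site_counts",
    "write_window_stats",
    "export_sweepfinder",
]

SITE_COLUMNS = ["scaffold", "pos", "x", "n"]
GROUP_COLUMNS = ["x_a", "n_a", "x_b", "n_b"]

#: Default minimum number of segregating sites for D / H / CLR in a window.
MIN_SEGREGATING_SITES = 10


@dataclass(frozen=True)
class SFS:
    """Unfolded site frequency spectrum: probabilities over derived counts 1..n-1."""

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if self.n < 2:
            raise ValueError("SFS requires n >= 2 chromosomes")
        if probs.shape != (self.n - 1,):
            raise ValueError(f"SFS for n={self.n} needs {self.n - 1} classes, got {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("SFS probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("SFS probabilities must sum to 1 within 1e-12")
        object.__setattr__(self, "probs", probs)

    @property
    def freqs(self) -> np.ndarray:
        """Derived-allele frequencies i/n for classes 1..n-1."""
        return np.arange(1, self.n) / self.n


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Normalization constants of Tajima's D for sample size ``n`` chromosomes."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def site_pi(x, n):
    """Per-site mean pairwise difference 2 x (n-x) / (n (n-1))."""
    x = np.asarray(x, dtype=float)
    return 2.0 * x * (n - x) / (n * (n - 1.0))


def site_theta_h(x, n):
    """Per-site homozygosity-weighted estimator 2 x^2 / (n (n-1))."""
    x = np.asarray(x, dtype=float)
    return 2.0 * x**2 / (n * (n - 1.0))


def _faywu_h_normalized(x: np.ndarray, n: int) -> float:
    """Variance-standardized Fay & Wu's H (Zeng et al. 2006 normalization).

    Uses the identity pi - thetaH = 2 (pi - thetaL) with
    thetaL = sum(x) / (n - 1).
    """
    const = tajima_constants(n)
    s = x.size
    theta_w = s / const.a1
    theta_sq = s * (s - 1.0) / (const.a1**2 + const.a2)
    pi = float(np.sum(site_pi(x, n)))
    theta_l = float(np.sum(x)) / (n - 1.0)
    bn1 = const.a2 + 1.0 / n**2
    var = (
        (n - 2.0) / (6.0 * (n - 1.0)) * theta_w
        + (18.0 * n**2 * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0))
        / (9.0 * n * (n - 1.0) ** 2)
        * theta_sq
    )
    if var <= 0:
        return math.nan
    return (pi - theta_l) / math.sqrt(var)


def window_sfs_stats(
    x: Iterable[int],
    n: int,
    sites_passing: int,
    min_segregating: int = MIN_SEGREGATING_SITES,
    normalized_h: bool = False,
) -> dict:
    """SFS summary statistics for the variants of one window.

    Parameters
    ----------
    x
        Derived-allele counts of the variant sites in the window.  Counts
        equal to 0 or ``n`` (monomorphic) are not segregating and are
        dropped before any computation.
    n
        Sampled chromosomes.
    sites_passing
        Total callable sites in the window (the denominator that turns the
        window sums into per-site estimates).
    min_segregating
        D and H are reported as NaN below this number of segregating sites.
    normalized_h
        If true, report the variance-standardized H instead of the plain
        pi - thetaH difference.

    Returns a dict with keys ``n_sites, S, pi, theta_w, taj_d, faywu_h``.
    ``pi`` and ``theta_w`` are per-site; D is the usual dimensionless
    statistic; H is a window sum (or dimensionless when normalized).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    x = np.asarray(list(x), dtype=int)
    if np.any((x < 0) | (x > n)):
        raise ValueError("derived counts must satisfy 0 <= x <= n")
    seg = x[(x > 0) & (x < n)]
    s = int(seg.size)
    out = {
        "n_sites": int(sites_passing),
        "S": s,
        "pi": math.nan,
        "theta_w": math.nan,
        "taj_d": math.nan,
        "faywu_h": math.nan,
    }
    if sites_passing <= 0:
        return out
    const = tajima_constants(n)
    pi_sum = float(np.sum(site_pi(seg, n)))
    out["pi"] = pi_sum / sites_passing
    out["theta_w"] = (s / const.a1) / sites_passing
    if s == 0 or s < min_segregating:
        return out
    var_d = const.e1 * s + const.e2 * s * (s - 1.0)
    if var_d > 0:
        out["taj_d"] = (pi_sum - s / const.a1) / math.sqrt(var_d)
    if normalized_h:
        out["faywu_h"] = _faywu_h_normalized(seg, n)
    else:
        out["faywu_h"] = pi_sum - float(np.sum(site_theta_h(seg, n)))
    return out


def hudson_fst(x_a, n_a, x_b, n_b) -> float:
    """Window F_ST (Hudson estimator, Bhatia et al. ratio of averages).

    Per site: N = (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1) and
    D = pA(1-pB) + pB(1-pA); the window estimate is sum(N)/sum(D).
    Sites where either group has fewer than 2 chromosomes are skipped;
    a window with sum(D) = 0 is reported NaN.
    """
    x_a = np.asarray(x_a, float)
    n_a = np.asarray(n_a, float)
    x_b = np.asarray(x_b, float)
    n_b = np.asarray(n_b, float)
    ok = (n_a >= 2) & (n_b >= 2)
    x_a, n_a, x_b, n_b = x_a[ok], n_a[ok], x_b[ok], n_b[ok]
    if x_a.size == 0:
        return math.nan
    p_a = x_a / n_a
    p_b = x_b / n_b
    num = (p_a - p_b) ** 2 - p_a * (1 - p_a) / (n_a - 1) - p_b * (1 - p_b) / (n_b - 1)
    den = p_a * (1 - p_b) + p_b * (1 - p_a)
    dsum = float(np.sum(den))
    if dsum == 0.0:
        return math.nan
    return float(np.sum(num)) / dsum


def global_sfs(x: Iterable[int], n: int) -> SFS:
    """Empirical unfolded SFS from all segregating sites (classes 1..n-1)."""
    x = np.asarray(list(x), dtype=int)
    seg = x[(x > 0) & (x < n)]
    if seg.size == 0:
        raise ValueError("cannot build an SFS without segregating sites")
    counts = np.bincount(seg, minlength=n)[1:n]
    return SFS(n, counts / counts.sum())


def polarize(sites: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Polarize ref/alt allele counts against an outgroup base.

    ``sites`` needs columns ``scaffold, pos, ref, alt, ref_count, alt_count,
    outgroup``.  The derived allele is the one NOT carried by the outgroup;
    sites whose outgroup base matches neither ref nor alt (including missing
    bases) are dropped and tallied in the returned report.
    """
    ref_is_anc = sites["outgroup"] == sites["ref"]
    alt_is_anc = sites["outgroup"] == sites["alt"]
    keep = ref_is_anc | alt_is_anc
    dropped = int((~keep).sum())
    kept = sites.loc[keep]
    x = np.where(ref_is_anc[keep], kept["alt_count"], kept["ref_count"])
    out = pd.DataFrame(
        {
            "scaffold": kept["scaffold"].to_numpy(),
            "pos": kept["pos"].to_numpy(),
            "x": x.astype(int),
            "n": (kept["ref_count"] + kept["alt_count"]).astype(int).to_numpy(),
        }
    )
    report = {"n_input": int(len(sites)), "n_kept": int(len(out)), "n_dropped_outgroup": dropped}
    return out.reset_index(drop=True), report


def make_windows(
    scaffold_lengths: Mapping[str, int], size: int, min_scaffold: int = 0
) -> pd.DataFrame:
    """Tile scaffolds with non-overlapping windows of ``size`` bp.

    Scaffolds shorter than ``min_scaffold`` are discarded entirely.  A
    terminal window shorter than ``size`` is kept but flagged ``partial``.
    Windows are 0-based half-open.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not scaffold_lengths:
        raise ValueError("empty scaffold length table")
    rows = []
    for scaf, length in scaffold_lengths.items():
        if length < min_scaffold:
            continue
        start = 0
        while start < length:
            end = min(start + size, length)
            rows.append((scaf, start, end, end - start < size))
            start += size
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "partial"])


def assign_windows(sites: pd.DataFrame, windows: pd.DataFrame) -> pd.Series:
    """Index of the window containing each site (-1 when uncovered).

    Sites carry 1-based positions; windows are 0-based half-open, so site
    ``pos`` falls in window [start, end) iff start < pos <= end.
    """
    idx = np.full(len(sites), -1, dtype=int)
    for wi, w in windows.iterrows():
        mask = (
            (sites["scaffold"] == w["scaffold"])
            & (sites["pos"] > w["start"])
            & (sites["pos"] <= w["end"])
        )
        idx[mask.to_numpy()] = wi
    return pd.Series(idx, index=sites.index, name="window")


def window_stats_table(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    sites_passing: Iterable[int] | None = None,
    min_segregating: int = MIN_SEGREGATING_SITES,
    normalized_h: bool = False,
) -> pd.DataFrame:
    """Per-window SFS statistics (and Hudson F_ST when group columns exist).

    ``sites_passing`` defaults to the window length, i.e. every base callable
    — the right convention for synthetic data where only variants are
    materialized.
    """
    widx = assign_windows(sites, windows)
    if sites_passing is None:
        passing = (windows["end"] - windows["start"]).to_numpy()
    else:
        passing = np.asarray(list(sites_passing), dtype=int)
    has_groups = all(c in sites.columns for c in GROUP_COLUMNS)
    rows = []
    for wi in range(len(windows)):
        sub = sites.loc[widx == wi]
        n = int(sub["n"].iloc[0]) if len(sub) else 2
        stats = window_sfs_stats(
            sub["x"], n, int(passing[wi]), min_segregating=min_segregating,
            normalized_h=normalized_h,
        )
        if has_groups and len(sub):
            stats["fst"] = hudson_fst(sub["x_a"], sub["n_a"], sub["x_b"], sub["n_b"])
        else:
            stats["fst"] = math.nan
        rows.append(stats)
    out = pd.concat([windows.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    return out


def subsample_one_allele(genotypes: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One sampled allele per individual per site (single-read sampling).

    ``genotypes`` holds one row per site with columns ``scaffold, pos`` and
    one integer column per individual giving the derived-allele dosage
    (0, 1 or 2).  A heterozygote contributes a fair coin; homozygotes are
    deterministic.  Returns a site table with n = number of individuals.
    """
    meta = [c for c in ("scaffold", "pos") if c in genotypes.columns]
    indiv = [c for c in genotypes.columns if c not in meta]
    dosage = genotypes[indiv].to_numpy(dtype=int)
    if np.any((dosage < 0) | (dosage > 2)):
        raise ValueError("dosages must be 0, 1 or 2")
    rng = np.random.default_rng(seed)
    draws = rng.random(dosage.shape) < dosage / 2.0
    out = genotypes[meta].copy()
    out["x"] = draws.sum(axis=1).astype(int)
    out["n"] = len(indiv)
    return out


# ---------------------------------------------------------------------------
# plain-text IO (TSV dialects)

def write_site_counts(sites: pd.DataFrame, path: str | Path) -> None:
    cols = SITE_COLUMNS + [c for c in GROUP_COLUMNS if c in sites.columns]
    sites[cols].to_csv(path, sep="\t", index=False)


def read_site_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_window_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Window stats TSV, BED-compatible first three columns, NA for missing."""
    stats.to_csv(path, sep="\t", index=False, na_rep="NA")


def export_sweepfinder(sites: pd.DataFrame, path: str | Path) -> None:
    """SweepFinder2 site file: header ``position x n folded``, folded=0."""
    seg = sites[(sites["x"] > 0) & (sites["x"] < sites["n"])]
    out = pd.DataFrame(
        {"position": seg["pos"].astype(int), "x": seg["x"].astype(int),
         "n": seg["n"].astype(int), "folded": 0}
    )
    out.to_csv(path, sep="\t", index=False)
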