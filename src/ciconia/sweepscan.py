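"""Sweep evidence: composite likelihood ratio, DCMS compositing, outliers.

The scan layer takes per-window SFS statistics and adds

* a SweepFinder-style composite likelihood ratio (CLR).  The sweep model:
  a lineage at distance d from the swept site escapes the sweep with
  probability p_e = 1 - exp(-alpha d); escapees carry the derived allele at
  its background frequency, non-escapees copy the swept haplotype.  The CLR
  maximizes the composite likelihood over a grid of alpha and a grid of
  test positions per window and compares it with the background spectrum;
* the de-correlated composite of multiple signals (DCMS): each statistic is
  converted to a one-sided empirical p-value by fractional ranking, and the
  per-window score is the sum of log-odds ln((1-p)/p), each statistic
  down-weighted by its total absolute Spearman correlation with all
  statistics (self-correlation included);
* top-quantile outlier calling with ceiling rule and adjacent-window
  merging, and the exact hypergeometric test for the overlap between two
  outlier sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popstats import SFS, MIN_SEGREGATING_SITES

__all__ = [
    "OverlapResult",
    "sweep_site_prob",
    "clr_window",
    "clr_scan",
    "default_alpha_grid",
    "rank_to_pvalue",
    "dcms",
    "scan_table",
    "top_outliers",
    "merge_regions",
    "overlap_test",
]


def default_alpha_grid(n_points: int = 40, lo: float = 1e-7, hi: float = 1e-2) -> np.ndarray:
    """Geometric grid of per-bp sweep intensities."""
    return np.geomspace(lo, hi, n_points)


def _sweep_pmf(b, n: int, pe, bg: SFS):
    """Unconditioned P(derived count = b) under the escape model.

    Mixing over the swept haplotype's allelic state collapses the escape
    configuration sum to two thinned binomials:
    P(b) = sum_p bg(p) [ (1-p) Bin(b; n, pe p) + p Bin(n-b; n, pe (1-p)) ].
    Broadcasts over sites: ``b`` and ``pe`` are arrays of equal shape.
    """
    b = np.atleast_1d(np.asarray(b, dtype=int))[..., None]
    pe = np.atleast_1d(np.asarray(pe, dtype=float))[..., None]
    p = bg.freqs[None, :]
    w = bg.probs[None, :]
    anc = sps.binom.pmf(b, n, pe * p)
    der = sps.binom.pmf(n - b, n, pe * (1 - p))
    return np.sum(w * ((1 - p) * anc + p * der), axis=-1)


def sweep_site_prob(
    b, n: int, d, alpha: float, bg: SFS, conditioned: bool = True
):
    """Probability of derived count ``b`` at distance ``d`` from a sweep.

    ``conditioned=True`` renormalizes over the polymorphic classes
    1..n-1 (the model, like the data, is defined on segregating sites).
    Vectorized over ``b`` and ``d``.
    """
    b_arr = np.asarray(b)
    if np.any((b_arr <= 0) | (b_arr >= n)):
        raise ValueError("b must lie strictly between 0 and n")
    if alpha < 0 or np.any(np.asarray(d) < 0):
        raise ValueError("alpha and d must be non-negative")
    scalar = np.isscalar(b) and np.isscalar(d)
    pe = 1.0 - np.exp(-alpha * np.asarray(d, dtype=float))
    raw = _sweep_pmf(b_arr, n, pe, bg)
    if conditioned:
        p0 = _sweep_pmf(np.zeros_like(np.atleast_1d(b_arr)), n, pe, bg)
        pn = _sweep_pmf(np.full_like(np.atleast_1d(b_arr), n), n, pe, bg)
        raw = raw / (1.0 - p0 - pn)
    return float(raw[0]) if scalar else raw


def clr_window(
    pos: np.ndarray,
    b: np.ndarray,
    n: int,
    bg: SFS,
    test_positions: Sequence[float],
    alpha_grid: np.ndarray,
) -> float:
    """CLR for one window: Lambda = 2 [max_{alpha, c} l_sweep - l_background],
    clipped at 0.  Invariant to uniform translation of all positions."""
    pos = np.asarray(pos, dtype=float)
    b = np.asarray(b, dtype=int)
    log_bg = float(np.sum(np.log(bg.probs[b - 1])))
    best = -np.inf
    for c in test_positions:
        d = np.abs(pos - c)
        for alpha in alpha_grid:
            with np.errstate(divide="ignore", invalid="ignore"):
                pr = sweep_site_prob(b, n, d, alpha, bg)
            if np.any(~np.isfinite(pr)) or np.any(pr <= 0):
                continue  # this alpha cannot produce the observed counts
            ll = float(np.sum(np.log(pr)))
            if ll > best:
                best = ll
    return max(0.0, 2.0 * (best - log_bg))


def clr_scan(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    bg: SFS,
    alpha_grid: np.ndarray | None = None,
    test_spacing: int = 10_000,
    min_segregating: int = MIN_SEGREGATING_SITES,
) -> np.ndarray:
    """Per-window CLR.  Test positions sit at the midpoints of
    ``test_spacing`` bins inside each window; windows below the segregating
    site floor are NaN."""
    from .popstats import assign_windows

    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    widx = assign_windows(sites, windows)
    out = np.full(len(windows), np.nan)
    for wi, w in windows.iterrows():
        sub = sites.loc[widx == wi]
        seg = sub[(sub["x"] > 0) & (sub["x"] < sub["n"])]
        if len(seg) < min_segregating:
            continue
        n = int(seg["n"].iloc[0])
        centers = np.arange(w["start"] + test_spacing / 2, w["end"], test_spacing)
        out[wi] = clr_window(
            seg["pos"].to_numpy(), seg["x"].to_numpy(), n, bg, centers, alpha_grid
        )
    return out


def rank_to_pvalue(values, higher_is_evidence: bool = True) -> np.ndarray:
    """One-sided empirical p-values by fractional ranking.

    Fractional rank r = rank/(m+1) over the m non-NA values (average ranks
    on ties) makes a uniform sample; the inverse-normal / z-score / normal
    tail chain then collapses identically to p = 1 - r for statistics where
    high values are evidence.  NA propagates.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    m = int(ok.sum())
    if m < 2:
        raise ValueError("need at least 2 non-missing values to rank")
    ranks = sps.rankdata(v[ok], method="average")
    frac = ranks / (m + 1.0)
    out[ok] = 1.0 - frac if higher_is_evidence else frac
    return out


def dcms(
    pvals: np.ndarray,
    stats: np.ndarray | None = None,
    corr: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """DCMS scores and the Spearman weighting matrix.

    ``pvals`` and ``stats`` are (windows x statistics) matrices of one-sided
    p-values and the oriented statistics they came from.  Spearman
    correlations are computed complete-case from ``stats`` (or taken from a
    precomputed ``corr``); the score for window t is
    sum_i ln((1-p_it)/p_it) / sum_j |r_ij|, with |r_ii| = 1 in the
    denominator.  Windows with any missing statistic get a missing score.
    """
    pvals = np.atleast_2d(np.asarray(pvals, dtype=float))
    if stats is None and corr is None:
        raise ValueError("provide stats (to estimate correlations) or corr")
    if stats is None:
        stats = pvals  # completeness bookkeeping only
    stats = np.atleast_2d(np.asarray(stats, dtype=float))
    if pvals.shape != stats.shape:
        raise ValueError("pvals and stats must have the same shape")
    k = pvals.shape[1]
    complete = ~np.isnan(stats).any(axis=1) & ~np.isnan(pvals).any(axis=1)
    if complete.sum() < 3 and corr is None:
        raise ValueError("need at least 3 complete windows")
    if np.any((pvals[complete] <= 0) | (pvals[complete] >= 1)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError("corr must be k x k")
    elif k == 1:
        corr = np.ones((1, 1))
    elif k == 2:
        r, _ = sps.spearmanr(stats[complete, 0], stats[complete, 1])
        corr = np.array([[1.0, r], [r, 1.0]])
    else:
        corr, _ = sps.spearmanr(stats[complete])
        corr = np.atleast_2d(corr)
    weights = np.sum(np.abs(corr), axis=1)
    scores = np.full(pvals.shape[0], np.nan)
    lp = np.log((1.0 - pvals[complete]) / pvals[complete])
    scores[complete] = lp @ (1.0 / weights)
    return scores, corr


def scan_table(
    window_stats: pd.DataFrame,
    clr: np.ndarray | None = None,
    flip_h: bool = False,
) -> pd.DataFrame:
    """Assemble the window-by-statistic scan table and DCMS scores.

    Expects columns ``taj_d``, ``faywu_h`` (and ``clr`` unless passed
    separately).  Tajima's D is multiplied by -1 so that, for every
    statistic, larger values mean more sweep evidence; H is flipped only
    when ``flip_h`` is set (sweeps drive the classic pi - thetaH strongly
    negative, so flipping is the correctness knob, not the default).
    Returns a copy with columns ``p_negd, p_h, p_clr, dcms``; the 3x3
    Spearman matrix is stored in ``result.attrs["spearman"]``.
    """
    out = window_stats.copy()
    if clr is not None:
        out["clr"] = np.asarray(clr, dtype=float)
    oriented = np.column_stack(
        [
            -out["taj_d"].to_numpy(float),
            (-1.0 if flip_h else 1.0) * out["faywu_h"].to_numpy(float),
            out["clr"].to_numpy(float),
        ]
    )
    pvals = np.column_stack([rank_to_pvalue(oriented[:, j]) for j in range(3)])
    scores, corr = dcms(pvals, oriented)
    out["p_negd"], out["p_h"], out["p_clr"] = pvals.T
    out["dcms"] = scores
    out.attrs["spearman"] = corr
    return out


def top_outliers(scores, q: float = 0.01) -> np.ndarray:
    """Indices of the ceil(q*m) highest-scoring windows (m = non-NA count).

    Ties at the cutoff are broken by genomic order (input order) and
    reported with a warning.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    ok = np.flatnonzero(~np.isnan(s))
    m = ok.size
    if m == 0:
        raise ValueError("no non-missing scores")
    k = math.ceil(q * m)
    order = ok[np.lexsort((ok, -s[ok]))]  # score desc, then genomic order
    chosen = order[:k]
    if k < m and s[order[k - 1]] == s[order[k]]:
        warnings.warn("tied scores at the outlier cutoff; broken by genomic order")
    return np.sort(chosen)


def merge_regions(outlier_windows: pd.DataFrame, score: str | None = None) -> pd.DataFrame:
    """Merge maximal runs of genomically adjacent outlier windows.

    Windows must be sorted by (scaffold, start); two windows are adjacent
    when they share a scaffold and the second starts where the first ends.
    Returns one row per region: scaffold, start, end, n_windows and, when a
    ``score`` column is named, the peak value in the region.
    """
    regions = []
    cur = None
    for row in outlier_windows.itertuples(index=False):
        r = row._asdict()
        if cur is not None and r["scaffold"] == cur["scaffold"] and r["start"] == cur["end"]:
            cur["end"] = r["end"]
            cur["n_windows"] += 1
            if score:
                cur["peak"] = max(cur["peak"], r[score])
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "scaffold": r["scaffold"],
                "start": r["start"],
                "end": r["end"],
                "n_windows": 1,
            }
            if score:
                cur["peak"] = r[score]
        # guard against unsorted/overlapping input
        if cur["start"] > cur["end"]:
            raise ValueError("outlier windows must be sorted and non-overlapping")
    if cur is not None:
        regions.append(cur)
    return pd.DataFrame(regions)


@dataclass(frozen=True)
class OverlapResult:
    """Exact upper-tail probability of a multi-set intersection."""

    universe: int
    sizes: tuple[int, ...]
    intersection: int
    p_value: float
    expected: float


def overlap_test(n_universe: int, sizes: Sequence[int], k: int) -> OverlapResult:
    """Probability that two random subsets of a universe of ``n_universe``
    windows, of the given sizes, share at least ``k`` members.

    For two sets this is the exact hypergeometric upper tail
    P(X >= k), X ~ Hypergeom(N, K=size1, n=size2), evaluated in log space.
    """
    sizes = tuple(int(s) for s in sizes)
    if any(s > n_universe for s in sizes):
        raise ValueError("set sizes cannot exceed the universe")
    if k > min(sizes):
        raise ValueError("intersection cannot exceed the smallest set")
    if k < 0:
        raise ValueError("intersection must be non-negative")
    if len(sizes) != 2:
        raise NotImplementedError("only the two-set overlap test is implemented")
    k1, k2 = sizes
    expected = k1 * k2 / n_universe
    if k == 0:
        p = 1.0
    else:
        p = float(np.exp(sps.hypergeom.logsf(k - 1, n_universe, k1, k2)))
    return OverlapResult(n_universe, sizes, k, p, expected)
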