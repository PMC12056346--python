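"""Migratory-strategy analysis of GPS-tracked birds.

A bird-winter is summarized by its wintering latitude — the minimum
latitude reached in October, when the birds sit on stable wintering
grounds — and classified migrant (crossed the Strait of Gibraltar,
i.e. wintering latitude south of 36 N) or resident (stayed in Iberia).

Three inference pieces:

* ``repeatability``: intraclass correlation R = s2_between /
  (s2_between + s2_within) from a one-way Gaussian random-intercept model
  fit by REML (closed-form profile over the variance ratio), SE by seeded
  parametric bootstrap, p by the likelihood-ratio test against zero
  between-bird variance with the half-and-half chi-square mixture;
* ``fit_age_model``: random-intercept logistic regression of strategy on
  age (classes 1, 2, 3, adult coded 4), maximum likelihood with adaptive
  Gauss-Hermite quadrature over the per-bird effect;
* ``transition_summary``: year-to-year strategy switches among adults.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "GIBRALTAR_LAT",
    "RepeatabilityResult",
    "AgeModelResult",
    "wintering_latitude",
    "classify_strategy",
    "repeatability",
    "fit_age_model",
    "transition_summary",
]

#: Latitude of the Strait of Gibraltar used as the migrant/resident boundary.
GIBRALTAR_LAT = 36.0


def wintering_latitude(fixes: pd.DataFrame, month: int = 10) -> pd.DataFrame:
    """Minimum latitude per (bird, year) over the fixes of ``month``.

    ``fixes`` needs columns ``bird_id, timestamp, lat`` (timestamps parseable
    as UTC).  Bird-years with no fix in the month are absent from the
    output; callers needing them explicit should reindex.
    """
    ts = pd.to_datetime(fixes["timestamp"], utc=True)
    sel = fixes.loc[ts.dt.month == month].copy()
    if sel.empty:
        warnings.warn(f"no fixes in month {month}; returning empty table")
        return pd.DataFrame(columns=["bird_id", "year", "winter_lat"])
    sel["year"] = ts.dt.year[sel.index]
    out = (
        sel.groupby(["bird_id", "year"], as_index=False)["lat"]
        .min()
        .rename(columns={"lat": "winter_lat"})
    )
    return out


def classify_strategy(winter_lat, threshold: float = GIBRALTAR_LAT):
    """'migrant' below the Gibraltar threshold, 'resident' at or above it.

    Accepts a scalar or an array/Series; missing latitudes give missing
    strategies.
    """
    lat = np.asarray(winter_lat, dtype=float)
    out = np.where(np.isnan(lat), None, np.where(lat < threshold, "migrant", "resident"))
    if out.shape == ():
        return out.item()
    return pd.Series(out, name="strategy")


# ---------------------------------------------------------------------------
# Gaussian repeatability (one-way random-intercept, REML)


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    se: float
    p_value: float
    n_birds: int
    n_obs: int
    var_between: float
    var_within: float


def _group_summaries(values: np.ndarray, groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=values)
    means = sums / sizes
    ssw = float(np.sum((values - means[inv]) ** 2))
    return sizes, means, ssw


def _profile_reml(sizes, means, ssw, n_total):
    """REML deviance profiled over gamma = s2_between / s2_within."""

    def neg2_reml(log_gamma):
        g = math.exp(log_gamma)
        w = sizes / (1.0 + sizes * g)
        mu = float(np.sum(w * means) / np.sum(w))
        t = ssw + float(np.sum(w * (means - mu) ** 2))
        return (
            (n_total - 1) * math.log(t / (n_total - 1))
            + float(np.sum(np.log1p(sizes * g)))
            + math.log(float(np.sum(w)))
        )

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(-15.0, 30.0), method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = math.exp(res.x)
    if neg2_reml(-30.0) <= res.fun:  # boundary: no between-group variance
        gamma = 0.0
    w = sizes / (1.0 + sizes * gamma)
    mu = float(np.sum(w * means) / np.sum(w))
    t = ssw + float(np.sum(w * (means - mu) ** 2))
    s2e = t / (n_total - 1)
    return gamma * s2e, s2e, mu


def _ml_deviance(sizes, means, ssw, n_total, gamma):
    w = sizes / (1.0 + sizes * gamma)
    mu = float(np.sum(w * means) / np.sum(w))
    t = ssw + float(np.sum(w * (means - mu) ** 2))
    return n_total * math.log(t / n_total) + float(np.sum(np.log1p(sizes * gamma)))


def repeatability(
    values,
    groups,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityResult:
    """Intraclass correlation of ``values`` grouped by bird.

    The point estimate comes from the REML variance components; the SE from
    ``n_boot`` parametric-bootstrap refits (0 skips the bootstrap and
    reports NaN); the p-value from the ML likelihood-ratio test of zero
    between-bird variance using the half chi2_0 + half chi2_1 mixture.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must align")
    sizes, means, ssw = _group_summaries(values, groups)
    if sizes.size < 2:
        raise ValueError("need at least 2 birds")
    if np.all(sizes < 2):
        raise ValueError("need repeated measures for at least one bird")
    n_total = int(values.size)
    if np.var(values) == 0.0:
        warnings.warn("zero total variance; repeatability defined as 0")
        return RepeatabilityResult(0.0, 0.0, 1.0, sizes.size, n_total, 0.0, 0.0)
    s2a, s2e, mu = _profile_reml(sizes, means, ssw, n_total)
    r = s2a / (s2a + s2e) if (s2a + s2e) > 0 else 0.0

    # LRT against s2_between = 0 (ML, boundary mixture)
    def ml_dev(gamma):
        return _ml_deviance(sizes, means, ssw, n_total, gamma)

    res = optimize.minimize_scalar(
        lambda lg: ml_dev(math.exp(lg)), bounds=(-12.0, 12.0), method="bounded"
    )
    dev1 = min(res.fun, ml_dev(0.0))
    lr = max(0.0, ml_dev(0.0) - dev1)
    p = 0.5 * sps.chi2.sf(lr, 1) if lr > 0 else 1.0

    se = math.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        sqrt_a, sqrt_e = math.sqrt(max(s2a, 0.0)), math.sqrt(max(s2e, 1e-12))
        for b in range(n_boot):
            alpha = rng.normal(0.0, sqrt_a, size=sizes.size)
            # simulate group sums directly from the balanced sufficient stats
            sim_means = mu + alpha + rng.normal(0.0, sqrt_e / np.sqrt(sizes))
            sim_ssw = float(
                sps.chi2.rvs(df=n_total - sizes.size, random_state=rng) * s2e
            )
            ba, be, _ = _profile_reml(sizes, sim_means, sim_ssw, n_total)
            reps[b] = ba / (ba + be) if (ba + be) > 0 else 0.0
        se = float(np.std(reps, ddof=1))
    return RepeatabilityResult(
        float(r), se, float(p), int(sizes.size), n_total, float(s2a), float(s2e)
    )


# ---------------------------------------------------------------------------
# binomial GLMM (random intercept per bird, adaptive Gauss-Hermite)


@dataclass(frozen=True)
class AgeModelResult:
    slope: float
    slope_se: float
    intercept: float
    re_sd: float
    n: int
    loglik: float
    converged: bool
    separation: bool


def _agq_loglik(beta0, beta1, sigma, y, a, gi, n_groups, nodes, wts):
    """Marginal log-likelihood, adaptive quadrature, vectorized over birds.

    The per-bird posterior mode is found by a joint Newton iteration (the
    1-D problems are independent, so segment sums via bincount run them all
    at once); quadrature nodes are then centred and scaled per bird.
    """
    eta0 = beta0 + beta1 * a
    u = np.zeros(n_groups)
    for _ in range(60):
        p = special.expit(eta0 + u[gi])
        grad = np.bincount(gi, weights=p - y, minlength=n_groups) + u / sigma**2
        hess = np.bincount(gi, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma**2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = special.expit(eta0 + u[gi])
    hess = np.bincount(gi, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma**2
    scale = np.sqrt(2.0 / hess)
    # (Q, G) node grid, per-group log joint density at each node
    z = u[None, :] + scale[None, :] * nodes[:, None]
    log_joint = np.empty((nodes.size, n_groups))
    for k in range(nodes.size):
        eta = eta0 + z[k, gi]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        log_joint[k] = (
            np.bincount(gi, weights=ll_obs, minlength=n_groups)
            - 0.5 * z[k] ** 2 / sigma**2
            - 0.5 * math.log(2 * math.pi * sigma**2)
        )
    log_w = np.log(wts)[:, None] + nodes[:, None] ** 2 + log_joint
    return float(np.sum(special.logsumexp(log_w, axis=0) + np.log(scale)))


def fit_age_model(
    bird_years: pd.DataFrame,
    n_quad: int = 20,
    adults_once: bool = True,
    adult_age: int = 4,
) -> AgeModelResult:
    """Random-intercept logistic regression of migration on age.

    Age enters numerically with every adult record coded ``adult_age``;
    when ``adults_once`` is set, each bird contributes at most one adult
    record (its first), mirroring designs where birds tagged as adults have
    a single strategy determination.  The outcome is 1 for migrant.
    """
    df = bird_years.dropna(subset=["strategy"]).copy()
    df["age_num"] = np.minimum(df["age"].to_numpy(int), adult_age)
    if adults_once:
        adult = df[df["age_num"] >= adult_age].drop_duplicates("bird_id", keep="first")
        df = pd.concat([df[df["age_num"] < adult_age], adult], ignore_index=True)
    y = (df["strategy"] == "migrant").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    a = df["age_num"].to_numpy(float)
    _, gi = np.unique(df["bird_id"].to_numpy(), return_inverse=True)
    n_groups = int(gi.max()) + 1
    if np.max(np.bincount(gi)) == 1:
        # every bird observed once: the random intercept is unidentifiable
        # and the model is ordinary logistic regression
        import statsmodels.api as sm

        x = np.column_stack([np.ones_like(a), a])
        logit = sm.Logit(y, x).fit(disp=0)
        return AgeModelResult(
            float(logit.params[1]), float(logit.bse[1]), float(logit.params[0]),
            0.0, int(len(df)), float(logit.llf), True, False,
        )
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)

    def nll(theta):
        b0, b1, log_s = theta
        sigma = math.exp(min(log_s, 4.0))
        return -_agq_loglik(b0, b1, max(sigma, 1e-4), y, a, gi, n_groups, nodes, wts)

    # start from the plain logistic fit (falls back when age is degenerate)
    import statsmodels.api as sm

    x = np.column_stack([np.ones_like(a), a])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        start = np.array([glm.params[0], glm.params[1], 0.0])
        if not np.all(np.isfinite(start)):
            raise ValueError
    except Exception:
        start = np.array([special.logit(np.clip(y.mean(), 0.01, 0.99)), 0.0, 0.0])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    b0, b1, log_s = res.x
    # sigma -> 0 profile: when the random effect adds nothing (e.g. every
    # bird observed once) the model collapses to ordinary logistic regression
    nll0 = nll(np.array([start[0], start[1], -12.0]))
    if nll0 <= res.fun + 1e-6:
        b0, b1, log_s = start[0], start[1], -12.0
        res.fun = nll0
    sigma = math.exp(min(log_s, 4.0))
    separation = abs(b1) > 20 or abs(b0) > 60
    if separation:
        warnings.warn("possible complete separation; estimates may diverge")

    # observed-information SE for the slope (central differences on (b0, b1))
    se = math.nan
    try:
        eps = 1e-4
        hess = np.zeros((2, 2))
        base = np.array([b0, b1])
        for i in range(2):
            for j in range(2):
                t = np.zeros(2)
                t[i] += eps
                u = np.zeros(2)
                u[j] += eps
                f = lambda v: nll(np.array([v[0], v[1], log_s]))
                hess[i, j] = (
                    f(base + t + u) - f(base + t - u) - f(base - t + u) + f(base - t - u)
                ) / (4 * eps * eps)
        cov = np.linalg.inv(hess)
        if cov[1, 1] > 0:
            se = math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        pass
    return AgeModelResult(
        float(b1), float(se), float(b0), float(sigma), int(len(df)),
        float(-res.fun), bool(res.success), bool(separation),
    )


def transition_summary(
    bird_years: pd.DataFrame, adults_only: bool = True, adult_age: int = 4
) -> dict:
    """Count year-to-year strategy transitions and switches.

    A transition is a (bird, year t -> t+1) pair with both strategies known
    (both years adult when ``adults_only``); a switch is a transition whose
    strategies differ.
    """
    df = bird_years.dropna(subset=["strategy"]).sort_values(["bird_id", "year"])
    if adults_only:
        df = df[df["age"].to_numpy(int) >= adult_age]
    transitions = 0
    switches = 0
    for _, sub in df.groupby("bird_id"):
        years = sub["year"].to_numpy(int)
        strat = sub["strategy"].to_numpy()
        consec = years[1:] == years[:-1] + 1
        transitions += int(consec.sum())
        switches += int(np.sum(consec & (strat[1:] != strat[:-1])))
    return {"switches": switches, "transitions": transitions}
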