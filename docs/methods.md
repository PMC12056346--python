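# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would need to know.

## Site-frequency-spectrum statistics

All genomic statistics operate on polarized biallelic sites: a derived
count x out of n sampled chromosomes (polarization against an outgroup
base is provided by `popstats.polarize`, which drops and tallies sites
whose outgroup allele matches neither sample allele). Statistics are
computed from known allele counts; genotype-likelihood estimation for
low-coverage data is deliberately out of scope — the statistical
definitions, not the coverage model, are what the package implements.

Per window of L callable sites with S segregating variants:

* π̂ = Σ 2x(n−x)/(n(n−1)) / L (dividing the window sum by all callable
  sites, not just variants, gives the unbiased per-site estimate);
* θ̂_W = (S/a₁)/L with a₁ = Σ_{i<n} 1/i;
* Tajima's D = (Σπ_site − S/a₁)/√(e₁S + e₂S(S−1)) with the standard 1989
  constants (a₁…e₂ are exposed via `tajima_constants`);
* Fay & Wu's H = Σπ_site − Σ 2x²/(n(n−1)), the classic unnormalized
  difference. `normalized_h=True` switches to the variance-standardized
  version (via the identity π − θ_H = 2(π − θ_L) and the Zeng-style
  variance); the unnormalized form is the default because ranks, not
  magnitudes, feed the composite.
* Hudson's F_ST as a ratio of window-summed numerators and denominators
  (per site N = (p_A−p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1),
  D = p_A(1−p_B)+p_B(1−p_A)). The ratio-of-averages form is stable for
  windows and nearly unbiased; it can be slightly negative, which is
  information (identical groups give non-positive values) and is never
  clipped.

Windows are 0-based half-open, tiled from 0; BED columns on disk;
1-based site positions in allele-count tables (the SweepFinder dialect,
and `export_sweepfinder` writes the `position x n folded` site file).
D, H and the CLR are reported missing below a floor of 10 segregating
sites per window (the floor is a package choice — window statistics on a
handful of variants are rank noise — and is configurable); missing values
are written as explicit `NA`, never 0, and are excluded from rank
transforms.

## The sweep model and the CLR

The hitchhiking model: a lineage at distance d from the swept site escapes
the sweep with probability p_e = 1 − exp(−αd). Conditional on a background
derived-allele frequency p drawn from the background SFS (classes i/n),
each of the n lineages escapes independently; escapees carry the derived
allele with probability p; non-escapees copy the swept haplotype, which is
itself derived with probability p. Mixing over the swept haplotype's state
collapses the escape-configuration sum to a two-binomial closed form

    P(b) = Σ_p bg(p) [ (1−p) Bin(b; n, p_e p) + p Bin(n−b; n, p_e (1−p)) ],

renormalized over the polymorphic classes 1..n−1. The test suite verifies
this closed form against brute-force enumeration of every escape and
allele configuration.

One property of this formulation is worth stating precisely: at full
escape (p_e → 1) the model converges to the *frequency-resampled*
background Σ_k bg(k)·Bin(b; n, k/n), not to bg itself — every lineage
redraws its allele at the background frequency rather than keeping its
identity in the original sample. The distinction is invisible to the scan
in practice (the likelihood-ratio is clipped at zero and neutral data are
never fit better by the resampled spectrum than by the empirical
background), and it keeps the generator and the scan model exactly
matched, which is what turns sweep detection into a parameter-recovery
exercise.

The CLR for a window is Λ = 2[max_{α,c} Σ log P(b_i | d_i, α) −
Σ log bg(b_i)], clipped at 0, maximized over a geometric α grid (default
40 points, 10⁻⁷–10⁻² per bp) and test positions at the midpoints of 10 kb
bins inside the window. The grid and spacing are configurable; they are a
discretization choice, not a statement about the true α.

## DCMS

Each oriented statistic (−D, H, CLR; D is flipped so that large values
always mean sweep evidence, H can additionally be flipped with `flip_h`
since hitchhiking drives the classic H strongly negative — the default
follows the orientation convention of flipping only D) is converted to a
one-sided empirical p-value by fractional ranking: r = rank/(m+1) with
average ranks on ties, p = 1 − r. The inverse-normal / z-score / normal
tail chain sometimes described for this transform is the identity on
these quantities (Φ then Φ⁻¹ cancel), so the collapsed form is exact, and
p is always strictly inside (0,1). The composite is

    DCMS_t = Σ_i ln((1−p_it)/p_it) / Σ_j |r_ij| ,

with r the Spearman matrix of the oriented statistics over complete
windows and |r_ii| = 1 included in each denominator. Natural log is used;
the base cancels in any ranking of scores. Outliers are the ⌈qm⌉
highest-scoring of the m non-missing windows (q = 0.01 default); ties at
the cutoff are broken by genomic order and flagged with a warning.
Adjacent outlier windows (same scaffold, end = next start) merge into
regions. Overlap between two outlier sets is tested with the exact
hypergeometric upper tail P(X ≥ k); the multi-set generalization is not
implemented (two sets are all the analysis needs).

## Movement models

The wintering latitude of a bird-year is the minimum latitude over its
October fixes (October in UTC; by then the birds sit on stable wintering
grounds). Classification is a fixed threshold at the Strait of Gibraltar,
36.0°N, applied to that latitude — for this geography the latitude proxy
is equivalent to detecting a strait crossing, and crossing-event detection
from raw fixes is intentionally not the default.

Repeatability is the intraclass correlation from the one-way Gaussian
random-intercept model y_ij = μ + α_i + ε_ij. The REML criterion is
profiled analytically down to a 1-D search over the variance ratio
γ = σ²_α/σ²_ε (given γ, the GLS mean and both variances have closed
forms), which makes one fit cheap enough that the standard error comes
from 1000 seeded parametric-bootstrap refits (simulated directly from the
sufficient statistics: group means and the within-group sum of squares).
The p-value is the ML likelihood-ratio test of σ²_α = 0 with the
½χ²₀ + ½χ²₁ boundary mixture. statsmodels' MixedLM is used in the test
suite as an independent cross-check of the variance components, never as
the implementation.

The age model is a random-intercept logistic GLMM: logit P(migrant_ij) =
β₀ + β₁·age_ij + u_i, u_i ~ N(0, σ²). Age is numeric with every adult
record coded 4 (classes 1, 2, 3, adult); birds whose records are all
adult contribute one record (their first), mirroring designs in which an
adult-tagged bird yields a single strategy determination. The marginal
likelihood is integrated by adaptive Gauss–Hermite quadrature (20 nodes
default): per bird, a Newton iteration finds the posterior mode of u_i
(all birds at once via segment sums), nodes are centred and scaled by the
local curvature, and the outer optimization is Nelder–Mead over
(β₀, β₁, log σ). Slope standard errors come from the observed information
(central-difference Hessian in β at the optimum). When every bird is
observed once the random intercept is unidentifiable and the fit
collapses, by construction, to ordinary logistic regression; a σ→0
profile comparison also guards near-degenerate cases, and |β| blowing up
is flagged as likely complete separation.

Strategy transitions are consecutive-year pairs (t, t+1) with both
strategies known (adults only by default); a switch is a differing pair.

## Census arithmetic

The resident proportion is W/(2B): wintering individuals over twice the
breeding pairs. The factor 2 (pairs → individuals) is made explicit
because only that reading makes the two published census anchors round to
18% and 83%. Fold change is a plain ratio. Pair extrapolation is OLS on
(x, pairs); the mapping of calendar years onto x is a required explicit
argument because published fit coefficients are meaningless without it —
for the same reason the package never tries to reproduce the published
lower-bound 68% figure, whose x-encoding is not recoverable.

## What the synthetic data emulates — and what it does not

The generators produce data with exactly the structure the estimators
assume: neutral derived counts i.i.d. from the 1/i spectrum (under which
E[π̂] = E[θ̂_W] = E[θ̂_H] per site, so D and H are centred near zero by
construction), sweep windows from the same escape model the CLR tests,
group splits that are hypergeometric draws from one pool (expected
F_ST = 0), and bird-years whose marginal migration probabilities equal
the age schedule 0.98/0.67/0.33/0.19 with a 2.7%/yr adult flip rate
(≈3/113). Wintering destinations default to Iberia N(39, 1.5°),
Morocco N(33, 1°), Sahel N(15, 1.5°) — only the 36°N threshold matters
for classification, so the means are free parameters; draws are truncated
to the strategy's side of the threshold so labels and latitudes never
disagree. Adults keep one destination while their strategy is unchanged,
and strategy flips are short-distance (migrant→Iberia, resident→Morocco),
matching the observed switch type; this is what makes adult repeatability
near-perfect. The first-year Morocco/Sahel split is 13/87.

None of this emulates linkage, recombination, demography, genotype
likelihoods from low-coverage reads, GPS fix error, or immigration. A
passing suite therefore demonstrates that the estimators recover the
truth under their own assumptions (calibration and power), not that real
data satisfy those assumptions.

Per-year conditional abandonment probabilities for juveniles are not
modelled; the generator parameterizes the marginal age schedule directly,
drawing each immature year independently, which is the weakest assumption
consistent with the marginals (and makes juvenile repeatability ≈ 0, the
intended contrast with adults).

## Numerical choices and degenerate inputs

* Sweep generator: polymorphism conditioning is rejection sampling; the
  analytic acceptance probability P(0 < x < n) has a closed form, and any
  site below the acceptance floor (default 10⁻³, e.g. the hard-sweep
  limit α = 0) raises a degenerate-parameter error instead of looping.
* CLR: α values that assign zero probability to an observed count are
  skipped (they cannot explain the data); Λ is clipped at 0; windows
  below the segregating-site floor are missing.
* REML/ML searches run on log γ over [−15, 30] with a boundary check at
  γ = 0; zero total variance defines R = 0 with a warning.
* Ranking: average ranks on ties keep the p-values in (0,1); all-missing
  vectors are an error, missing entries propagate.
* Pipeline: every stage draws its seed as a hash substream of the global
  seed, so stages are independently reproducible; outputs are stamped
  with config hash, seed and version, and reruns are byte-identical.

## Problem sizes used in the checks

The simulation suites run at sizes chosen to make their tolerances sharp
but cheap: 2000 neutral windows (n = 20, 100 sites) for the D/H centring
bands; 100 window pairs (108 chromosomes split 22/86) for the null-F_ST
band; 200 neutral + 100 sweep windows (n = 40, 60 sites, 24-point α grid)
for CLR power at a sweep with mean p_e ≈ 0.21; 200 birds × 4 observations
for ICC recovery; 500 birds × 4 ages for GLMM slope recovery; and a
250-window neutral pipeline for the null overlap band. The acceptance
replay runs the windowed statistics and DCMS compositing at the full
22,766-window scale with a two-statistic composite (D and H), since the
outlier count depends only on the number of scored windows and the
quantile rule.

## Known limitations

* The CLR grid search is a composite likelihood: no p-values are attached
  to Λ itself; inference is rank-based downstream, as in the scan
  literature.
* The overlap test treats windows as exchangeable; autocorrelation along
  the genome (adjacent outlier windows) makes it mildly anticonservative
  on real data.
* `movement.repeatability` assumes Gaussian latitudes; the bimodal
  migrant/resident mixture violates this for pooled cohorts, which is
  exactly why the estimator is applied within age classes where one mode
  dominates (the same caveat applies to the original rpt-style analysis).
* The GLMM's quadrature is 1-D; nothing beyond a random intercept is
  supported.
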