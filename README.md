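# ciconia

Analysis toolkit for the question *"why does a long-lived migratory bird
stop migrating?"*, built around the Iberian white stork (*Ciconia
ciconia*), a population that shifted from ~18% to ~80% year-round
residency within 25 years. Three mechanisms could produce such a shift,
and each leaves a different statistical fingerprint:

* **phenotypic flexibility** — individual adults switching strategy between
  years: measurable as low within-individual repeatability of the wintering
  latitude;
* **developmental plasticity** — juveniles abandoning migration before
  maturity while adults stay fixed: a declining migration probability with
  age together with near-perfect adult repeatability;
* **microevolution** — selection on standing variation: selective-sweep
  signatures in the genomes of resident birds and allele-frequency
  differentiation between migrants and residents.

The package implements the full computational chain for all three
fingerprints, plus a synthetic-data layer so every stage is testable
without any external download. It is a library first (`import ciconia`),
with narrative scripts in `examples/` and a thin `ciconia` command line for
pipeline runs.

## What is computed

**Genome scan** (`ciconia.popstats`, `ciconia.sweepscan`) — on tables of
derived-allele counts *x* out of *n* chromosomes in non-overlapping
windows:

* per-site diversity π̂ = Σ 2x(n−x)/(n(n−1)) / L, Watterson's θ̂_W = S/a₁/L,
  Tajima's D with the 1989 normalization, Fay & Wu's H = π − θ_H with
  θ_H = Σ 2x²/(n(n−1));
* a SweepFinder-style composite likelihood ratio: under the sweep model a
  lineage at distance d escapes with probability p_e = 1 − e^(−αd), and
  Λ = 2[max_{α,c} ℓ_sweep − ℓ_background], maximized over a geometric α
  grid and test positions in each window;
* Hudson's F_ST between groups as a windowed ratio of averages;
* the DCMS composite: each statistic is converted to a one-sided empirical
  p-value by fractional ranking (p = 1 − rank/(m+1)), and
  DCMS_t = Σ_i ln((1−p_it)/p_it) / Σ_j |r_ij| with Spearman correlations
  r_ij estimated across windows;
* top-1% outlier calling (⌈qm⌉ windows), adjacent-window merging, and the
  exact hypergeometric test for overlap between outlier sets.

**Movement** (`ciconia.movement`) — wintering latitude as the October
minimum per bird-year; migrant/resident classification at the Strait of
Gibraltar (36°N); repeatability R = σ²_between/(σ²_between+σ²_within) from
a one-way Gaussian random-intercept model (REML, bootstrap SE,
likelihood-ratio p); and a random-intercept logistic GLMM of strategy on
age fit by adaptive Gauss–Hermite quadrature.

**Census** (`ciconia.census`) — resident proportion W/(2B) from wintering
individuals W and breeding pairs B, fold changes, and OLS extrapolation of
breeding pairs (the year→x encoding must be given explicitly).

**Synthetic data** (`ciconia.synthgen`) — neutral allele counts with the
1/i spectrum, sweep-distorted counts under the escape model, hypergeometric
two-group splits of one panmictic pool, GPS cohorts with the age schedule
0.98/0.67/0.33/0.19 and a 2.7%/yr adult flip rate, and linear census
series. Everything is bit-reproducible under a fixed seed.

## Worked example

```sh
python examples/census_residency.py
```

```
first census : 1187 winterers / (2 x 3302 pairs)   -> 18.0% resident
last census  : 19295 winterers / (2 x 11691 pairs) -> 82.5% resident
wintering population increase: 16.26-fold
```

The resident share is the wintering count over twice the breeding-pair
count; the two census anchors bracket the 25-year rise of residency while
the wintering population grew 16-fold.

```sh
python examples/movement_ontogeny.py
```

```
migrant fraction by age class
  age 1 : 0.96
  age 2 : 0.67
  age 3 : 0.33
  adult : 0.18

age GLMM slope (logit/yr): -1.46 +- 0.09  (random-intercept SD 0.42, n = 900)
adult repeatability    : R = 0.948 (SE 0.005, p = 0)
juvenile repeatability : R = 0.000 (SE 0.028, p = 1)
adult strategy switches: 15 of 600 transitions
```

Migration probability collapses across the immature years (negative GLMM
slope) while adults are almost perfectly repeatable — the developmental
plasticity fingerprint. `examples/sweep_scan.py` runs the genomic side:
it plants two sweeps among 20 neutral windows and the DCMS top set
recovers exactly those windows.

A full pipeline run (genomes → scan → overlap, tracks → movement, census)
with one seed and one YAML config:

```sh
ciconia run-all --seed 7 --out runs/demo
```

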