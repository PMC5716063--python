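# Methods

This note records the statistical model the package implements, the
defaults and numerical conventions it adopts, what the synthetic-data
generator does and does not emulate, and the design choices made where
the survey protocol leaves room.

## Survey structure and the sample unit

An SPC survey site is one dive at one location: a pair of divers count
and size fish in adjacent 15-m diameter cylinders centred on the quarter
points (7.5 m, 22.5 m) of a 30-m transect. The two cylinders are
surveyed simultaneously over the same patch of reef, so they are treated
as non-independent: all metrics are averaged within the SPC pair first
and then across pairs (a few sites carry two pairs), and the **site** is
the base sample unit for estimation. When pairs have unequal replicate
counts the two-stage mean is still applied, weighting each pair equally;
for balanced pairs it coincides with the grand mean of the replicates.

## From observations to densities

Each record is one diver's count of one taxon at one size in one
cylinder. Individual weight is `W = a (c L)^b` grams, with the length
conversion `c` applied to the recorded total length *before*
exponentiation, because the constants of some species are referenced to
fork or standard length. Recorded sizes ("to the nearest cm") are used
as-is with no mid-bin correction; a size above the species' maximum
length is converted but flagged with a warning rather than rejected.
Densities divide per-species sums by the cylinder plan area π(7.5)² m²;
the diameter is the protocol's stated quantity, the area a derived
constant, and both are configurable through `CylinderGeometry`.

Observation types gate which rows enter densities. The routine density
filter pools I and N; F and T (species first seen 5–10 and 10–30 min
into the survey) integrate over longer exposure windows and are excluded
by default; P (present near the cylinder) is presence-only and is
rejected outright by the density path. F/T rows, when explicitly
included, are area-normalized the same way — users should treat such
densities as upper-bound relative indices, which is why the default
excludes them.

## Validation semantics

The protocol states rules; enforcement severity is this package's own
split. Error severity (record excluded from analysis sets): invalid
observation-type/enumeration codes, counts < 1, non-positive sizes,
depth outside (0, 30] m, cylinder centre shallower than 1.5 m,
visibility below the 7.5-m survey floor (strict: 7.5 m itself is valid)
or above the 30-m cap, benthic-cover or substrate-height vectors not
summing to 100 ± 0.5, F/T types before 2012. Warning severity
(informational): a recorded depth-bin label disagreeing with the depth
classifier, and habitat codes outside the published enumeration.
Pre-2012 fields (substrate heights, urchin DACOR) and pre-2013 current
strength are nullable and never imputed.

Two enumerations carry deliberate conventions:

- **Depth bins** are printed with shared endpoints (0–6, 6–18, 18–30 m);
  the classifier is lower-closed/upper-open with the deepest bin closed
  at 30 m, making it a total monotone step function on (0, 30].
- **DACOR bands** as printed leave one count unassigned in each scale
  (5 for free urchins, 25 for boring urchins); both gaps are closed
  toward the rarer class (R ≤ 5, R ≤ 25), configurable via explicit
  bounds.

The schema accepts COMPLEXITY scores 1–6 (the column's own description),
even though part of the protocol text describes a five-point scale; the
wider range is accepted so no historical record is rejected.

## Stratified estimation

Within stratum *i*, `X̄_i` is the mean of site values and
`VAR_i = s²_i / n_i` with the unbiased (n−1) sample variance — simple
random sampling within stratum, no finite-population correction, the
conservative convention for sparse marine surveys where sampled sites
are a tiny fraction of stratum area. Pooling to the reporting unit uses
hard-bottom-area weights `w_i = A_i / Σ A_j` over the *sampled* strata:
unsampled strata are dropped and weights renormalized, so the estimate
covers the sampled domain only. `X = Σ X̄_i w_i`,
`VAR = Σ VAR_i w_i²`.

Single-site strata contribute their mean but have no variance estimate;
by default their `VAR_i` is imputed as the mean `VAR_i` of the unit's
other strata and the stratum is flagged in the output
(`single_site="strict"` drops the term instead). If no stratum has two
sites the variance is declared unestimable rather than silently zero.
Sectors are handled as reporting-unit subdivisions with their own
strata; pooling sectors to island scale reuses the same two equations
with sector-area weights. Depth-zone pooling for sparsely replicated
backreef/lagoon zones is available (`pool_depth_zones`) but off by
default, since whether the original workflow pooled before or after
weighting is not stated.

Allocation is Neyman-style: demand `A_h · s_h` per stratum,
largest-remainder rounding to the target total, ties broken toward the
larger area and then the lexicographically smaller stratum key so plans
are deterministic.

## Observer QC

Diver performance is the per-site difference between a diver's estimate
and their partner's, computed only for pairs with exactly two
replicates; each pair contributes antisymmetric rows for both divers, so
deltas over any closed set of pairs sum to zero. The protocol inspects
boxplots; the formal bias flag here — an exact two-sided sign test on
the delta signs with zeros dropped, level 0.05 by default — is this
package's addition, chosen because it is distribution-free and exact at
the small per-diver sample sizes a cruise produces (and conservative, so
unbiased divers are flagged at no more than the nominal rate). Size
calibration reports mean error ± SE per diver against models of known
length; the identification test passes only strictly above 90%.

## Structural complexity

Height-bin vectors are reduced to a mean substrate height via bin
midpoints {0.10, 0.35, 0.75, 1.25, 1.75} m; the open top bin (">1.5 m")
has no printed upper edge and 1.75 m assumes an effective 1.5–2 m span
(configurable). The bridge between the pre-2012 ordinal score and the
height encoding is an ordinary least-squares line fitted to externally
supplied co-scored pairs — none are shipped — exposed in both
directions because the published conversion's direction is unstated.

## The synthetic generator

The generator emulates the design hierarchy (reporting unit → stratum →
site → SPC pair → diver replicate → species observation) with analytic
ground truth:

- Per species, a base mean count (log-uniform in 0.5–8 per cylinder) and
  a per-stratum multiplier give the expected abundance `μ`; site-level
  variation is Gamma with dispersion k = 4 (negative-binomial style),
  and the latent site intensity is **shared by the pair's two divers**,
  which is what makes paired-difference QC meaningful.
- Each diver's count is Poisson(Λ·m) with mean-one multiplicative
  observer error m = exp(σz − σ²/2), σ = 0.15 by default, so counts
  stay unbiased.
- Lengths come from a per-species lognormal (median 8–30 cm, σ_log
  0.25) discretized to whole cm and truncated at lmax, so E[W] is an
  exact finite sum; diver size error is additive Gaussian (σ = 1 cm),
  rounded and clipped to [1, lmax].
- Every (diver, species) encounter draws one observation type from the
  configured five-way distribution (I 0.85, N 0.05, F 0.04, T 0.03,
  P 0.03); P encounters are recorded as a single fish at the median
  length. Truth under the I+N filter is therefore
  `(p_I + p_N) Σ_s μ_s E[W_s] / area` exactly.
- Benthic covers and substrate heights are Dirichlet draws around fixed
  means; depths are uniform within the stratum's bin (never above the
  1.5-m centre floor).

The default unit is Saipan-like — backreef and lagoon (shallow) plus a
forereef split across the three depth bins, 35 sites — matching the
routine 30–50 sites per reef area. `species_seed` fixes the simulated
population across replicate surveys so Monte Carlo calibration studies
hold the truth constant. In `noiseless` mode counts equal the rounded
means, each species has one fixed length, all types are I, and covers
sit at their means: the end-to-end pipeline then reproduces truth to
machine precision and the two divers record identical cylinders.

What the generator does **not** emulate: spatial autocorrelation among
sites, fish behavioural responses to divers (attraction/avoidance),
species detectability differences, within-cylinder size–abundance
correlation, and cryptic/nocturnal under-sampling. Passing calibration
tests therefore demonstrates that the estimators are correct for the
declared design, not that real surveys are free of those field biases.

Known small-sample effects worth noting: symmetric size error inflates
`E[(L+ε)^b]` by roughly `b(b−1)σ²/2L²` (≲1% at the default settings),
and using z = 1.96 with ~38 effective degrees of freedom costs about
half a coverage point; both are visible in, and absorbed by, the Monte
Carlo calibration bands below.

## Problem sizes and calibration checks

The test suite verifies, among others: exact truth recovery of the
noiseless pipeline (|error| < 1e-9); pooled-mean census equivalence
under proportional weights (1e-9); and a 1,000-replicate Monte Carlo of
a two-stratum unit with 20 sites per stratum in which the pooled mean's
relative bias stays below 2%, the nominal 95% interval covers truth
within 0.95 ± 0.02, and the mean estimated variance tracks the empirical
variance within 15%. `scripts/acceptance.py` re-runs the same chain at
500 Monte Carlo replicates, which keeps the full run around a minute on
one CPU while leaving the bias and coverage estimates' own Monte Carlo
error well inside those bands.
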