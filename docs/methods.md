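# Methods

`stpscan` implements a retrospective space-time permutation scan
statistic together with a cluster-injection simulation framework for
studying how spatial aggregation of case coordinates (exact address vs
ZIP-like vs county-like centroids) affects outbreak detection. This note
records the models, the parameter choices and their rationale, the
numerical decisions, and what the synthetic study does and does not
establish about real surveillance data.

## The scan statistic

Case records are cross-tabulated into counts `n_st` over distinct
locations `s` and months `t` (`N` cases total, location marginal `n_s`,
month marginal `n_t`). Candidate clusters are **cylinders**: a circular
base, grown around each data location by adding other locations in order
of Euclidean distance, crossed with a month interval. The base stops
growing when the included case mass would exceed `max_spatial_fraction ·
N` (default 50%; the singleton is always admitted), and intervals run
over every start and length up to `max_temporal_fraction` of the study
period (default 50%, i.e. 1–24 of 48 months).

Under the permutation null — case months exchangeable with respect to
locations — the expected count of a cylinder factorizes from the
marginals:

    mu = (1/N) · Σ_{s in circle} n_s · Σ_{t in interval} n_t

and each cylinder is scored by the Poisson generalized likelihood ratio
in log space,

    log GLR = c log(c/mu) + (N − c) log((N − c)/(N − mu))   if c > mu,
              0                                             otherwise.

Inference is by Monte Carlo: each of `S` replicates permutes the month
labels of the `N` cases against their locations — the exact null of the
permutation model, preserving both marginals — and records the maximum
log GLR over the *same* cylinder set. The observed maximum has rank
p-value `p = R/(S+1)` with `R = 1 + #{replicate maxima ≥ observed}`;
replicate ties count toward `R` (conservative). With the defaults
(α = 0.05 and `S` chosen so that `α(S+1)` is an integer: 999, 199 or
19), the test is exact at level α.

Reported clusters are extracted best-evidence-first: cylinders sorted by
log GLR (ties broken toward smaller radius, shorter interval, lower
center id, earlier start — a fixed deterministic order) are kept
greedily if their closed disk does not overlap any previously kept disk
(distance between centers ≤ sum of radii; coincident zero-radius
singletons also overlap). Each kept cluster's p-value is computed
against the distribution of replicate *maxima* (conservative for
secondary clusters); clusters with `p ≤ α` are reported, plus the
primary regardless of significance, flagged. A reported cluster carries
the relative-risk estimate `c/mu`.

Assumptions worth stating: geometry is planar Euclidean (coordinates in
km — appropriate for a state-sized region, avoiding geodesy); time is
pre-aggregated to months; the model detects space-time *interaction*
only — purely spatial or purely seasonal structure is adjusted away by
the marginals, so a persistent geographic hot spot is invisible by
design.

## Synthetic at-risk population

The real study population (geocoded administrative claims) is
proprietary, so the package generates a stand-in with the features the
design needs: spatial heterogeneity, seasonality, and two nested-scale
areal-unit systems.

* **Region**: a 700 × 180 km rectangle (Tennessee-like extent and
  aspect). All coordinates are planar km.
* **Pool**: 122,500 candidate background cases, drawn from a mixture of
  `n_blobs = 6` isotropic Gaussian "cities" holding `blob_weight = 65%`
  of the mass (centers uniform over the interior, σ drawn uniformly from
  4–18 km, blob masses proportional to 1/rank as a crude heavy-tailed
  city-size law) plus a uniform rural background with the remaining 35%.
  Gaussian draws falling outside the rectangle are resampled.
* **Months**: 48 (four years). Each point's month is drawn from a
  seasonal multinomial with weight `1 + A·cos(2π((m mod 12) − peak)/12)`,
  amplitude `A = 0.5` peaking in January — a winter-respiratory-
  infection profile.
* **Areal units**: 617 ZIP-like and 95 county-like units. Seeds are
  placed on the point cloud by k-means++ (so unit density tracks
  population density, as administrative units do) and every point joins
  its nearest seed (Voronoi cells); the unit centroid is the mean of its
  member points. Empty units are reseeded once, then dropped with a
  warning. The two levels are built independently — they need not nest,
  as real ZIP/county boundaries need not.

The pool doubles as the at-risk population: the inside-cluster share `C`
is computed against it and control cases are sampled from it, which
makes the null exactly exchangeable.

## Cluster injection

Each simulated dataset holds exactly 1000 records. One artificial
cluster is drawn per dataset: a square with inscribed-circle radius
`r ~ U(1.6, 48)` km (side `2r`), placed uniformly among positions that
keep the square inside the region; an integer relative risk
`RR ~ U{1..10}`; and a 3-month onset window uniform over feasible
starts. With `C` the share of the pool inside the square, the excess
inside-probability is

    p = C (RR − 1) / (1 − C),  clamped to 1;  p = 0 when RR = 1,

chosen so that the expected inside-square count, `N_t + C·N_c =
1000·C·RR`, is `RR` times the no-excess expectation — i.e. the scan's
observed/expected ratio inside the square is unbiased for the injected
RR. This is verified empirically by a generative-oracle test (realized
risk within 5% of RR over hundreds of simulations) rather than assumed.
Where `C > 1/RR` the formula clamps (the target RR is unattainable with
1000 cases); the clamp is logged and such datasets become nearly
all-treatment.

`N_t ~ Binomial(1000, p)` treatment cases are placed uniformly on the
square with months uniform over the window, and assigned ZIP/county ids
by the same nearest-seed rule as the pool (so later aggregation is a
pure lookup). `N_c = 1000 − N_t` controls are drawn from the pool
without replacement, keeping true coordinates and unit assignments but
re-drawing months i.i.d. from the pool's month distribution — removing
any space-time interaction while preserving both purely spatial and
purely temporal structure.

## Aggregation and metrics

Aggregation replaces each record's coordinates with its areal-unit
centroid; months, flags and ids are untouched, so counts per
(unit, month) are preserved exactly and the operation is idempotent. The
ground-truth cluster is never aggregated. Matched triplets (the same
records at three resolutions) make spatial resolution the only varying
factor.

Per (resolution × RR × size-bin) group — size bins small 0–16 km,
intermediate 16–32 km, large 32–48 km by inscribed radius —
four metrics are computed over the significant clusters (p ≤ 0.05):

* **power** — share of datasets with any significant cluster;
* **PSP** — power with spatial precision: some significant cluster's
  circle contains the true center (distance from detected center ≤
  detected radius; a radius-0 singleton only succeeds if exactly at the
  center). PSP ≤ power by construction;
* **sensitivity** — share of treatment cases captured by significant
  clusters, where capture means membership in a cluster's cylinder
  (location set AND month interval; a `space_only` switch is provided
  for sensitivity analysis);
* **PPV** — share of captured cases that are treatment cases.

Sensitivity and PPV pool numerators and denominators across a group's
datasets (sum/sum), avoiding undefined per-dataset ratios; a
`mean_of_ratios` estimator is available because either convention is
defensible. Union semantics: a case inside two reported cylinders counts
once.

## Numerical and performance choices (all exact)

The scan kernels are numba-compiled. Counts are integers bounded by
`N`, so every logarithm comes from integer-indexed tables (`i log i`,
`log i`, `log(N² − ns·nt) − log N`), removing transcendentals from the
inner loop; `c > mu` is tested in integer arithmetic. Because month
permutation preserves both marginals, every cylinder's expectation is
constant across replicates; unit-level datasets therefore precompute
per-cylinder thresholds and log-expectations once per dataset and stream
them sequentially (single-precision for the logs, with 5·10⁻³ safety
margins on all pruning bounds so the prunes stay conservative). An
evidence floor (log GLR ≥ 1) discards hopeless cylinders via a
minimum-count table; if a pass maximum or collect threshold ever falls
below the floor the pass automatically reruns unpruned, so results are
exact in every case. Address-level data (every location holding one
case) uses a variant whose per-cylinder tables depend only on (circle
size, interval) and fit in cache. Replicate passes stop early once their
running maximum exceeds the observed maximum — beyond that point only
the order relation matters. Tests verify kernel-vs-kernel agreement and
equivalence with an independent brute-force enumeration oracle.

Cluster extraction materializes only cylinders that could still be
significant (log GLR at least the 10th-largest replicate maximum at
S = 199), which provably reproduces the greedy-over-all-cylinders
result for the reported set.

Seeds: every stage draws from named children of a master seed
(`numpy.random.SeedSequence`), so datasets are reproducible individually
and independent of execution order; reruns are bit-identical.

## Study profiles and problem sizes

The experiment pipeline's desk profile (300 datasets, 199 replications)
reproduces the design's qualitative behavior in minutes on one CPU;
`ExperimentConfig.full_scale()` switches to the full design of 10,000
datasets per resolution with 999 replications. The test suite runs further
scaled-down versions (dozens to low hundreds of datasets, S = 199 or 19)
with statistical bands recomputed for the scaled sample sizes; S is
always chosen so that α(S+1) is an integer, keeping the test exact at
α = 0.05 at any scale. The acceptance script uses 300 null datasets and
15 datasets per RR per size bin at S = 199.

## What the synthetic study does and does not show

The generator reproduces the design's *structure* — heterogeneous
population, seasonal months, random square clusters with controlled RR,
matched aggregation levels — and the package's validated claims are of
two kinds: exactness properties (null calibration at 5%, marginal
preservation, oracle equivalence, realized-RR recovery) and directional
aggregation effects (detected radii grow, observation-level sensitivity
rises and PPV falls as coordinates coarsen, at small-to-intermediate
cluster sizes).

Quantitative levels, by contrast, depend strongly on how concentrated
the at-risk population is, and the blob-mixture stand-in is visibly
*less* dispersed than real geocoded claims data: a randomly placed small
square here typically captures ~10⁻³ of the pool, so even moderate RR
values inject enough cases to be detected, giving higher small-cluster
power and much higher observation-level PPV than a real claims
population (where a random rural square captures an order of magnitude
less of the at-risk mass, detections of small clusters are rare, and the
detections that do occur are diluted by chance clusters of background
cases). Absolute power ceilings and PPV levels from this simulation
should therefore not be read as estimates for any real population;
the calibration and directional results should transfer.

Other known limitations: square clusters only, fixed 3-month windows,
one cluster per dataset, monthly time resolution, no covariate
adjustment, and the permutation model only (no Poisson/Bernoulli
population-at-risk models). Prospective/surveillance-mode analysis is
out of scope.
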