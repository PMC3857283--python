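# Methods

## Model

The package estimates animal density from camera-trap capture histories
with a Bayesian spatially explicit capture–recapture (SECR) model under
data augmentation. The observed `n` individuals are embedded in a
super-population of fixed size `M = n + naug` (default `naug = 375`, the
augmentation used in the study design this package emulates). Each member
`i` has

* an inclusion indicator `z_i ~ Bernoulli(ψ)` — whether the animal is part
  of the population occupying the state space during the survey;
* a latent activity centre `s_i`, uniform over the *suitable* points of
  the discretised state space.

Given inclusion, captures are independent Bernoulli trials per trap `j`
and occasion `k` with

    p_ijk = 1 − exp(−λ_ijk),
    λ_ijk = λ0 · exp(−d_ij²/(2σ²)) · exp(b1 · C_ijk),

a half-normal encounter-rate function of the centre-to-trap distance
`d_ij` (km). `C_ijk` is the deterministic prior-capture indicator (1 once
`i` has been caught in trap `j` on an earlier occasion), so `b1` is a
*trap-specific* behavioural response on the log-rate scale ("model Mb"):
`b1 > 0` means an animal returns preferentially to a trap site where it
was already photographed. Realised abundance is `Ns = Σ z_i`; density is
`D = Ns / A_suitable × 100` per 100 km², recomputed at every retained
iteration.

A note on conventions: some software reports the half-normal scale via the
decay coefficient `b` of `λ0·exp(−b·d²)`. The conventional relation is
`σ = sqrt(1/(2b))`, which this package uses; an alternative printed form
`σ = sqrt(1/b²)` circulates in some outputs and a conversion helper for
both is provided (`sigma_to_b`, `b_to_sigma`, `sigma_from_printed_b`).
Relatedly, the per-occasion *post*-initial-encounter probability implied by
the log-link at distance zero is `1 − exp(−λ0·e^{b1})` (≈ 0.083 at
λ0 = 0.029, b1 = 1.10); post-encounter probabilities quoted much higher
than this by other software (e.g. 0.649) are not reproducible under any
standard link evaluated at the centre and are not a quantity this package
defines.

## State space

The state space is the rectangle bounding the trap array extended by a
buffer `B` on every side, meshed at regular spacing (defaults: `B` =
20 km, spacing 1 km; configurable, with 2 km used throughout the tests for
speed). The grid is anchored at `(xmin−B, ymin−B)` with inclusive
endpoints — point counts depend on anchoring, so this is fixed and
documented. Buffers differing by a multiple of the spacing produce nested
grids. Habitat masks (shapely geometries or per-point flags) remove
candidate activity centres and shrink the suitable area; traps are never
removed. Working units are km in a planar (projected) coordinate system;
metre inputs are converted on read.

**Choosing the augmentation.** Data augmentation imposes a hard ceiling
`D ≤ M / A_suitable × 100`. The ceiling must sit far above any plausible
posterior mass, otherwise the posterior is truncated and the density
estimate is silently pulled down — and because the ceiling falls as the
buffer (hence area) grows at fixed `M`, an inadequate augmentation
masquerades as a density decline with buffer width. The buffer- and
mask-sensitivity tests therefore use a larger augmentation (800) than the
default 375; the parameter-recovery runs keep 375 to match the emulated
study configuration.

## Priors and sampler

Priors (vague, proper; configurable): `log λ0, log σ ~ Normal(0, 10²)`,
`b1 ~ Normal(0, 10²)`, `ψ ~ Beta(1, 1)`. One sweep updates, in fixed
order:

1. `z` for never-captured members by its exact Bernoulli full conditional
   (captured animals have `z = 1` with probability one);
2. `ψ` by its conjugate `Beta(1 + Σz, 1 + M − Σz)`;
3. every activity centre: excluded members are redrawn uniformly (their
   full conditional); included members move by Metropolis with a mixture
   proposal — uniform over the 8 neighbouring mesh cells, plus a 10%
   long-range jump uniform over all suitable points so chains can cross
   masked regions;
4. `(log λ0, log σ, b1)` by single-site random-walk Metropolis.

Proposal SDs are adapted every 200 iterations toward 20–40% acceptance
during burn-in only, then frozen, preserving the correct stationary
distribution. The sampler works from sufficient statistics (per
individual × trap counts of hits and misses before and after first
capture), so iteration cost is independent of the number of occasions.
Defaults follow the emulated study profile: 100,000 iterations, 20,000
burn-in, thinning 1. Initial values: centres of captured animals at the
mesh-snapped centroid of their capture locations, λ0 = 0.05, σ = half the
mean nearest-neighbour trap spacing, b1 = 0, ψ = 0.5; a non-finite
starting likelihood widens σ and warns.

Correctness was verified two independent ways: with detection parameters
pinned, the sampler's posterior mean of `Ns` matches exhaustive
enumeration over `(z, centres)` with `ψ` integrated analytically (the
`posterior_ns_bruteforce` oracle); with parameters free, posterior means
of `(λ0, σ, b1)` on a tiny instance match a 3-D grid quadrature of the
marginalised posterior to three decimals.

## Diagnostics

*Geweke z*: compares the mean of the first 10% of a chain against the last
50%, with window-mean variances from batch means (`⌈√n⌉` batches) as a
simple spectral-density-at-zero estimate. |z| > 1.6 is flagged as
non-convergence. A chain whose windows are internally constant but at
different levels returns ±∞ (divergent); z = 0 with a warning is reserved
for a genuinely constant chain.

*Bayesian p-value*: for each retained latent snapshot, the Freeman–Tukey
discrepancy `T = Σ(√obs − √exp)²` is computed on individual × trap
encounter frequencies for (a) the observed data and (b) a replicate
simulated from the same parameters and centres, each against expected
counts under its own realised prior-capture indicator; `p = Pr(T_rep ≥
T_obs)`, ties counting in favour of fit. Values near 0 or 1 indicate
misfit. The exact discrepancy used by legacy SECR software is not
documented, so this choice is recorded here and kept pluggable; in
simulation it is well calibrated under the true model and collapses to
p ≈ 0 under strong unmodelled trap-level rate heterogeneity
(log-normal trap effects with SD 2).

## Synthetic data

The generator emulates the montane leopard survey the package was built
around: 13 paired camera stations (a pair = one trap) over ~31 km², every
nearest-neighbour distance in [1.7, 3.5] km, a sliding 9 km² window always
holding ≥ 2 stations, 63 nightly occasions (819 trap nights). Station
layouts come from a flattened triangular lattice (rows of 4–5 stations,
row gap 0.6 × pitch) scaled to the target area, jittered, and
rejection-sampled against the design rules. Generating truth defaults to
the emulated study's fitted posterior means — density 10.73 per 100 km²,
λ0 = 0.029, σ = 1.69 km, b1 = 1.10 — so simulate-then-fit round trips
double as parameter recovery at the study's own operating point.
Population size is Poisson(D/100 × area) by default (a fixed-N option
exists for low-variance unit tests); centres are uniform over suitable
mesh points of the *full buffered state space*, so edge effects are
present exactly as the estimator assumes. Capture histories are simulated
sequentially over occasions so the behavioural indicator updates after
each first capture; each capture event emits two flank photographs, as a
paired station would record. A Poisson photo-stream generator (per
species × station, with optional within-hour bursts) feeds the
relative-abundance module.

What the generator does **not** emulate: sex- or age-dependent detection
(the model has no covariates), misidentification, camera failures
(effort masks are supported but default to fully active), non-uniform
density surfaces, and temporal non-closure. Passing recovery tests
therefore show the estimator works when its assumptions hold at the
study's sample sizes — not that those assumptions hold in any real survey.

## Relative abundance indices

A photograph is an *independent event* if the previous photo at the same
station was a different species, or the previous same-species photo is
more than the independence window (default 1 h) older. The window is
timed against the previous *photograph* (not the previous independent
event); both conventions are implemented and the choice is configurable.
Filtering is per station, since non-independence is about one animal
lingering at one camera. Capture frequency is independent events per 100
camera days (station-nights); the RAI is the whole-day count from survey
start to a species' first photo (0 = first day; never-detected species
return an explicit not-detected value, not a number).

## Numerical and scale choices

* Log-probabilities use `log(−expm1(−λ))`; `log(1−p)` is exactly `−λ`.
  Rate underflow at extreme distance yields −∞ log-probabilities that are
  handled without NaNs (a zero count contributes zero, not 0 × ∞).
* HPD intervals are the shortest contiguous interval containing
  `⌈prob·N⌉` sorted draws.
* Tests and the acceptance script run the pipeline at a reduced profile —
  2 km mesh, 10,000–25,000 iterations — chosen so the whole suite stays in
  the minutes range while posterior means are stable to well under the
  tolerances being checked; the paper-scale profile (1 km mesh, 100,000
  iterations) is the CLI default.
* Single-survey posterior means scatter substantially across simulated
  data draws at this design's sample size (n ≈ 9–25 observed): SDs of
  roughly 2.1 (D), 0.25 (σ) and 0.39 (b1) per draw. The acceptance script
  therefore averages over 16 replicate surveys; posterior-mean σ and b1
  retain a small upward bias under the vague priors at these sample
  sizes, which is a property of the estimand, not a sampler defect.
* All randomness flows from explicit seeds; generators are pure functions
  of (inputs, seed), and `buffer_sensitivity` derives one deterministic
  seed per cell.

## Known limitations

* No sex/age covariates on detection or movement (heterogeneous capture
  probabilities bias density, as the emulated study itself discusses).
* Activity centres live on the discrete mesh; a very coarse mesh relative
  to σ discretises the detection function visibly (a warning fires when
  spacing exceeds twice the buffer, and 1–2 km spacing at σ ≈ 1.7 km is
  the tested regime).
* The data-augmentation ceiling requires the user to check `M` against
  the plausible density range (see above); the fitted ψ sitting near 1 is
  the tell-tale symptom.
* Closure is assumed within the survey window; the RAI is an index, not a
  density estimate.
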