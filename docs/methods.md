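# Methods

## The model

`ordmisfit` fits a Bayesian threshold ("liability") animal model to an
ordinal trait that may have been recorded with error.  Each record `i` has
an unobserved Gaussian liability

    l_i = x_i' beta + z_i' u + e_i,        e_i ~ N(0, 1)

and a true ordinal class `r_i = j` iff `t_{j-1} < l_i <= t_j`, with
thresholds `t = (-inf, t_0, ..., t_{C-2}, +inf)`.  Identifiability of the
augmented model is fixed by `t_0 = 0` and `var(e_i) = 1`; neither is a
parameter anywhere in the sampler state.  The breeding values follow the
animal model `u ~ N(0, A sigma_u2)` with `A` the pedigree numerator
relationship matrix; its sparse inverse is assembled directly by
Henderson's rules with inbreeding coefficients from the Meuwissen–Luo
recursion, so `A^{-1} A = I` holds exactly for arbitrary (including
inbred) pedigrees.  Priors: independent bounded uniforms on the
fixed-effect levels, a scaled inverse chi-squared `(nu, s2)` on
`sigma_u2`, and Dirichlet rows on the misclassification matrix.

### The misclassification layer

The recorded class `y_i` may differ from the true class `r_i`.  A
misclassification matrix `pi` with `pi[j, k] = P(recorded k | true j)`
(rows are simplices) links the two, and a per-record switching indicator
`alpha_i` carries the putative true class.  Its full conditional is
multinomial over candidate true classes `j` with weights

    w_j  ∝  pi[j, y_i] * theta_ij,     theta_ij = Phi(t_j - eta_i) - Phi(t_{j-1} - eta_i),

and the rows of `pi` are conjugately updated, `pi_j. ~ Dirichlet(tau_j. +
gamma_j.)`, where `gamma[j, k]` counts records currently assigned true
class `j` while recorded as `k`.

A note on parameterization, because it is the one place where the design
was genuinely open and the choice is load-bearing.  One could instead
treat each *observed* class's origin vector `(pi_0k, ..., pi_(C-1)k)` as
the simplex.  That reading breaks the generative structure: the implied
per-record likelihood `sum_j pi_jk theta_ij` then no longer sums to 1 over
`k` (the row sums are unconstrained), and a chain can inflate the joint
density without bound by routing every record through a single true class.
In development this manifested as a reproducible collapse — within tens of
iterations the top class emptied, the free threshold drifted to its
fallback bound, and the "origin" probabilities converged to the observed
class frequencies — on clean data.  With the generative row convention the
model is a coherent probability model for `y` (`r ~ theta`, `y | r ~ pi`
row), the no-switch diagonal count enters each row's Dirichlet normalizer
(which makes the update self-stabilizing), and the estimated `pi[j, k]` is
directly comparable to the simulation's true miscoding rates.

### Prior on the misclassification rows

Default `tau` puts 90 on the diagonal and 5 split over the `C-1` miscoding
directions per row (prior mean 94.7% "recorded correctly", total weight 95
pseudo-records per true class), scaled by a single `prior_weight`;
`default_tau(flat=True)` gives Dirichlet(1,...,1).  Misclassification
rates in latent-class models of this kind are weakly identified without
informative no-switch mass, so a flat prior is available but not the
default.

## Gibbs sampler

One compiled (numba) kernel executes the per-iteration scan in fixed
order: (1) switching indicators and true classes, tallying `gamma`; (2)
liabilities from truncated normals on the class intervals (half-open
`(t_{j-1}, t_j]`, matching the simulator's discretisation); (3)
fixed-effect levels, single-site; (4) breeding values, single-site with
`A^{-1}/sigma_u2` in the precision; (5) `sigma_u2` from
`(u'A^{-1}u + nu s2) / chi2_{q+nu}`; (6) each free threshold uniformly
between the bracketing liability order statistics (an empty class falls
back to the neighbouring threshold, or `t_upper = 6.0` at the top); (7)
the `pi` rows.  Truncated-normal draws use inverse-CDF sampling with a
double-precision rational approximation of `Phi^{-1}` and clamping at
extreme truncation, so the scan cannot produce a liability outside its
class interval.

Numerical/bookkeeping choices:

* classical mode (no layer) pins `r = y`; known-P mode fixes the `pi`
  rows and still samples the indicators;
* `misclass_warmup` (default `min(1000, burnin/2)`) keeps the layer inert
  at the start of the chain so location parameters adapt before switching
  begins — defence against early-chain transients reassigning records
  while the scale is still mislocated;
* per-record miscoding probabilities are the fraction of *retained*
  (post burn-in, thinned) sweeps in which `alpha_i` differs from
  no-switch; burn-in sweeps are not draws from the posterior and are
  excluded;
* posterior means of `u` are accumulated online (no `q x draws` storage);
  `sigma_u2` and `t_1` chains are retained in full;
* default chain: 20,000 sweeps, burn-in half, thinning 10; default
  hyperparameters `beta` bounds ±1e6, `nu = 4`, `s2 = 0.05` (prior mean
  of `sigma_u2` ~ 0.1, weak at any realistic pedigree size).

The compiled kernel is validated two ways: every conditional has a plain
NumPy/SciPy reference implementation unit-tested against closed forms, and
a Geweke-style successive-conditional test cycles the kernel itself
(1-sweep warm-started calls) against the generative model on a 20-record
pedigree, checking that the prior marginals of `sigma_u2`, the fixed
effects, and the `pi` rows are preserved.

## Synthetic data

The simulator draws: a discrete-generation random-mating pedigree
(founders 10% by default, sires/dams sampled from the previous
generation); breeding values by Mendelian sampling down the pedigree
(exactly `u ~ N(0, A sigma_u2)`, including inbreeding corrections);
per-level systematic effects from the design's normal distributions;
liabilities with `sigma_e2 = 1`; classes by thresholds `(0, 1)`; and
optional miscoding by a generative matrix (symmetric 2.5% per direction,
or the asymmetric set `pi12, pi21, pi23, pi32, pi13, pi31 = 1, 3, 1.5, 1,
0.1, 0.1 %`).  All sub-draws come from named substreams of one master
seed; a replicate is byte-reproducible.  Replicates with an extreme-case
problem (a systematic-effect level whose records all share one observed
class) are regenerated with a seed offset, up to 100 attempts.

Two named designs emulate a calving-ease-style genetic evaluation setting: `d1`
(pedigree 10,000, 8,939–9,042 phenotyped, effects with 20/10/5 levels)
and `d2` (pedigree 1,563, 1,393–1,425 phenotyped, 5/5/5 levels), both
with `sigma_u2 = 0.1` and heritability 0.1/1.1 ≈ 0.091.  The second
parameter of each effect's normal is interpreted as a **variance** by
default (`effect_param="sd"` switches the reading); phenotypes attach to
the latest pedigree members; levels are assigned uniformly at random.

**Intercept calibration.**  The stated effect distributions alone put the
mean liability at −0.7, i.e. ~75% of records in the bottom class — not
the balanced three-class regime the emulated study describes (incidences
≈ 0.39/0.38/0.23).  The named designs therefore add a fixed liability
intercept solving `Phi((0 − m)/sd_l) = p_0` for the design's bottom-class
rate (0.39 for `d1`, 0.36 for `d2`), computable in closed form because a
record's marginal liability is normal.  One scalar cannot match all three
incidences — the printed triple implies a total liability SD below 1,
impossible with `sigma_e2 = 1` — so the middle/top split lands at roughly
0.29/0.32 rather than 0.38/0.23.  This is the main known gap between the
generator and the study it emulates, and it matters: class balance
controls both how much miscoding attenuates the genetic variance and how
sharply miscoded records are detected.  Quantities that depend on it
(attenuation depth under the classical model, per-record detection
probabilities) should be compared across configurations with that caveat
in mind.

What the generator does *not* emulate: selection or non-random mating,
overlapping generations, structured (non-uniform) level assignment,
covariate-dependent miscoding, genomic relationships.  Passing tests show
the estimator recovers the parameters of *this* generative process; real
ordinal data can violate it in all of the above ways.

## Study replication and reported scales

`replicate_study` runs simulate → fit → summarise over replicates for any
subset of the five analysis models (M1 true/classical, M2 noisy/classical,
M3 noisy/known-P, M4 noisy/estimated-P, M5 true/estimated-P) and reports
the mean over replicates of per-replicate posterior summaries.  EBV
accuracy is the Pearson correlation between posterior-mean and true
breeding values over **all** pedigree animals (a flag restricts to
phenotyped ones).  HPD intervals are the shortest contiguous window
holding `ceil(0.95 n)` sorted draws (ties to the first window);
percentiles interpolate linearly between order statistics.

The package's own reproduction runs (`scripts/acceptance.py`, and the
heavier tests) use a subsampled large design — pedigree 4,500, ~4,060
phenotyped records (scale 0.45) — and the full small design, with 5–6
replicates of 20,000-sweep chains (50% burn-in, thinning 10).  These sizes
keep a full study loop in minutes while leaving the posterior means of
`sigma_u2` replicate-stable; the full-size design remains available
through `d1_config()`.

## Known limitations

* Single-site location updates mix slowly on large, deep pedigrees;
  blocked updates would be the natural optimisation.
* No automated convergence diagnostics (trace output only), no multi-chain
  orchestration, no residual-variance estimation (fixed at 1 by design).
* The intercept-calibration gap above: the generator matches the emulated
  study's bottom-class rate exactly and its remaining class split only
  approximately, so headline quantities tied to class balance are
  reproduced in direction and order, not always in magnitude.
* With `C = 3` there is one free threshold; the code paths generalise to
  `C > 3` but the study designs and tests exercise `C = 3`.
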