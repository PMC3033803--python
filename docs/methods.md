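# Methods

## The problem

During meiotic prophase I, paired homologous chromosomes (bivalents)
exchange segments at crossovers (COs).  Crossovers interfere: a CO
suppresses further COs nearby, and in most species a second, non-interfering
pathway contributes a minority of COs.  Given either (a) continuous CO
positions observed on bivalents (immunostained foci, late recombination
nodules) or (b) marker segregation data from backcross / doubled-haploid
gametes, `xofit` estimates the interference strength and the proportion *p*
of COs from the non-interfering pathway, with confidence intervals and
diagnostic histograms.

## Coordinate convention

All fitting happens in genetic space on the gamete Morgan scale: 1 Morgan =
1 expected CO per gamete = 2 expected COs per bivalent.  The bivalent CO
intensity is therefore pinned at exactly 2 per Morgan; it is a unit
convention, not a parameter, and the total intensity is preserved by every
model (interference redistributes COs, it does not destroy them).
Positions are 0-based, intervals half-open `[a, b)`.

Physical-unit CO positions are converted by the pooled empirical CDF:
`L = (mean CO count per bivalent) / 2` Morgans and `x -> L * C(x)`, where
`C` is the pooled CDF binned into 50 equal physical bins with linear
interpolation inside bins (deterministic and resolution-controlled; the
pooled CO density in the output is uniform by construction).  For
segregation data without a map, interval lengths are the observed
recombination fractions (map-function-free; fractions >= 0.5 are capped at
0.4999 with a warning).  This direct-`r` estimate slightly shrinks long
intervals relative to their true Morgan length; with the dense maps used
here the effect is far below the sampling noise.

## Gamma and gamma-sprinkling models

The interfering pathway P1 is a stationary renewal process whose
inter-arrival distances are Gamma(shape `nu`, rate `2*nu*(1-p)`): mean gap
`1/(2(1-p))`, intensity `2(1-p)` per Morgan.  `nu = 1` is no interference
(Poisson); larger `nu` gives more regular spacing.  The non-interfering
pathway P2 is homogeneous Poisson with intensity `2p`, superposed
("sprinkled") on P1.  Chromosome ends carry the stationary (equilibrium)
boundary condition -- the process conceptually extends beyond the observed
segment -- and there is no obligate-CO constraint.  The admissible fitting
box is `nu` in [0.1, 50], `p` in [0, 1]; at `p = 1` the gamma pathway is
degenerate and all quantities reduce to the pure Poisson branch.

Key closed forms (F = gamma inter-arrival CDF):

* equilibrium first-point density: `f_e(x) = 2(1-p) (1 - F(x))`;
* integrated survival `int_0^x (1-F)`, exactly
  `x(1-F(x)) + (nu/rate) F_[nu+1](x)`;
* single-interval gap probability `Z_P1([0,l]) = 1 - 2(1-p) int_0^l (1-F)`;
* the sum of k gamma gaps is Gamma(`k*nu`, same rate), so the CO-count
  distribution on `[0, L]` needs only 1-D integrals of `f_e` against gamma
  CDFs (Gauss-Legendre, 400 nodes -- accurate to ~1e-9, verified against
  the Poisson collapse and the intensity identity mean = 2L).

## Likelihoods

**Bivalents.**  The density of k observed CO positions sums over all 2^k
assignments of COs to P1/P2.  Because only consecutive P1 members couple
(renewal structure), the sum collapses to an O(k^2) dynamic program over
the sorted positions; the P1-empty assignment contributes the window gap
probability.  Exactness was verified against brute-force enumeration.

**Gametes.**  Each bivalent CO enters a gamete independently with
probability 1/2 (no chromatid interference).  Conditional on interval
occupancy, the recombination parity of a marker interval is exactly 1/2
when the interval contains at least one bivalent CO, and 0 otherwise,
giving

    P(r) = 2^-M sum_{B subset} (-1)^{|B intersect R|} Z(B),

with `Z(B) = Z_P1(B) exp(-2p|B|)` the probability that no CO falls in the
union of intervals B.  Missing genotype calls are handled by merging
intervals per gamete (no imputation); regions before the first and after
the last informative marker are marginalized by stationarity.

Multi-interval `Z_P1` has no closed form; it is computed by a forward
filter over the position of the next P1 renewal, discretized by product
integration: cell-to-cell transfer masses are exact gamma-CDF differences
and the state is piecewise constant (midpoint rule).  This scheme is O(h^2)
in the cell width, is exact for the exponential case, and remains stable
for `nu < 1` where the gamma density diverges at zero.  Two linear
operators act on the state -- free propagation (a discrete Volterra
renewal recursion) and empty propagation (forbid renewals) -- and the
signed two-branch operator

    O_j = 1/2 T_free + (1{r_j=0} - 1/2) e^{-2p g_j} T_empty

evaluates P(r) in time linear in the number of intervals.  The
inclusion-exclusion route composes the same operators subset by subset, so
the two algorithms agree to floating-point precision by linearity; their
common value is checked against simulated gamete pattern frequencies
(independent route) in the test suite.

Default grid: span/2000 cells for standalone pattern probabilities;
dataset-level fitting uses span/500 (quadrature error ~1e-6 on pattern
probabilities, orders of magnitude below the statistical error of any
dataset fitted here).  Dataset likelihoods batch all unique gamete
patterns into a prefix trie on one global grid, so each hill-climbing step
costs one set of transfer-matrix builds regardless of the number of
distinct patterns.

## Beam-film model

The mechanical alternative: precursor sites (Poisson(`n_precursors`)
uniform on [0,1]) carry critical thresholds uniform on (0,1); global
stress rises quasi-statically to `s_max`, always cracking the precursor
needing the least stress under the relief field
`sigma_eff(x) = sigma * max(0, 1 - sum_cracks exp(-|x - x_c|/d))`.
Each crack is a CO; `d` is the interference distance.  `d -> 0` recovers a
Poisson thinning of the precursors; `d` much larger than the chromosome
allows at most one crack; intermediate `d` suppresses close pairs and
shrinks the count variance.  Sprinkling adds Poisson(`2pL`) uniform COs as
in the gamma family.  `s_max` is not fitted: it is calibrated by bisection
(common random numbers across iterations, 2e4 cells per evaluation,
tolerance 0.02 on the mean) so the mean P1 count matches the observed
mean; the reachable means saturate when interference caps the crack count,
and an unreachable target is an error.  Chromosome ends are unclamped and
no obligate CO is enforced.  This is a minimal, seedable variant of
beam-film mechanics exposing exactly one interference parameter; it is not
the full ceramic-film elasticity treatment, and `d` is not numerically
interchangeable with the parameters of other beam-film implementations.
Defaults: `n_precursors = 10` per bivalent (a few-fold excess over the
typical 2-4 COs, so calibration has headroom).

## Histograms and the projected-likelihood score

Three summaries: CO count per chromosome (k = 0..15), CO positions (10
bins) and inter-CO distances within records (20 bins over [0, L]).  For
gametes, "positions" are midpoints of recombinant merged intervals.
Observed histograms carry 95% Clopper-Pearson intervals per bin.

The beam-film model has no tractable likelihood, so fits maximize a
projected-likelihood score: the multinomial log-likelihood of the observed
count and distance bins under bin frequencies estimated from a simulated
population (default 1e6 meioses; 1e5 in the scaled studies below),
with empty simulated bins floored at `eps = 1/(2 n_sim)`.  The two
components enter as an unweighted sum (a "score type" setting exposes
counts-only or distances-only).  The observed proportions maximize the
score (Gibbs inequality), and each parameter evaluation reuses one master
seed (common random numbers) so the surface seen by the optimizer is
smooth.  The score is also available for the gamma family, where it agrees
with maximum likelihood to within the statistical resolution of the data.

## Search and confidence intervals

Grid scan evaluates every node of the (interference, p) grid and keeps the
full surface (halving the steps quadruples the cost).  Hill climbing
evaluates the 8 neighbours at the current step sizes, moves to the best
strictly improving one (ties break on a fixed neighbour order), halves
both steps when stuck, and stops when both steps drop below the precision
thresholds (defaults 0.01 for `nu`/`d`, 0.005 for `p`).  Evaluations are
cached, deterministic given the seed, and budget-limited (default 1e4).
On the smooth single-peaked surfaces these models produce, scan and hill
agree to within one grid step; both are exposed because the scan is immune
to multimodality.

Fisher intervals: numerical Hessian of the log-likelihood at the optimum
(central differences, step `max(1e-3 |theta|, 1e-4)`); 95% Wald intervals
from the inverse observed information.  An estimate on a box bound (e.g.
`p_hat = 0`) gets one-sided differences and a flagged one-sided interval;
a non-positive-definite information matrix yields a flagged result with no
interval rather than a fabricated one.  Resimulation intervals: `n_boot`
(default 100) datasets simulated at the estimate with the observed design
(same record count, marker map and missing pattern), each refitted by
warm-started hill climbing; the 2.5/97.5 percentiles of the refits are the
interval.  Refit failures are recorded; more than 10% is an error.

## Synthetic data

The generator produces exactly what the models assume: stationary gamma
renewal bivalents (equilibrium first point by inverse CDF on a 4000-point
grid, then i.i.d. gamma gaps; Poisson sprinkling), binomial(1/2) thinning
to gametes, and genotyping by parity against a marker map with
independent missing calls.  Presets emulate a mouse-like backcross panel
(200 gametes x 20 chromosomes, 10 markers each, 2% missing), a wheat-like
single-chromosome doubled-haploid set (180 gametes, 20 markers over 1.5 M)
and a maize-like nodule set (300 bivalents, positions emitted in
synaptonemal-complex micrometers through a smooth monotone distortion).
What the generator does **not** emulate: genotyping error, segregation
distortion, obligate COs, chromosome-specific precursor maps, or
chromatid interference.  Passing tests therefore demonstrate correctness
of the inference machinery under the stated model assumptions, not
robustness to violations of them.

## Study conditions used in tests and the acceptance script

* Parameter recovery: truth `nu = 5.6`, `p = 0.18` (a strong-interference,
  two-pathway regime typical of plant and cytological fits), 2000 gametes,
  11 equally spaced markers over 1.5 Morgans, 5% missing calls; ML fits
  from a cold start (2.0, 0.1) in the box nu in [0.5, 20], p in [0, 0.8].
  Tolerances +-1.5 on nu and +-0.08 on p (median over 10 seeds) reflect the
  information loss from thinning at this sample size.
* Single-pathway bias: the same fits with p forced to 0; the refitted nu
  falls at or below the two-pathway value in >= 9/10 seeds.
* Scan vs hill (score objective, 1e5 simulated meioses per evaluation,
  common random numbers): one 1000-bivalent dataset; optima agree within
  one grid step (0.5 on nu, 0.05 on p).
* Beam-film limits: 1e5 cells; `d -> 0` and `p = 1` pass chi-square
  goodness of fit against Poisson at alpha = 0.01; the fraction of inter-CO
  gaps below 0.05 L drops strictly from the Poisson limit to `d = 0.2`.
* Resimulation coverage (scaled down for desk-scale runtime): 50 replicate
  datasets of 1000 bivalents at (5.0, 0.2), `n_boot = 50`; the nu interval
  covers the truth in >= 80% of replicates (nominal 95%, generous slack for
  the reduced bootstrap size).

## Numerical choices and degenerate inputs

* All tolerances and grid defaults live in `xofit.defaults`.
* Pattern probabilities are floored at 1e-300 inside log-likelihoods to
  guard against quadrature round-off on impossible patterns.
* Zero-length map intervals (no observed recombinant) are dropped from the
  likelihood when their parity is 0 and make the likelihood -inf when 1.
* A position exactly at the declared chromosome length is accepted and
  clamped; empty rows are legitimate 0-CO cells.
* Count-distribution tails beyond `kmax` above 1e-6 raise rather than
  silently truncate.

## Known limitations

* Tetrad data, F2/heterozygote designs and chromatid-interference models
  are out of scope; gametes must come from backcross/DH-type designs.
* The transfer-operator quadrature degrades gracefully but measurably for
  `nu < 1` combined with very coarse grids; the defaults keep the error
  below 1e-6 on the tested maps.
* Score-based fitting inherits Monte-Carlo noise of order `1/sqrt(n_sim)`;
  with common random numbers this biases no direction but can shift the
  optimum by a fraction of a grid step.
* The beam-film `d` is defined in relative chromosome units; comparing `d`
  across chromosomes of different genetic lengths requires rescaling.
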