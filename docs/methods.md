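# Methods

## The cline model

A locus's spatial allele-frequency profile is modeled as a scaled curve
`p(x) = p_L + (p_R - p_L) s(x)` on the 1-D transect coordinate `x` (km),
where `s` is an ascending sigmoid with optional exponential tails:

- center region: `s0(x) = 1 / (1 + exp(-4 (x - c) / w))`, so the slope at
  the center `c` is exactly `1/w`;
- left of the junction `x_L = c - z_L`:
  `s(x) = s0(x_L) exp(theta_L * lambda_L * (x - x_L))` with
  `lambda_L = (4/w) / (1 + exp(-4 z_L / w))`, the sigmoid's log-slope at
  the junction; symmetrically on the right with
  `1 - s` decaying at rate `theta_R * lambda_R`.

This is the Szymura–Barton "stepped cline" family as used by Porter's
ClineFit: continuous everywhere by construction, and continuously
differentiable at a junction exactly when that side's `theta = 1`
(`theta < 1` produces a kink, the tail being `theta` times shallower than
the sigmoid). Descending clines are represented by `p_L > p_R` acting on
the ascending curve — one canonical internal form.

One point of this family deserves emphasis: an exponential tail with
`theta = 1` and `z = 0` matches the sigmoid's value and slope at the
(central) junction but is not globally identical to it. We define that
configuration as the *unmodified* sigmoid, so the two-parameter model is
exactly nested in the eight-parameter one at `(theta, z) = (1, 0)`, and
the pure-sigmoid model can also be requested explicitly through per-side
tail-disable flags rather than magic parameter values. The literature is
not unanimous on the tail exponent (some variants use the square root of
`theta`); the adopted algebra is isolated in `clinekit.model.scaled_cline`
so it can be swapped without touching fitting or comparison code.

`z` is interpreted as the distance from the center to the tail
*junction*; nothing vertical-asymptote-like is encoded.

## Likelihood and fitting

Populations are independent binomial samples: `k_i` copies of the focal
R allele out of `n_i` sampled copies, with success probability
`p(x_i)` clamped to `[1e-9, 1 - 1e-9]` so boundary asymptotic
frequencies keep the log-likelihood finite. Binomial coefficients are
included (true log-probabilities). Genotype data are converted to allele
counts under Hardy–Weinberg; no within-population inbreeding (F_IS) term
is modeled, a deliberate divergence from ClineFit's options.

Maximum likelihood uses bounded L-BFGS-B from `n_starts` starts (default
20): one data-driven heuristic (center at the midpoint-frequency
crossing, width = span/4) plus seeded Latin-hypercube draws over the
box: `c` in `[min x - span, max x + span]`, `w` in `[0.01, 10 span]`,
`z` in `[0, span]`, `theta` in `[1e-3, 1]`, `p` in `[0, 1]`, with
`span` the extent of populations with `n > 0` (so adding an empty
population changes nothing). Everything is a pure function of
(data, spec, n_starts, seed). The original ClineFit program explores the
same model by Metropolis sampling with unrecoverable "default settings";
equivalence is promised with the model, not with that sampler's numbers.

Support limits follow the 2-log-likelihood drop convention (analogous to
a 95% CI): the profile log-likelihood — re-optimizing the other free
parameters, warm-started from the MLE — is marched geometrically from
the MLE toward each bound and the crossing bracketed by Brent's method
(profile tolerance ~1e-3 lnL units). A side that never drops by 2 before
the search bound is reported at the bound with an `unbounded` flag.

The nested 8-vs-2-parameter LRT refers `D = max(0, 2 dlnL)` to
chi-square with 6 df (D clipped at 0 against optimizer noise). Note the
chi-square reference is conservative here: under the reduced model four
of the six extra parameters (`theta` at 1, `z` at 0) lie on the boundary
of the parameter space, so the true null distribution is a chi-bar-square
mixture stochastically well below chi-square(6). Monte-Carlo calibration
in the test suite shows null rejection rates below the nominal level —
reported significance for this test errs on the safe side.

## Cross-locus shape comparison

For the ordered pair (i, j), the data at marker i are re-scored with the
six shape parameters pinned to marker j's ML estimates while keeping
marker i's own `p_L`, `p_R` — only shape differs between the free and
constrained model, hence 6 df. The constrained model is *evaluated*, not
re-optimized (re-optimizing the two nuisance frequencies is available
behind a flag for sensitivity analysis). D is asymmetric by design and
the matrix is never symmetrized. Family-wise error is Bonferroni
controlled over the `m (m - 1)` ordered pairs — for ten markers, 90
tests, per-test alpha 0.05/90 ≈ 0.00056 and critical deviance 23.85; the
divisor is configurable for the unordered convention. Flower-color data,
coded as genotypes (red = RR, red-orange/orange = RY, yellow = YY), enter
as an ordinary marker.

## Supporting statistics

**F_ST.** Between-ecotype differentiation per locus uses Weir &
Cockerham's theta with the two ecotypes as subpopulations (populations
pooled within ecotype), from the a/b/c variance components with observed
heterozygosity. Components are computed in exact rational arithmetic
over the integer allele and heterozygote counts, so fixed differences
yield theta = 1.0 exactly with no floating-point cancellation. This
replaces an AMOVA-based estimate; numerical agreement with AMOVA
implementations is expected only in the fixed-difference case.

**Map distance.** F2 recombinants are counted as recombinant *gametes*
(a recombinant individual carries one; rare double recombinants carry
two), giving `r = n_rec / 2N`. The default "direct" function (100 r) is
supplemented by Haldane and Kosambi, both requiring `r < 0.5`.

**Exact tests.** 2xK contingency tables (K = 2..4) are tested by
conditional multivariate-hypergeometric enumeration with the two-sided
point-probability rule (for 2x2 this is the standard two-sided Fisher
exact test, cross-checked against scipy and R). Tables whose conditional
support exceeds 1e6 outcomes fall back to seeded Monte-Carlo with the
add-one estimator. A zero margin returns p = 1 with a degeneracy flag.

**Geography.** Localities are projected to the transect as the shortest
distance to a coastline polyline, computed with shapely on a local
equirectangular plane centered at the query point (mean Earth radius
6371.0088 km). The planar approximation is accurate to well under 0.5%
at the ~100 km extent of a typical study region (about 1% at several
hundred km, the bound used by the property tests). A longitude-only
fallback coordinate is provided, and precomputed distances can bypass
the module entirely.

## Synthetic data

The simulators generate exactly what the likelihood assumes, so passing
tests certify the estimation machinery, not robustness to
misspecification: transect datasets are independent binomial draws from
a true cline (no spatial autocorrelation, drift, or linkage between
loci); ecotype panels are Hardy–Weinberg at each group's frequency; F2
gametes recombine independently with probability r. Default study
conditions mirror the emulated design: 30 populations spanning four
cline widths around the center (x in [34, 66] km for c = 50, w = 8), 80
allele copies per population (~40 diploids), ecotype panels of 267 and
107 diploids, and a 359-individual F2 cross. Real transects add
overdispersion, uneven sampling, and spatially correlated drift that
these generators deliberately omit.

## Problem sizes and numerical choices

The suite and the acceptance script use the sizes above; the two
simulation-heavy checks are 50 transects for support-interval coverage
and 200 same-cline pairs (200 alleles/population, the "large n" regime
where the chi-square reference is meaningful) for null calibration of
the cross-locus test, run with 6-8 optimizer starts per fit — enough
that multi-start scatter contributes negligibly next to sampling noise.
Other constants: frequency clamp 1e-9; D clipped at 0; grid-search
oracles at 0.05 km resolution; profile bracketing tolerance 1e-3 lnL.

## Known limitations

- No mechanistic interpretation of `w` (no selection or dispersal
  estimation), no MCMC posterior, no F_IS, no linkage during fitting.
- The cross-locus D statistic compares an estimated shape, not a known
  one; its null distribution is only approximately chi-square(6) and the
  nested 8-vs-2 test is conservative (boundary parameters).
- Only biallelic loci; hierarchical AMOVA variance components are out of
  scope.
- The coastline actually used for a given study is a user input; results
  that depend on its digitization are not certified by the tests.
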