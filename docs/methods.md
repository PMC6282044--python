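# Methods

## Model

The prior over inter-onset intervals (IOIs) is a K-component Gaussian
mixture over *durations* in milliseconds,

    G(d) = Σₖ φₖ · N(d; μₖ, σₖ),   σₖ = s·μₖ,   φₖ = 1/K,

with strictly increasing means μ₁ < … < μ_K.  An n-event rhythm contributes
n−1 i.i.d. interval draws; adjacent ratios rᵢ = dᵢ₊₁/dᵢ are derived
quantities.  Perceptual attribution is Bayesian: p(z=k|d) ∝ φₖ N(d; μₖ, σₖ),
computed in log space, with MAP labels (1-based, ties to the lower index).

The mixture is defined over durations rather than ratios: every concrete
number in the model's worked arithmetic (100 ms, 200 ms, the 200–1,000 ms
bounds) is a duration, and ratio categories follow as ratios of adjacent
duration-category means.  A ratio-space mixture is a legitimate alternative
formulation; this package exposes `ratios_of` for ratio-space analyses but
does not implement ratio-space attribution.

### Overlap algebra

Adjacent categories meet at a boundary x* written two ways,
x* = μₖ(1 + s·c_u) = μₖ₊₁(1 − s·c_l), giving

    rₖ = (1 + s·c_u)/(1 − s·c_l),            (ratio formula)

well defined only for c_l < 1/s — this feasibility condition is *enforced*
(raised as `FeasibilityError`) in every consumer of an overlap, never
clamped.  Demanding equal component densities at x* gives

    c_u² − c_l² = 2·ln(rₖ).                  (intersection identity)

Since the right side is strictly positive for an increasing system, c_u
can never equal c_l; the package exposes both parameters and interprets
neither psychophysically.  `joint_solve_overlap` solves both constraints
simultaneously: substituting the ratio formula into the identity yields the
quadratic (r²−1)c_l² − (2r(r−1)/s)c_l + (r−1)²/s² − 2 ln r = 0; roots
outside (0, 1/s) or with non-positive implied c_u are rejected, and if two
roots qualify the smaller c_l (better-separated categories) is returned.
At s = 0.025 and r = 2 the feasible root is c_l = 13.3160, c_u = 13.3679;
the second algebraic root sits just above 1/s = 40 and is discarded.

Category systems are built by the recursion μₖ₊₁ = rₖ·μₖ from μ₁, stopping
when the next mean would exceed mu_max; K is therefore the largest count of
categories with all means within bound.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| s | Weber fraction (CV of timing) | — | 0.025 | empirical sub-second estimate |
| mu_min | smallest admissible category mean | ms | 200 | lower bound of categorical timing range |
| mu_max | largest admissible category mean | ms | 1000 | sub-second ceiling on category means |
| μ₁ | first category mean | ms | 200 | the stated lower bound; the 100 ms worked example is honored by overriding mu_min |
| s_perception, s_motor | per-stage chain noise | — | 0.025 each | timing noise is scalar; the split between stages is unspecified, so both default to the one published value |
| seed_low, seed_high | chain generation-0 uniform range | ms | 100, 1000 | the random starting material of iterated-reproduction experiments |
| max_int | largest p, q in "small" fractions | — | 4 | named target ratios (2/1, 3/2, 2/3) fit comfortably below it |
| ratio tolerance | relative deviation counting as "small" | — | 0.05 | the equal-tempered fifth (0.11% from 3/2) sits far inside; 23/51 (≈10% from 1/2) far outside |

`ScalarTimingParams.s` is not consulted by `build_category_system`, which
takes the Weber fraction as an explicit argument and uses the params object
only for the admissible mean range — one source of truth per quantity.

## Estimation

`fit_scalar_mixture` is EM with the scalar tie enforced at every M-step.
E-step: responsibilities from the current (μ, s, φ).  M-step: each μₖ is the
*exact* maximizer of its tied objective — the stationarity condition of
Σᵢ wᵢₖ[−ln μ − (xᵢ−μ)²/(2s²μ²)] reduces to the quadratic
Nₖs²μ² + S1ₖμ − S2ₖ = 0 (S1ₖ = Σwᵢₖxᵢ, S2ₖ = Σwᵢₖxᵢ²), whose unique
positive root is closed-form; then s² is the responsibility-weighted mean
of (xᵢ−μₖ)²/μₖ².  Both coordinate updates are exact maximizations, so the
log-likelihood is non-decreasing every iteration (asserted in tests, and
cross-checked against a 2-parameter grid search at K = 1).  Initialization
is k-means++ on a fixed seed (deterministic given data and seed); means are
reported sorted ascending to resolve label switching; weights are fixed at
1/K by default with a `free_weights` option for probing that assumption.
Convergence: log-likelihood gain < 1e-8.  Components starved of
responsibility (< 1e-12 total) keep their previous mean; s is floored at
1e-6 to avoid a degenerate spike.  Systems produced by the fitter set
mu_max to max(1000, largest fitted mean) so that fits to arbitrary data
(e.g. uniform stress data spanning the full 100–1,000 ms range) do not
violate the ordering/bound invariants of `CategorySystem`.

`select_K` fits K = 1..K_max and chooses by BIC with K+1 free parameters
(K means + s; +K−1 if weights are free).

## Chain simulation

Generation 0 is uniform on (seed_low, seed_high).  Each later generation:
(i) *perceive* — every interval is corrupted by Gaussian noise with SD
s_perception·d and MAP-categorized under the fixed prior; (ii) *reproduce* —
every label k is realized as a draw from N(μₖ, s_motor·μₖ).  Reproduction
samples from the category Gaussian; regressing to the posterior mean is the
documented alternative and would only sharpen convergence.  Non-positive
Gaussian draws are redrawn rather than truncated-renormalized — at
s = 0.025 such draws sit ~40 SDs out, so the bias is nil; the choice only
matters in large-s stress tests.  All randomness in a chain flows through
one generator seeded by `rng_seed`, so identical configs give bit-identical
records.

Because the observer's prior is fixed, convergence of the interval
distribution to the prior's modes is *expected by construction* — standard
iterated-learning behavior.  The simulator demonstrates the proposed
mechanism (scalar noise + categorical attribution turning a uniform seed
into integer-ratio multimodality); it does not discover it.  Two empirical
signatures follow and are tested: the Wasserstein distance to a large prior
sample drops sharply after generation 0 and then plateaus — the plateau
reflects the seed generation's category frequencies, which MAP + faithful
reproduction preserve rather than re-equalize toward 1/K — and label
entropy stays flat (within boundary-noise fluctuation of ±0.05 bits)
rather than growing, since near-perfect label preservation cannot create
category structure.

Mode detection fits tied-variance mixtures for K = 1..max_modes and selects
by BIC — respecting the scalar constraint instead of free kernel-density
peaks, and deterministic for given data.  The public default requires 50
intervals for a meaningful fit; the chain simulator passes a lower floor
(8) so that short per-generation sequences (32 intervals in the default
convergence analysis) can still be classified, at the cost of noisier mode
estimates.  K is additionally capped at n/10 points per component.  A
generation counts as converged to the ratio-2 prior when its BIC-selected
mode count equals the prior's K and every adjacent mode ratio is within 5%
of 2.

`nearest_small_integer_ratio` is an exhaustive enumeration over fractions
p/q in lowest terms with p, q ≤ max_int, minimizing relative deviation,
ties to smaller p+q.  It is the classification primitive everywhere a ratio
is judged "small".

## Synthetic data

The fixture panels emulate archetypal interval distributions: uniform
100–1,000 ms (B); 3 random centroids with SDs independent of means (C,
SDs uniform on 5–80 ms — the "no further assumptions" panel has no canonical
recipe, so this choice is illustrative only); the same centroids with
scalar SDs (D); and the 200/400/800 ms scalar system (E).  Default fixture
size is n = 1,000.  What the generator deliberately omits: sequential
structure (intervals are i.i.d., no meter, no autocorrelation), motor drift,
participant heterogeneity in s, and any across-generation learning of the
prior itself.  Passing tests therefore show that the algebra, estimator and
simulator behave as designed under the model's own assumptions — not that
human drumming data satisfy those assumptions.

## Numerical choices and problem sizes

- Posterior and density computations in log space (`logsumexp`), so
  attributions survive durations tens of SDs from every category.
- The joint overlap solve is closed-form (quadratic), validated in tests
  against an independent scan-and-bisect oracle over (0, 1/s).
- CSV interval values are written with 9 decimal places: round trips are
  lossless to 1e-9 ms.
- Convergence analyses use 20 seeded replicates of 8-generation chains
  with 32 intervals per generation, and recovery analyses use n = 5,000
  intervals — sizes at which every statistic in the test suite is stable
  while the whole suite stays fast.
- Exploration tables serialize list-valued cells (means, ratios,
  deviations) as `;`-joined `repr` floats, so rebuilding a system from a
  row reproduces its ratios exactly.

## Known limitations

- No supra-second intervals, no Weber-law breakdown at extremes, no
  per-category s.
- Overlap parameters are model-implied only; nothing estimates c's directly
  from behavioral misattribution data.
- The chain models one observer with one fixed prior; multi-participant
  chains and prior drift are out of scope.
- Whether ~8–13 SD overlaps (the values ratio-1.5 and ratio-2 boundaries
  require at s = 0.025) are psychophysically plausible is an open question;
  the package reports the values and judges nothing.
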