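# Methods

This note records the statistical conventions behind `causaltrio`: the
generative model, each inference procedure's exact construction, the
numerical choices, and what the simulation benchmark can and cannot
establish.

## Generative model

Each replicate is a triplet (G, X, Y) of one SNP genotype and two
continuous traits on n individuals, drawn from one of twelve
linear-Gaussian structural scenarios (module `simulate`, table
`EQUATIONS`).  Conventions:

* **Genotype.** G is the minor-allele count, G ~ Binomial(2, maf), i.e.
  Hardy–Weinberg equilibrium; maf defaults to 0.1, so the expected
  genotype split at n = 1000 is roughly 810/180/10.  G enters every
  structural equation numerically (additive coding); there are no
  dominance terms.
* **Traits.** X and Y are generated in the topological order implied by
  the scenario's arrows, each as a Gaussian with mean
  μ + Σ (effect × parent) and a scenario-specific noise SD.  All noise
  terms are independent given parents.
* **Confounder.** Scenarios (h)–(l) first draw a latent E ~ N(0, σE²)
  that feeds both traits with effect ζ.  E is stored on the dataset for
  diagnostics only; the accessors the methods use (`triplet()`,
  `to_frame()`, `as_array()`) expose exactly (g, x, y).  This is the
  point of those scenarios: the confounder is *unmeasured*.
* **Defaults.** All effect sizes (α, β, γ, δ, ζ) default to 1 (trait
  units per unit of parent), trait means to 10, all SDs to 0.3, n to
  1000.  With these values the genotype explains a large share of trait
  variance (e.g. corr(G, X) ≈ 0.82 under mediation) — a deliberately
  easy regime in which a method's failures are structural, not
  power-related.  Effect-size sweeps (`run_sweep`) probe the hard
  regimes.
* **Randomness.** A single integer base seed; replicate r of scenario s
  draws from `SeedSequence((base_seed, index(s), r, stream))`, stream 0
  for data and stream 1 for method-internal randomness (the CIT's
  permutations).  Runs are bit-for-bit reproducible and replicates are
  independent substreams, so the scheme survives parallelisation.
* **Degenerate replicates.** Monomorphic-G replicates are kept, not
  regenerated (at maf = 0.1, n = 1000 they essentially never occur, but
  user data may contain them): MR and the CIT return flagged
  non-detections; the selection methods raise `DegenerateDataError`,
  which the benchmark counts in `failure_rate`.

**What the generator does not emulate:** linkage disequilibrium or
multiple variants, non-Gaussian or heteroskedastic noise, dominance,
case–control outcomes, selection/ascertainment, measurement error. A
green benchmark therefore certifies behaviour under clean linear-Gaussian
triplets only.

## Mendelian randomisation (`mr`)

Single-instrument two-stage least squares, which for one instrument is
algebraically the Wald ratio cov(G,Y)/cov(G,X) (an exact identity the
test suite checks to 10 significant digits).  The standard error is the
textbook homoskedastic 2SLS one — residuals y − â − β̂x use the
*observed* exposure, the denominator is the fitted-exposure sum of
squares — and the p-value is a two-sided normal approximation.  The
estimator family (ratio / 2SLS / LIML) is asymptotically equivalent
here; 2SLS was fixed as the conventional choice.  Detection means
p < 0.05 (configurable).  A numerically zero instrument–exposure
covariance yields a flagged weak-instrument result rather than an
exception, counted as a non-detection.

Note the deliberate behaviour under pleiotropy (scenario (a)): the Wald
ratio converges to β/α with a shrinking standard error, so MR
confidently "detects" an X→Y effect that does not exist.  That is the
exclusion-restriction violation the benchmark is designed to exhibit.

## Causal inference test (`cit`)

An intersection–union test of complete mediation G → X → Y.  Components:

1. p₁ — F test of G in Y ~ G;
2. p₂ — partial F of G in X ~ Y + G;
3. p₃ — partial F of X in Y ~ G + X;
4. p₄ — permutation *equivalence* test of Y ⟂ G | X.

The omnibus p is the maximum; all four conditions must hold jointly, so
the test is conservative under the global null (each component is
stochastically ≥ uniform under its own null).

**Construction of p₄.** The observed statistic is the partial F for G in
Y ~ X + G, which is small exactly when X absorbs G's effect on Y.  The
reference distribution must represent "no mediation": we fit X ~ G, keep
each individual's fitted G-component, and permute the residuals across
individuals.  The permuted X\* retains its association with G (and G its
marginal effect on Y) but loses any X–Y link beyond the G-channel;
recomputing the partial F for G in Y ~ X\* + G gives the null draws, and

    p4 = (1 + #{b : F*_b ≤ F_obs}) / (B + 1)

(add-one estimator, so p₄ ∈ [1/(B+1), 1] and never exactly 0).  Small p₄
means the observed residual G effect sits far below the no-mediation
reference.  An earlier variant that permuted X wholesale was discarded:
its reference is so extreme at the default effect sizes that a residual
direct effect (scenario (d)) or a confounder-borne X–Y link (scenario
(i)) also looks "equivalent to zero", i.e. the test would claim complete
mediation precisely where it should not.  With the residual scheme the
suite verifies near-certain detection under (b) and non-detection as the
typical outcome under (i) — the behaviour expected of a mediation test
that is robust to pleiotropy and reverse causation.  At the default
effect sizes p₄ saturates at its floor under both (b) and (d); the
monotonicity property (mean p₄ larger under (d) than (b)) is therefore
tested at n = 200, where the statistic is informative.

Genotype coding is additive by default (matching the generative model);
a 2-df factor coding is available (`coding="factor"`).  B defaults to
1000 permutations, seeded from the replicate's substream.

## SEM path-model selection (`sem`)

Only five of the twelve structures are testable (one spare degree of
freedom): a (G→X, G→Y), b (G→X→Y), c (G→Y→X), f (G→X, Y→X), g (G→Y,
X→Y).  Each is a recursive linear-Gaussian path model with uncorrelated
errors, for which per-equation least squares is the exact ML fit — the
suite confirms equality with a generic numeric optimiser to 1e-6.
Conventions, chosen so that a correctly specified model's average BIC
sits near 1 − ln n:

* S is the unbiased (n−1) sample covariance of (G, X, Y); means are
  saturated (covariance-only fit);
* F_ML = ln|Σ(θ̂)| − ln|S| + tr(S Σ(θ̂)⁻¹) − 3, χ² = (n−1)·F_ML,
  df = 1 (six distinct second moments, five free parameters);
* BIC = χ² − df·ln n, lower better; selection is argmin, ties (BICs
  within 1e-6) are flagged but not broken — they are measure-zero on
  continuous data.

G's variance is a free parameter in every model.  Under scenarios (k)
and (l) no testable model is correct; the benchmark reports the
selected-model distribution and marks `correct_rate` not-applicable.
A quirk worth knowing: at the default effect sizes, data from scenario
(d) satisfies model (c)'s single constraint *exactly* in population
(cov(G,X|Y) = αβ·var(G)·(β² var(G)+σY²)⁻¹… works out to 0 when
α = β = γ), so SEM systematically reads (d) as (c) and, symmetrically,
(e) as (b): the genotype correlates more strongly with the downstream
trait than with the mediator, which the reversed chain fits cheaply.

## Bayes-factor partitions (`buf`)

Each trait is classed U (unassociated with G), D (directly associated)
or I (indirectly associated — only through the other trait), giving nine
partitions; (D,D), (D,I), (I,D), (D,U), (U,D) coincide with models a, b,
c, m, n.  The partition likelihood factorises as p(U) · p(D | U, G) ·
p(I | D, U), so against the (U,U) reference everything cancels except
one "G in vs G out" regression Bayes factor per D trait (with a U trait
as covariate); I traits contribute a factor of 1, and partitions with no
D trait score exactly 0 on the log scale.

BF₁ is the conjugate Gaussian-regression Bayes factor: flat priors on
intercept/covariate and on log σ², and βG | σ ~ N(0, σₐ²σ²).  In closed
form, with g̃ the genotype residualised on the nuisance columns,

    BF(σₐ) = (1 + σₐ² g̃'g̃)^(-1/2) · (RSS₁(σₐ)/RSS₀)^(-(n-k)/2),

averaged uniformly over the scale grid σₐ ∈ {0.05, 0.1, 0.2, 0.4} — the
published default of the conjugate genotype-regression framework this
score follows.  Responses are standardised to unit variance before
scoring (the scale-free prior makes this a formal no-op, but it keeps
reported RSS quantities comparable across traits).  Selection is pure
argmax of the log₁₀ Bayes factor (uniform partition prior); exact ties
are flagged and count as incorrect.

Because the (D,D) score adds a Bayes factor for a *null* effect whenever
only one trait is truly direct, the framework misselects under mediation
whenever that null factor drifts above 1 — the benchmark measures this
misselection rate under scenario (b) at roughly one replicate in six
with the default grid.  The rate is sensitive to the prior scales
(broader effect priors sharpen the Occam penalty, tighter ones weaken
it), so only its order of magnitude, not its exact value, transfers
across prior conventions.

## Bayesian-network scores (`bn`)

The admissible space is every DAG over {G, X, Y} with no arrow into G —
twelve models, enumerated exhaustively (no search heuristics).  Both
scores decompose over node families; the suite checks decomposability
and that the Markov-equivalent pairs d/e and X→Y / Y→X score identically
to 1e-8 on arbitrary data.

**BIC-CG.**  G is a 3-level multinomial (2 free parameters).  A
continuous node with G as parent is fitted as a separate regression —
intercept, slope per continuous parent, variance — per genotype level; a
continuous node without G is a single (possibly marginal) regression.
Score = Σ maximised log-likelihood − (k/2)·ln n with n the total sample
size.  A genotype level with fewer than 3 observations is pooled with
its nearest level (flagged); a level that still cannot support its
parameters, or a zero residual variance, raises `DegenerateDataError`
and the benchmark counts the replicate as failed for this scorer.

**ISS-weighted Bayesian score.**  A conjugate marginal likelihood whose
hyperparameters derive from one *master prior* built from empirical
moments, weighted by an imaginary sample size (ISS, default 6):
Dirichlet counts ISS·p̂ₗ on the genotype multinomial, and for the
continuous block a normal-inverse-Wishart prior per genotype level with
location the empirical mean of (x, y), scale matrix κ·S_emp and degrees
of freedom κ + q + 1, where κ is the level's prior count (ISS·p̂ₗ, or
ISS when G is not a parent) and q the block dimension.  These choices
are closed under marginalisation — the prior of a sub-vector equals the
marginal of the joint prior — which is precisely what makes the score
identical on Markov-equivalent DAGs by construction rather than by
numerical accident.  Node terms are conditionals of that joint
(log m(family) − log m(parents)).  ISS defaults to 6, a conventional
choice for data of this shape; the score is genuinely sensitive to ISS
(verified qualitatively), and this prior construction is *not* a clone
of the historical DEAL package — in particular, under pure pleiotropy
(scenario (a)) this score prefers the true model (a), whereas
implementations with other default priors are known to prefer the
over-parameterised d/e class there.  Absolute score values are
implementation conventions throughout; only rankings are meaningful.

**Selection.**  Argmax at the equivalence-class level: d/e and the two
trait-only orientations share classes; a winning class counts as correct
iff it contains the true model.  A *different* class within 1e-8 of the
maximum flags a tie.

## Benchmark conventions (`bench`)

* Truth is derived from the generative equations, not hand-coded: the
  correct model of a confounded scenario is its structure with E
  deleted (h→a, i→b, j→c, k→m, l→n); MR's truth set is the scenarios
  containing an X→Y arrow ({b, d, g, i}); the CIT's is the pure chains
  ({b, i}).
* For selection methods, correct + incorrect + tie + failure = 1 per
  cell; detection methods report a detection rate and whether the
  scenario counts as a true detection.
* Default grid: 1000 replicates of n = 1000, single 0.05 threshold, no
  multiplicity correction (one decision per replicate).
* The mean-score matrices (`summarize_scores`) use the layout
  rows = tested models (5 for SEM, the 5 lettered partitions for BUF,
  all 12 DAGs for the network scores), columns = scenarios, with the
  per-column preferred model and the correct cell annotated in the JSON
  report.

## Known limitations

* Three variables only; no extension to larger networks, multiple
  instruments (MR-Egger-style), or summary-statistic methods.
* The CIT's p₄ is this package's permutation construction, not a line-
  by-line port of the historical implementation; omnibus behaviour is
  calibrated qualitatively (detection under mediation, conservatism
  under the null, non-detection under confounded mediation), not to the
  original's per-replicate p-values.
* Bayesian score magnitudes (BUF, ISS score) depend on prior conventions
  that the source material does not pin down; cross-implementation
  comparisons should use rankings, never absolute scores.
* Single-process execution; the substream design permits parallelism but
  none is implemented.
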