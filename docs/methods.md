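# Methods

## Setting and model

A two-arm superiority RCT with binary endpoint tests `H0: θ = 0` against
`HA: θ > 0`, where θ is the risk difference between the intervention (a
digital medical device) and control. The framework inserts a single interim
look whose only purpose is to decide whether to apply for temporary
regulatory authorization; the trial always continues to its planned end, so
the look spends no α.

All interim machinery lives on the canonical z-scale of group-sequential
theory. With `G_t` the difference estimator at information time `t` and
`k²` the variance of the full-sample estimator `G_1`,
`Z_t = G_t √t / k ~ N(√t θ/k, 1)`. For the binary endpoint,
`k = √([π_I(1−π_I) + π_C(1−π_C)] / (n/2))` under equal allocation. Only
these general properties of the estimator are used, so the z-scale
operations apply to any asymptotically normal estimator.

### Sample size

Per-arm size is the ceiling of the textbook normal-approximation formula for
a one-sided two-sample test of proportions, pooled SD under the null and
unpooled under the alternative. This convention reproduces the six design
sizes used throughout (112, 248, 104, 218, 84, 164 for the retained rate
pairs at α = 0.025, power 0.9); other roundings or SD conventions do not.

### Interim metrics

- Conditional power, given `Z_t = z_t` and a post-interim drift θ′:
  `CP = Φ([√t z_t + θ′(1−t)/k − z_{1−α}]/√(1−t))`. The default drift is the
  empirical trend θ′ = g_t.
- Predictive power: the flat-prior posterior average of CP,
  `PP = Φ([√t z_t − t z_{1−α}]/√(t(1−t)))`. The identity
  `PP = Φ(√t Φ⁻¹(CP_empirical))` makes its behavior transparent: PP is CP
  shrunk toward 1/2, increasingly so at earlier looks.
- Design-stage expectations `E[CP]`, `E[PP]` average the metric over
  `Z_t ~ N(√t θ_A/k, 1)`; exceedance probabilities `P(CP ≥ c*)`,
  `P(PP ≥ c*)` are the corresponding tail probabilities.

`E[CP]`/`E[PP]` are computed by adaptive Gauss–Kronrod quadrature over
`z_t ∈ mean ± 10 SD` (requested absolute tolerance 1e−9; a reported error
bound above 1e−6 raises). Both integrals also admit closed forms —
`E[CP] = Φ((θ_A/k − z_{1−α})/√(1−t+1/t))` and
`E[PP] = Φ(√t(θ_A/k − z_{1−α})/√(2−t))` — which the test suite uses as
independent oracles at 1e−6 across a parameter grid. The exceedance
probabilities are exact normal tails obtained by inverting the monotone CP
and PP inequalities analytically; tests invert them numerically instead.

### Interim-timing solver

Given a target c\* and a grid of candidate times (default
{0.5, 0.6, 0.7, 0.8, 0.9}, reflecting the view that a regulatory submission
needs at least half the planned information), the solver returns the grid
time whose `E[metric]` is closest to c\* (or whose exceedance probability is
closest to a target γ). Ties break toward the *smallest* t: the framework
exists to enable early access, so the earlier of two equally good looks
wins. The rule is deterministic and documented rather than clever.

### Interim and final analyses of counts

At the interim, the plug-in `k̂` evaluates the observed rates at the
full-trial per-arm size — the SD the final estimator would have if the
interim rates were the truth. A switch accepts the design-stage k instead;
on the bundled example both conventions give CP = 0.99 to two decimals. The
final test is the one-sided pooled-variance score z-test; the *unpooled*
plug-in SE of the risk difference is reported alongside, because that is the
σ the meta-analysis consumes.

Zero-cell rule: if any cell of a 2×2 table is empty, 0.5 is added to every
cell *for variance estimation only* (point estimates are never touched).
Plug-in SEs are then strictly positive for any data, which both `Z_t` and
the meta-analysis require. A fully degenerate final table (pooled variance
zero) carries no evidence and is assigned p = 0.5.

## Reference-model meta-analysis

Two summaries enter: the trial `(g₁, σ₁)` and the RWD `(g₂, σ₂)`, both
treated as normal with known SE. Rather than the symmetric random-effects
model, the asymmetric "reference model" variant of the normal-normal
hierarchical model is used: `θ⁽¹⁾ | a ~ N(a, 0)` (the trial measures the
target effect directly) and `θ⁽²⁾ | a, b ~ N(a, b²)` (the RWD deviates with
uncertain scale). The effect `a` has an improper flat prior — proper
posteriors follow for two studies with finite σ — and the deviation scale is
`b = √2·τ` with τ half-normal. The default τ scale of 0.5 is weakly
informative for risk differences, whose magnitude cannot exceed 1.

Computation is fully deterministic 1-D numerics, in the spirit of
`bayesmeta`-style direct integration:

- marginal posterior of b ∝ `HN(b; √2·τ_scale) · N(g₂−g₁; 0, σ₁²+σ₂²+b²)`;
- `a | b` is normal with precision-weighted mean of g₁ (weight 1/σ₁²) and
  g₂ (weight 1/(σ₂²+b²));
- the marginal posterior of `a` is the corresponding normal mixture over a
  2000-node b-grid: uniform up to 12·√(σ₁²+σ₂²) (the scale on which the
  likelihood turns over), then geometric up to 50·τ_scale (the prior's
  range). The two-piece layout keeps the quadrature accurate even when the
  prior scale and the data scale differ by orders of magnitude.
- posterior quantiles of `a` by Brent root-finding on the mixture CDF.

Reported: posterior mean (and median — they agree to two decimals on all
bundled examples and the package does not distinguish them further), the
equal-tailed 95% shrinkage interval, its width δ, the relative width
`q = δ/(2·1.96·σ₁)` and the effective-sample-size gain `q⁻² − 1` (SEs scale
as 1/√n, so an interval q times narrower acts like n/q² subjects).

Limiting behavior, verified by tests against adaptive-quadrature and
importance-sampling references: τ_scale → 0 recovers fixed-effect
inverse-variance pooling; τ_scale → ∞ returns the trial's own estimate.
One subtlety: in the diffuse limit the residual gain vanishes only
logarithmically in the prior scale (a sliver of posterior mass remains at
small b), e.g. ≈ 2% at τ_scale = 10³ for the bundled example — the point
estimate converges much faster than the interval width.

## Simulation engine

The generator emulates the framework's intended deployment:

- Trial: `n/2` Bernoulli(π_I) and `n/2` Bernoulli(π_C) subjects, n from the
  sample-size rule. The interim reads the first `n_t/2` per arm
  (`n_t = t·n` rounded to the nearest even integer), so interim counts are a
  prefix of final counts — the same accrual stream, not a fresh draw.
- RWD: a parallel cohort of `m = n(1−t)` (nearest integer; odd m favors the
  device arm), the number of trial entrants after the look, with its own
  rates (π_I^RWD, π_C^RWD) — matched to the trial or deliberately divergent.
- Each replicate then runs interim → final → RWD → reference-model
  meta-analysis with `(g₁, σ₁) = (d_trial, unpooled SE)` and
  `(g₂, σ₂) = (d_rwd, unpooled SE)`.

Randomness: `numpy` PCG64 seeded with `[base_seed, replicate_index, stream]`
(stream 0 = trial, 1 = RWD), so any replicate is reproducible in isolation
and scenarios parallelize deterministically.

The default scenario grid uses trial device-arm rates {0.7, 0.8, 0.9} with
control rates 0.1–0.3 lower, keeps designs with 60 ≤ n ≤ 300 (≥ 30 per arm
for the normal approximation; six designs survive), solves the interim time
for target levels {0.8, 0.85, 0.9} (always landing on t ∈ {0.5, 0.7, 0.9}),
and pairs each with a matched and a strongly divergent RWD population.
Summaries default to 5000 replications. Aggregation is over *all*
replications; a `condition_on_authorization` flag restricts to replicates
that cleared the interim threshold, which demonstrably inflates the mean
trial estimate and is therefore not the default. A null mode reruns any
scenario with all response rates set to the control rate while keeping the
planned n and t, reporting realized type-I error and the frequency of
erroneous authorization.

What the generator does *not* emulate: dropout, unequal or adaptive
allocation, accrual-time dynamics, confounding in the RWD (summaries enter
the meta-analysis as if exchangeably estimated — in practice the RWD
estimate must first be causally adjusted), multiple RWD sources, or repeated
interim looks. Passing tests therefore certify the statistical machinery
under clean sampling, not robustness to those real-world complications.

## Problem sizes and tolerances in the test suite

Deterministic quantities are checked at their printed precision or against
independent oracles (closed forms at 1e−6, numeric inversions at 1e−10,
importance-sampling posteriors within 3 MC standard errors). Simulation
checks use 5000 replications for the flagship operating characteristics
(rejection frequency, authorization frequency, mean conditional power, mean
gain) and 300–4000 replications for secondary calibration checks; these
sizes put Monte-Carlo error comfortably inside the asserted tolerances while
keeping the full suite around a minute.
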