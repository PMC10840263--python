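# Methods

## Model and procedures

For P simultaneous two-group comparisons the package tests
`H_0i: δ_i = 0` against `H_1i: δ_i ≠ 0`, where `δ_i = |μ_1i − μ_2i|` is the
absolute group-mean difference of feature i. Each feature is tested with the
pooled-variance two-sample t statistic

    t_i = |X̄_1i − X̄_2i| / (S_i √(1/n₁ + 1/n₂)),   df = n₁ + n₂ − 2,
    S_i² = ((n₁−1) S²_1i + (n₂−1) S²_2i) / (n₁ + n₂ − 2),

with a two-sided p-value from the t reference (a `normal_approx` flag
substitutes the standard normal for large-sample emulation; the t is exact
under the Gaussian model and converges to it, so it is the default
regardless of df).

All six multiple-comparison procedures are expressed as threshold ladders
over the ascending sorted p-values `p_(1) ≤ … ≤ p_(P)`: procedure-specific
multipliers `l_i` define thresholds `l_i α / P_eff`, and the step-up rule
rejects ranks `1..k` with `k = max{ i : p_(i) ≤ l_i α / P_eff }` (exact
floating `≤`, no epsilon — the thresholds are exact rationals of α and a
tolerance would silently change k).

* BF: `l_i = 1`; BH: `l_i = i`; BY: `l_i = i` with `P_eff = P·C(P)`,
  `C(P) = Σ_{i≤P} 1/i` (summed smallest-term-first with `math.fsum`).
* M1/M2/M3: `l_1 = 1` and `l_i = l_{i−1} + g(r_i)` where `r_i` is the
  Pearson correlation between the feature columns at ranks i−1 and i, and
  `g` is the conditional Fisher information the rank-i statistic adds beyond
  its predecessor under a strong, moderate or mild assumption:
  `(1−|r|)/(1+|r|)`, `1−|r|`, `1−r²` respectively.

Since `0 ≤ g_strong ≤ g_moderate ≤ g_mild ≤ 1` pointwise, the thresholds and
rejection counts are deterministically sandwiched
`BF ≤ M1 ≤ M2 ≤ M3 ≤ BH` on every input; `r ≡ 0` collapses all three to BH
exactly and `|r| ≡ 1` to Bonferroni.

### Adjusted p-values

The reported adjusted p-value at rank i is the pointwise ratio
`p_(i) · P_eff / l_i`. It is deliberately **not** monotonicity-enforced and
**not** capped at 1, so the duality `adjusted_p_i ≤ α ⇔ p_(i) ≤ threshold_i`
holds rank by rank and the values agree with the published comparison table
(whose BH column is itself non-monotone, e.g. rank 3 below rank 2).
Rejection therefore always comes from the max-k rule, never from pointwise
adjusted-p comparison — without monotonicity the two can disagree. The
conventional step-up report (running minimum from rank P downward, capped at
1) is available behind `monotone=True` / `--monotone-adjust`, default off.

## Correlation estimation

The neighbour correlations are computed from the data columns in sorted
order. Two centerings are offered:

* `none` (default): raw Pearson correlation across all samples — the literal
  reading of `Corr(X_(i), X_(i−1))`. Under genuine group differences this
  estimate absorbs the shared group-mean shift, which inflates |r| and makes
  the M-procedures slightly conservative even at true ρ = 0; the simulation
  results reflect that behaviour.
* `within_group`: each group's mean is removed first, estimating the
  within-population correlation only.

Neither is asserted as "the" correct choice; both are surfaced in the API
and CLI. Correlations may also be supplied directly (adjust-only mode),
aligned to the sorted rank order. Values within 1e−12 outside [−1, 1] are
clamped (floating error from correlation computation); anything further out
is an error. Ties among p-values are broken by original feature index
(stable sort) so the correlation sequence is reproducible.

## Simulation harness

Each replication of `run_study`:

1. draws effect sizes `δ ~ N(0, σ²_δ I)` of length P (σ²_δ = 0.0678 by
   default, which keeps the expected Bonferroni count below 5% of the
   features — strong FWER control);
2. draws n₁ case samples from `MVN(δ, (1−ρ)I + ρJ)` and n₂ controls from
   `MVN(0, (1−ρ)I + ρJ)` via the one-factor construction
   `x = δ·group + √ρ·g·1 + √(1−ρ)·ε` (scalar factor g per sample), which is
   exact for compound symmetry and avoids factorising a P × P covariance;
3. screens the replicate end to end — t-tests, sorting, neighbour
   correlations estimated from the replicate's own data (an option
   substitutes the true ρ for oracle comparisons) — and records the
   discovery count of each procedure plus the unadjusted count `#{p ≤ α}`.

Defaults: P = 1000, n₁ = n₂ = 100, α = 0.05, 1000 replications,
ρ ∈ [0, 1) (negative ρ is rejected: `(1−ρ)I + ρJ` loses positive
semidefiniteness below −1/(P−1)). δ is redrawn each replication;
`freeze_delta=True` fixes one draw across replications for
variance-decomposition experiments. Replication r uses an RNG stream
spawned from `(seed, r)`, so studies are deterministic, order-independent
and parallelisable.

What the generator emulates: equicorrelated Gaussian features with
Gaussian random effects — the regime in which the conditional-information
increments have their exact meaning. What it does not: heteroscedastic or
heavy-tailed noise, block or AR(1) correlation, non-random (sparse) effects,
and sample-level dependence. Passing the simulation checks therefore
demonstrates correctness of the procedures under compound symmetry, not
robustness of the screening advice on arbitrary real data.

## Power utility

`power_formula(delta, n, alpha)` evaluates the screening-power expression

    1 − β = 2 · (1 − Φ(δ √(n/2) − z_{1−α/2}))

verbatim as a convenience. Note it doubles the upper-tail term of the
two-sided z-test without subtracting the lower tail, so it exceeds 1 for
small `δ √(n/2)` (δ = 0, α = 0.05 gives ≈1.95); treat it as a rough
large-effect approximation, not a probability.

## Numerical and design choices

* Thresholds are computed as `l_i · α / P` in that association order; the
  published 4-decimal table values (including ties such as 0.03425) are
  reproduced by correctly-rounded decimal display of the resulting doubles.
* Zero pooled variance is a hard error naming the offending feature — never
  a silent p of 0 or 1. Missing matrix values are load-time errors, not
  imputed.
* The t-test is the classical pooled (equal-variance) form to match the
  ladder's information model; Welch, moderated/shrinkage statistics and
  paired designs are out of scope.
* BY at P = 1 has C(1) = 1 and coincides with BF/BH; allowed, not an error.
* Machine output is full precision (`%.17g`, exact round-trip); 4-decimal
  formatting is display-only (`--pretty`).
* Scaled-down study sizes in the test suite: the simulation-reproduction
  checks run 100 replications per ρ (the published study used 1000) and the
  global-null calibration runs 1000 replications with the Bonferroni-only
  pipeline; these sizes give 3·SE tolerance bands of a few counts while
  keeping the default suite fast.

## Known limitations

* The M-procedures' FDR control is motivated information-theoretically for
  consecutively sorted statistics under compound-symmetric Gaussian
  dependence; no finite-sample FDR guarantee under arbitrary dependence is
  claimed (BY remains the worst-case-safe choice).
* With `centering="none"`, strong true effects inflate the estimated
  neighbour correlations, making the M-procedures conservative relative to
  their oracle-ρ behaviour.
* No q-value/π₀ estimation, no PRDS diagnostics, no step-down variants.
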