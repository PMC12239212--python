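# Methods

## Model

A tumor is a collection of independently dividing and dying cell lineages
of three genotypes: drug-sensitive (s), aneuploid (a), and resistant
mutant (m). Genotype k divides at rate λ_k and dies at rate μ_k per day;
r_k = λ_k − μ_k. Under therapy the sensitive population declines
(r_s < 0) and the mutant grows (r_m > 0); the aneuploid growth rate r_a
may fall anywhere in between. Nine events drive the dynamics:

| event | rate | effect |
|---|---|---|
| sensitive birth | λ_s·s | s+1 |
| sensitive death | μ_s·s | s−1 |
| missegregation | u·λ_s·s | a+1 (parent kept) |
| sensitive mutation | v·λ_s·s | m+1 (parent kept) |
| aneuploid birth | λ_a·a | a+1 |
| aneuploid death | μ_a·a | a−1 |
| aneuploid mutation | v_a·λ_a·a | m+1 (parent kept) |
| mutant birth | λ_m·m | m+1 |
| mutant death | μ_m·m | m−1 |

Missegregation and mutation happen at division and add a daughter of the
new type without removing the parent, exactly as listed. The (1−u−v) and
(1−v_a) factors on the birth rates are dropped by default (they are ≤1%
corrections at realistic rates); `exact_division_factors=True` restores
them for sensitivity checks. In the logistic variant each genotype's death
rate gains λ_k·(s+a+m)/K, so the drug-free aneuploid-only model
equilibrates at the effective capacity K_e = K·r_a/λ_a.

*Assumptions*: lineage independence (checked against the logistic
variant), no spatial structure or immune compartment, no back-transition
from aneuploid to euploid, aneuploidy as a single genotype class rather
than per-karyotype fitness.

## Analytic layer

**Extinction probabilities.** A mutant lineage dies with probability
q_m = min(1, μ_m/λ_m); its establishment probability is p_m = r_m/λ_m.
Aneuploid and sensitive founders satisfy the PGF fixed-point quadratics

    λ_a(1−v_a)q² − (λ_a+μ_a−v_aλ_a q_m)q + μ_a = 0
    λ_s(1−u−v)q² − (λ_s+μ_s−uλ_s q_a−vλ_s q_m)q + μ_s = 0

whose smaller roots in [0,1] are q_a and q_s. Roots are computed with the
cancellation-safe form 2c/(−b+√(b²−4ac)); a fixed-point iteration from
q = 0 is kept in the package as an independent oracle, and the two agree
to 1e-10 across a 1,000-point random rate sweep in the test suite. Roots
within 5e-13 of 1 are snapped to 1 so subcritical lineages report exact
certain extinction.

**Thresholds and rescue probability.** p_rescue = 1 − q_s^N exactly, or
1 − e^(−Λ∞) with Λ∞ = N/N*_m + N/N*_a in the threshold approximation.
T* = √(λ_m/(v_a·r_m))/(2λ_a) is the expected survival time an aneuploid
lineage needs to spawn an established mutant; r_a·T* decides the regime.
The regime classifier applies the asymptotic conditions as hard cutoffs at
±1 and additionally reports the raw condition values plus an
`aneuploid_type` label (tolerant/stationary/resistant by r_a·T* alone),
because a strongly tolerant aneuploid can still be irrelevant to rescue
when it is produced too rarely (u·λ_a < |r_a|) — the TNBC SA1035/SA535
presets are exactly this case: tolerant clones whose rescue runs through
direct mutation.

**Hazard and time summaries.** In the tolerant and direct regimes,
established mutant lineages arrive as an inhomogeneous Poisson process
with intensity p_m[vλ_s·s̄(t) + v_aλ_a·ā(t)] over the mean-field
trajectories s̄ = N·e^(r_s t), ā = uλ_sN(e^(r_s t)−e^(r_a t))/(r_s−r_a).
The cumulative hazard Λ(t) integrates in closed form and satisfies
Λ∞ = N/N*_m + N/N*_a exactly. Conditional mean rescue times use the
closed small-tumor (−1/r_s − 1/r_a) and large-tumor (λ_m/(vλ_sN·r_m))
branches when N is at least a factor 10 inside them, and the numeric
integral of the conditional survival function in between. Recurrence and
detection times use the same branch structure; the intermediate branch is
a Monte-Carlo over lineage arrivals: K ~ Poisson(Λ∞) conditioned on
K ≥ 1, arrival times by inverting Λ on a 4,096-point log grid, and each
lineage born at t_i contributing (1/p_m)·e^(r_m(t−t_i)) cells — the
conditional expectation of a surviving supercritical lineage. The
stationary and resistant regimes route all time quantities to stochastic
simulation, where aneuploid-lineage stochasticity is not subdominant.

Natural logarithms are used throughout; the large-tumor recurrence
constant is (1/r_m)·ln((r_m−r_s)/(vλ_s)), read with r_m−r_s as a
difference (1,542 days at melanoma rates), and the small-tumor growth term
is ln(p_m·N)/r_m, i.e. a conditioned surviving lineage grows like
(1/p_m)e^(r_m t).

*Known limitation.* The two-step small-tumor forms condition implicitly on
rescue via the aneuploid route. The full-hazard Monte-Carlo also samples
direct-route rescues, a fixed ≈ N*_a/(N*_a+N*_m) ≈ 10% admixture at
melanoma rates that arrives within days instead of ~10⁴ days, so its mean
recurrence time at N = 10⁶ (9.6×10³ days) sits below the two-step closed
form (1.12×10⁴ days) by more than its Monte-Carlo error; the estimator was
verified against an exact conditional-expectation integral. Restricting
the sampler to one route (`sample_rescue_lineages(..., paths="aneuploid")`)
recovers the two-step limit. The corresponding acceptance test documents
this gap and is expected to fail.

## Simulation layer

The SSA and τ-leaping inner loops are numba-compiled. Waiting times are
exponential in the summed rate; events are chosen proportionally. Each
mutant-founding event opens a tagged lineage (capacity 8,192 per run) and
mutant births/deaths are attributed to lineages proportionally to size, so
the *rescue time* — the birth time of the earliest lineage still alive
when the establishment threshold is crossed — is recorded exactly. The
establishment threshold ⌊3·ln10/ln(λ_m/μ_m)⌋+1 (66 for melanoma rates) is
the smallest mutant count whose joint extinction probability is < 0.1%.
τ-leaping draws independent Poisson counts per channel over fixed steps
(default 0.1 days at melanoma rate scales) and clamps each genotype at
zero, which slightly biases totals near extinction; the SSA is the
reference. Censoring defaults: t ≤ 1e6 days, ≤ 1e9 events, both recorded.

Replicate i of an ensemble is seeded by
`numpy.random.SeedSequence((base_seed, i))`, making ensembles
reproducible across machines; the kernel consumes the seed folded to
uint32. No stochastic code path runs without an explicit seed.

## Scaled operating points

Published tumor sizes (N up to 10¹⁰ at v = 10⁻⁷) imply ~10⁸ events per
replicate and are not simulated directly. Stochastic validation uses
scaled instances — melanoma rates with v = 10⁻³ and N ≈ 10³, chosen so
N/N* is of order one and a replicate takes ~10⁴ events — plus full-scale
evaluation of the analytic layer. The generator therefore emulates the
dimensionless operating point of the published regime, not its absolute
population sizes; agreement on scaled instances demonstrates the
simulator and theory agree with each other, and says nothing extra about
parameter values measured in real tumors. Bootstrap intervals are
percentile bootstrap (b = 1000 default); rescue fractions use normal
binomial intervals.

## Numerical choices

- Quadratic PGF roots via the stable conjugate form; near-critical
  discriminants clipped at 0.
- Mean-field expressions use the limit form t·e^(xt) when |x−y| < 1e-12;
  the closed-form mutant mean is cross-checked against quadrature at 1e-8
  relative tolerance in the tests.
- Hazard integrals via adaptive quadrature on [0, 60/|r_slow|], where
  r_slow is the slowest declining background rate.
- Asymptotic branch switchovers at N ≤ N*/10 and N ≥ 10·N*_m; every time
  estimate carries a method tag so callers can see which approximation
  produced it.
- Table 2's sensitive death rate is stored as published (0.1215) even
  though recomputing it from the underlying fitness estimates gives
  0.12193; `tnbc_sensitive_death_rate_recomputed()` documents the
  recomputation without overriding the preset.
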