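# Methods

## Model

Two-sample Mendelian randomisation treats L independent SNPs as
instrumental variables. For SNP *j*, γⱼ is its true effect on the exposure
(per effect-allele copy, exposure in SD units) and Γⱼ its true effect on
the outcome (log-odds for binary outcomes). With causal effect β and
direct (pleiotropic) effect αⱼ,

    Γⱼ = β γⱼ + αⱼ .

Valid instruments have αⱼ = 0. Observed summary statistics add independent
sampling noise in the two non-overlapping samples:
γ̂ⱼ ~ N(γⱼ, σ²_γⱼ), Γ̂ⱼ ~ N(Γⱼ, σ²_Γⱼ).

Estimators and their identifying assumptions:

- **IVW**: β̂ = Σwⱼγ̂ⱼΓ̂ⱼ / Σwⱼγ̂ⱼ², wⱼ = 1/σ²_Γⱼ. Unbiased only when
  Σwⱼγⱼαⱼ = 0 (no pleiotropy, or exactly balanced). Fixed-effect
  SE = (Σwⱼγ̂ⱼ²)^(−1/2); the multiplicative random-effects variant
  (default) inflates it by max(1, √(Q/(L−1))). Normal inference.
- **MR-Egger**: weighted regression Γ̂ = β₀ + βγ̂ with the same weights.
  Requires the InSIDE assumption (cov(αⱼ, γⱼ) = 0) and an
  exposure-increasing orientation of all SNPs (enforced; γ̂ⱼ ≥ 0). SE
  inflated by max(1, √(RSSw/(L−2))); t(L−2) inference on both slope and
  intercept. The intercept test at α = 0.05 is the pleiotropy test.
- **Weighted median**: per-SNP ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ sorted, weights
  wⱼ = γ̂ⱼ²/σ²_Γⱼ (first-order ratio variance), cumulative standardized
  weight sⱼ = (Σₖ≤ⱼwₖ − wⱼ/2)/Σw, estimate interpolated at s = 0.5.
  Consistent while valid SNPs carry ≥50% of total weight. SE by seeded
  parametric bootstrap (default 1000 reps).
- **Mode-based**: normal-kernel density of the ratios with bandwidth
  h = φ·0.9·min(sd, 1.4826·MAD)·L^(−1/5); simple (equal) or
  inverse-variance kernel weights normalized to sum L; the estimate is the
  density argmax on a 512-point grid spanning [min−h, max+h], ties broken
  at the smallest grid index; default φ = 1. SE by seeded parametric
  bootstrap. Consistent when the largest cluster of ratios is valid
  (zero-modal-pleiotropy assumption).
- **MR-Egger + SIMEX**: noise in γ̂ dilutes the Egger slope toward the null
  when I²_GX = max(0, (Q_GX−(L−1))/Q_GX) is well below 1, with
  Q_GX = Σ(γ̂ⱼ−γ̄w)²/σ²_γⱼ. SIMEX adds extra noise √λ·εⱼ,
  εⱼ ~ N(0, σ²_γⱼ), for λ ∈ {0, 0.5, 1, 1.5, 2} (n_sim = 1000 pseudo-sets
  per λ by default, each re-oriented before fitting), averages the Egger
  slopes per λ, fits a quadratic in λ and extrapolates to λ = −1. The SE
  extrapolates the sampling variance per λ estimated as
  mean(model-based variance) − var(slopes across simulations), with the
  plain Egger SE as fallback when the extrapolated variance is
  non-positive; t(L−2) inference.

First-order (delta-method) ratio variances are used throughout for Wald,
median and heterogeneity weights; the NOME violation this entails is
quantified by I²_GX and addressed by SIMEX rather than by second-order
weights.

## Harmonisation

Outcome records are matched to the exposure's effect allele directly or
through the strand complement (A↔T, C↔G); a swapped match flips the sign
of Γ̂ and complements the allele frequency. Palindromic SNPs (A/T, G/C)
cannot be strand-resolved from alleles: the default "frequency" policy
requires both allele frequencies outside [0.5 − w, 0.5 + w] (ambiguity
window w = 0.08, the conventional choice) and infers orientation from
which side of 0.5 each frequency falls on — agreeing minor alleles keep
the direct reading, disagreeing ones imply an opposite-strand report and
flip it. Inside the window, or with a missing frequency, the SNP is
dropped; a strict "drop" policy is available. Using frequencies to *flip*
rather than only to *confirm* follows common practice in summary-data MR
tooling; analyses that must be conservative should use the drop policy.

Proxy SNPs substitute for instruments missing from the outcome table when
their r² exceeds 0.8 (best r² wins); the proxy table's allele
correspondence carries the haplotype phase, so proxy alleles are
translated, never inferred. After alignment, every pair is oriented so
γ̂ⱼ ≥ 0 (required by Egger; Wald ratios unchanged); γ̂ⱼ = 0 has no defined
orientation and is dropped. Instrument selection prunes
genome-wide-significant SNPs greedily by ascending p-value against a
user-supplied pairwise r² table (missing pairs are treated as r² = 0 with
a warning; ties broken by larger |β̂|, then rsID, for determinism). LD is
consumed, never estimated: reproducing externally clumped instrument lists
exactly is out of scope.

## Power

For a binary outcome with N = cases + controls, case fraction K,
instrument strength R²_GX and odds ratio OR per SD of exposure, the
two-sided asymptotic power at level α is

    Φ(ncp − z₁₋α/₂) + Φ(−ncp − z₁₋α/₂),  ncp = |log OR|·√(N·R²_GX·K(1−K)).

The second (wrong-tail) term is negligible except under the null; it makes
power exactly α at OR = 1. This is the standard approximation for
summary-data MR power; R²_GX = 0 returns α.

## Synthetic data

`simulate_summary_stats` draws γⱼ from a configurable law (default
U[0.01, 0.1] SD/allele), marks round(p_invalid·L) SNPs invalid, gives them
αⱼ ~ N(μ_α, σ_α²) plus, when an InSIDE violation is requested,
ρ·(γⱼ−γ̄)·σ_α/sd(γ), and adds independent noise in the two samples.
Alleles are assigned non-palindromic with frequencies U[0.1, 0.9] and
identical coding in both tables, so the harmonisation path is exercised
but never drops simulated SNPs. What the generator does *not* emulate:
LD between SNPs, winner's curse in instrument discovery, sample overlap,
allele-coding discrepancies and palindromic ambiguity (tested separately
with hand-built records), and effect-size–frequency coupling. Passing
simulation tests therefore validates the estimators' statistical
behaviour under the stated model, not robustness to those artefacts of
real consortium data.

The `education_like` preset fixes the study conditions the package is
validated against: L = 162 SNPs, γⱼ ~ U[0.005, 0.027], EAF U[0.1, 0.9], so
the instrument explains ≈1.8–1.9% of exposure variance
(Σ2p(1−p)γ², computed from the truth record); σ_γ = 0.0028 and
σ_Γ = 0.0075, the sampling SEs implied by ≈300k exposure and ≈194k
case-control outcome samples at those allele frequencies; true effect
−0.40 log-odds per SD (odds ratio ≈ 0.67 per SD of exposure).

## Validation scenarios and problem sizes

The canonical scenarios in `validation_scenarios()` (all β = −0.4):

| scenario | L | pleiotropy | purpose |
|---|---|---|---|
| none | 50 | — | IVW bias < 0.01, CI coverage 0.93–0.97 |
| balanced | 50 | all SNPs, μ_α=0, σ_α=0.02 | Egger intercept type-I error ≈ 5% |
| directional_inside | 50 | 30%, μ_α=0.1, σ_α=0.02 | Egger/median robust, IVW biased |
| attenuated | 162 | — , σ_γ=0.017 (I²_GX≈0.7) | SIMEX recovers the diluted slope |
| near_nome | 162 | — , σ_γ=10⁻⁴ (I²_GX≈1) | SIMEX coincides with Egger |

Monte-Carlo sizes: 1000 replicates per scenario in the test suite
(200 for the SIMEX comparison, whose inner loop simulates
n_sim × |λ-grid| pseudo-datasets per fit), 600 in the acceptance script;
these sizes put Monte-Carlo error comfortably below the tolerances being
checked. In `directional_inside`, σ_Γ = 0.01 keeps per-ratio sampling
noise below the pleiotropic shifts so that estimator bias, not noise,
dominates the comparison; the weighted median, like all
finite-sample median estimators, retains a small bias at fixed SE that
vanishes as the outcome sample grows.

## Numerical choices

- IVW and Egger use closed-form weighted normal equations; an independent
  statsmodels WLS oracle cross-checks both in the tests (dual route).
- Degenerate inputs: a single-SNP set degrades IVW to the Wald ratio with
  a warning; constant γ̂ makes the Egger design rank-deficient (error);
  identical ratios give bandwidth 0 and the mode returns the common ratio.
- All stochastic estimators (median/mode bootstrap, SIMEX) demand an
  explicit integer seed and are bit-reproducible given (inputs, settings,
  seed); replicate seeds in the harness derive deterministically from one
  master seed.
- p-values are floored at the smallest positive float to stay in (0, 1].
- OR-scale inputs are log-converted at read time; non-positive ORs and
  non-ACGT alleles are dropped row-wise and counted.

## Limitations

Multivariable MR, correlated-instrument IVW, Steiger direction filtering,
penalized medians, Rucker model selection and radial MR are not
implemented. Indels and multi-allelic variants are rejected at the record
level. The Egger intercept's published asymmetric interval in the
motivating literature cannot be checked against this implementation's
symmetric t-intervals. Real-data replication depends on external
consortium downloads and on their exact clumping and overlap-exclusion
choices, which this package consumes as inputs rather than reproduces.
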