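# Methods

## Model

Drug in a carrier occupies two states: free (concentration `c_F`, available
for first-order transport out of the carrier at rate `k_S`) and bound
(`c_A`, requiring disassociation at rate `k_off` before release; free drug
re-associates at `k_on`). Under perfect-sink conditions the normalized
concentrations follow the linear system

    d(c_F)/dt = -(k_S + k_on) c_F + k_off c_A
    d(c_A)/dt =   k_on c_F - k_off c_A ,

with the equilibrium initial split `c_F(0)/c_0 = k_off/(k_on+k_off)`. The
closed form is a sum of two exponentials with decay constants

    λ₁,₂ = [ s ± sqrt(s² - 4 k_S k_off) ] / 2 ,   s = k_S + k_on + k_off,

and cumulative release `M_t/M_0 = a₁(1-e^{-λ₁t}) + a₂(1-e^{-λ₂t})` with
`a₁ + a₂ = 1` identically. `k_S` lumps diffusion, convection and osmotic
transport into one first-order constant; its mechanistic decomposition
(diffusivity, partition coefficient, shell thickness, convection,
permeability) is out of scope, as are non-sink boundary conditions and
carrier erosion/volume change (which produces, e.g., second-burst profiles
the model cannot represent).

Binding strength is reported as the free-energy difference
`ΔG = -k_B T ln(k_on/k_off)` in units of 10⁻²¹ J, with
`k_B = 1.380649 × 10⁻²³ J/K` (exact SI) and `T = 300 K` by default, giving
`k_B T = 4.1419 × 10⁻²¹ J`. The equilibrium free fraction — the burst
magnitude — is `1/(1+e^{-ΔG/k_B T})`; at `ΔG = k_B T` it is 73.1%.
Internally parameters are stored as rates `(k_S, k_on, k_off)`; ΔG is a
view, so optimizers never accumulate exp/log round-trip error.

Two limiting cases are exposed:

* `k_on/k_off → 0`: essentially all drug free, `M_t/M_0 = 1 - e^{-k_S t}`.
  (Descriptions of this case sometimes state the inequality the other way
  round; the equilibrium formula makes clear that *small* `k_on/k_off`
  maximises the free pool, and only that limit reproduces the
  single-exponential form. We follow the mathematics.)
* `k_S ≫ k_on, k_off`: transport and binding decouple;
  `M_t/M_0 = f₀(1-e^{-k_S t}) + (1-f₀)(1-e^{-k_off t})` with equilibrium
  weights. When the separation is imperfect this form over-predicts release
  pointwise, since it ignores transport as a bottleneck in the sustained
  phase.

## Numerical choices

* **Eigenvalues** are computed with the stable quadratic branch (larger root
  additive, smaller via the product identity `λ₁λ₂ = k_S k_off`), avoiding
  subtractive cancellation.
* **Repeated root.** The discriminant vanishes only on the line `k_on = 0,
  k_S = k_off`; when the relative discriminant falls below 10⁻¹² the
  confluent limit `(1 + c t)e^{-λt}` is used instead of the two-root form —
  a continuous extension, not an epsilon perturbation.
* **Prefactors** `a₁, a₂` are evaluated in extended (long-double) precision
  so the identity `a₁+a₂=1` holds to 10⁻¹² even near-degenerate.
* **Conservation** `free + bound + released = 1` holds to rounding by
  construction (`released` is computed as the complement and clipped to
  `[0, 1]`, a ≤1-ulp correction).
* **ODE oracle.** An adaptive high-order integration (DOP853, rtol 10⁻¹²,
  atol 10⁻¹⁴) of the two-state system serves as an independent cross-check
  of the closed form in the tests; it is never used in production paths.
* **Time units** (minute/hour/day) are metadata on every parameter set and
  curve; conversions are explicit, and the fit inherits the curve's unit.

## Parameter estimation

Initial values follow the curve's anatomy:

1. **Burst magnitude** `f̂₀` — the released value at the *knee* of a
   shape-preserving (PCHIP) interpolant: the maximum-curvature point with
   curvature computed on axis-normalized coordinates (curvature is not
   scale-invariant; normalizing by the observation window puts the maximum
   at the burst-to-sustained bend rather than at the first sample). The
   search is bounded to [first sample, 60% of the window];
   `ΔĜ = k_B T ln(f̂₀/(1-f̂₀))`.
2. **Transport rate** — the first finite-difference release rate divided by
   `f̂₀` (at `t = 0` the release rate is `k_S f₀`).
3. **Disassociation rate** — the slope of `ln(1 - released)` over the
   post-knee tail (the slow eigenvalue ≈ `k_off` when transport is faster).

Curves with no discernible burst fall back to the first released value with
a logged warning. These heuristics are coarse (tens of percent) but land
inside the optimizer's basin for model-generated curves.

Refinement is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, tolerances 10⁻¹⁴)
in `(ΔG, ln k_S, ln k_off)`: log-rates keep the parameters positive and
well-conditioned across minute/hour/day data. Bounds: `ΔG ∈ [-30, 30] ×
10⁻²¹ J` (≈ ±7 k_B T, covering every published fit with margin), `k_S ∈
[10⁻⁸, 10⁸]`, `k_off ∈ [10⁻¹⁰, 10⁶]` per time unit. The 10⁻¹⁰ floor stands
in for `k_off = 0`, which log-space cannot represent; at that value the
bound pool is static over any realistic window. Objective: unweighted SSE —
release tables are typically means or representative curves; per-point SDs
are carried and 1/sd² weighting is an opt-in flag. Up to five
deterministically perturbed starts are tried before a fit is declared
non-converged, and the initializer itself is always a candidate, so
refinement never worsens it.

**Variant selection.** The single-exponential model (`k_on → 0`, one
parameter) is nested in the full model, so the choice is an
extra-sum-of-squares F-test, `F = ((SSE₁ - SSE₃)/2)/(SSE₃/(n-3))` against
`F(2, n-3)` at α = 0.05; near-perfect single-exponential fits short-circuit
to the simpler model, and selections with n < 6 carry a low-power warning.

**Classification.** Burst axis: high iff equilibrium free fraction ≥ 0.5
(i.e. ΔG ≥ 0). Sustained axis: steady-state iff `k_off × horizon ≥ 1`
(meaningful bound-pool depletion within the observation window). Mapping:
(high, little) → I, (low, little) → II, (high, steady) → III, (low, steady)
→ IV; single-exponential fits are all burst, category I by convention. The
thresholds are configurable — "high" and "steady" have no canonical
quantitative definition — and the defaults are anchored so the four
canonical exemplar triples, (ΔG, k_S, k_off) = (4, 0.18, 0.002),
(−4, 0.18, 0.001), (1, 0.24, 0.015), (−5, 0.36, 0.013) per day over a
100-day window, classify as I–IV respectively. Note the same parameters can
legitimately change category with the observation window.

## Bootstrap and diagnostics

Case resampling of `(t, y)` pairs with replacement is the default — the
appropriate scheme when observations are independent; residual resampling
(fixed design, resampled fitted residuals) is available as an option. Each
replicate is refit starting from the original estimate (two starts at
most); non-converged replicates are dropped and counted, and a summary with
≥ 50% failures is flagged invalid. Replicates default to 1000. Per
parameter the summary reports mean, SD, and a two-sided proportion-based
p-value against zero with a +1 continuity correction (so zero exceedances
report `2/(B+1)` rather than 0). `k_on` is summarized alongside
`(k_S, k_off, ΔG)` for completeness although only three are independent;
consequently the reported means satisfy `ΔG ≈ -k_B T ln(k_on/k_off)` well
within the bootstrap spread. All resampling uses a user-supplied seed and is
bitwise reproducible.

The model-vs-line comparison uses `F = ((SSE_lin - SSE_nl)/1)/(SSE_nl/(n-3))`
with `(1, n-3)` degrees of freedom; a perfect nonlinear fit reports an
infinite F with p = 0 and a log note. Residual independence — the bootstrap's
assumption — is screened with the lag-1 Durbin–Watson statistic; values in
[1, 3] are taken as consistent with independence. The screen is advisory.

## Synthetic data and fixtures

The generator evaluates the closed form on a uniform, geometric or explicit
schedule and adds seeded Gaussian noise — additive and homoscedastic by
default (fractional noise by flag), clipped at 0 but allowed to exceed 1
slightly, as cumulative assays do. The generating parameters travel with the
curve for recovery studies. Synthetic curves emulate the *shape* and noise
scale of real release data, not assay-specific features: no systematic
drift, no heteroscedastic early-phase error, no inter-batch variability, no
carrier erosion. Passing recovery tests therefore demonstrates estimator
correctness under the model, not robustness to model misspecification.

The fixture library (`data/release_model_parameters.tsv`) transcribes all 60
published parameter sets (drug, carrier, condition, `k_S`, `k_off`, ΔG, time
unit) spanning liposomes, nanocapsules, nanoparticles, micelles and fibers,
including the four single-exponential rows that need no binding term. It is
shipped as reviewable delimited text, not code constants, and a checksum
test guards against drift. Three table rows carry ambiguous unit
superscripts in the source; they were resolved against the accompanying
narrative (fiber doxorubicin rates quoted per minute, fiber protein rates
per day, leaving the hollow-glass-fiber rows per hour).

## Study designs used in validation

* **Noiseless recovery**: each of the four exemplar triples sampled at 30
  log-spaced points on `[0.1/k_S, 3/k_off]` and refit; recovery is exact to
  optimizer tolerance (≪ 0.1%).
* **Noisy Monte-Carlo recovery**: 100 replicates of the category-I triple
  (ΔG = 4, k_S = 0.18, k_off = 0.002/day), 100 log-spaced points on
  `[0.1/k_S, 3/k_off]`, additive noise SD 0.02; success = all of ΔG, k_S,
  k_off within 10% relative error. The sampling density was set by a pilot
  power analysis so that per-parameter sampling SDs are about a third of the
  10% band — the study probes estimator correctness rather than the
  information content of a sparse schedule. **Limitation:** exemplars with
  small |ΔG| are information-limited for *relative* ΔG error — 10% of
  ΔG = 1 × 10⁻²¹ J is ±0.024 k_B T, a free-energy resolution below what
  SD-0.02 release data contain at any realistic sampling density (the
  sampling SD of ΔĜ is ≈ 0.18 × 10⁻²¹ J even at n = 100 with refits started
  at the truth). Absolute ΔG precision, not relative, is the meaningful
  target in that regime.
* **Bootstrap sanity**: zero-noise curves give bootstrap SDs at rounding
  level (≤ 10⁻⁶); seeded summaries are bitwise reproducible.

Problem sizes throughout (50-draw oracle sweeps, 100-replicate recovery,
1000-replicate bootstraps) were chosen as the smallest designs that give
stable, interpretable rates.

## Known limitations

* The model cannot represent three-phase (second-burst) profiles caused by
  carrier erosion or swelling, non-sink media, or time-varying rates.
* `k_S` is semi-phenomenological; fitted values absorb geometry effects
  (e.g. open fiber ends) that the two-state picture does not resolve.
* The knee heuristic assumes the burst is at least partially resolved by the
  sampling schedule; curves whose first sample already sits on the plateau
  carry little information about `k_S`.
* Bootstrap p-values are proportion-based with resolution `2/(B+1)`; they
  are not studentized or bias-corrected intervals.
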