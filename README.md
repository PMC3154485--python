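# relkin

Release kinetics of drugs (and other bioactive payloads) from nanocarriers —
liposomes, lipid and polymeric nanocapsules, nanoparticles, micelles, fibers
and hollow fibers — under **reversible drug–carrier binding**.

Controlled-release data almost universally show two phases: a fast *initial
burst* followed by slow *sustained release*. `relkin` implements the
three-parameter two-state model that captures both. Drug inside a carrier is
either *free* (molecularly dispersed, ready to leave by first-order
diffusion/convection under perfect-sink conditions) or *bound* (aggregated,
crystallised, complexed or adsorbed), with reversible first-order exchange:

```
dc_F/dt = -(k_S + k_on) c_F + k_off c_A
dc_A/dt =   k_on c_F - k_off c_A
```

starting from binding equilibrium, `c_F(0)/c_0 = k_off/(k_on + k_off)`.
The cumulative release is biexponential,

```
M_t/M_0 = a_1 (1 - e^{-λ₁ t}) + a_2 (1 - e^{-λ₂ t}),      a_1 + a_2 = 1,
```

where `-λ₁, -λ₂` are the eigenvalues of the linear system (the roots of
`λ² - (k_S + k_on + k_off) λ + k_S k_off = 0`). Instead of `k_on`, the model
is usually parameterised by the free-energy difference between the free and
bound states, `ΔG = -k_B T ln(k_on/k_off)` (reported in 10⁻²¹ J; `k_B T ≈
4.14 × 10⁻²¹ J` at 300 K): the magnitude of the burst is the logistic
function `1/(1 + e^{-ΔG/k_B T})`, so negative ΔG (strong binding) suppresses
the burst and favours sustained release.

The package provides:

* **`relkin.kinetics`** — the closed form, its eigenstructure, the limiting
  cases (pure single-exponential release when binding is negligible; the
  decoupled burst + sustained form when transport is much faster than
  binding), the ΔG ↔ rate mapping, and an independent ODE-integration oracle;
* **`relkin.estimation`** — burst/initial-rate/tail heuristics for starting
  values, bounded nonlinear least squares, nested-model selection between the
  full and single-exponential variants (extra-sum-of-squares F-test), and
  classification of profiles into the standard four categories (high/low
  burst × little-additional/steady-state release);
* **`relkin.bootstrap`** — case- or residual-resampling bootstrap of
  parameter distributions (mean, SD, p-values), an F-test against a linear
  trend, and a Durbin–Watson residual-independence screen;
* **`relkin.synthetic`** — model-faithful noisy curve generation, a fixture
  library of 60 published parameter sets across 16 carrier systems, and the
  four canonical category exemplars;
* **`relkin.io` / `relkin.cli`** — delimited-text release tables with unit
  metadata and a `relkin` command with `simulate`, `fit`, `bootstrap` and
  `classify` subcommands.

## Worked example

Simulate a low-burst, steady-release system (category IV: ΔG = −5 × 10⁻²¹ J,
k_S = 0.36/day, k_off = 0.013/day), sampled at 25 log-spaced times over 230
days with additive noise (SD 0.02), then fit it:

```sh
$ relkin simulate --delta-g -5 --k-s 0.36 --k-off 0.013 --time-unit day \
    --horizon 230 --n-points 25 --spacing log --noise-sd 0.02 --seed 11 \
    --out release.csv
$ relkin fit release.csv
variant: full
time_unit: day
k_S_per_day: 0.330366
k_off_per_day: 0.0120939
k_on_per_day: 0.0368359
delta_G_1e-21J: -4.61318
sse: 0.00701984
r_squared: 0.996329
n_obs: 25
variant_f_statistic: 233.687
variant_p_value: 1.51568e-15
category: IV
```

The fit selects the full three-parameter model (the F-test against the
nested single-exponential variant is decisive), recovers the generating
parameters within the noise-limited uncertainty, and classifies the profile
as category IV: the equilibrium free fraction `1/(1+e^{5/4.14})` ≈ 23% (a low
burst) and `k_off × horizon ≈ 3` (meaningful depletion of the bound pool
within the observation window). Bootstrap inference quantifies that
uncertainty:

```sh
$ relkin bootstrap release.csv --replicates 1000 --seed 7
...
k_S_estimate: 0.330366
k_S_boot_mean: 0.330419
k_S_boot_sd: 0.0579486
k_S_p_value: 0.001998
delta_G_1e-21J_estimate: -4.61318
delta_G_1e-21J_boot_mean: -4.5605
delta_G_1e-21J_boot_sd: 0.336225
f_statistic_vs_linear: 994.168
f_test_p_value: 8.32103e-20
durbin_watson: 2.38013
residuals_independent: True
```

All four parameters are significant (bootstrap p ≈ 0.002, the resolution of
1000 replicates), the model beats a straight line overwhelmingly, and the
residuals show no lag-1 autocorrelation. Fixture curves can be simulated by
name, e.g. `relkin simulate --fixture "dox base" --out dox.csv` for the
hydrophobic-doxorubicin / poly(L-lactide)-fiber parameter set.

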