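# Methods

## The regulatory model

The simulator integrates a three-state polynomial ODE for insulin (`x1`),
glucose (`x2`) and β-cell (`x3`) concentrations (all dimensionless). Each
right-hand side is a sum of monomials, one rate constant per monomial,
including a logistic glucose term `w11·x2·(1−x2)` and a glucose–β-cell
cross term `−w19·x2·x3`. The nominal constants put the system in a bounded,
strongly initial-condition-sensitive regime; the four disorder presets each
sweep one constant through four values:

| scenario          | constant | values                  |
|-------------------|----------|-------------------------|
| type2             | w8       | 0.5, 0.2, 0.42, 0.3     |
| hypoglycemia      | w1       | 1.3, 1.7, 1.8, 2.04     |
| hyperinsulinemia  | w7       | 1.9, 2.01, 2.5, 3.1     |
| type1             | w15      | 0.16, 0.3, 0.25, 0.13   |

All trajectories start from `x0 = (0.53, 1.31, 1.03)`.

**Finite-time escape and the sampling step.** The disorder vector fields
are cubic and not globally bounded: from `x0`, the `w1 = 1.3` system
escapes to infinity near `t ≈ 23` and the `w15 ∈ {0.16, 0.13}` systems
near `t ≈ 10.6` (confirmed with an adaptive high-accuracy solver, not an
artifact of the fixed-step integrator). A disorder segment is 1002 samples,
so the default step `dt = 0.005` (segment horizon 5.01 time units) keeps
every mandated parameter value at least a factor two inside its bounded
window while retaining visibly irregular dynamics (per-segment glucose
standard deviation 0.26–0.49). `dt` is exposed everywhere; a blow-up guard
(`|x| > 1e6`) converts divergence into a clear error naming the failing
step.

**Integrator.** Fixed-step classical RK4: deterministic, bit-reproducible,
and order-testable (the suite checks the error-halving ratio is ≈ 2⁴
against a 10× finer reference). Adaptive or stiff stepping is deliberately
out of scope; datasets must be byte-identical across runs.

**Datasets.** Each of a scenario's four parameter values is simulated for
`samples_per_value + 2` states (two states feed the lags) restarting from
`x0` (a flag chains segments instead). Rows are
`[x1(k), x1(k−1), x2(k), x2(k−1), x3(k), x3(k−1)] → x2(k+1)`; segments are
concatenated in preset order and split 70/30 into contiguous train/test
partitions (4000 rows → 2800/1200 at the default segment length). The
generation is noise-free and fully deterministic; the `seed` argument is
recorded in the CSV sidecar only to tie downstream stochastic training
runs to their input.

## Identifier architectures

* **FRNN** (5 tanh hidden units): `net = Wᴵx + WʳYᴴ(k−1)`, dense `Wʳ`,
  linear output `ŷ = Wᴼ·tanh(net)`. No hidden biases.
* **DRNN**: same, with `Wʳ` restricted to a diagonal (self-feedback
  gains). A DRNN is exactly an FRNN with diagonal recurrence, and the
  tests hold the two implementations to bit-equality.
* **DFNN** (6–28–1): sigmoid hidden layer with biases, linear output with
  bias; stateless.

Weights initialize uniform(−0.5, 0.5), seeded — small enough to keep tanh
units in their responsive region for inputs of order one.

**Gradients** are the depth-1 truncated chain rules of per-sample online
training: `∂E/∂Wᴼ_m = −e·Yᴴ_m`, `∂E/∂Wᴵ_ml = −e·Wᴼ_m·F′(net_m)·x_l`, and
the recurrent partials use the *frozen* previous hidden state (its own
dependence on the weights is not back-propagated). The finite-difference
oracle in the tests applies the same truncation. Full backpropagation
through time is a non-goal.

## The fractional-order learning rule

The continuous descent flow `dθ/dt = −η ∂E/∂θ` generalizes to fractional
order `α ∈ (0, 1]` via the Grünwald–Letnikov derivative. Discretizing with
step `h` and solving for the newest value gives the update implemented in
`fo_learning.fo_update`:

```
θ(k+1) = −η ∂E/∂θ · hᵅ − Σ_{j=1..J} C_j θ(k+1−j),   J = min(k+1, memory_length)
```

with `C_0 = 1`, `C_j = (1 − (α+1)/j) C_{j−1}` — the alternating binomial
coefficients of `(1−z)ᵅ`, checked against the Gamma closed form to 1e−10.
At `α = 1, h = 1` the coefficients collapse to `(1, −1, 0, …)` and the rule
is plain gradient descent *bit for bit* (asserted over full training runs).
Defaults: `h = 1` (so `hᵅ = 1`), `memory_length = 50`, per-layer rates.

**Equilibrium bias of the truncated rule.** For `j ≥ 1` the memory weights
`−C_j` are positive and sum to `1 − P_J`, where `P_J = Σ_{j≤J} C_j > 0` is
the truncated binomial partial sum, decaying only like `J^(−α)`. Every
update therefore leaks a fraction `P_J` of the held weight value: a weight
survives only under persistent gradient pressure, and training equilibrates
where `η·|∂E/∂θ|·hᵅ ≈ P_J·|θ|` instead of at a stationary point of the
cost. At `α = 0.3109` the leak is `P_50 ≈ 0.23` (memory 50) and still
`P_2800 ≈ 0.065` with full history — the scalar-quadratic check in the
development analysis reproduces the predicted biased fixed point to three
digits. Consequences, measured by the experiment suite: the FO-trained
networks plateau at a training RMSE far above the gradient-descent
baselines (≈ 0.35 vs ≈ 0.02 on the type-2 case), and no epoch budget or
memory length removes the gap, because the leak is structural. The package
implements the rule exactly as defined and reports what it does; the
acceptance suite documents the resulting model ordering rather than
adjusting the rule to flatter it.

## Learning rates and stability

A one-step Lyapunov argument on `L = ½e²` with the exact Taylor step gives
the stable band `0 ≤ η ≤ 2/‖∂ŷ/∂θ‖²` for the parameter block being
updated. Two consequences shape the implementation:

* The band is *per update block*. Applying `2/g²` to every scalar weight
  simultaneously is far outside the joint stability region and empirically
  diverges within tens of samples. Adaptive mode therefore treats θ as the
  full stacked parameter vector and uses `η = min(μ/‖∂ŷ/∂θ‖², η_cap)` with
  `μ = 1`: the one-step error change is `e ← e·(1 − η‖g‖²)`, which the
  band edge `μ = 2` merely sign-flips, while `μ = 1` is the quadratic
  minimum of the one-step decrease. `adaptive_rate_bound` exposes the band
  edge itself (`min(2/g², cap)`, with the cap absorbing `g → 0`).
* Fixed mode (the default) uses the preset per-layer rates listed in
  `experiments.MODEL_PRESETS`. The DRNN-FO preset (`η = 0.77/0.55/0.97`)
  sits outside the joint band at five hidden units and diverges on every
  seed tried; the comparison drivers record such runs as diverged
  (infinite RMSE, an explanatory `error` string) rather than crashing.

Training (`train_online`) iterates samples in order, resets the hidden
state at each epoch boundary and before any evaluation pass (so evaluation
never leaks training history), keeps one GL ring buffer over the stacked
parameter vector, and raises a located error if any weight magnitude
exceeds 1e6.

**Protocol.** The experiments layer trains for 30 online passes
(`DEFAULT_EPOCHS`): the per-epoch training-RMSE traces of the
gradient-descent models flatten by roughly then at the preset rates, while
a single pass leaves every model visibly underfit. `TrainingConfig`
defaults to a single pass for direct library use; an explicit config owns
its pass count.

## Metrics and uncertainty

RMSE and `FIT% = (1 − ‖y−ŷ‖₂/‖y−mean(y)‖₂)·100` are evaluated per
partition (Euclidean norms over the evaluated partition; FIT% is undefined
for a constant observed series and says so). For uncertainty, a linear
quantile regression `y = a_τ·ŷ + b_τ` is fitted at τ = 0.05 and 0.95 by
minimizing the pinball (check) loss — the asymmetric *absolute* loss whose
minimizer is the conditional quantile; a squared variant would not yield
coverage semantics. The fit is delegated to statsmodels' quantile
regression (IRLS); a constant predictor degrades to an intercept-only fit
at the empirical quantile, with a warning. The band is fitted on the
training partition and applied to both (a flag refits per partition);
crossing quantile lines are reordered elementwise. PICP is the *fraction*
of observations strictly inside the band and MPI the *mean* width — both
normalized by the sample count so they are a probability and a width.
On the type-2 training residuals of the featured model the 5–95% band
covers ≈ 0.90, and simulated Gaussian-residual checks at n = 2000 bound
coverage in [0.86, 0.94].

## What the generator does and does not emulate

The synthetic data are exact (noise-free) trajectories of the stated ODE
under the stated parameter sweeps — the study conditions themselves, not a
proxy for clinical measurements. There is no measurement noise, no unit
calibration (mg/dL etc.), no inter-patient variability, and the disorder
labels index parameter shifts, not diagnoses. Passing tests therefore
demonstrate properties of the identification algorithms on this dynamical
system, and nothing about real physiological recordings.

## Numerical choices and degenerate inputs

* RK4 convergence asserted via the halving-ratio window [12, 20].
* GL recursion vs Gamma closed form: 1e−10 relative, j ≤ 30.
* Finite-difference gradient oracle: central differences, 1e−6 relative.
* The truncated GL coefficient sum `Σ_{j≤n} C_j → 0` like `n^(−α)`: slow
  for small α (0.146 at α = 0.3109, n = 200) — the basis of the leak
  analysis above, and a warning against assuming short memory is cheap.
* Degenerate inputs fail loudly: non-finite parameters or states, constant
  observed series in FIT%, constant predictor in quantile fits, empty
  weight histories, dimension mismatches.
* Determinism: simulation is seed-free and exact; training randomness is
  confined to seeded weight initialization; repeated runs are
  byte-identical (asserted on written CSVs).

## Known limitations

* One-step-ahead identification only; free-running (recursive) prediction
  is not evaluated.
* Depth-1 gradient truncation understates recurrent credit assignment.
* The FO rule's equilibrium bias (above) is inherent to its truncated GL
  memory over weight values; variants that apply fractional memory to
  gradients, or compensate the truncated tail, are out of scope.
* The quantile band assumes a linear predicted-observed relation per
  quantile.
* Problem sizes in tests are scaled down where a property does not need
  the full 4000-sample study (segment lengths of 15–50); the acceptance
  suite and script run the full size.
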