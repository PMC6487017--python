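# Methods

## Model

Circuits are systems of `N` coupled ODEs for dimensionless transcription
factor concentrations `y_i`, normalised to their maximal level. The
canonical (additive) variant is the non-dimensional form

    dy_i/dt = k_i ( φ(Σ_j W_ij y_j) + I_i − y_i )

in which the decay rate `k_i` scales the whole bracket, i.e. it sets the
time-scale of gene `i`. A switch (`k_on_decay_only`) selects the
alternative convention `dy_i/dt = φ(Σ_j W_ij y_j) + I_i − k_i y_i` in
which `k` scales only the linear decay; the two coincide for `k = 1`. The
nonlinearity is the logistic `φ(x) = 1/(1+e^{−x})`: transcription is
always positive, saturates at strong activation, and `φ(0) = 1/2` sets the
basal rate of an unregulated gene. Two extensions:

- **Dimer decay** adds a pairwise degradation channel `− y_i Σ_j Γ_ij y_j`
  with `Γ` symmetric and non-negative (each dimer pair `(i, j)` drains
  both partners at rate `Γ_ij y_i y_j`): the dimer loss of species `i` is
  summed over all partners `j`, and the input term is kept so driven nodes
  remain usable. `Γ` is learnable
  by default in this variant, starting from zero, with symmetry and
  non-negativity re-imposed after every update.
- **Repressor product** replaces additive regulation by a product of
  independent Hill repressors `Π_j 1/(1+(W_ij y_j)^n)` with `n = 3` by
  default; `W` is then a matrix of non-negative repressor strengths,
  enforced at construction and re-projected after every update.

Inputs are routed onto gene 1 and the readout is the last gene, unless a
circuit says otherwise. Inputs are piecewise-constant on the solver grid
(left-continuous); rectangular pulse edges snap to the nearest step
boundary so grid-aligned pulses cover exactly `duration/dt` steps.

## Solver and gradients

Fixed-step Euler, `y_{n+1} = y_n + f(y_n, t_n) δt` with `δt = 0.01`
throughout. No positivity clipping is applied: with the bounded production
terms and this step size, states stay non-negative up to transient
overshoots; a diagnostic warning fires if any state falls below `−10·δt`.
A state that leaves the finite range aborts the run with the offending
step index. Trajectories may be recorded on a thinned grid
(`record_every`), but the recurrence always advances at `δt`.

Gradients of a scalar cost with respect to all learnable parameter groups
(`W`, `k`, `y0`, the readout scale `A`, and `Γ`) are computed by
reverse-mode differentiation of the unrolled recurrence — the discrete
adjoint of the Euler scheme, hand-derived per model variant and
JIT-compiled. This gives machine-precision gradients at a cost comparable
to one extra simulation, independent of the parameter count (forward
sensitivities or finite differences would cost one simulation *per
parameter*). The independent oracle is the central finite-difference
estimator `(C(p+h) − C(p−h))/2h`, implemented alongside; the test-suite
requires agreement to 1e−4 relative / 1e−6 absolute on batches of random
circuits of every variant. Batches of input cases are integrated side by
side in a single kernel call.

## Costs

- Endpoint squared error `Σ_x (A·y(x) − ŷ(x))²`, with `A` a learnable
  rescaling of the readout (relative rather than absolute levels are what
  matter biologically).
- Trajectory target `Σ_t (y(t) − A_osc cos(ωt))²` over the recorded grid,
  for oscillator design. `A_osc` is a fixed target amplitude; the
  learnable scale is off here and the phase is absorbed by learnable
  initial conditions instead.
- Binary cross-entropy on the rescaled readout, clamped to
  `[1e−7, 1 − 1e−7]` so the loss is total on all real outputs.
- L1 penalty `λ Σ_ij |W_ij|` on the interaction weights only (a flag
  extends it to `k`); its subgradient at exactly 0 is taken as 0 so that
  pruned weights feel no penalty pressure.

## Optimisation

Adam with `l_r = 0.1`, `b1 = 0.02`, `b2 = 0.001`, `e = 1e−8`. The
`(b1, b2)` values are used **directly** as the moment decay rates
(`parameterization="decay"`, the default): the moments are then nearly
memoryless and each update approaches `l_r · sign(g)` with a per-parameter
adaptive scale. In our experiments this short-memory setting is what makes
the harder design objectives trainable — it escapes the broad plateaus of
the stripe, oscillator and counter cost landscapes where long-memory Adam
and classic gradient descent stall — at the price of limited fine
convergence on easy objectives (the step magnitude is pinned near `l_r`).
`parameterization="decay_complement"` maps `β = 1 − b` (i.e. 0.98/0.999),
recovering conventional long-memory Adam, which converges finely and is
the better choice for the simple switch objective. Classic gradient
descent (`δp = −l_r ∂C/∂p`) is provided for comparison.

Training iterates: draw a batch of `B` cases without replacement
(`B = min(16, n_cases)` by default; reshuffle when the pool is exhausted),
compute the adjoint gradient of batch cost + L1 penalty, take one
optimizer step, re-project constraints, and record the **full-data** cost.
The trace records full-data cost (not batch cost) because the
iterations-to-cost metric `N(C)` — the first iteration at which the cost
reaches level `C` — is too noisy on batch costs. An optional `stop_cost`
ends a run once the full-data cost reaches a floor; budgets below state
"up to" iteration counts for this reason. One Adam state is created per
training stage; the regularisation and pruning stages are fresh
re-implementations of the optimisation and reset it.

The pipeline then sparsifies: re-train under an ascending ladder of `λ`
values (each stage warm-starts from the previous), pick a candidate with
`select_network` (the sparsest network whose data cost is within 2× of the
least-regularised stage — `λ` is ultimately a user choice and all
candidates are returned), prune weights with `|W_ij| < ε` to exactly zero
(the magnitude is compared, not the signed value, so learned repressions
survive), freeze them via a mask, and re-fit the survivors at `λ = 0`.

## Task generators and default study conditions

All generators are pure functions of their arguments and seed. Exact task
dimensions are free choices of this package, set once to realistic
desk-scale values:

| Task | Inputs | Target | Defaults |
|---|---|---|---|
| Switch | static levels, uniform grid | 1 if `x ≥ x*` else 0 | 11 levels on [0,1], `x* = 0.5`, `T = 10` |
| Stripe (French flag) | static levels | 1 inside band, else 0 | 11 levels, band [0.3, 0.7], `T = 10` |
| Duration detector | one rectangular pulse from `t = 0` | 1 iff duration strictly exceeds critical | 8 log-spaced durations 0.5–8, critical 2, judged 4 time units after the longest pulse |
| Oscillator | zero input | `A_osc cos(ωt)` trajectory | `A_osc = 1`, `ω = 0.5`, `T = 40` (≈3.2 periods), `k` and `y0` learnable |
| Counter | stochastic pulse trains | endpoint = pulse count | 40 trains of 1–5 pulses, amplitude and duration uniform in [0.5, 1.5] (±50%), gaps in [1, 3], `T = 30`, 5 nodes, `k` learnable |

Boundary conventions (`≥` at the switch threshold, strict `>` at the
critical duration, inclusive band edges up to grid round-off) are fixed
and documented here; pulse trains use rectangular pulses with uniform
draws. The naive counting baseline divides the integrated input by the
reference pulse area `a0·d0`; its error grows in proportion to
amplitude/duration variability, which is what the learned counter is
measured against on a held-out ensemble.

Per-task optimizer settings: endpoint tasks train at the default
`l_r = 0.1`. The oscillator trains at `l_r = 0.05` and the counter at
`l_r = 0.01`: their costs sum over thousands of recorded residuals (or
count-scale targets), so they are one to two orders of magnitude larger
than endpoint costs and the sign-like step at `l_r = 0.1` overshoots the
oscillatory/excitable solutions. `k` is fixed at 1 for the switch, stripe
and duration tasks and learnable for the oscillator and counter, where the
solution needs per-node time-scales.

## Baselines

The evolutionary algorithm and the random screen optimise the identical
cost on the identical model. Evolution: population 20, truncation
selection of the best 25%, refill by mutating random survivors with
`Normal(0, 0.1)` weight noise. Screen: i.i.d. `W ~ Normal(0, 1)` draws,
running minimum. Comparisons are indexed by cumulative cost evaluations;
one gradient iteration is charged as 2 evaluations (one forward pass plus
one adjoint sweep of comparable expense; configurable), since the fair
abscissa is compute, not iterations.

## What the synthetic tasks do and do not show

The generators emulate idealised experimental drives: noiseless static
morphogen levels, perfectly rectangular pulses, exact binary or count
targets. Real inputs carry measurement noise, ramped edges and
cell-to-cell variability, and real outputs are stochastic; passing these
tasks demonstrates that the optimisation machinery can discover circuit
mechanisms (ultrasensitivity, irreversible activation, limit cycles,
excitable off-detection), not that a specific learned parameter set would
function quantitatively in vivo. Learned topologies are seed- and
λ-dependent; distinct seeds may find distinct mechanisms with similar
cost.

## Numerical choices and limitations

- `δt = 0.01` with `k` floored at `1e−3` (and `A` at `1e−6`) keeps the
  explicit Euler map stable for the learned parameter ranges; `k` above
  `2/δt` would make it expansive, which the solver reports as overflow.
- Finite-difference checks use `h = 1e−5` and central differences;
  Hill-variant probe circuits keep weights away from the `W ≥ 0` boundary
  so the symmetric perturbation stays feasible.
- Training is first-order and non-convex: a minority of seeds stall in
  local minima (e.g. monotone responses instead of a stripe). This is
  inherent to the method; medians over seeds are the meaningful statistic,
  and multiple restarts are the practical remedy.
- Only fixed-step explicit Euler is implemented; stiff circuits (very
  large learned `k`) would need an implicit or adaptive solver. No
  stochastic (Gillespie) simulation, no delay equations, no spatial/PDE
  coupling, no fitting to experimental data.
- Test-suite and script problem sizes (5–10 seeds per condition, a
  24-train counter ensemble, evaluation budgets of ~10³) are chosen to
  keep a full run in minutes on one CPU while leaving the measured
  orderings unambiguous.
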