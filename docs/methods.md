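# Methods

## Reactor model

The environment is a tubular (plug-flow) reactor carrying out the
irreversible bimolecular condensation of benzylamine (1) and benzaldehyde
(2) to the imine *N*-benzylidenebenzylamine (3) in methanol. Modeling
assumptions: homogeneous single-phase reaction, no axial dispersion,
constant mixture density, feed temperature equal to the initial reactor
temperature, constant overall heat-transfer coefficient, heat produced only
by reaction and removed only by the jacket, and 100% selectivity (the model
carries a single reaction; no side products).

Feeds: two 4 mol/L stocks are mixed at the inlet. The equivalent ratio
ER = Q₁/Q₂ sets the inlet concentrations c₁f = C_s1·ER/(1+ER),
c₂f = C_s2/(1+ER); with equal stocks c₁f + c₂f = 4 mol/L, so the largest
attainable product concentration is 2 mol/L at ER = 1. Residence time is
Res_t = V/Q with V = 1.32 mL.

Kinetics: r = k·c₁·c₂ with k = k_ref·exp(−Eₐ/R·(1/T − 1/T_ref)),
Eₐ = 21.57 kJ/mol and k_ref = 0.413 L mol⁻¹ min⁻¹. The reference
temperature that defines k_ref is not part of the calibrated parameter set;
the package fixes T_ref = 298.15 K and exposes it in configuration — k_ref
is only meaningful relative to the chosen T_ref.

Species balances: ∂cᵢ/∂t = −v_z ∂cᵢ/∂z ± r with v_z = L/Res_t and inlet
boundary cᵢ(0) = cᵢf. Energy balance (optional, on by default):

ρC_p ∂T/∂t = −v_z ρC_p ∂T/∂z + r·ΔH_react + UA·(T_c − T)

with ΔH_react = 160 kJ/mol treated as an exothermic release (positive
generation term), UA = 100 W/K over the 1.32 mL reactor volume, and the
coolant held at the set point, T_c = T_f (the jacket maintains the set
temperature; no separate coolant temperature is modeled). The volumetric
heat capacity ρC_p is computed as Σ cᵢ·C_p,i over all species including the
solvent, with the solvent concentration obtained by mass difference from
the constant density (800 kg/m³) and the species molar masses
(107.15, 106.12, 195.26, 32.04 g/mol); a single scalar override
(`heat_capacity_vol`) replaces this composition-based value when desired.
Because UA per unit volume is very large (≈75 kW L⁻¹ K⁻¹), the computed
temperature rise at any admissible condition is below 1 mK — the reactor is
effectively jacket-pinned, and the isothermal closed form is an excellent
approximation everywhere in the decision box.

Two Arrhenius evaluation modes exist: `local-temperature` (default;
kinetics evaluated at the local T(z), the physically standard choice) and
`feed-temperature` (kinetics evaluated at T_f throughout, reproducing the
literal rate-law statement). With the jacket-pinned temperature profile the
two differ by well under 0.1%.

## Numerics

* **Transient route** (`simulate`): method of lines on a uniform axial
  grid, first-order upwind advection, inlet node held at the feed state,
  stiff BDF integration with a banded Jacobian sparsity pattern.
  Integration proceeds in chunks of one residence time up to ten residence
  times; steady state is declared when the maximum time derivative falls
  below 1e-8. Default 400 axial nodes: first-order upwinding at the
  spec-sheet-style 50 nodes carries ≈0.3% discretization error at the
  strongest-conversion corner, while 400 nodes bring it to ≈0.04%,
  comfortably inside the 0.1% tolerance we hold the solver to against the
  closed form. Tolerances rtol 1e-7 / atol 1e-9.
* **Steady-state route** (`steady_state_outlet`): direct integration of
  dcᵢ/dz = ±r/v_z (plus the temperature analogue) with adaptive LSODA,
  rtol 1e-8 / atol 1e-10. This grid-free path is ~100× faster and is what
  the optimizers and the RL environment call.
* **Closed form** (`analytic_isothermal_outlet`): the exact solution of
  the isothermal bimolecular system, written via `expm1` for unequal feeds
  and the 1/(a₀−x) − 1/a₀ = k·t form for equal feeds, with a branch switch
  at |c₁f−c₂f| < 1e-10. It serves as the independent oracle for both ODE
  routes and as the fastest environment evaluator (`evaluator="analytic"`),
  valid because the temperature profile is jacket-pinned.

Conservation (c₁f − c₁ = c₂f − c₂ = c₃ at every node) holds to the solver
tolerance by construction of the single-reaction stoichiometry and is
asserted in the tests.

## Reward

The hybrid reward normalizes the outlet product concentration by the
running extremes experienced during training (global across episodes, not
per-episode) and applies a +100 bonus above 1.6 mol/L and a −15 penalty at
or below 1.2 mol/L. The tracker starts empty (±∞ sentinels) and must see a
concentration before the first reward; a degenerate tracker (max = min)
returns 0 through a 1e-9 guard instead of NaN. Thresholds and offsets are
configuration constants.

## Agent

State: the three decision variables min-max scaled to [−1, 1] plus the
latest outlet c₃ scaled by 2 mol/L — the richer feature sets one could add
(gradients, condition history) are deliberately excluded. Actions are
bounded increments: each component of the actor output in [−1, 1] moves its
variable by at most 20% of that variable's range per step, and the
resulting conditions are clipped to the box. Episodes run 10 steps from
uniformly random initial conditions; `done` is flagged only at the horizon
and the target is not bootstrapped past it.

Networks: actor 4→64→64→3 with ReLU hidden layers and tanh output; critic
processes the state through one 64-unit layer, concatenates the action, and
applies a second 64-unit layer before the linear Q head. Hidden layers use
uniform fan-in initialization; output layers start in ±3e-3 so early
policies and values are near zero. Both networks are plain numpy with
manual backpropagation (verified against finite differences in the tests)
and Adam updates — at this size a tensor framework would add nothing but a
dependency.

Updates: exactly one critic step (minibatch TD error against the target
networks), one actor step (deterministic policy gradient through the
critic's action input), and one soft target update per environment step,
starting once the replay buffer holds one batch (64). The soft update uses
θ′ ← τθ + (1−τ)θ′, the convention in which larger τ makes the target track
the main network faster; the opposite (literal) convention is available
behind `literal_soft_update` for comparison. Default hyperparameters are
the Bayesian-optimization tuned set (α_critic 0.00043, α_actor 0.002,
γ 0.961, σ_e 0.1019, τ 0.0004).

Exploration: Ornstein–Uhlenbeck noise per action dimension
(θ = 0.15, μ = 0, dt = 1, σ = σ_e), reset to the mean each episode; or an
ε-greedy policy that takes a uniform random action with probability
ε = ε_min + (1−ε_min)·exp(−λ·N_t) — exponential decay in the global step
count, with a probability-ε uniform action being the natural continuous-
space reading of ε-greedy.

The environment evaluates the outlet once per episode reset (to form the
initial state) and once per step, so a 100×10 training makes 1100 outlet
evaluations, all logged.

## Adaptive schedule

HP_t = max(HP_max − α·A_t, HP_min) with progress metric
A_t = N_total·Ep_t + N_t. Scheduled quantities and endpoints: exploration
noise σ_e 0.1 → 0.01, and the two learning rates from one tenth of their
search-range ceiling to one tenth of the floor (α_critic 0.002 → 2e-5,
α_actor 0.001 → 1e-5) — the schedule endpoints are package choices, since
only the scheduled quantities (noise and learning rates) are prescribed.
The decay rate α defaults to reaching the floor at 80% of total training
steps. The schedule is strictly non-increasing in training progress and
respects its bounds exactly.

## Hyperparameter search

`bayesian_search` is a self-contained tree-structured Parzen estimator:
after a uniform startup phase, completed trials are split at the top
quantile (default 25%), per-dimension Parzen mixtures l(x) and g(x) are fit
to the good and remaining sets (each mixed with a uniform prior component),
candidates are drawn from l and the candidate maximizing log l − log g is
evaluated next. Learning rates, σ_e and τ are searched in log space. Failed
objectives mark their trial failed and the search continues. The default
scalar objective of a training run is the mean cumulative reward over the
final 20% of episodes (`best-c3` and reward-curve area are selectable) —
the objective metric is a package choice, as is the scaled-down default
budget (15 trials of 30-episode trainings; the full-scale budget is one
configuration key away).

## Baselines and benchmarking

Nelder–Mead runs scipy's downhill simplex with candidates projected onto
the box before evaluation (a penalty-free projection treatment; the simplex
itself is the textbook algorithm and is deterministic for a fixed start).
The branch-and-fit optimizer is a simplified SNOBFIT-style method — seeded
Latin-hypercube design of 10·dim points, then alternating local steps
(diagonal quadratic surrogate fitted to the incumbent's neighbors,
maximized in a ±15%-of-range trust box) and exploration steps (maximin
points over the box) — not a bit-exact re-implementation of the published
SNOBFIT code. The grid search oracle evaluates the full Cartesian product
and is used for dominance and proximity checks.

"Number of experiments" is standardized across all methods to the number of
outlet evaluations, counted exactly by a budgeted wrapper that logs every
point; a method's reported best is by construction the argmax of its logged
trajectory. In the benchmark harness the agent runs a scaled-down training
(20 episodes → 220 evaluations) so its budget is comparable to the
gradient-free budgets (Nelder–Mead 200, branch-and-fit 250).

## Synthetic kinetics data

`generate_synthetic_profiles` emulates the temperature-controlled outlet
experiments: steady-state outlet c₂ (benzaldehyde) and c₃ (imine) at 12
residence times spanning [0.5, 8] min under each of 288, 298, 313 and
318 K, with the energy balance off (the experiments hold the reactor at the
set temperature) and equimolar feeds. Multiplicative Gaussian noise
(default 2% relative) is applied and clipped at zero. The generator
reproduces the *design* of the real experiments, not their chemistry: real
measurements carry spectroscopic calibration error, drift, and possible
side-reaction bias that multiplicative i.i.d. noise does not represent, so
parameter-recovery results demonstrate estimator correctness, not
instrument-grade accuracy.

The estimator fits (Eₐ, log k_ref) with T_ref fixed, by trust-region least
squares on the stacked c₂ and c₃ residuals; bounds Eₐ ∈ [1, 100] kJ/mol,
k_ref ∈ [1e-3, 10]. Its forward model is the isothermal closed form —
deliberately a different code path from the ODE generator, so noise-free
self-consistency (recovery to <1e-4 relative) is a genuine cross-check.
Standard errors come from the Gauss–Newton covariance at the optimum.
Steady-outlet-versus-residence-time data are fitted; fitting transient
profiles instead would require only replacing the forward model.

## Problem sizes and validation scales

The solver/oracle equivalence is verified on a 5×5×5 condition grid; the
reported global optimum by a 20×20×20 grid search (8000 steady-state
solves, about a minute); kinetics recovery on the 4×12 design at 2% noise
(median relative error across 10 seeds < 3%); DRL convergence over 5 seeds
of 100 episodes against the same grid oracle, using the analytic evaluator
(jacket-pinned temperatures make it equivalent to the ODE route to ~1e-9).
These sizes were chosen so the whole validation runs in a few minutes while
each check remains at full methodological strength.

## Known limitations

* No axial dispersion, laminar profile, pressure drop or multi-reaction
  network; the 100%-selectivity assumption makes c₃ equivalent to
  conversion.
* The jacket-pinned energy balance means the temperature field is almost
  inert in this parameter regime; the energy-coupled machinery is exercised
  but cannot be stress-tested against data here.
* DDPG with the tuned (very small) critic learning rate and target update
  rate learns slowly by deep-RL standards; a minority of seeds converge to
  a suboptimal corner of the decision box. This is a property of the tuned
  configuration, reflected honestly in the ≥3-of-5-seed convergence
  criterion; the adaptive learning-rate schedule mitigates it.
* The branch-and-fit optimizer shares SNOBFIT's ideas, not its exact
  branching rules; evaluation counts are not comparable to published
  SNOBFIT iteration counts.
* Reported "experiments" counts are environment evaluations; counts quoted
  elsewhere under other conventions (per-episode, per-iteration) are not
  directly comparable.
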