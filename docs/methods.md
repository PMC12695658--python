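# Methods

## Model

A neuron is a tree of cylindrical compartments.  Each compartment `i`
carries a membrane potential `V_i` (mV) obeying the spatially discretized
cable equation

    C_i dV_i/dt = − Σ_c ḡ_c A_i p_c(V_i)(V_i − E_c)
                  − Σ_s g_syn,s s_s (V_i − E_syn,s)
                  + Σ_j g_ax,ij (V_j − V_i) + I_ext,i

where `C_i = Cm·A_i` is the compartment capacitance, `A_i = 2π a_i l_i` its
lateral area, `p_c` the open fraction of channel `c` (product of gate
variables raised to integer powers), and the axial coupling between
adjacent compartments is `g_ax,ij = 1/(R_i/2 + R_j/2)` with the
half-compartment axial resistance `R/2 = Ra·(l/2)/(π a²)`.  Junction nodes —
explicit zero-area voltage nodes inserted at branch points — carry no
membrane; their equation is pure current balance.

Units are fixed package-wide (mV, ms, μm, S/cm², μF/cm², Ω·cm, nA, nS, MΩ)
and chosen so per-node capacitance in nF and conductances in μS satisfy
`μS·mV = nA` and `nF/ms = μS` with no further constants; the conversion
table lives in `cablegrad.units` and is pinned by the passive analytic
tests (RC step response, steady-state cable attenuation against
`exp(−x/λ)`, `λ = √(a·R_m/(2·Ra))`).

### Channels and synapses

The default channel kit is the canonical squid-axon set: Na (m³h),
K (n⁴) and ohmic leak, with `E_Na = 50`, `E_K = −77`, `E_leak = −54.3` mV
and default densities 0.12 / 0.036 / 0.0003 S/cm²; no temperature scaling.
The removable singularities of the linoid rate terms `x/(1−exp(−x/k))` are
evaluated with `expm1` and replaced within `|x/k| < 1e−4` by their 4th-order
Taylor expansion; both branches are finite everywhere, so reverse-mode
gradients are defined through the `where`-selection.

Synapses use first-order transmitter–receptor kinetics: the steady-state
activation is a logistic function of presynaptic voltage (threshold
−35 mV, slope 10 mV — the classic published constants; both configurable
because the originating formulation leaves them free) and the relaxation
time constant is `(1 − s̄)/k₋`, where `k₋` (1/ms) is the dissociation rate.
The postsynaptic current is `g_syn·s·(V_post − E_syn)`.

## Numerics

One step is operator-split:

1. gates and synaptic activations advance by **exponential Euler** using
   the voltage at the start of the step — exact for frozen voltage, and
   structurally incapable of leaving [0, 1];
2. voltages advance by one **implicit (backward) Euler** step with
   conductances frozen at the updated states.  Synaptic conductances enter
   the matrix diagonal (implicit in `V_post`), with the driving term
   `g·s·E_syn` on the right-hand side, so the linear solve remains exact
   for synapses.

The implicit system is symmetric, diagonally dominant and tree-structured.
It is solved exactly in linear time by elimination from the leaves onto
branch points and back-substitution (the elimination order a compartment
tree admits).  Stand-alone tridiagonal solvers are provided for unbranched
cables: serial Thomas elimination, and a recursive-doubling solver that
expresses elimination, forward and back substitution as O(log n) stages of
parallel-prefix scans (continuants of the LU recurrence as normalized 2×2
matrix products; first-order recurrences as doubling scans).  Both agree
with the dense solve to 1e−10 on diagonally dominant systems.

Implicit Euler is first-order (observed order ≈ 1 on the passive step
response) and unconditionally stable (bounded passive dynamics at
dt = 1 ms).  The default step is dt = 0.025 ms; 200 ms of simulated time is
exactly 8,000 steps.

Initial conditions: `V(0) = −65 mV` everywhere (configurable), gates at
their steady state for `V(0)`, synaptic activations 0.  Stimulus currents
are evaluated at the end-of-step time (consistent with the implicit
discretization).  Non-finite states abort the run immediately, naming the
first offending node and time.

## Differentiation

Reverse-mode differentiation is implemented in `cablegrad.autodiff`: a
small tape over numpy arrays whose creation order is a topological order,
plus a custom adjoint for the tree solve (the matrix is symmetric, so the
adjoint system reuses the same solve: `db = A⁻¹v`, `d(diag) = −y∘x`,
`d(off_i) = −(y_i x_p + y_p x_i)`).  The same physics code runs on plain
arrays (fast forward path) or on the tape (differentiable path).

Losses of recorded traces are backpropagated through time segment-wise:

* the forward pass runs untaped, storing the recorded trace and (under a
  **multilevel checkpoint plan**) segment-boundary state snapshots;
* the loss's adjoint with respect to the trace is computed once;
* segments are replayed on a tape from their snapshots, in reverse order,
  seeding each replay with the incoming state adjoint plus the per-step
  trace adjoints; parameter gradients accumulate across segments.

A plan with segment counts `(s_1, …, s_k)` stores at most `Σ s_i` snapshots
(versus one state per step for full storage) and reproduces the
full-storage gradient to machine precision; a single-segment plan *is* the
full-storage path, bitwise.  **Truncated BPTT** severs the state adjoint at
fixed intervals by partitioning the reverse sweep at the truncation
boundaries and zeroing the adjoint between partitions; the forward trace is
unchanged.  One gradient costs a small constant multiple of one simulation
(forward + one taped replay per level + reverse sweep), independent of the
parameter count; the central-finite-difference oracle
(`finite_difference_gradient`, step `1e−6·max(1, |value|)` per coordinate in
unconstrained space) is the acceptance reference.

Trainable parameters are held in a `ParameterView`: every entry has box
bounds `(l, u)` and is optimized through the inverse-sigmoid transform
`T(θ) = −log(1/((θ−l)/(u−l)) − 1)`, so any unconstrained update maps back
strictly inside the box.  Entries may tie several compartments to one
scalar (per-branch conductances).  Per-entry *group* labels control the
normalized-gradient optimizer: `step = −γ·g/‖g‖^β` with the Euclidean norm
taken per group, β ∈ [0.8, 0.99], optional heavy-ball momentum, and
optional multiplication of the gradient by the loss value (default before
normalization; configurable, since with β < 1 pre-normalization scaling
retains a `L^{1−β}` factor while post-normalization scaling gives the full
automatic step-size decay).  A standard Adam is provided for task training.

## Dynamics analysis

The maximal Lyapunov exponent treats one solver step as a map
`x_{t+1} = f(x_t)` on the concatenated state (voltages, gates, synaptic
activations).  A unit tangent vector is propagated with the step Jacobian,
renormalized every step (Euclidean norm), and
`λ_max = (1/T) Σ log r_t`, reported per step and per ms.  The
Jacobian-vector product is computed by **complex-step differentiation**:
one evaluation of `f(x + i·h·q)` at `h = 1e−100` yields the next state
(real part) and the exact directional derivative (imaginary part / h) —
O(1) cost per step and no subtractive cancellation.  A dense Jacobian
(complex step on each basis vector) serves as the oracle on ≤ tens-of-state
models, where λ from the tangent iteration matches the log-magnitude of
the dominant eigenvalue.

Desk-scale defaults are 500 ms discard / 1 s measurement (configurable);
the chaos-transition study below uses 300 ms / 600 ms per gain, which the
seed-invariance test shows is converged to within a few 1e−4 per step.

## Synthetic studies

All generators are pure functions of their seed.

**GP conductance profiles.**  Per-branch ground-truth densities are drawn
from a squared-exponential Gaussian process over path distance from the
soma (lengthscale default: 25% of the maximal distance), clipped strictly
inside the channel's bounds.  Sibling branches at equal distance receive
perfectly correlated values — a property of a distance-indexed GP, kept
deliberately.

**Profile recovery.**  A 10-branch cell (binary-ish tree, 2 compartments
per branch) receives GP-sampled Na and leak profiles
(Na: mean 0.25, SD 0.15, bounds [0.05, 1.1]; leak: mean 5e−4, SD 2.2e−4,
bounds [1e−4, 1e−3] S/cm²); the observation is its own response to a 5-ms,
0.3-nA somatic step recorded at the distal compartment of every branch.
Fitting minimizes the mean absolute voltage error at every fifth sample
between 1 and 5 ms plus the neighbor-smoothness penalty
`λ·Σ_b (ḡ_b − ḡ_parent(b))²`, λ = 0.001, with per-branch tied parameters,
by group-normalized gradient descent (β = 0.8, momentum 0.9) for 300
steps: γ = 0.1 for the first 80 steps, then exponentially decayed to 5e−4
— the decay drives the fit below the level where sodium errors can mask
the (smaller) leak signature.  Recovery is scored by the Pearson
correlation between fitted and true profiles, box-normalized and
concatenated over both channels.

**Nonlinear two-dendrite task.**  The 12-compartment cell (2-compartment
soma, two 5-compartment dendrites) has Na/K/leak everywhere; trainable are
the three densities plus radius, length and axial resistivity of every
compartment — 72 parameters, bounds [0.05, 1.1] / [0.01, 0.3] /
[0.0001, 0.001] S/cm², [0.1, 5] μm, [1, 20] μm, [500, 5500] Ω·cm, all
initialized uniformly inside their boxes.  Step currents at the two
dendritic tips take weak/intermediate/strong amplitudes; the four-pattern
XOR-like layout maps (mid, mid) and (strong, strong) to a target somatic
voltage of −70 mV and (strong, weak)/(weak, strong) to +35 mV, which no
linear function of the amplitude pair separates (logistic probe ≤ 75%).
The amplitude levels are a repository convention chosen so the untrained
default cell sits near firing threshold, and the steps are transient
(0–1.5 ms) while the decision is read at 3 ms: spike latency — earlier
under stronger total drive — then becomes the natural variable separating
the classes (a matched-strong pattern can fire early and be
hyperpolarized again at decision time, while a single-strong pattern
peaks near it).  Training is Adam (lr 0.01), batch size 1, 200 epochs,
MAE between the somatic voltage after 3 ms and the label; a pattern is
classified by the nearer label voltage.

**Integration stimuli.**  Per trial a mean is drawn from N(±0.005, 0.0002)
(nA), per-step noise with SD 0.05 added, and the sequence low-pass
filtered with a brick-wall FFT cutoff at 2,500 Hz (sampling rate 40 kHz at
dt = 0.025 ms).  The brick-wall filter preserves DC exactly and gives
effectively unbounded stopband attenuation.

**Biophysical RNN.**  Units are three-section cells (soma, apical, basal
stub) with the standard channel kit; recurrent synapses run soma → apical
with Bernoulli(p) connectivity, p = 0.2.  Weight magnitudes are
`|N(0,1)|·g/√(p·n)`, so the signed weight matrix (inhibitory columns
negated) has an eigenspectrum bulk of radius ≈ g by the circular law —
verified over 50 seeds at n = 100.  A configurable fraction of units is
inhibitory (E_syn = −75 mV; excitatory 0 mV).  All units project to
passive readout cells through slow synapses (k₋ = 0.025/ms vs 1/ms
recurrent).  For the chaos-transition study the network is 8 units with an
80/20 E/I split and a constant 0.1 nA somatic drive — subthreshold for an
isolated unit, so the low-gain network rests at a stable fixed point
(λ_max < 0) whose stability margin shrinks monotonically as recurrent gain
rises, crossing into irregular spiking (λ_max > 0); the default sweep
(0.4, 0.6, 0.8, 1.0, 2.0 nS) brackets the transition.  In the deeply
chaotic regime λ_max saturates and is no longer monotone in gain, which is
why the sweep is placed across the transition.

## What the synthetic data do and do not show

The generators produce data from the same model family that is being fit:
passing recovery tests therefore demonstrates correctness of the solver,
gradients and optimizers — not robustness to model misspecification,
recording noise, or electrode artifacts, none of which are emulated.  GP
profiles are functions of distance only (siblings collapse); real
dendritic heterogeneity is richer.  The desk-scale studies use
10-branch/12-compartment cells and 8-unit networks with millisecond-scale
protocols; conclusions about wall-clock scaling to thousands of
compartments or second-scale protocols are out of scope.

## Numerical choices and degenerate inputs

* Compartment radius under discretization: length-weighted mean of the
  linearly interpolated point radii spanned (constant-radius branches are
  exact; flagged as a convention since SWC dialects differ).
* Soma sections default to length = 2·radius, so a cylindrical soma has
  the surface area of the sphere with the same radius.
* Distance from soma: path length to the compartment midpoint; soma
  compartments are the origin.  Trees without a soma marker measure from
  the root's proximal end.
* Zero-norm gradient groups produce a zero update and a logged warning
  (never 0/0).
* Hard max in the sliding-window reduction for observations; a
  log-sum-exp soft max (configurable temperature) is available where
  gradients must pass through the reduction of simulated traces.
* Soft-DTW uses the max-shifted log-sum-exp softmin; the `|i−j|` index
  penalty is applied on the reduced (post window-max) axis and is not
  normalized by sequence length.
* `ceil(t_max/dt)` steps are executed, with a round-to-9-decimals guard so
  that e.g. 200/0.025 is exactly 8,000 despite floating-point division.

## Known limitations

* The tape engine targets clarity over throughput: per-step overhead is
  Python-level, so very long taped segments (≫10⁵ steps) should use
  checkpoint plans; there is no GPU path.
* Calcium dynamics are limited to a minimal optional decaying pool; no
  calcium channel ships with the default kit.
* The recursive-doubling tridiagonal solver is validated for the
  diagonally dominant systems the discretization produces; it is not a
  general pivoting solver.
* Leak profiles are only weakly expressed in short (few-ms) voltage
  windows: at the recovery study's conditions the leak block of the trace
  sensitivity (Jacobian) is ill-conditioned (singular values spanning two
  orders of magnitude, versus a well-conditioned sodium block), so a few
  hundred first-order steps resolve the sodium profile essentially exactly
  while leaving much of the leak profile's fine structure unresolved —
  even when sodium is clamped at its true values.  This mirrors the known
  finding that whole-cell voltage constrains some conductance profiles
  strongly and others only weakly.
* Single training runs of the two-dendrite task frequently converge to a
  3-of-4-pattern local minimum in which one dendrite is effectively
  silenced (satisfying the matched-strong "low" pattern at the cost of one
  asymmetric "high" pattern); task protocols of this kind conventionally
  select the best of several independent runs.  Within a run, training
  accuracy is evaluated periodically and the best checkpoint is kept,
  since batch-1 stochastic updates routinely perturb an already-solved
  task.
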