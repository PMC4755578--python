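# Methods

## Model

The package implements a two-layer sensory rate network. An input vector
`x` of N components drives, through a fixed feedforward matrix `W`
(M × N, with an overcomplete output layer, M ≥ N), a population of M
sigmoidal units coupled by a recurrent matrix `K`:

    tau ds_i/dt = -s_i + g(sum_j W_ij x_j + sum_k K_ik s_k)

with `g` the logistic function (gain at zero input gamma0 = g'(0) = 1/4)
and tau = 1. The network's response to an input is the steady state
`s = g(Wx + Ks)`. Because the map from input to steady state is
deterministic, the mutual information between input and output is governed
by the output entropy alone, and maximizing it is equivalent to minimizing

    eps = -1/2 < ln det(chi^T chi) >_x,

where `chi_ij = ds_i/dx_j` is the susceptibility (Jacobian) of the
steady-state map. Differentiating the fixed-point condition gives
`(I - GK) chi = GW` with `G = diag(g'(u_i))` evaluated at the steady
state. The learning rule for K is plain gradient descent on eps:

    dK = eta < (chi Gamma)^T + phi^T a s^T >,
    phi = (G^-1 - K)^-1,  Gamma = (chi^T chi)^-1 chi^T phi,
    a_k = [chi Gamma]_kk g''_k / (g'_k)^3.

The first term is the explicit dependence of chi on K; the second tracks
the motion of the fixed point itself. The rule is verified in the test
suite against central finite differences of eps with respect to every
entry of K (relative error < 1e-3 on random subcritical networks); the
susceptibility solve is likewise verified against finite differences of
the steady state with respect to the input.

## Ring hypercolumn and its analytic limit

The toy model is a visual hypercolumn on a ring: M neurons with preferred
angles theta_i = 2 pi i / M, feedforward rows (cos theta_i, sin theta_i),
and inputs x = r (cos theta0, sin theta0) with theta0 uniform and r
Gaussian (sd = 0.1 of the mean). Full 360-degree periodicity is used for
the toy model; the orientation doubling (period 180 degrees) appears only
in the population-vector metric and in the ecological model.

In the limit r -> 0, for a translation-invariant profile
K(theta) = (1/M) sum_n k_n cos(n theta), only the first harmonic enters
the objective:

    eps(k1) - eps(0) = 2 ln(1 - gamma0 k1 / 2),

which decreases monotonically and diverges to -infinity at the critical
amplitude k1c = 2/gamma0 (= 8 for the logistic). The optimal profile is a
pure cosine with M × K amplitude 8, i.e. the infomax optimum sits exactly
at the pattern-forming instability of the uniform state. The numeric
objective reproduces the closed form to better than 1e-3 at probe
contrast r = 1e-4 (a tiny but nonzero r exercises the same code path as
training; the residual difference is the genuine O(r^2) correction,
amplified near the critical point).

At finite contrast the optimum moves off the critical point: on a fixed
batch at mean contrast 0.1 the pure-cosine objective is minimized near
k1 ≈ 7.7–7.8, and at mean contrast 0.9 near k1 ≈ 5 with a shallow
landscape that also rewards higher odd harmonics. Full-matrix learning at
intermediate contrast therefore has no sharp endpoint: after reaching the
first-harmonic optimum the trajectory keeps drifting slowly along a
shallow higher-harmonic valley. The reported "learned amplitude" at
intermediate contrast is the quasi-converged state reached by the same
training budget that brings the low-contrast network to its (analytically
known) optimum; see "Training protocol" below.

## Fixed-point solver

Steady states are computed by the damped iteration
`s <- (1-alpha) s + alpha g(Wx + Ks)` with alpha = 0.5, which is forward
Euler on the rate dynamics with step alpha·tau; a separate explicit
integrator cross-checks the fixed points in the tests. Convergence is
declared when every neuron moves less than tol (default 1e-9 for
analysis, 1e-8 during training) in one step. The iteration count is the
"convergence time" metric (one step = alpha·tau time units). Batched
solves shrink the active set as samples converge, so an occasional slow
sample costs only its own matrix-vector products. The initial state is
the homogeneous baseline g(0) = 1/2; supercritical runs add a seeded
perturbation of scale 1e-6 to let the symmetry break.

Near the critical point relaxation rates vanish (critical slowing down)
and occasional samples — typically unusually weak inputs for a network
sitting at the zero-contrast instability — miss the strict tolerance
within any reasonable budget. Two distinct behaviors must be told apart.
Almost-converged stragglers (final per-step change below a soft tolerance
of 1e-6) are effectively at their steady state and are used as-is.
Genuinely unsettled samples are a different matter: in the supercritical
regime a weak stimulus cannot pin the activity hill and the dynamics
settle into a rotating-wave limit cycle with no fixed point at all — and
because the rotation can be slow, the soft tolerance must stay tight, or
a point mid-rotation passes for a fixed point and its spuriously huge
susceptibility biases the objective downward (a generous 1e-4 threshold
let the trainer climb to k1 = 8.6 this way). Unsettled samples make a
batch unusable —
during training an unusable gradient batch is skipped (with a cap of 25
consecutive skips before aborting with a checkpoint), and an unusable
trial batch rejects the lookahead step and halves the learning rate.
This strictness matters: silently dropping unsettled samples biases the
batch average, because the samples that fail are exactly the ones that
penalize stronger interactions, and the bias feeds a runaway across the
critical surface (observed when a drop-based policy was tried: the first
harmonic climbed from its optimum near 7.8 to 8.65, where rotating waves
made whole batches insoluble). With strict rejection the trainer cannot
cross into the rotation regime, and the rejection-driven learning-rate
collapse doubles as a natural stopping criterion. The public
`objective`/`gradient_K`/`susceptibility` functions keep the strict
contract and raise on any non-converged sample.

## Training protocol

Learning starts from K = 0 with no symmetry constraint (M^2 - M + M free
parameters; self-connections are learned like any other entry, with a
config flag to zero them). The learning rate starts at eta0 = 0.01 with
batches of 50–400 inputs. Before each update is applied, the objective is
re-evaluated on the same batch after a trial step; if it would increase
(or the trial leaves the subcritical regime entirely), the step is
rejected and the learning rate halved, down to a floor of 1e-7. Near the
critical point single samples can contribute near-divergent gradients, so
the batch update direction is norm-clipped at 5.0 (typical batch
directions have norm 0.3–1.1 throughout training; the clip only binds in
pathological batches and bounds the random walk around the optimum).

Desk-scale budgets: the low-contrast ring run (M = 41, mean contrast 0.1)
uses batches of 400 for 1250 steps — the knee of the learning trajectory,
where the learned first harmonic reaches its finite-contrast optimum
(k1 ≈ 7.7–7.8, within a few percent of the analytic zero-contrast value
8; the scale sweep then locates its minimum at 1.0) and beyond which
steps only polish the endpoint at rapidly growing cost, since every
near-critical batch carries slowly relaxing samples. The large batch is
needed here because stochastic gradient noise accumulates in the nearly
flat non-circulant directions of K (their restoring curvature is O(r^2))
and its effect is amplified near criticality: it sets the floor of the
subcritical population vector. A short annealing tail
(`train_annealed`, three stages of 50 steps with the learning rate
halved per stage) further damps this residue; with it the learned matrix
is circulant to ~0.2% and the zero-input population vector stays near
zero up to 90% of the learned scale. The intermediate-contrast run
(mean 0.9), whose dynamics stay far from critical slowing and whose
landscape is far less noise-sensitive, uses batches of 50 for 2500
steps, reflecting its slower asymptotic approach to a shallower optimum.
The ecological run uses 400 steps, by which point the interaction
profile's sign structure (the Mexican hat) is stable. Longer budgets
deepen but do not reshape these results, except for the slow
higher-harmonic drift at intermediate contrast discussed above.

## Criticality metrics

* Convergence time: solver steps to meet the per-neuron stability
  criterion.
* Population vector: resultant of `s_i exp(1j angle_i)`; for orientation
  variables the angle is doubled before summation and the phase halved
  after. Zero for uniform responses; finite when a hill forms.
* Scaling sweep: with the input batch held fixed, K is replaced by c·K
  over a grid of c; eps, mean convergence steps and the zero-input
  population-vector magnitude (with seeded 1e-6 initial noise) are
  recorded per scale. Scales where eps is undefined (supercritical) are
  recorded as NaN, not errors. The default transition detector for the
  population vector is a >10x jump between adjacent scales.

## Ecological pipeline

Since no photographs ship with the package, the ecological model trains
on synthetic textures: Gaussian random fields with radially averaged
power spectrum ~ 1/f^2 (the natural-image slope) and RMS contrast 0.05 on
a 0..1 luminance scale — capturing the two first-order statistics that
matter for this model, scale-free spatial correlation and the dominance
of low contrasts. They lack the higher-order structure of real scenes
(edges, occlusions, sparse heavy-tailed filter statistics), so passing
tests demonstrate that the learning dynamics produce the Mexican-hat
profile and near-critical operation for 1/f-correlated low-contrast
input, not that the pipeline reproduces photographic training exactly.

25 × 25-pixel patches are cut at random locations, rescaled to 0..1,
mean-centered and reduced by PCA with variance whitening (eigenvalues
floored at 1e-8 of the largest). The feedforward matrix is the product of
a Gabor bank (M rows; shared center, wavelength, envelope and phase;
orientations i·180/M degrees; mean-subtracted and unit-normed) with the
PCA reconstruction map, so applying it to a whitened code gives the
filter responses to the reconstructed patch.

Desk-scale parameter choice: with d retained components of a 1/f^2
process, the kept subspace spans spatial frequencies up to roughly
f ≈ sqrt(d/pi)/25 cycles/pixel, while a bank of same-center same-frequency
Gabors spans only ~2·(2 pi sigma_eff / lambda) angular harmonics. The
composed feedforward matrix is full rank (and oriented probes project
into the kept subspace) only when the Gabor passband lies inside the PCA
band and d does not exceed the bank's harmonic span. The defaults
d = 10, wavelength 12 px, sigma 7 px, M = 60 satisfy both with a
singular-value ratio ~6e-4; a full-scale combination of a 100-dimensional
code with a higher-frequency bank is outside what a 25-px patch of 1/f^2
texture can support at full rank. Oriented Gabor probes are rescaled so
their whitened code has the mean RMS of the training codes ("typical
contrast").

## Numerical choices

* chi solves (I - GK) chi = GW by LU factorization (no explicit inverse
  of G^-1 - K, which is ill-defined for tiny gains); phi reuses the same
  factorization.
* ln det(chi^T chi) via Cholesky of the small N × N Gram matrix; a
  failed factorization (rank-deficient susceptibility) is reported as a
  criticality error.
* The condition number of (I - GK) is monitored; above 1e12 the
  susceptibility call fails with a criticality error (disable by passing
  `cond_threshold=None` when probing the divergence itself).
* Fourier harmonics of an interaction matrix use the normalization
  K(theta) = (1/M) sum_n k_n cos(n theta), so a matrix
  (c/M) cos(theta_i - theta_j) has k1 = c; k0 is the mean term (the
  analysis never uses it, but the convention is fixed so the mean maps
  to k0). Non-circulant matrices are circularly averaged over wrapped
  diagonals first and the relative rms residual is reported.

## Known limitations

* Only the recurrent matrix is learned; the feedforward matrix is fixed
  by construction (unit vectors on the ring, Gabors in the ecological
  model).
* Exact training trajectories are not reproducible targets: batch sizes,
  learning-rate schedules and training lengths are not fully determined
  by the model, and at intermediate contrast the objective has no sharp
  full-matrix optimum. Endpoints and limits are the tested quantities.
* The supercritical regime is explored only through its signatures
  (population vector, slowing down); attractor dynamics per se (basins,
  multistability) are out of scope.
* Deterministic rate units only: no stochastic spiking, no avalanche
  statistics, no time-varying stimuli.
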