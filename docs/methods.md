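# Methods

This note records the models as implemented, the parameters that matter,
the numerical choices made where the design was open, and what the
synthetic experiments do and do not show.

## Discretization conventions

Time bins are left-edge labelled, half-open `[t, t+dt)`.  Binary firing
variables `φ_i(t)` are per-bin spike counts, so sums of interaction
kernels over spikes carry no `dt` factor (one spike contributes
`λ_syn(t - t0)` to the membrane potential, exactly).  Kernel–kernel
integrals — the STDP window's entropy term, lag-correlation integrals and
the frequency sum of the spatiotemporal learning rule — are rectangle-rule
sums at grid resolution.  Lag grids are uniform, symmetric about zero and
contain the zero lag; on such grids the even/odd window decomposition
identity holds to machine precision, and the test suite asserts it at
1e-12.

Cross-correlations `C_ij(l)` average `φ_i(t) φ_j(t-l)` over the bins where
both arguments exist, normalizing each lag by its own pair count, so
`C_ij(l) = C_ji(-l)` holds exactly.

The synaptic alpha function is implemented verbatim as
`α(t) = g e^{-g}` with `g = max[(τ_d - t)/τ_c, 0]` — note this places the
pulse *before* the delay time and makes `α` vanish for `t ≥ τ_d`.  The
integrate-and-fire response kernel
`λ_syn(t) = C^{-1} ∫_0^t e^{γ(t'-t)} α(t') dt'` is evaluated by adaptive
quadrature per grid point (the unit tests compare against an independent
fine-grid trapezoid oracle at 1e-6 relative).  Defaults: `τ_d = 2 ms`,
`τ_c = 1 ms`, `γ = 0.15/ms` (membrane time constant ≈ 7 ms, in the
biological range), `C = 1`, with an option to normalize the kernel to
unit peak since every use multiplies it by a free calibration constant.

## Hopfield network

Outer-product storage, zero diagonal, asynchronous updates.  Ties (local
field exactly zero) resolve to +1, matching the threshold rule's `≥`.
Finite temperature uses single-spin Metropolis acceptance
`min[1, e^{-ΔE/T}]`; `T = 0` is a strict limit with no division — flip
iff `ΔE < 0`, ties handled by the threshold convention — which makes the
`T = 0` Metropolis trajectory identical to the deterministic one.  Update
order is a fresh uniform permutation per sweep.  The energy is checked
non-increasing after every single-neuron update in the recall experiment.

## Boltzmann machine

Exact statistics on `N ≤ 20` neurons by full enumeration
(`F = -T log Z` via log-sum-exp); these serve as oracles for the sampler
and for the KL-gradient learning rule.  Clamped statistics pin the
visible units to each data configuration and enumerate the hidden ones.
The learning step `ΔJ ∝ C - C0` is applied off-diagonal and symmetrized.

### Structural plasticity

Each macro step interleaves one Metropolis firing sweep with one wiring
phase in which every neuron pair attempts a toggle with probability
`(1/τ) min[e^{-ΔF/T}, 1]`.  Given the frozen window estimates of `C` and
`ρ` the pair energies are independent, so the attempts are vectorized;
a pair toggle updates `J_ij` and `J_ji` together (the energy model needs
symmetric couplings).  The moving window is 100 sweeps (its stated
scale); the window is filled by 100 burn-in firing sweeps before the
first wiring attempt, and while fewer sweeps have elapsed the available
prefix is used.  `ΔE` bookkeeping for a flip is exact (tested at 1e-12),
and with frozen `C, ρ` the per-edge stationary wired fraction matches the
two-state Boltzmann ratio (detailed balance test).

The figure-scale run uses `N = 200`, `T = 0.1`, `J = 0.5 = 5T` (the
quantum is kept well above `T` so wired/unwired is a crisp distinction),
`τ = 2`, uniform bias `B = -0.3`, 4000 macro steps, starting from an
empty graph.  The bias sets isolated neurons' rates low so that the
wiring propensity `μ` (17–21 `T`) initially dominates; the network then
self-organizes to a mean rate near the marginal point where
`η ρ² ≈ C + μ`, and the `-η ρ_i ρ_j` penalty caps what any single neuron
can sustain, producing a broad, heavy-tailed degree distribution with
continuous edge turnover.  The reported distribution pools degree
snapshots over the second half of the run (the ergodic estimate of the
stationary law).  The log-log line is fit over the central range
`0.02 ≤ Pcum ≤ 0.8`: below, the tail rests on a handful of nodes and
shows the finite-size cutoff; above, `Pcum → 1` by construction.  Across
`η ∈ {5, 10, 20}` × `μ ∈ {17T, 19T, 21T}` and seeds, the fit gives
`R² = 0.91–0.97` with slopes around −1.6 to −2.3.  A finite 200-neuron
network cannot certify a true power law; the claim tested is the
near-linearity of the central cumulative range, not an asymptotic
exponent.

## Feature maps

The linear network solves `u = (I - J)^{-1} W h` exactly (or uses a
prescribed recursive interaction `K` directly, never inverting it, when
an experiment defines `K` rather than `J`).  The Gaussian free energy
uses the closed forms `U = -½ B'KB`, `S = ½ tr log(TK)`; additive
constants independent of `B` and `W` are dropped, which leaves all
derivatives — the quantities with physical content — unchanged.

The noise in the Langevin picture is *quenched* on the firing time scale
("pseudo-stochastic"): each episode draws a static input `h ~ N(0, Q)`
and endogenous noise `ξ ~ N(0, βI)`, relaxes the linear dynamics (exact
solve by default, explicit Euler as an option) and records the settled
state, so the stationary output covariance is
`β K K† + K W Q W† K†`.  White (per-step refreshed) noise would instead
give a Lyapunov-equation covariance `∝ K`, which is not the regime these
learning rules live in.

### Ocular dominance

Two inputs with correlation `Q = [[1, η], [η, 1]]`, `η = 0.3`, feed a
40×40 sheet through `ΔW = lr · K W Q` with the Mexican-hat interaction
`K = (1 - k r²/σ²) e^{-r²/2σ²}`, `σ = 2`, non-periodic boundaries.
Weights start at `0.5 ± 0.1` and are clipped to `[0, 1]` after every step
(pure linear Hebbian growth is unbounded; the clip is the saturating
nonlinearity).  The learning rate is divided by the spectral norm of `K`
so the per-step growth is comparable across grid sizes; 200 steps at
`lr = 0.02` reach saturation of the pattern.  With `k = 0.5` the
difference mode's fastest-growing eigenvector sits at a nonzero spatial
frequency and the dominance map forms stripes about 10 neurons wide
(dominant frequency ≈ 0.11 cycles/neuron); with `k = 0` both channels
grow along the uniform mode and saturate together, leaving a spatially
uniform map whose spectrum peaks at zero frequency.

### Topographic map

10×10 input and output sheets, `K = e^{-r²}`, `Q = e^{-r²}`, `T = 0.1`,
approximate competition `(W W†)^{-1} ≈ I - W W†`, and row normalization
`(W W†)_ii = 1` after every step.  The captions' kernels come with no
length unit; the lattice spacing is taken as 0.7, which makes the kernels
smooth enough for global ordering while keeping the competition
selective (spacing 1.0 leaves topological defects, order ≈ 0.6–0.75;
spacing ≤ 0.5 over-smooths and the map collapses).  2000 steps at
`lr = 0.05` from uniform-random normalized weights give a topographic
order (Spearman correlation between output-grid and RF-center pairwise
distances) of 0.96 across seeds; the `T = 0` control collapses all
receptive fields onto a common centroid (order ≈ 0.04).  RF centers are
centroids of the rectified-squared weight mass, which localizes them
without being thrown off by small negative entries the approximate
competition can introduce.

## Path-integral spiking model

The refractory kernel's divergence is realized as a hard veto: the
conditional rate is exactly zero within `τ_r` of the neuron's own last
spike.  The proportionality constant of the conditional rate is an
explicit `rate_const` calibration parameter (the theory fixes only the
exponent).  The Monte Carlo samples bins at probability
`min(rate·dt, 1)` and warns when `rate·dt > 0.5` anywhere.

### Cluster expansion

The one-point series is evaluated with the printed diagrams through third
order, with only causal `f⁺` legs attached to the observed site.  Because
the binary variables are hard-core (`φ² = φ`), the bare series — whose
zeroth term is the fugacity `z` itself — carries an `O(z²)` single-site
error (the non-interacting limit is exactly `z/(1+z)`, not `z`).  The
default evaluation therefore applies the standard diagonal resummation:
the site activity `ζ = z/(1+z)` replaces `z`, and the pair term carries a
saturation factor `(1 - ζ_a)`.  This choice reproduces the exact activity
expansion through `O(z³)` (verified analytically for causal geometry),
and numerically the truncation error scales as `z^{order+1}`: measured
log-log slopes 1.9 / 2.8 / 3.9 for orders 1/2/3 over
`z ∈ {0.02, 0.04, 0.08}`, with maximum errors 7e-4 / 1.8e-5 / 7e-7 at
`z = 0.02`.  The slopes sit ~0.1 below the asymptotic order+1 because of
`O(z)` sub-leading corrections at finite fugacity; the tests allow for
that.  A `resummed=False` switch evaluates the verbatim series.

The comparison against the exact spatiotemporal trace is made on the
*postsynaptic* neuron of a directed synapse: the symmetric trace carries
backward-in-time influence onto the presynaptic neuron which the causal
series deliberately eliminates, so only the driven neuron's one-point
function is the series' target (this is also the quantity the
firing-statistics experiments measure).  Exact traces enumerate up to 20
(neuron, bin) sites; bias-derivative identities for the one- and
two-point functions are tested at 1e-5.

### STDP window and learning

The window `Ω(t) = λ_syn(t) - ∫ Σ(t,t') λ_syn(t') dt'` uses the Gaussian
entropy-curvature model `Σ(t,t') = A e^{-(t+t')²/2σ² - (t-t')²/2σ²}`
(`A = 0.02`, `σ = 30 ms`) by default; a network-derived `Σ` can be
substituted since the function takes any symmetric kernel.  With the
default LIF kernel the window potentiates causal lags out to ~17 ms,
depresses all anti-causal lags, shows a weak second depression interval
at larger causal lags, and decays below 1e-6 of its peak beyond 5σ.

Weight learning descends the exact-trace free energy by central finite
differences on small grids, with sign projection (only conductances are
plastic, so a weight can shrink to zero but never change sign).  The
gradient is cross-checked against the correlation route — the
window-weighted sum of the exact two-point function — at 1e-4.

The frequency-domain learning rule sums `K̃(ω) W Q̃(ω)` over a uniform
Hermitian frequency grid (Riemann sum) and subtracts
`β (W W†)^{-1} W`.  The two printed forms of the competition term differ
in sign between the rate-based and frequency-domain rules as stated; this
package implements each verbatim, and their documented correspondence at
zero-frequency concentration holds with `β = -T` (tested to 1e-6 relative).

## Synthetic data, reproducibility, and scope

All inputs are generated: uniform ±1 patterns, Bernoulli spike rasters,
Gaussian input ensembles with prescribed covariance (eigendecomposition
factor), square lattices.  A single integer seed fans out to named child
streams (CRC-keyed `SeedSequence` spawn), so adding a consumer never
perturbs existing streams and identical configurations byte-reproduce
their outputs.

The generators emulate the models' idealized conditions — stationary
statistics, independent noise, exact binary spikes on a fixed grid.  They
do not emulate real recordings (non-stationarity, measurement noise,
bursting, conduction delays), so passing tests certify the
implementations and the models' internal identities, not fits to
biological data.  Problem sizes are chosen so every stochastic check runs
against an exact oracle or with comfortable Monte Carlo margins: 200
neurons for the wiring equilibrium, 40×40 and 10×10 sheets for the maps,
2 neurons × 8 bins for exact spatiotemporal traces.

Known limitations: no Hodgkin–Huxley integration (the conditional-rate
Monte Carlo is the simulation oracle); no expansion beyond third order;
the weight-range function regularizing free-energy learning is left as
the sign projection plus the caller's choice (no canonical form exists);
and the structural-plasticity model's scale-free claim is tested as
central log-log linearity at `N = 200`, not as an asymptotic exponent.
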