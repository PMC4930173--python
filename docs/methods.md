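# Methods

## The model

We simulate N cells in the plane, each carrying a position r_i and a
polarity p_i — the velocity the cell would have in isolation.  Motion is
overdamped:

    dr_i/dt = p_i + Σ_{j≠i} F_ij
    dp_i/dt = −p_i/τ + σ ξ_i(t) + β_i q_i + χ (∇c/|∇c|) Θ(|∇c| − g0)

The noise ξ is white and Gaussian with ⟨ξ_μ(t) ξ_ν(t′)⟩ = 2 δ_μν δ(t−t′),
making the first two terms an Ornstein–Uhlenbeck process: an isolated cell
performs an unbiased persistent random walk with persistence time τ,
stationary polarity variance σ²τ per component, and RMS speed √2·σ·√τ.
Isolated cells are blind to the external signal S(r) — all directionality
is collective.

**Units.** One length unit is the equilibrium cell–cell separation
(20 µm); one time unit is the polarity relaxation time τ (20 min).  A
speed of 1 in simulation units is 1 µm/min.  Defaults τ = σ = 1.

**Forces** (pair, radial): a repulsive spring v_r(1 − d) for separations
d < 1, an attractive spring −v_a(d − 1)/(D0 − 1) for 1 ≤ d < D0, zero
beyond D0.  Strongly adherent ("rigid") clusters use v_r = v_a = 500 with
Δt = 1e−4; co-attraction studies use v_a = 0, v_r = 100 with Δt = 1e−3.
D0 defaults to 1.2 cell diameters and doubles as the contact range for
CIL and inhibitor exchange; it is configurable, and results should be
reported with the D0 used.

**Contact inhibition of locomotion (CIL).** Cells in contact (distance
< D0) bias their polarity away from their neighbors along
q_i = Σ_{j∼i} r̂_ij.  The susceptibility β_i is regulated by the signal:

* minimal: β_i = β̄·S(r_i);
* LEGI linear: β_i = β̄·R_i/R0;
* LEGI switch: β_i = β̄·g(R_i/R0), g(x) = ½[1 + tanh((x−1)/λ)], λ = 1e−2.

**LEGI.** The signal produces a cell-local activator A (dA_i/dt =
k_A S_i − k_{−A} A_i) and an inhibitor I exchanged between contacting
cells at rate k_D (dI_i/dt = k_I S_i − k_{−I} I_i − k_D(L I)_i, with L the
contact-graph Laplacian, so exchange conserves ΣI exactly).  The readout
obeys dR_i/dt = k_R A_i(1 − R_i) − k_{−R} I_i R_i.  At steady state
A tracks the local signal while I tends toward the cluster mean, so R
encodes the *relative* signal profile and adapts perfectly to uniform
levels.  The quality of collective sensing is set by α = k_{−I}/k_D:
for α ≪ 1/N, R_i → R0·S_i/S̄; at the physiologically plausible α = 0.25
(k_I = k_{−I} = 1, k_D = 4, gap-junction FRAP scale) sensing degrades in
large clusters, which makes cluster speed non-monotonic in N.

**Co-attraction.** Every cell secretes a molecule c that diffuses and
degrades much faster than cells move; each point source contributes a
screened 2-D profile with decay length ℓ (default 5 cell diameters).  The
gradient at cell i is the Bessel-kernel sum −Σ_j K1(d_ij/ℓ) r̂_ij; its
overall prefactor is irrelevant because the polarity response normalizes
the gradient to a unit vector of strength χ above the tiny threshold
g0 = 1e−5 (whose only role is avoiding division by zero).  The scalar
field for visualization is ℓ·Σ_j K0(d_ij/ℓ), scaled so its analytic
gradient is exactly the K1 sum.

## Numerics

Explicit Euler–Maruyama.  The polarity noise increment per step is
σ·√(2Δt) per standard-normal component — the factor 2 comes from the
stated noise correlator and is easy to get wrong; the package asserts the
resulting stationary variance σ²τ in its tests.  Positions advance with
the pre-step polarity and forces; the contact graph, forces and
co-attractant gradient are recomputed every step from the pre-step
positions (brute-force O(N²); N ≤ 127 throughout).  Non-finite states
raise an instability error advising a smaller Δt, and parameter sets with
Δt·max(v_r, v_a) > 0.5 warn at construction.

LEGI kinetics are advanced two ways.  The default quasi-static mode
integrates only the inhibitor and enslaves A to its steady state and R to
the exact fixed point R_i = k_R A_i/(k_R A_i + k_{−R} I_i) — the fast-
excitation, fast-readout regime.  The full mode integrates all three
species explicitly and is used for step-response transients.  We
implement the exact R fixed point rather than the fast-decay
approximation (k_R/k_{−R})·A/I; with the default k_R/k_{−R} = 1e−3 the
approximation is recovered to that order.  k_A, k_{−A}, k_R, k_{−R} have
no canonical values (only ratios and orderings matter at steady state);
defaults are k_A = k_{−A} = 1, k_R = 1e−3, k_{−R} = 1.  For step-response
transients the activator kinetics must be fast relative to the inhibitor
(local excitation rapid, global inhibition lagging) or no pulse occurs;
the adaptation tests use k_A = k_{−A} = 20.  Tests of the ideal-sensing
limit R → R0 S/S̄ use k_R = 1e−6 to sit deep in the fast-decay regime
that the limit formula assumes.

The inhibitor steady state solves the symmetric positive-definite system
(k_{−I}·Id + k_D·L) I = k_I S by dense direct solve (N ≤ 200).  The ODE
relaxation oracle for it integrates the full kinetics with LSODA at
rtol 1e−10 for 50 slow-decay timescales.

**Initial conditions.** Clusters start as unit-spacing triangular-lattice
packings (closed hexagonal shells at N = 1, 7, 19, 37, 61, 91, 127;
otherwise the N sites nearest the lattice center), centroid at the
origin, rotated by a uniform random angle per trajectory.  Polarities
start at zero and the inhibitor at the uniform steady state for the
initial mean signal; measurement windows (default 12.5τ–50τ for
co-attraction ensembles, the full span for short rigid runs) absorb the
burn-in.  Each trajectory owns one RNG stream seeded from (master seed,
trajectory index), so ensembles are reproducible and extensible.

An isolated cell has identically zero forces, CIL bias and co-attractant
gradient, so `run_trajectory` dispatches N = 1 runs to a vectorized
linear-recursion integrator (`scipy.signal.lfilter`) that consumes the
RNG stream in exactly the same order as the generic stepper; equality is
unit-tested.  This makes 1e4·τ single-cell statistics runs take about a
second.

## Observables

Cluster velocity is centroid displacement over a window divided by its
duration — robust to snapshot cadence and identical in the mean to
averaged instantaneous velocity.  The chemotactic index is
CI = ⟨V_x⟩/⟨|V|⟩ over an ensemble.  Angular velocity per frame is the
cell average of [(r_i − r_cm) × (v_i − v_cm)]_z/|r_i − r_cm|² with
central-finite-difference velocities (cells at the centroid excluded);
frames are then time-averaged to one signed Ω per trajectory.  At
snapshot spacing Δ the estimator carries a sin(ΩΔ)/(ΩΔ) factor, so
rotation studies record at Δ = 0.05τ (≤ 1.5% bias at the fastest
rotations swept).  Fragmentation is the number of connected components
of the contact graph.

**Rigid-cluster predictor.** For strongly adherent clusters the mean
drift at fixed configuration is ⟨V⟩ = (1/N) Σ_i β_i q_i with the LEGI
variables at steady state; the reported ⟨V_x⟩ averages 64 equally spaced
cluster orientations (doubling changes results < 0.1%, which is tested).
Velocity fluctuations about each orientation's mean are Gaussian with
per-component variance σ²τ/N, so E|V| is a mixture of Rice means,
evaluated by adaptive quadrature and cross-checked against the
closed-form confluent-hypergeometric expression in the tests.

**Rotation onset.** Projecting the polarity dynamics of a rigid circular
cluster with purely radial biases onto the rotation angle gives
dW/dt = Ω² − (W − W0)/τ and dΩ/dt = −(1/τ + W)Ω: a pitchfork at
W0τ = −1, with stable rotating states Ω = ±(1/τ)√(−1 − W0τ) beyond it.
In the full model the inward bias comes from co-attraction, giving
|Ω|(χ) = Ω0·√(χ − χ_c) above a critical χ_c.  The fitter treats both
signed branches through |Ω| (branch assignment by the sign of each
trajectory's mean Ω; the per-χ branch magnitudes are count-weighted,
which equals the per-χ mean of |Ω|), and minimizes least squares jointly
over (Ω0, χ_c): Ω0 is a linear projection for fixed χ_c, and χ_c is
located by a deterministic 200-point grid multi-start (the objective is
non-smooth where χ_c crosses data points) plus bounded local refinement,
with ties broken toward smaller residual then smaller χ_c.  All-zero
rotation data raises a degeneracy error reporting the identifiable lower
bound.  Sweeps above χ = 120 are outside the validated range (cluster
breakup makes results unreliable there); the bundled sweeps stop at 100.

**Pair scattering.** For two colliding cells with strong CIL the
relative polarity projection on the contact axis reverses almost
elastically, Δ_out ≈ −Δ_in, while the total gains
−2Δ_in(β_i − β_j)/(β_i + β_j): the separation time scales as
1/(β_i + β_j), so the net polarity change depends only on the *relative*
susceptibility contrast — for a shallow exponential signal,
Σ_out ≈ Σ_in − Δ_in·S1·D0, independent of the overall level S0.  This is
how graded CIL adapts without any dedicated circuit.  The numeric
realization integrates a deterministic (σ = 0) pair from the moment of
contact (separation D0(1 − 1e−9); starting deeper inside the range
inflates the contact time and overshoots the elastic limit) at
Δt = 1e−5 until separation exceeds D0.  Elasticity holds to ~0.5% at
β̄ = 50; the S0-independence of Σ_out is sharpest at large β̄ (the
corrections scale as the inverse total susceptibility) and is verified
at β̄ = 100 over a factor-4 range of S0.

## Scaled-down study sizes

Stochastic ensembles are sized to run on a single CPU in minutes while
keeping the statistical resolution the assertions need, and the sizes are
stated with each result: the rotation-onset protocol uses 10 trajectories
of 25τ per χ over χ ∈ {5, 20, 35, 50, 65, 80, 95} (the reference
protocol used 100 of 50τ), which resolves χ_c and Ω0 to well within the
span of the fit's bootstrap confidence interval; isotropy and drift checks use
12–48 trajectories with 3-standard-error bounds; single-cell statistics
use one 1e4·τ trajectory.

## What the generator does and does not emulate

The synthetic study conditions are the model's own: point cells, pairwise
radial forces, scalar switchlike chemotaxis to the co-attractant, no cell
division, death, shape, or torque on individual cells (polarities are
fixed in the lab frame — collective rotation may differ in shape- or
torque-resolving models), no receptor saturation, no reaction noise in
the LEGI species, and a 2-D substrate.  Passing tests therefore validate
the implementation of this model and its analysis chain, not the
biological fidelity of any particular parameter set.  Chirality-dependent
drift of rotating clusters is measured (branch-averaged ⟨V_y⟩ by rotation
sign) but its magnitude is sensitive to the equal-response-to-all-
gradients assumption, so no quantitative value is asserted for it.

## Degenerate inputs and guards

Coincident cells raise a degenerate-overlap error everywhere (the
repulsive core makes coincidence dynamically inaccessible at the stated
time steps); kernel evaluations floor distances at 1e−12 only to produce
that clean error, never to clamp silently.  Linear signal fields raise if
any sampled point sees S ≤ 0.  The inhibitor solve raises on a singular
system (k_{−I} = 0 with a disconnected graph).  Configuration files are
fully validated before any simulation starts.
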