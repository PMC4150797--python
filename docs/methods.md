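# Methods

## The model

Chromatin between ~10 kb and a few Mb is represented as a bead-spring
copolymer of N monomers, each covering `bin_size` bp (default 10 kb) and
carrying a chromatin-state label (default alphabet: active, HP1,
Polycomb, black — the merged-active four-state epigenome of the fly).
The Hamiltonian is

    H = (3 kT / 2 l²) Σₙ (Xₙ − Xₙ₋₁)²  +  Σ_{n<m} U_hc(r_nm)
        + Σ_{n<m} E_nm exp(−r_nm² / (2 r0²)),

with `E_nm = U_ns + U_s[s_n, s_m]`: a non-specific attraction between
all monomer pairs (an effective account of nuclear confinement and
crowding) plus a specific attraction between monomers of the same
chromatin state (bridging by HP1/Polycomb-group proteins, transcription
factories, lamina association).  `U_s` is a symmetric per-type-pair
table, so heterogeneous specificity (e.g. Polycomb–Polycomb stronger
than black–black) is expressed by the same code path as the uniform
model.

Reduced units: l = kT = mass = 1; MD time unit τ = l√(m/kT); the
solver's time unit is ξ l²/kT with friction ξ = 1.

## Self-consistent second-moment dynamics

The overdamped Langevin dynamics of the chain induces a Fokker–Planck
equation for the conformational distribution.  Approximating that
distribution at every instant by a centered multivariate Gaussian and
matching first/second moments closes the dynamics on the covariance —
equivalently on the per-component mean-squared-distance matrix
`D_mn = ⟨(X_m − X_n)²⟩/3`:

    ξ dD_mn/dt = 4 kT − Σ_k (⟨J⟩_mk − ⟨J⟩_nk)(D_mk − D_nk),

where ⟨J⟩ is the Gaussian-ensemble average of minus the Hessian of H,
reduced to an isotropic scalar per pair block (trace/3, consistent with
the isotropic ansatz).  For the Gaussian pair potential the averages are
closed-form:

    ⟨u⟩   = E (a² / (a² + D))^{3/2}
    tr⟨∇∇u⟩/3 = −E a³ / (a² + D)^{5/2},

(a = interaction range, D = per-component separation variance); the
harmonic chain contributes exactly −(3kT/l²)·(path-graph Laplacian).
Both forms are validated against Monte-Carlo sampling in the test suite.

Two useful exact facts, verified numerically at build time:

* the ideal-chain profile `D_mn = |m−n| l²/3` is an **exact** fixed
  point of the equation above for any N — the 4 kT noise amplitude
  needs no calibration constant (the constant contemplated as an open
  design choice is identically 1);
* every row of ⟨J⟩ sums to zero (translation invariance), which is how
  the diagonal is assembled.

## Excluded volume

MD uses the Weeks–Chandler–Andersen potential (LJ truncated and shifted
at 2^{1/6}σ; defaults σ = l, ε = kT) — the standard purely repulsive
realization of a truncated-LJ hard core.  The Gaussian average of a hard
core is not closed-form, so the solver represents excluded volume by a
repulsive Gaussian `+U_hc0 exp(−r²/(2 r_hc²))`.  Its defaults
(U_hc0 = 10 kT, r_hc = 0.3 l) are set by two requirements:

1. **Virial matching**: the integrated strength U_hc0 (2π)^{3/2} r_hc³ ≈
   4.3 l³ matches the WCA second virial (≈ 4.7 l³), so the solver and
   the MD engine describe comparably swollen chains;
2. **Contact dominance**: the repulsive curvature at contact,
   U_hc0/r_hc², must exceed the attractive curvature |E|/r0² for every
   coupling scanned, else the soft surrogate is overwhelmed and every
   strong-coupling state collapses to a type-blind point.  The defaults
   dominate up to |E| ≈ 45 kT.

With r0 = 0.5 l this places the coil–globule transition of the
120-bead toy copolymer near U_ns ≈ −2.5 kT and the entire phase diagram
at the few-kT scale.  Published parameter values for this class of model
are sometimes quoted at tens of kT; those scales depend on the
(unpublished) choices of r0 and of the hard-core treatment and are not
comparable between implementations.  The *topology* of the diagram —
coil, globule, microphase separation, and a multistability wedge between
coil and MPS — is the reproducible object.

## Integrators

`evolve(..., method="rk45")` is the reference integrator: adaptive
Dormand–Prince 5(4) (rtol 1e-6, atol 1e-8) with stationarity declared
when the dimensionless residual max|ξ dD/dt|/4kT drops below
`steady_tol` (default 1e-6).  Being explicit, it is stability-limited by
the stiffest mode of ⟨J⟩: in collapsed states |⟨J⟩| entries reach
10²–10³ kT/l², forcing steps ≲ 1e-3 and making deep-phase scans
infeasible; near a fixed point its residual also floors at ~rtol ×
stiffness, which the integrator reports by stopping on a stall counter
rather than burning `t_max`.

`method="exponential"` propagates the centered covariance exactly under
⟨J⟩ frozen over the step (a Lyapunov-equation update in the eigenbasis
of ⟨J⟩), making the stiff linear part unconditionally stable.  Step
size is adapted by three guards: a cap on the relative change of D per
step, rejection of steps whose residual grows faster than the
exponential envelope of the most unstable frozen mode (undamped
self-consistent iterations otherwise flip-flop), and a refresh of the
eigendecomposition whenever ⟨J⟩ drifts.  The two methods agree on
stationary states to <1e-2 relative Frobenius and on transient snapshots
to <5e-3 (tested), so the exponential stepper is used wherever many
solves are needed.

`polish_fixed_point` refines a near-stationary state by Jacobian-free
Newton–Krylov on the stationarity condition.  The phase-scan protocol is
therefore: integrate at a loose tolerance (scaled residual 3e-2, ≤3000
steps) to *select the basin*, then polish to an exact fixed point; for
glassy transits that resist polishing, integration is continued and the
polish retried (≤2 rounds).  The guard `max_rel_move` rejects polished
roots that moved far from the integrated state (basin-jump protection).

The slow mode this protocol sidesteps is real physics, not a solver
artifact: coil swelling relaxes on the Rouse scale (t ~ N²), and inside
the collapsed phases the copolymer orders glassily (long near-stationary
transits with a persistently unstable segregation mode) — the same
slow-compaction-then-fast-transition phenomenology the time-resolved
contact maps show.

## Initial conditions

* `init_coil` — the ideal-chain profile |m−n| l²/3 (a valid Gaussian
  embedding by construction).
* `init_globule` — coil saturated at a plateau variance.
* `init_mps` — small same-type / large cross-type variances, short-range
  chain structure kept by an elementwise minimum with the coil profile.
* `init_from_contact_map` — inverts P = A·D^{−3/2} ("experimental-like"
  starts).

Constructed matrices are projected to the nearest valid embedding by
clipping negative Gram eigenvalues (double-centering −D/2).  Phase scans
replace the coil member by the *zero-coupling swollen-coil fixed point*,
computed once per scan: for a chain with excluded volume the extended
reference state is the self-avoiding coil, and starting every weakly
coupled node from the ideal profile would repeat the same slow swelling
transient 25 times.

## Phase classification

A node is labeled from the polished fixed points reached from the init
set (default scan set: swollen coil + MPS):

* `multistable` — ≥2 distinct fixed points (relative Frobenius distance
  > 1e-2);
* `coil` — mean long-range D (pairs |m−n| ≥ N/4) above 0.5× the
  ideal-chain value;
* `MPS` — checkerboard index > 0.1, where the index is the contrast
  (mean cross-type D − mean same-type D)/(mean D) over pairs with
  |m−n| ≥ 10;
* `globule` — compact and type-blind;
* `unresolved` — a run failed to converge/polish.

Thresholds are configuration (`ClassifyParams`); their defaults are
calibrated so the four archetypes are recovered on the toy copolymer
(the published classification of this diagram is visual).  The reference
5×5 grid used by the acceptance suite is U_ns ∈ {0,−1,−2,−3,−4} ×
U_s ∈ {0,−2,−4,−6,−10} kT; all 25 labels are verified stable under
halving the solver tolerances.  An axis value of −8 was rejected during
calibration because the (0,−8) node sits exactly on a glassy basin
boundary where the coil-started run lands on either the pearl-necklace
or the merged-MPS fixed point depending on step size.

## MD engine

Velocity-Verlet with an Andersen thermostat (per-particle collision
probability ν·dt per step, Maxwell–Boltzmann resampling).  Defaults:
dt = 0.005 τ, ν = 1/τ, initial configuration a self-avoiding random walk
with bond length l, initial velocities Maxwell–Boltzmann with the center
of mass at rest.  Forces are the exact gradient of the Hamiltonian
above; all-pairs evaluation is numba-compiled (N ≲ a few hundred is the
intended regime, where all-pairs is faster than cell lists and exactly
equals the reference force).  Trajectories are bitwise reproducible for
a fixed seed.  `sample_pair_statistics` accumulates mean squared
distances and contact frequencies in chunks without storing frames, for
long equilibrium runs.

Contact maps from trajectories count frames with r < cutoff (default
1.5 l, configurable).  The contact-probability scaling test uses a
smaller radius (0.5 l) because P ∝ D^{−3/2} is the point-contact limit:
at cutoff r_c the log-log slope is −3/2 + ⟨r²⟩_{r<r_c}/(2D), a bias of
~+0.2 at r_c = 1.5 and s = 10 that would mask the asymptotic law.

Equilibration burn-in defaults to the measured 1/e decay time of the
end-to-end vector autocorrelation.

## Contact maps and comparison

P_mn = A·D_mn^{−3/2}; A is never fixed by the theory, so the default
normalizes the mean nearest-neighbor contact probability to 1 (then
clips at 1).  Comparisons are Spearman and Pearson correlations of
log-transformed entries at |m−n| ≥ min_separation, over entries positive
in both maps, plus per-separation-stratum correlations; rank-based by
default because experimental maps come in unknown normalization states.
Map diagonals are set to the maximum off-diagonal entry and excluded
from comparisons.  Log transforms use a pseudocount equal to the
smallest positive entry when zeros are present.

## What the synthetic world does and does not establish

All tests run on synthetic inputs: block patterns, random block
sequences, segmentations generated programmatically, and the package's
own MD as the conformational-sampling oracle.  A green suite establishes
internal consistency (solver ↔ simulation ↔ closed forms) and the
qualitative phase phenomenology; it does not establish agreement with
any experimental Hi-C map, which requires external data and an inference
step for (U_ns, U_s) that are both out of scope.  The comparison
machinery (`compare_maps`, experimental-like initial conditions) is the
hook for such studies.

## Known limitations

* The Gaussian ansatz underestimates excluded-volume correlations; MD
  equilibrium distances run ~10–25% above the solver's at moderate
  coupling (rank agreement is excellent, Spearman ≳ 0.99).
* Deep in the collapsed phases the scan protocol reports polished
  stationary points that may be marginally stable (glassy) states;
  their basin assignment depends on the integration path at the stated
  tolerances, which is why the label-stability check is part of
  acceptance.
* Chain crossing is only penalized energetically (no topological
  constraints); appropriate below a few Mb where topological
  confinement is negligible.
* The MD engine targets N ≲ few hundred (all-pairs forces); no
  hydrodynamics, confinement sphere, or replica exchange.
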