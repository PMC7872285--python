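# Methods

## The model class

A graph neural field places a dynamical system for neuronal-population
activity on every vertex of a *metric graph* and couples vertices by
spatial convolution.  The graph is undirected, each edge carries a
physical length M\_ij in meters, and two edge kinds are distinguished:
`local` edges (mesh/grid neighbours, length = Euclidean endpoint
distance) and `tract` edges (long-range, fast connections whose
effective length is the fiber path length divided by a conduction speed
factor, default 200 — the approximate ratio of myelinated white-matter
to local surface propagation speed).

Geometry enters through the **distance-weighted Laplacian**
Δ = A − D, A\_ij = Ã\_ij/M\_ij², D = Diag(row sums).  Under this sign
convention Δ is negative semidefinite; its eigenvalues λ\_k play the role
of −k² of the continuum Laplace operator.  (Describing the same operator
with non-negative eigenvalues is common elsewhere; we keep λ\_k ≤ 0 so
that the Gaussian filter profile e^{σ²λ/2} decays, which is the only
internally consistent choice here.)  Eigenvalues are sorted
non-increasing, so index 0 is the constant (DC) mode; eigenvector signs
are fixed by making each column's largest-magnitude entry positive,
which makes the decomposition bit-reproducible.  A Lanczos option
computes only the m smoothest modes for large graphs with a fixed
starting vector (identical values for the modes computed).

**Spectral filters.**  A symmetric spatial kernel with Fourier transform
K̂(k²) becomes the graph filter K\_g = U Diag(K̂(−λ\_k)) U^T.  All filters
are DC-normalized (K̂(0) = 1) by default so that spatially constant
signals pass unchanged; this is what reduces homogeneous steady states
to a 2-dimensional scalar problem.  The Mexican-hat profile vanishes at
DC identically, so it is normalized by its maximum over the spectrum
instead.  Rectangular/triangular filters are provided but ring (Gibbs
phenomenon) because of their spatial jump discontinuities; no
anti-ringing correction is applied.

**Wilson–Cowan field.**  Two populations per vertex (fractions of active
excitatory/inhibitory neurons), sigmoid activation, four Gaussian
filters with independent sizes, constant drives P and Q, additive white
noise of amplitude σ.  Parameters are space-independent; this is the
assumption that lets the linearized dynamics decouple per eigenmode and
is also the main modelling restriction.

## Steady states and stability

Homogeneous steady states solve d\_E E\* = S[α\_EE E\* − α\_IE I\* + P] and
its inhibitory counterpart.  A multistart root search over a 21×21 grid
of initial guesses in (0, 1/d\_E)×(0, 1/d\_I) collects all roots
(deduplicated at 1e-6, residual < 1e-10).  When several coexist, the
selected root is DC-stable (trace < 0, det > 0 of the λ=0 Jacobian) and
closest to the sigmoid midpoint (0.5/d\_E, 0.5/d\_I); degenerate roots
with vanishing sigmoid gain are flagged rather than rejected.

Linearization about (E\*, I\*) gives, per eigenmode k, a 2×2 Jacobian J\_k
whose entries scale the couplings by the filter gains e^{σ²λ\_k/2} and
the sigmoid gains a = d\_E E\*(1−d\_E E\*), b = d\_I I\*(1−d\_I I\*).  For 2×2
systems the stability verdict is Routh–Hurwitz (trace < 0 and det > 0
per mode); the report carries each mode's leading real part and whether
its eigenvalues are complex (oscillatory).

## CHAOSS

With noise power B = diag(σ²/τ\_E², σ²/τ\_I²) treated as the spectral
density of the driving noise, the mode cross-spectrum is
S\_k(ω) = [iωI − J\_k]⁻¹ B [iωI − J\_k]⁻†.  The harmonic spectrum H(k) is
its frequency integral, evaluated in closed form (the numerically
integrated version agrees to better than 1e-6 relative and serves as a
test oracle); the temporal spectrum is T(ω) = 2 Σ\_k S\_k(ω) (one-sided:
k only runs over positive indices); functional connectivity normalizes
Σ = U Diag(H) U^T to unit diagonal; coherence applies the same
normalization to the vertex-domain cross-spectrum at a single frequency.
The coherence construction diagonalizes per mode and per population,
which is exact for one population with space-independent parameters and
is applied to each population of the two-population model as an
extension (cross-population vertex correlations are not represented).
All of these refuse unstable parameter sets: fluctuation spectra about
an unstable state are not stationary, and silently returning them would
be misleading.  F and C are invariant under rescaling of σ, which
cancels in the normalization.

## Simulation

Both integrators are Euler–Maruyama with per-step noise standard
deviation (σ/τ\_pop)·√dt; under this convention the injected noise has
exactly the spectral density B of the linearized theory, which the
Ornstein–Uhlenbeck limit (all couplings zero) verifies against the
closed forms.  The nonlinear integrator works in the vertex domain with
dense filter matrices; the linearized integrator works in the graph
Fourier domain where the system is n independent 2×2 SDEs (an n-fold
dimensionality reduction), and its trajectories map to the vertex domain
by the inverse GFT.

Time steps: the explicit scheme is mean-square stable for a mode with
eigenvalue μ only if dt < −2 Re μ/|μ|²; weakly damped resonant modes
(Re μ ≈ −2.5 1/s, |Im μ| ≈ 330 rad/s in the shipped presets) therefore
need dt ≲ 4e-5 s, and the analysis runs use dt = 2e-5 s (nonlinear
boundary-straddling runs: 1e-5 s).  Euler–Maruyama also inflates the
stationary variance of a weakly damped oscillator by roughly
|μ|²dt/(2|Re μ|); at dt = 2e-5 this is tens of percent for the sharpest
resonant mode and negligible for the bulk, which is why
analytic-vs-simulated comparisons quote the median relative error across
modes.  Burn-in defaults to 10% of the steps; doubling it does not move
the estimates by more than a standard error.  A recording stride is
available to emulate TR-like downsampling, and an HDF5 streaming writer
lets long runs bypass memory.

Empirical estimators mirror the analytic objects: harmonic spectrum =
temporal mean of the squared GFT of demeaned timecourses; temporal
spectrum = averaged periodogram (boxcar windows, no overlap, so Parseval
holds within 1%) summed over vertices; functional connectivity = Pearson
correlation matrix.

## Synthetic data

The generators produce the two study settings at configurable scale:

* **Line graphs**: n vertices (default 1000) spaced h meters, open ends
  (a finite cortical line; a periodic ring variant exists for the
  filter-convergence checks, and carries no coordinates because chord
  and arc lengths differ).  Non-local edges are specified as
  (i, j, speed factor) and get effective length |i−j|·h/speed.
* **Toy two-hemisphere connectomes**: two triangulated spheres (random
  surface points + convex-hull triangulation, so any vertex count is
  realizable), physically separate, joined only by random tract edges
  whose path length is the chord times a curvature factor in [1.1, 1.6]
  divided by the speed factor.  Hemisphere radius 0.05 m and center
  separation 0.13 m are set to brain-like proportions.  Everything is
  seed-deterministic.

What the generators do *not* emulate: cortical folding, non-uniform
vertex density, tractography error structure, measurement noise and
hemodynamic filtering of real fMRI.  Passing tests on these fixtures
demonstrates internal consistency of model, analysis and simulation, not
agreement with any particular empirical dataset.

## Regime presets

The shipped parameter set was found by numerical search and is the
package's own calibration (the analyses it echoes used parameter tables
that are not available), chosen to reproduce the qualitative regime
claims on the 1000-vertex line:

    tau_E = tau_I = 0.01 s,  d_E = d_I = 1
    alpha_EE = 10.78, alpha_IE = alpha_EI = 14.2, alpha_II = 10.8
    sigma_EE = 0.01327 m, sigma_IE = sigma_EI = 1.37e-3 m, sigma_II = 0.05774 m
    P = 1.71, Q = -1.7   (placing the steady state at E* = I* = 0.5)
    sigma_noise = 1e-3

The mechanism is an *excitation window* in eigenvalue space: the
excitatory self-coupling gain a·α\_EE·e^{σ\_EE²λ/2} exceeds the combined
decay and inhibition only for λ roughly in (−3.9e3, −1.0e3).  Growing
the vertex spacing compresses the Laplacian spectrum toward zero, so the
sweep h = 1e-5 → 1e-4 → 2e-4 m moves the low harmonics from far below
the window (broadband), to its edges (weakly damped ≈ 52 Hz resonance),
to inside it (oscillatory instability at the λ ≈ −2221 harmonic).  The
(250, 750) tract edge couples strongly to exactly that harmonic and
pushes its eigenvalue below the window (eigenvalue interlacing caps the
push at the next harmonic), restoring stability.  Widening σ\_IE twentyfold
makes the cross-coupling — and hence each resonant mode's frequency
√det J\_k — fall steeply across the weakly damped band, splitting the
single resonance into peaks near 22 and 40 Hz; tripling the widening
instead drives det J\_k negative and destabilizes, so the ×20 variant
sits deliberately between the two behaviours.  Spectral peaks are
counted as interior local maxima of log10 T(ω) with prominence ≥ 0.05
decades on a 3000-point grid over (0, 1500] rad/s.

Analyses at reduced scale reuse the same ladder of Laplacian eigenvalues
by scaling the spacing with n (λ\_k ≈ −(πk/(nh))² for a line), e.g.
n = 200 at h = 5e-4 m and n = 40 at h = 2.5e-3 m reproduce the low modes
of n = 1000 at h = 1e-4 m; this keeps test and acceptance runtimes in
minutes without changing the dynamics being probed.

## Fitting

Empirical harmonic spectra are regularized by a log-log binned median
(default 300 bins; the abscissa of each bin is the median log k of its
members so exact power laws remain exactly collinear) before comparison.
The observation model is a single rescaling β whose log-domain optimum
is closed form.  The parameter search is basin-hopping (seeded random
steps within the bounds around L-BFGS-B local minimizations) on the sum
of squared differences of binned log spectra; unstable parameter sets
receive a large penalty and are counted.  Which parameters are free is a
user choice; residual degeneracy between parameters is expected, and the
contract of self-recovery is spectrum match, not parameter identity.
Mode truncation (dropping high-k modes that reach the resolution limit
of measured data) is available as `max_k` and off by default for
synthetic graphs.

## Known limitations

Space-dependent parameters, conduction delays (frequency-dependent
filters), higher-order temporal operators, directed or time-varying
graphs, and normalized Laplacians are out of scope.  Coherence for the
two-population model is the per-population extension described above.
The explicit integrator's step-size constraints near criticality are the
user's responsibility; the simulator aborts on non-finite states but
cannot detect slow mean-square growth within a short run.
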