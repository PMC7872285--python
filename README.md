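# gnfields — graph neural fields

Dynamical models of neural-population activity defined directly on
*metric graphs*: graphs whose edges carry physical lengths, such as a
triangulated cortical surface mesh augmented with fast white-matter
tracts.  The package implements

* the **distance-weighted graph Laplacian** Δ = A − D with adjacency
  weights A\_ij = 1/M\_ij², where M\_ij is the edge length in meters, and
  the graph Fourier transform (GFT) defined by its orthonormal
  eigenvectors ("connectome harmonics");
* **spectral graph filters** that translate continuous spatial
  convolution kernels (Gaussian, exponential, Mexican-hat, rectangular,
  triangular) to arbitrary metric graphs by substituting the Laplacian
  eigenvalue λ\_k for −k²;
* the **stochastic Wilson–Cowan graph neural field**

      τ_E dE/dt = −d_E E + S[α_EE K_EE E − α_IE K_IE I + P] + σ ξ_E
      τ_I dI/dt = −d_I I + S[α_EI K_EI E − α_II K_II I + Q] + σ ξ_I

  with S[x] = 1/(1+e^{−x}) and four Gaussian graph filters K of sizes
  σ\_EE, σ\_IE, σ\_EI, σ\_II (meters), plus generic Type 1 / Type 2
  single-operator fields;
* **CHAOSS** (Connectome-Harmonic Analysis Of Spatiotemporal Spectra):
  closed-form harmonic power spectra H(k), temporal power spectra T(ω),
  functional-connectivity (correlation) matrices and coherence matrices
  of the fluctuations about a stable homogeneous steady state, obtained
  from the per-eigenmode 2×2 Jacobians

      S_k(ω) = [iωI − J_k]⁻¹ B [iωI − J_k]⁻†,
      H(k) = (1/2π) ∫ S_k(ω) dω   (closed form),
      T(ω) = 2 Σ_k S_k(ω),  Σ = U Diag(H) U^T,  F = D^{-1/2} Σ D^{-1/2};

* **stochastic simulation** (Euler–Maruyama) of the nonlinear field and
  of the n decoupled linearized mode systems, with matched empirical
  estimators (harmonic spectrum = temporal mean of the squared GFT);
* **spectrum fitting**: log-log binned-median regularization, a linear
  observation model H\_obs(k) = β·H\_model(k), and a seeded basin-hopping
  search over bounded model parameters.

The intended users are computational neuroscientists modelling
whole-brain resting-state activity at vertex-wise (unparcellated)
resolution, and anyone studying linear(ized) stochastic dynamics on
weighted graphs.

## Worked example

A 1000-vertex cortical line with spacing h = 1e-4 m, destabilized by
increasing h and rescued by one fast non-local edge:

```python
import numpy as np
from gnfields import (GraphWilsonCowan, LineGraphSpec, make_line_graph,
                      regime_presets, temporal_peaks, temporal_spectrum)

presets = regime_presets()
for name in ("broadband", "resonance", "oscillatory_instability", "rescued",
             "long_range_inhibition"):
    preset = presets[name]
    model = GraphWilsonCowan(preset.graph(), preset.params)
    report = model.stability()
    line = f"{name:24s} stable={report.stable!s:5s} " \
           f"leading Re={report.leading_real_part:+8.2f} 1/s"
    if report.stable:
        omega = np.linspace(0.0, 1500.0, 3000)
        t = temporal_spectrum(model.mode_system(), "E", omega)
        hz = temporal_peaks(omega, t) / (2 * np.pi)
        line += f"  peaks at {np.round(hz, 1)} Hz"
    print(line)
```

prints

```
broadband                stable=True  leading Re=  -99.98 1/s  peaks at [] Hz
resonance                stable=True  leading Re=   -2.52 1/s  peaks at [51.2 54.2] Hz
oscillatory_instability  stable=False leading Re=   +7.49 1/s
rescued                  stable=True  leading Re=   -2.51 1/s  peaks at [51.2 54.2] Hz
long_range_inhibition    stable=True  leading Re=   -2.51 1/s  peaks at [22.5 40.4] Hz
```

Reading the output: at spacing h = 1e-5 m every eigenmode is heavily
damped (leading eigenvalue real part ≈ −100 1/s, the decay rate d/τ) and
the temporal spectrum is featureless broadband.  At h = 1e-4 m the first
non-constant harmonics become weakly damped (−2.5 1/s) and oscillate
near 52 Hz — a spectral resonance.  At h = 2e-4 m one harmonic crosses
into positive real part: a limit-cycle instability.  Adding a single
tract edge between vertices 250 and 750 (effective length 2.5e-4 m =
Euclidean span 5e-2 m divided by the myelination speed factor 200)
pushes that harmonic out of the unstable band and restores stable
resonance.  Widening the inhibitory-to-excitatory kernel twentyfold
(σ\_IE × 20) splits the resonance into two peaks, at ≈ 22 and 40 Hz.

The same model objects expose the analytic observables and simulation:

```python
model = GraphWilsonCowan(presets["resonance"].graph(), presets["resonance"].params)
bundle = model.chaoss(np.linspace(0, 1500, 3000))   # H(k), T(omega), FC
run = model.simulate_linearized(dt=2e-5, n_steps=500_000, seed=0, stride=100)
```

A command-line pipeline wraps the library (`gnfields line-graph`,
`build-graph`, `chaoss`, `simulate`, `empirical`, `stability`, `fit`,
`compare`); see `gnfields --help`.

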