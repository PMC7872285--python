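"""Stochastic Wilson-Cowan dynamics on metric graphs.

The model tracks the fractions E(t), I(t) of active excitatory and
inhibitory neurons at every graph vertex:

    tau_E dE/dt = -d_E E + S[a_EE K_EE E - a_IE K_IE I + P] + sigma xi_E
    tau_I dI/dt = -d_I I + S[a_EI K_EI E - a_II K_II I + Q] + sigma xi_I

where S[x] = 1/(1+exp(-x)), the K_** are Gaussian graph filters of sizes
sigma_** built on the distance-weighted Laplacian spectrum, P and Q are
constant subcortical drives, and xi are white-noise realizations.  Because
the filters are DC-normalized, spatially homogeneous steady states solve a
two-dimensional scalar fixed-point problem independent of the graph.

Linearizing about a homogeneous steady state (E*, I*) and moving to the
graph Fourier domain decouples the system into n independent 2x2 linear
SDEs, one per Laplacian eigenmode k, with Jacobian

    J_k = [[-d_E/tau_E + (a/tau_E) a_EE g_EE(k),  -(a/tau_E) a_IE g_IE(k)],
           [ (b/tau_I) a_EI g_EI(k),  -(b/tau_I) a_II g_II(k) - d_I/tau_I]]

where g_**(k) = exp(sigma_**^2 lambda_k / 2) and the sigmoid gains are
a = d_E E*(1 - d_E E*), b = d_I I*(1 - d_I I*).  The shared noise-power
matrix is B = diag(sigma^2/tau_E^2, sigma^2/tau_I^2), interpreted as the
covariance power entering the cross-spectrum S_k = K B K^dagger.  The
linear stability of the steady state is the stability of every J_k.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.optimize

from .graph import LaplacianSpectrum, MetricGraph, eigendecompose, weighted_laplacian
from .kernels import KernelSpec, build_filter

__all__ = [
    "WilsonCowanParams",
    "SteadyState",
    "ModeSystem",
    "StabilityReport",
    "sigmoid",
    "wc_filters",
    "wc_drift",
    "find_steady_state",
    "mode_jacobian",
    "noise_matrix",
    "build_mode_system",
    "stability_analysis",
    "GenericGraphField",
    "GraphWilsonCowan",
]


def sigmoid(x):
    """Numerically stable logistic function 1/(1+exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WilsonCowanParams:
    """The 15 scalar parameters of the stochastic Wilson-Cowan graph field.

    Times in seconds, kernel sizes in meters; couplings, decay rates and
    drives are dimensionless.  ``sigma_noise`` is the white-noise amplitude
    sigma of the stochastic terms.
    """

    tau_e: float
    tau_i: float
    d_e: float
    d_i: float
    alpha_ee: float
    alpha_ie: float
    alpha_ei: float
    alpha_ii: float
    sigma_ee: float
    sigma_ie: float
    sigma_ei: float
    sigma_ii: float
    p: float
    q: float
    sigma_noise: float

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "d_e", "d_i",
                     "sigma_ee", "sigma_ie", "sigma_ei", "sigma_ii"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_ee", "alpha_ie", "alpha_ei", "alpha_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")

    def replace(self, **kw) -> "WilsonCowanParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path) -> None:
        """Write a flat ``name = value`` parameter file."""
        units = {
            "tau_e": "s", "tau_i": "s", "sigma_ee": "m", "sigma_ie": "m",
            "sigma_ei": "m", "sigma_ii": "m",
        }
        lines = ["# Wilson-Cowan graph neural field parameters"]
        for k, v in self.to_dict().items():
            u = f"  # {units[k]}" if k in units else ""
            lines.append(f"{k} = {v!r}{u}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def from_file(cls, path) -> "WilsonCowanParams":
        if hasattr(path, "read"):
            text = path.read()
        else:
            with open(path) as fh:
                text = fh.read()
        values = {}
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            m = re.match(r"(\w+)\s*=\s*(\S+)", line)
            if not m:
                raise ValueError(f"malformed parameter line: {line!r}")
            values[m.group(1)] = float(m.group(2))
        return cls(**values)


@dataclass(frozen=True)
class SteadyState:
    """A spatially homogeneous fixed point and its linearization gains."""

    e_star: float
    i_star: float
    a: float  # d_E E* (1 - d_E E*)
    b: float  # d_I I* (1 - d_I I*)
    residual: float = 0.0
    degenerate: bool = False  # sigmoid gain vanished (d E* at 0 or 1)

    @property
    def state(self) -> np.ndarray:
        return np.array([self.e_star, self.i_star])


@dataclass(frozen=True)
class ModeSystem:
    """Per-eigenmode linearization: 2x2 Jacobians and shared noise power."""

    jacobians: np.ndarray  # (n_modes, 2, 2)
    noise_power: np.ndarray  # (2, 2) diagonal B
    eigenvalues: np.ndarray  # (n_modes,) Laplacian eigenvalues

    @property
    def n_modes(self) -> int:
        return self.jacobians.shape[0]


@dataclass(frozen=True)
class StabilityReport:
    """Leading real parts of the per-mode Jacobian eigenvalues."""

    max_real_parts: np.ndarray  # (n_modes,), 1/s
    oscillatory: np.ndarray  # bool per mode: complex eigenvalue pair
    stable: bool
    leading_mode: int  # index of the most unstable mode

    @property
    def leading_real_part(self) -> float:
        return float(self.max_real_parts[self.leading_mode])

    @property
    def leading_oscillatory(self) -> bool:
        return bool(self.oscillatory[self.leading_mode])


def _steady_residual(state, params: WilsonCowanParams):
    e, i = state
    pr = params
    re_ = pr.d_e * e - sigmoid(pr.alpha_ee * e - pr.alpha_ie * i + pr.p)
    ri_ = pr.d_i * i - sigmoid(pr.alpha_ei * e - pr.alpha_ii * i + pr.q)
    return np.array([re_, ri_])


def find_steady_state(
    params: WilsonCowanParams,
    grid: int = 21,
    return_all: bool = False,
):
    """Locate homogeneous steady states of the Wilson-Cowan field.

    A multistart root search over a ``grid x grid`` lattice of initial
    guesses in (0, 1/d_E) x (0, 1/d_I); roots are deduplicated at 1e-6
    distance and must satisfy a residual below 1e-10.  The *selected* root
    is the one whose DC-mode (lambda = 0) Jacobian is stable, preferring
    the root closest to the sigmoid midpoint (0.5/d_E, 0.5/d_I); if no
    root is DC-stable the closest-to-midpoint root is selected.

    Returns the selected :class:`SteadyState`, or ``(selected, all_roots)``
    when ``return_all`` is true.
    """
    pr = params
    roots: list[np.ndarray] = []
    guesses_e = np.linspace(0.0, 1.0 / pr.d_e, grid + 2)[1:-1]
    guesses_i = np.linspace(0.0, 1.0 / pr.d_i, grid + 2)[1:-1]
    for ge in guesses_e:
        for gi in guesses_i:
            sol = scipy.optimize.root(
                _steady_residual, x0=[ge, gi], args=(pr,), method="hybr",
                options={"xtol": 1e-13},
            )
            if not sol.success:
                continue
            res = np.abs(_steady_residual(sol.x, pr)).max()
            if res > 1e-10:
                continue
            if any(np.linalg.norm(sol.x - r) < 1e-6 for r in roots):
                continue
            roots.append(sol.x)
    if not roots:
        raise RuntimeError(
            "no homogeneous steady state found: the multistart root search "
            f"over a {grid}x{grid} grid in (0,1/d_E)x(0,1/d_I) produced no "
            "root with residual < 1e-10; check parameter magnitudes"
        )

    def make_state(x) -> SteadyState:
        e, i = float(x[0]), float(x[1])
        de, di = pr.d_e * e, pr.d_i * i
        a = de * (1.0 - de)
        b = di * (1.0 - di)
        res = float(np.abs(_steady_residual(x, pr)).max())
        degenerate = min(abs(a), abs(b)) < 1e-12
        return SteadyState(e, i, a, b, residual=res, degenerate=degenerate)

    states = [make_state(x) for x in sorted(roots, key=lambda r: (r[0], r[1]))]
    center = np.array([0.5 / pr.d_e, 0.5 / pr.d_i])

    def dc_stable(st: SteadyState) -> bool:
        j0 = mode_jacobian(pr, st, 0.0)
        return bool(np.trace(j0) < 0 and np.linalg.det(j0) > 0)

    stable_states = [s for s in states if dc_stable(s)]
    pool = stable_states or states
    selected = min(pool, key=lambda s: np.linalg.norm(s.state - center))
    if return_all:
        return selected, states
    return selected


def _gaussian_gain(sigma: float, lam) -> np.ndarray:
    return np.exp(sigma**2 * np.minimum(np.asarray(lam, dtype=float), 0.0) / 2.0)


def mode_jacobian(params: WilsonCowanParams, steady: SteadyState, lam: float) -> np.ndarray:
    """2x2 Jacobian of the linearized dynamics in eigenmode with eigenvalue lam."""
    pr, a, b = params, steady.a, steady.b
    gee = _gaussian_gain(pr.sigma_ee, lam)
    gie = _gaussian_gain(pr.sigma_ie, lam)
    gei = _gaussian_gain(pr.sigma_ei, lam)
    gii = _gaussian_gain(pr.sigma_ii, lam)
    return np.array([
        [-pr.d_e / pr.tau_e + (a / pr.tau_e) * pr.alpha_ee * gee,
         -(a / pr.tau_e) * pr.alpha_ie * gie],
        [(b / pr.tau_i) * pr.alpha_ei * gei,
         -(b / pr.tau_i) * pr.alpha_ii * gii - pr.d_i / pr.tau_i],
    ])


def noise_matrix(params: WilsonCowanParams) -> np.ndarray:
    """Noise power (covariance) matrix B = diag(sigma^2/tau_E^2, sigma^2/tau_I^2)."""
    s2 = params.sigma_noise**2
    return np.diag([s2 / params.tau_e**2, s2 / params.tau_i**2])


def build_mode_system(
    params: WilsonCowanParams,
    eigenvalues: np.ndarray,
    steady: Optional[SteadyState] = None,
) -> ModeSystem:
    """Assemble per-mode Jacobians J_k and noise power B for all eigenmodes."""
    if steady is None:
        steady = find_steady_state(params)
    lam = np.minimum(np.asarray(eigenvalues, dtype=float), 0.0)
    pr, a, b = params, steady.a, steady.b
    gee = _gaussian_gain(pr.sigma_ee, lam)
    gie = _gaussian_gain(pr.sigma_ie, lam)
    gei = _gaussian_gain(pr.sigma_ei, lam)
    gii = _gaussian_gain(pr.sigma_ii, lam)
    jac = np.empty((lam.size, 2, 2))
    jac[:, 0, 0] = -pr.d_e / pr.tau_e + (a / pr.tau_e) * pr.alpha_ee * gee
    jac[:, 0, 1] = -(a / pr.tau_e) * pr.alpha_ie * gie
    jac[:, 1, 0] = (b / pr.tau_i) * pr.alpha_ei * gei
    jac[:, 1, 1] = -(b / pr.tau_i) * pr.alpha_ii * gii - pr.d_i / pr.tau_i
    return ModeSystem(jacobians=jac, noise_power=noise_matrix(pr), eigenvalues=lam)


def stability_analysis(modes: ModeSystem) -> StabilityReport:
    """Per-mode leading eigenvalue real parts and the overall verdict.

    For a 2x2 Jacobian the eigenvalues are tr/2 +- sqrt(tr^2/4 - det); a
    mode is oscillatory when the discriminant is negative (complex pair).
    The steady state is stable iff every mode's leading real part is < 0.
    """
    j = modes.jacobians
    tr = j[:, 0, 0] + j[:, 1, 1]
    det = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
    disc = tr**2 / 4.0 - det
    oscillatory = disc < 0
    max_real = np.where(oscillatory, tr / 2.0, tr / 2.0 + np.sqrt(np.maximum(disc, 0.0)))
    leading = int(np.argmax(max_real))
    return StabilityReport(
        max_real_parts=max_real,
        oscillatory=oscillatory,
        stable=bool(np.all(max_real < 0)),
        leading_mode=leading,
    )


# ---------------------------------------------------------------------------
# generic graph neural fields (Type 1 / Type 2) and the Wilson-Cowan model


class GenericGraphField:
    """A first-order graph neural field with p interacting populations.

    Type 1 (membrane-potential interpretation):

        tau_s du_s/dt = -d_s u_s + sum_t w_st K_st S[u_t] + drive_s

    Type 2 (active-fraction interpretation):

        tau_s du_s/dt = -d_s u_s + S[sum_t w_st K_st u_t + drive_s]

    ``weights`` is the signed coupling matrix w_st (p x p) and ``filters``
    the matching matrix of :class:`~gnfields.kernels.GraphFilter` objects
    (``None`` entries mean no spatial spread, i.e. the identity filter).
    """

    def __init__(
        self,
        kind: int,
        tau: Sequence[float],
        decay: Sequence[float],
        weights: np.ndarray,
        filters,
        drives: Sequence[float],
        activation: Callable = sigmoid,
    ):
        if kind not in (1, 2):
            raise ValueError("kind must be 1 (Type 1) or 2 (Type 2)")
        self.kind = kind
        self.tau = np.asarray(tau, dtype=float)
        self.decay = np.asarray(decay, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.filters = filters
        self.drives = np.asarray(drives, dtype=float)
        self.activation = activation
        self.p = len(self.tau)

    def _coupled(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros_like(u)
        for s in range(self.p):
            acc = np.zeros(u.shape[1])
            for t in range(self.p):
                w = self.weights[s, t]
                if w == 0:
                    continue
                filt = self.filters[s][t]
                term = u[t] if filt is None else filt.apply(u[t])
                acc = acc + w * term
            out[s] = acc + self.drives[s]
        return out

    def drift(self, u: np.ndarray) -> np.ndarray:
        """Deterministic du/dt for state u of shape (p, n)."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        if self.kind == 2:
            act = self.activation(self._coupled(u))
        else:
            # Type 1 applies S inside the coupling sum; drives add linearly
            act = self._coupled(self.activation(u))
        return (-self.decay[:, None] * u + act) / self.tau[:, None]


def wc_filters(params: WilsonCowanParams, spectrum: LaplacianSpectrum) -> dict:
    """The four DC-normalized Gaussian graph filters K_EE, K_IE, K_EI, K_II."""
    return {
        key: build_filter(spectrum, KernelSpec("gaussian", getattr(params, f"sigma_{key}")))
        for key in ("ee", "ie", "ei", "ii")
    }


def wc_drift(
    e: np.ndarray,
    i: np.ndarray,
    params: WilsonCowanParams,
    filters: dict,
) -> tuple:
    """Deterministic (dE/dt, dI/dt) of the Wilson-Cowan graph field."""
    e = np.asarray(e, dtype=float)
    i = np.asarray(i, dtype=float)
    if e.shape != i.shape:
        raise ValueError("E and I must have the same shape")
    pr = params
    arg_e = pr.alpha_ee * filters["ee"].apply(e) - pr.alpha_ie * filters["ie"].apply(i) + pr.p
    arg_i = pr.alpha_ei * filters["ei"].apply(e) - pr.alpha_ii * filters["ii"].apply(i) + pr.q
    de = (-pr.d_e * e + sigmoid(arg_e)) / pr.tau_e
    di = (-pr.d_i * i + sigmoid(arg_i)) / pr.tau_i
    return de, di


class GraphWilsonCowan:
    """Stochastic Wilson-Cowan neural field bound to a metric graph.

    The central model object: it owns the Laplacian spectrum, the four
    Gaussian graph filters, the homogeneous steady state and the per-mode
    linearization, and exposes analytic observables (via
    :mod:`gnfields.chaoss`) and stochastic simulation (via
    :mod:`gnfields.simulate`).

    Parameters
    ----------
    graph : MetricGraph or LaplacianSpectrum
        The spatial substrate.  Passing a precomputed spectrum avoids
        repeated eigendecompositions.
    params : WilsonCowanParams
    """

    def __init__(self, graph, params: WilsonCowanParams):
        if isinstance(graph, LaplacianSpectrum):
            self.graph: Optional[MetricGraph] = None
            self.spectrum = graph
        elif isinstance(graph, MetricGraph):
            self.graph = graph
            self.spectrum = eigendecompose(weighted_laplacian(graph))
        else:
            raise TypeError("graph must be a MetricGraph or LaplacianSpectrum")
        self.params = params
        self._filters: Optional[dict] = None
        self._steady: Optional[SteadyState] = None
        self._modes: Optional[ModeSystem] = None

    @property
    def n_vertices(self) -> int:
        return self.spectrum.n_vertices

    @property
    def filters(self) -> dict:
        if self._filters is None:
            self._filters = wc_filters(self.params, self.spectrum)
        return self._filters

    def as_generic_field(self) -> GenericGraphField:
        """The model expressed as the built-in Type 2 two-population field."""
        f = self.filters
        pr = self.params
        return GenericGraphField(
            kind=2,
            tau=[pr.tau_e, pr.tau_i],
            decay=[pr.d_e, pr.d_i],
            weights=np.array([[pr.alpha_ee, -pr.alpha_ie], [pr.alpha_ei, -pr.alpha_ii]]),
            filters=[[f["ee"], f["ie"]], [f["ei"], f["ii"]]],
            drives=[pr.p, pr.q],
        )

    def drift(self, e: np.ndarray, i: np.ndarray) -> tuple:
        return wc_drift(e, i, self.params, self.filters)

    def steady_state(self, **kw) -> SteadyState:
        if self._steady is None:
            self._steady = find_steady_state(self.params, **kw)
        return self._steady

    def mode_system(self) -> ModeSystem:
        if self._modes is None:
            self._modes = build_mode_system(
                self.params, self.spectrum.eigenvalues, self.steady_state()
            )
        return self._modes

    def stability(self) -> StabilityReport:
        return stability_analysis(self.mode_system())

    def chaoss(self, omega: np.ndarray, population: str = "E",
               with_coherence: bool = False):
        from .chaoss import spectra_bundle

        return spectra_bundle(
            self.mode_system(), self.spectrum.eigenvectors, omega,
            population=population, with_coherence=with_coherence,
        )

    def simulate(self, dt: float, n_steps: int, seed: int, **kw):
        from .simulate import simulate_wc

        return simulate_wc(self, dt=dt, n_steps=n_steps, seed=seed, **kw)

    def simulate_linearized(self, dt: float, n_steps: int, seed: int, **kw):
        from .simulate import simulate_linearized_spectral

        return simulate_linearized_spectral(
            self.mode_system(), dt=dt, n_steps=n_steps, seed=seed, **kw
        )
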