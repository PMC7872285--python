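"""Fitting analytic harmonic spectra to empirical ones.

Empirical harmonic spectra (e.g. the temporal mean of the squared GFT of
fMRI timecourses) are regularized by a log-log binned median before
comparison: mode indices k are binned on a logarithmic axis (300 bins by
default) and the median of log10 H within each bin is taken.  The
observation model is a single linear rescaling

    H_obs(k) = beta * H_model(k),

whose optimal beta has a closed form in the log domain (an intercept
shift).  Model parameters are then optimized by a seeded basin-hopping
search (random perturbations around local L-BFGS-B minimizations) of the
sum of squared differences between binned log spectra; parameter sets
whose linearization is unstable are rejected with a large penalty
(fluctuation spectra about unstable states do not exist).

The fit is exposed statsmodels-style: :class:`HarmonicSpectrumFit` is the
model (data + builder + free-parameter box), ``fit()`` returns a
:class:`FitResults` with the estimates, the residual trace and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import scipy.optimize

from .graph import LaplacianSpectrum
from .wilson_cowan import WilsonCowanParams, build_mode_system, find_steady_state, stability_analysis
from .chaoss import harmonic_spectrum

__all__ = [
    "BinnedSpectrum",
    "loglog_binned_median",
    "observation_model",
    "fit_beta",
    "WilsonCowanSpectrumBuilder",
    "HarmonicSpectrumFit",
    "FitResults",
]

_UNSTABLE_PENALTY = 1e6


@dataclass(frozen=True)
class BinnedSpectrum:
    """Log-log binned median of a harmonic spectrum.

    ``log10_k`` are bin centers (log10 of mode index), ``log10_h`` the
    per-bin medians of log10 H, ``counts`` the modes per bin; empty bins
    are dropped and their indices reported in ``empty_bins``.
    """

    log10_k: np.ndarray
    log10_h: np.ndarray
    counts: np.ndarray
    empty_bins: np.ndarray


def loglog_binned_median(
    h: np.ndarray, n_bins: int = 300, k_start: int = 2
) -> BinnedSpectrum:
    """Median of log10 H in bins equally spaced in log10 k.

    Mode indices are 1-based with k = 1 the constant mode; binning starts
    at ``k_start`` (the first non-constant mode by default).  Modes with
    non-positive power are excluded (they have no logarithm); an all-zero
    spectrum is an error.
    """
    h = np.asarray(h, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not np.any(h > 0):
        raise ValueError("harmonic spectrum is identically zero")
    k = np.arange(1, h.size + 1)
    mask = (k >= k_start) & (h > 0)
    if not mask.any():
        raise ValueError("no modes left after excluding k < k_start and H <= 0")
    logk = np.log10(k[mask].astype(float))
    logh = np.log10(h[mask])
    lo, hi = logk.min(), logk.max()
    if hi == lo:
        edges = np.array([lo - 0.5, lo + 0.5])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, logk, side="right") - 1, 0, n_bins - 1)
    centers, medians, counts, empty = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            empty.append(b)
            continue
        # abscissa = median log-k of the bin members, so that an exact
        # power law stays exactly collinear after binning
        centers.append(np.median(logk[sel]))
        medians.append(np.median(logh[sel]))
        counts.append(int(sel.sum()))
    return BinnedSpectrum(
        log10_k=np.array(centers),
        log10_h=np.array(medians),
        counts=np.array(counts),
        empty_bins=np.array(empty, dtype=int),
    )


def observation_model(h_model: np.ndarray, beta: float) -> np.ndarray:
    """Linear observation model: predicted spectrum beta * H_model."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    return beta * np.asarray(h_model, dtype=float)


def fit_beta(binned_model: BinnedSpectrum, binned_obs: BinnedSpectrum) -> float:
    """Closed-form least-squares rescaling on binned log spectra.

    In the log domain beta is an intercept: the optimizer of
    sum (log10(beta H_m) - log10 H_o)^2 is
    log10 beta = mean(log10 H_o - log10 H_m) over shared bins.
    """
    if len(binned_model.log10_h) != len(binned_obs.log10_h):
        raise ValueError("binned spectra must share the same bins")
    return float(10.0 ** np.mean(binned_obs.log10_h - binned_model.log10_h))


class WilsonCowanSpectrumBuilder:
    """Map a named-parameter dict to the analytic harmonic spectrum H(k).

    Callable used by :class:`HarmonicSpectrumFit`: overrides the template
    parameters with the free values, finds the homogeneous steady state,
    builds the per-mode linearization on the stored eigenvalues, and
    returns H for the requested population.  Raises
    :class:`~gnfields.chaoss.UnstableModeError` for unstable sets.
    """

    def __init__(self, spectrum: LaplacianSpectrum, template: WilsonCowanParams,
                 population: str = "E"):
        self.eigenvalues = spectrum.eigenvalues
        self.template = template
        self.population = population

    def __call__(self, free: Dict[str, float]) -> np.ndarray:
        params = self.template.replace(**free)
        steady = find_steady_state(params, grid=7)
        modes = build_mode_system(params, self.eigenvalues, steady)
        return harmonic_spectrum(modes, self.population)

    def is_stable(self, free: Dict[str, float]) -> bool:
        params = self.template.replace(**free)
        steady = find_steady_state(params, grid=7)
        modes = build_mode_system(params, self.eigenvalues, steady)
        return stability_analysis(modes).stable


@dataclass(frozen=True)
class FitResults:
    """Outcome of a harmonic-spectrum fit."""

    params: Dict[str, float]
    beta: float
    residual: float
    n_unstable_rejections: int
    n_evaluations: int
    trace: np.ndarray  # best residual after each basin-hopping iteration
    success: bool
    message: str

    def summary(self) -> str:
        lines = [
            "Harmonic-spectrum fit",
            "=" * 46,
            f"{'residual (binned log10 SSR)':34s} {self.residual:.6g}",
            f"{'beta (observation rescaling)':34s} {self.beta:.6g}",
            f"{'objective evaluations':34s} {self.n_evaluations}",
            f"{'unstable rejections':34s} {self.n_unstable_rejections}",
            f"{'converged':34s} {self.success}",
            "-" * 46,
        ]
        for name, value in self.params.items():
            lines.append(f"{name:34s} {value:.6g}")
        return "\n".join(lines)


class HarmonicSpectrumFit:
    """Fit free Wilson-Cowan (or any builder's) parameters to a spectrum.

    Parameters
    ----------
    h_obs : array
        Empirical harmonic spectrum over modes k = 1..n.
    builder : callable
        Maps ``{name: value}`` to a model H(k) (e.g.
        :class:`WilsonCowanSpectrumBuilder`).  Must raise for unstable
        parameter sets.
    bounds : dict
        ``{name: (lo, hi)}`` finite box for each free parameter.
    max_k : int, optional
        Mode-truncation: only modes k <= max_k enter the objective
        (high modes of measured data may carry resolution artifacts).
    n_bins : int
        Bins of the log-log median regularization (default 300).
    """

    def __init__(
        self,
        h_obs: np.ndarray,
        builder: Callable,
        bounds: Dict[str, Tuple[float, float]],
        max_k: Optional[int] = None,
        n_bins: int = 300,
        k_start: int = 2,
    ):
        self.h_obs = np.asarray(h_obs, dtype=float)
        self.builder = builder
        self.names = list(bounds)
        self.bounds = [tuple(map(float, bounds[n])) for n in self.names]
        for n, (lo, hi) in zip(self.names, self.bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {n} must be finite with lo < hi")
        self.max_k = max_k
        self.n_bins = n_bins
        self.k_start = k_start
        self._obs_binned = loglog_binned_median(
            self._truncate(self.h_obs), n_bins=n_bins, k_start=k_start
        )

    def _truncate(self, h: np.ndarray) -> np.ndarray:
        return h[: self.max_k] if self.max_k is not None else h

    def residual_of(self, h_model: np.ndarray) -> Tuple[float, float]:
        """(SSR, beta) of a model spectrum against the stored observation."""
        bm = loglog_binned_median(
            self._truncate(np.asarray(h_model, dtype=float)),
            n_bins=self.n_bins, k_start=self.k_start,
        )
        if len(bm.log10_h) != len(self._obs_binned.log10_h):
            # bin layouts can differ if the model zeroes some modes
            raise ValueError("model and observed binned spectra are incompatible")
        beta = fit_beta(bm, self._obs_binned)
        diff = bm.log10_h + np.log10(beta) - self._obs_binned.log10_h
        return float(np.sum(diff**2)), beta

    def fit(self, seed: int = 0, n_iter: int = 30,
            x0: Optional[np.ndarray] = None) -> FitResults:
        """Seeded basin-hopping minimization over the bounded parameters."""
        counters = {"unstable": 0, "evals": 0}

        def objective(x):
            counters["evals"] += 1
            free = dict(zip(self.names, x))
            try:
                h_model = self.builder(free)
            except Exception:
                counters["unstable"] += 1
                return _UNSTABLE_PENALTY
            if not np.all(np.isfinite(h_model)) or not np.any(h_model > 0):
                counters["unstable"] += 1
                return _UNSTABLE_PENALTY
            try:
                ssr, _ = self.residual_of(h_model)
            except ValueError:
                counters["unstable"] += 1
                return _UNSTABLE_PENALTY
            return ssr

        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        if x0 is None:
            x0 = (lo + hi) / 2.0
        rng = np.random.default_rng(seed)
        trace = []

        class BoundedStep:
            def __init__(self, stepsize=0.25):
                self.stepsize = stepsize

            def __call__(self, x):
                step = rng.uniform(-1.0, 1.0, size=x.size) * self.stepsize * (hi - lo)
                return np.clip(x + step, lo, hi)

        def record(x, f, accept):
            trace.append(f)

        result = scipy.optimize.basinhopping(
            objective,
            x0=np.clip(np.asarray(x0, dtype=float), lo, hi),
            niter=n_iter,
            take_step=BoundedStep(),
            minimizer_kwargs={
                "method": "L-BFGS-B",
                "bounds": self.bounds,
            },
            callback=record,
            seed=np.random.default_rng(seed + 1),
        )
        best = np.clip(result.x, lo, hi)
        free = dict(zip(self.names, best))
        try:
            h_model = self.builder(free)
            ssr, beta = self.residual_of(h_model)
        except Exception:
            return FitResults(
                params=free, beta=float("nan"), residual=float("inf"),
                n_unstable_rejections=counters["unstable"],
                n_evaluations=counters["evals"],
                trace=np.minimum.accumulate(np.array(trace)) if trace else np.array([]),
                success=False,
                message="no stable parameter set found within the search budget",
            )
        return FitResults(
            params=free, beta=beta, residual=ssr,
            n_unstable_rejections=counters["unstable"],
            n_evaluations=counters["evals"],
            trace=np.minimum.accumulate(np.array(trace)) if trace else np.array([]),
            success=bool(ssr < _UNSTABLE_PENALTY),
            message=str(result.message),
        )
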