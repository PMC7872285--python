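"""Spectral graph filters for continuous spatial convolution kernels.

A spatially symmetric convolution kernel K(x) with Fourier transform
K̂(k) depends on k only through k**2.  On a metric graph the role of
``-k**2`` is played by the (non-positive) eigenvalues of the
distance-weighted Laplacian, so substituting lambda_k for -k**2 yields the
kernel's graph-domain filter profile.  Supported families:

    gaussian       K̂g(lambda) = exp(sigma**2 lambda / 2)
    exponential    K̂g(lambda) = 1 / (alpha**2 - lambda)
    mexican_hat    K̂g(lambda) = -lambda * exp(sigma**2 lambda / 2)
    rectangular    K̂g(lambda) = sinc(sqrt(-lambda) / (2 pi a))
    triangular     K̂g(lambda) = sinc(sqrt(-lambda) / (2 pi a))**2

with sinc(x) = sin(pi x)/(pi x).  Filtering multiplies GFT coefficients by
the profile; in the vertex domain this is the symmetric matrix
K_g = U Diag(K̂g(lambda_1..n)) U^T.

DC normalization (on by default) rescales the profile so K̂g(0) = 1,
which makes every filter preserve spatially constant signals -- the
property the homogeneous steady-state reduction of the neural-field
models relies on.  The mexican-hat profile vanishes identically at
lambda = 0, so it is instead normalized by its maximum over the spectrum.
The rectangular and triangular filters have jump discontinuities in the
spatial domain and exhibit the Gibbs phenomenon; no anti-ringing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .graph import LaplacianSpectrum

__all__ = ["KernelSpec", "GraphFilter", "spectral_profile", "build_filter", "apply_filter"]

FAMILIES = ("gaussian", "exponential", "mexican_hat", "rectangular", "triangular")

_LAMBDA_TOL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its size parameter.

    ``size`` is sigma in meters for gaussian/mexican_hat, alpha in 1/m for
    exponential, and a in 1/m for rectangular/triangular.
    """

    family: str
    size: float
    normalize_dc: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {FAMILIES}")
        if not (self.size > 0 and np.isfinite(self.size)):
            raise ValueError("kernel size parameter must be positive and finite")


def _raw_profile(kernel: KernelSpec, lam: np.ndarray) -> np.ndarray:
    s = kernel.size
    if kernel.family == "gaussian":
        return np.exp(s**2 * lam / 2.0)
    if kernel.family == "exponential":
        return 1.0 / (s**2 - lam)
    if kernel.family == "mexican_hat":
        return -lam * np.exp(s**2 * lam / 2.0)
    # np.sinc already is the normalized sinc sin(pi x)/(pi x), with sinc(0)=1
    arg = np.sqrt(-lam) / (2.0 * np.pi * s)
    if kernel.family == "rectangular":
        return np.sinc(arg)
    return np.sinc(arg) ** 2


def spectral_profile(kernel: KernelSpec, eigenvalue: Union[float, np.ndarray]) -> np.ndarray:
    """Evaluate the kernel's graph-domain profile at Laplacian eigenvalue(s).

    Eigenvalues must be non-positive (small positive round-off up to 1e-10
    is clipped to zero).  With ``normalize_dc`` the profile is divided by
    its value at lambda = 0 when that value is nonzero; the mexican-hat
    profile (zero at DC) is returned unnormalized here and normalized by
    its spectral maximum in :func:`build_filter`.
    """
    lam = np.asarray(eigenvalue, dtype=float)
    # round-off from eigendecomposition scales with the spectral radius
    tol = max(_LAMBDA_TOL, 1e-12 * float(np.abs(lam).max(initial=0.0)))
    if np.any(lam > tol):
        raise ValueError("eigenvalues must be non-positive (Delta = A - D convention)")
    lam = np.minimum(lam, 0.0)
    prof = _raw_profile(kernel, lam)
    if kernel.normalize_dc:
        dc = float(_raw_profile(kernel, np.asarray(0.0)))
        if dc != 0.0:
            prof = prof / dc
    return prof if prof.ndim else float(prof)


@dataclass(frozen=True)
class GraphFilter:
    """A diagonal spectral filter bound to a Laplacian spectrum."""

    spectrum: LaplacianSpectrum
    profile: np.ndarray  # K̂g(lambda_k), one value per mode

    @property
    def matrix(self) -> np.ndarray:
        """Vertex-domain filter matrix K_g = U Diag(profile) U^T (symmetric)."""
        u = self.spectrum.eigenvectors
        return (u * self.profile) @ u.T

    def apply(self, signal: np.ndarray) -> np.ndarray:
        """Filter a vertex-domain signal via the spectral path."""
        signal = np.asarray(signal, dtype=float)
        if signal.shape[0] != self.spectrum.n_vertices:
            raise ValueError("signal length does not match the filter's graph")
        coeffs = self.spectrum.gft(signal)
        if coeffs.ndim == 1:
            return self.spectrum.igft(self.profile * coeffs)
        return self.spectrum.igft(self.profile[:, None] * coeffs)


def build_filter(spectrum: LaplacianSpectrum, kernel: KernelSpec) -> GraphFilter:
    """Construct the graph filter for ``kernel`` on ``spectrum``."""
    if kernel.family == "mexican_hat" and kernel.normalize_dc:
        raw = KernelSpec(kernel.family, kernel.size, normalize_dc=False)
        prof = np.asarray(spectral_profile(raw, spectrum.eigenvalues))
        peak = np.abs(prof).max()
        if peak > 0:
            prof = prof / peak
    else:
        prof = np.asarray(spectral_profile(kernel, spectrum.eigenvalues))
    return GraphFilter(spectrum=spectrum, profile=prof)


def apply_filter(signal: np.ndarray, filt: GraphFilter) -> np.ndarray:
    """Apply a graph filter to a vertex signal (vector or n x T array)."""
    return filt.apply(signal)
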