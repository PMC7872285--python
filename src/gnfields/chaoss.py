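"""Closed-form spatiotemporal spectra of linearized graph neural fields.

CHAOSS (Connectome-Harmonic Analysis Of Spatiotemporal Spectra) exploits
the fact that, for space-independent parameters, the linearized dynamics
decouple per Laplacian eigenmode into 2x2 linear SDEs

    d u_k/dt = J_k u_k + B^(1/2)-driven noise,

so the cross-spectral matrix of mode k at angular frequency omega is

    S_k(omega) = [i omega I - J_k]^(-1) B [i omega I - J_k]^(-dagger)

with B the noise power matrix.  From it follow, for population s:

    harmonic spectrum   H_s(k)    = (1/2pi) Int S_k(omega)_ss domega
                                    (closed form below),
    temporal spectrum   T_s(omega) = 2 sum_k S_k(omega)_ss
                                    (one-sided; k only runs over 1..n),
    covariance          Sigma = U Diag(H) U^T, and functional connectivity
                        F = D^{-1/2} Sigma D^{-1/2} with D = Diag(Sigma),
    coherence           C(omega) from the vertex-domain cross-spectrum
                        S_v(omega) = U Diag(S_k(omega)_ss) U^T.

All formulas assume every mode is stable; fluctuation spectra about an
unstable state are not stationary and the functions refuse to evaluate
them (see :func:`gnfields.wilson_cowan.stability_analysis`).

The coherence construction diagonalizes per mode, which is exact for a
single population with space-independent parameters; applying it per
population of a multi-population model is a documented extension that
neglects cross-population vertex correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .wilson_cowan import ModeSystem, stability_analysis

__all__ = [
    "SpectraBundle",
    "mode_cross_spectrum",
    "excitatory_power",
    "population_power",
    "harmonic_spectrum",
    "temporal_spectrum",
    "functional_connectivity",
    "coherence",
    "spectra_bundle",
    "temporal_peaks",
]

_POP = {"E": 0, "I": 1, "e": 0, "i": 1, 0: 0, 1: 1}


class UnstableModeError(RuntimeError):
    """Raised when spectra are requested about an unstable steady state."""


def _require_stable(modes: ModeSystem, what: str) -> None:
    report = stability_analysis(modes)
    if not report.stable:
        raise UnstableModeError(
            f"{what} requires a stable steady state, but mode "
            f"{report.leading_mode} (Laplacian eigenvalue "
            f"{modes.eigenvalues[report.leading_mode]:.6g}) has leading "
            f"eigenvalue real part {report.leading_real_part:.6g} 1/s >= 0; "
            "run stability_analysis() for the full per-mode report"
        )


def mode_cross_spectrum(j: np.ndarray, b: np.ndarray, omega: float) -> np.ndarray:
    """Hermitian PSD cross-spectral matrix of one eigenmode at omega (rad/s)."""
    j = np.asarray(j, dtype=float)
    m = 1j * omega * np.eye(j.shape[0]) - j
    det = np.linalg.det(m)
    if abs(det) == 0.0:
        raise np.linalg.LinAlgError(
            "i*omega*I - J is singular: omega coincides with a purely "
            "imaginary Jacobian eigenvalue"
        )
    minv = np.linalg.inv(m)
    s = minv @ np.asarray(b, dtype=float) @ minv.conj().T
    return (s + s.conj().T) / 2.0


def population_power(j: np.ndarray, b: np.ndarray, omega, population="E") -> np.ndarray:
    """Power of one population in one eigenmode at temporal frequency omega.

    Closed form for a 2x2 Jacobian; the excitatory (index 0) expression is

        S_k(omega)_E = (B00 (J11^2 + omega^2) + J01^2 B11)
                       / ((J00 J11 - J01 J10 - omega^2)^2
                          + omega^2 (J00 + J11)^2)

    and the inhibitory one swaps the roles of the two rows.  Vectorized
    over ``omega``.
    """
    j = np.asarray(j, dtype=float)
    b = np.asarray(b, dtype=float)
    w2 = np.asarray(omega, dtype=float) ** 2
    s = _POP[population]
    o = 1 - s
    num = b[s, s] * (j[o, o] ** 2 + w2) + j[s, o] ** 2 * b[o, o]
    den = (j[0, 0] * j[1, 1] - j[0, 1] * j[1, 0] - w2) ** 2 \
        + w2 * (j[0, 0] + j[1, 1]) ** 2
    if np.any(den == 0):
        raise ZeroDivisionError("spectral denominator vanished (marginal mode)")
    return num / den


def excitatory_power(j: np.ndarray, b: np.ndarray, omega) -> np.ndarray:
    """Excitatory-population power of one eigenmode (population index 0)."""
    return population_power(j, b, omega, population="E")


def harmonic_spectrum(modes: ModeSystem, population="E") -> np.ndarray:
    """Frequency-integrated power per eigenmode, H_s(k).

    Closed form of (1/2pi) Int_-inf^inf S_k(omega)_s domega for 2x2 modes:

        H_E(k) = (B00 det J + J11^2 B00 + J01^2 B11)
                 / (2 (J01 J10 - J00 J11) (J00 + J11))

    (inhibitory: swap rows).  Equals the stationary variance of the mode's
    population coordinate.  Requires all modes stable.
    """
    _require_stable(modes, "harmonic_spectrum")
    j = modes.jacobians
    b = modes.noise_power
    s = _POP[population]
    o = 1 - s
    det = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
    tr = j[:, 0, 0] + j[:, 1, 1]
    num = b[s, s] * det + j[:, o, o] ** 2 * b[s, s] + j[:, s, o] ** 2 * b[o, o]
    return num / (2.0 * (-det) * tr)


def temporal_spectrum(modes: ModeSystem, population="E", omega=None) -> np.ndarray:
    """One-sided temporal power spectrum T_s(omega) = 2 sum_k S_k(omega)_s.

    ``omega`` is a grid in rad/s.  The factor 2 folds the negative
    frequencies, since mode index k only runs over 1..n.
    """
    _require_stable(modes, "temporal_spectrum")
    omega = np.asarray(omega, dtype=float)
    j = modes.jacobians
    b = modes.noise_power
    s = _POP[population]
    o = 1 - s
    w2 = omega[None, :] ** 2
    det = (j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0])[:, None]
    tr = (j[:, 0, 0] + j[:, 1, 1])[:, None]
    num = b[s, s] * (j[:, o, o][:, None] ** 2 + w2) + (j[:, s, o] ** 2)[:, None] * b[o, o]
    den = (det - w2) ** 2 + w2 * tr**2
    return 2.0 * np.sum(num / den, axis=0)


def temporal_peaks(omega: np.ndarray, t: np.ndarray, prominence: float = 0.05) -> np.ndarray:
    """Angular frequencies of interior local maxima of a temporal spectrum.

    Peaks are detected on log10 T with a minimum prominence (in decades);
    the endpoints of the grid are never peaks, so a spectrum decaying
    monotonically from omega = 0 reports none.
    """
    import scipy.signal

    idx, _ = scipy.signal.find_peaks(np.log10(np.asarray(t, dtype=float)),
                                     prominence=prominence)
    return np.asarray(omega, dtype=float)[idx]


def _normalize_unit_diagonal(mat: np.ndarray, what: str) -> np.ndarray:
    d = np.diag(mat).copy()
    if np.any(d <= 0):
        bad = int(np.argmin(d))
        raise ValueError(f"{what}: vertex {bad} has non-positive diagonal variance/power")
    inv = 1.0 / np.sqrt(d)
    out = mat * inv[:, None] * inv[None, :]
    np.fill_diagonal(out, 1.0)
    return out


def functional_connectivity(h: np.ndarray, eigenvectors: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by mode powers H(k).

    Sigma = U Diag(H) U^T is the vertex covariance; F normalizes it to
    unit diagonal.  Entries lie in [-1, 1]; symmetric.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("harmonic spectrum must be non-negative")
    u = np.asarray(eigenvectors, dtype=float)
    sigma = (u * h) @ u.T
    return _normalize_unit_diagonal(sigma, "functional_connectivity")


def coherence(modes: ModeSystem, eigenvectors: np.ndarray, population="E",
              omega: float = 0.0) -> np.ndarray:
    """Vertex-by-vertex coherence matrix C(omega) at one frequency.

    Builds the vertex-domain cross-spectrum S_v(omega) =
    U Diag(S_k(omega)_s) U^T (exact for space-independent parameters) and
    normalizes it to unit diagonal.  |C_ij| <= 1.
    """
    _require_stable(modes, "coherence")
    j = modes.jacobians
    b = modes.noise_power
    s = _POP[population]
    o = 1 - s
    w2 = float(omega) ** 2
    det = j[:, 0, 0] * j[:, 1, 1] - j[:, 0, 1] * j[:, 1, 0]
    tr = j[:, 0, 0] + j[:, 1, 1]
    power = (b[s, s] * (j[:, o, o] ** 2 + w2) + j[:, s, o] ** 2 * b[o, o]) \
        / ((det - w2) ** 2 + w2 * tr**2)
    u = np.asarray(eigenvectors, dtype=float)
    sv = (u * power) @ u.T
    return _normalize_unit_diagonal(sv, "coherence")


@dataclass(frozen=True)
class SpectraBundle:
    """Analytic spectra of one population: H(k), T(omega), F, optional C."""

    population: str
    harmonic: np.ndarray  # H(k), one value per mode
    omega: np.ndarray  # rad/s grid
    temporal: np.ndarray  # T(omega) on the grid
    fc: np.ndarray  # functional connectivity, n x n
    coherence: Optional[np.ndarray] = None  # (n_omega, n, n) if requested

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.omega / (2.0 * np.pi)

    def save(self, path) -> None:
        data = {
            "H": self.harmonic,
            "omega": self.omega,
            "T": self.temporal,
            "F": self.fc,
            "population": np.array(self.population),
        }
        if self.coherence is not None:
            data["C"] = self.coherence
        np.savez(path, **data)

    @classmethod
    def load(cls, path) -> "SpectraBundle":
        with np.load(path) as d:
            return cls(
                population=str(d["population"]),
                harmonic=np.array(d["H"]),
                omega=np.array(d["omega"]),
                temporal=np.array(d["T"]),
                fc=np.array(d["F"]),
                coherence=np.array(d["C"]) if "C" in d else None,
            )


def spectra_bundle(
    modes: ModeSystem,
    eigenvectors: np.ndarray,
    omega: np.ndarray,
    population: str = "E",
    with_coherence: bool = False,
) -> SpectraBundle:
    """Compute the full CHAOSS observable set for one population."""
    omega = np.asarray(omega, dtype=float)
    h = harmonic_spectrum(modes, population)
    t = temporal_spectrum(modes, population, omega)
    f = functional_connectivity(h, eigenvectors)
    c = None
    if with_coherence:
        c = np.stack([coherence(modes, eigenvectors, population, w) for w in omega])
    return SpectraBundle(
        population=str(population), harmonic=h, omega=omega, temporal=t, fc=f,
        coherence=c,
    )
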