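"""Synthetic metric graphs and calibrated dynamical-regime presets.

Two generators cover the experimental settings every other module is
exercised on:

* 1-D chain ("cortical line") graphs with vertex spacing ``h`` and
  optional fast non-local ("myelinated") edges whose effective length is
  the Euclidean gap divided by a conduction speed factor (default 200,
  the white-matter-to-surface propagation speed ratio).

* Toy two-hemisphere connectomes: two triangulated spherical meshes,
  physically separate, joined only by random long-range tract edges whose
  path lengths exceed the straight-line chord (fibers curve) and are then
  divided by the speed factor.

:func:`regime_presets` ships a Wilson-Cowan parameter set, found by
numerical search, that reproduces on the 1000-vertex line the canonical
regime progression as the vertex spacing grows:

    h = 1e-5 m   stable, featureless broadband fluctuations
    h = 1e-4 m   stable, oscillatory resonance (spectral peak)
    h = 2e-4 m   oscillatory instability (limit cycle)

plus the rescue of the unstable case by a single (250, 750) non-local
edge, and a long-range-inhibition variant (sigma_IE x 20) with multiple
temporal-spectral peaks.  The mechanism: the excitatory gain window in
Laplacian-eigenvalue space destabilizes modes whose eigenvalues fall in
it; growing h compresses the spectrum toward zero, moving the lowest
non-constant modes into the window, while a strong non-local edge pushes
the offending mode back out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.spatial

from .graph import LOCAL, TRACT, MetricGraph
from .wilson_cowan import WilsonCowanParams

__all__ = [
    "LineGraphSpec",
    "ToyConnectomeSpec",
    "RegimePreset",
    "make_line_graph",
    "make_toy_connectome",
    "regime_presets",
    "DEFAULT_SPEED_FACTOR",
]

DEFAULT_SPEED_FACTOR = 200.0


@dataclass(frozen=True)
class LineGraphSpec:
    """A 1-D chain graph: ``n_vertices`` points spaced ``spacing`` meters.

    ``nonlocal_edges`` lists ``(i, j, speed_factor)`` triples; each adds a
    tract edge of effective length ``|i - j| * spacing / speed_factor``.
    ``periodic`` closes the chain into a ring (used for filter-convergence
    checks against continuum convolution; the ring carries no coordinates
    since chord and arc lengths differ).
    """

    n_vertices: int = 1000
    spacing: float = 1e-4
    nonlocal_edges: tuple = ()
    periodic: bool = False

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for i, j, sf in self.nonlocal_edges:
            if not (0 <= i < j < self.n_vertices):
                raise ValueError(f"invalid non-local edge indices ({i}, {j})")
            if sf < 1:
                raise ValueError("speed_factor must be >= 1")


def make_line_graph(spec: LineGraphSpec) -> MetricGraph:
    """Build the chain (or ring) MetricGraph described by ``spec``."""
    n, h = spec.n_vertices, spec.spacing
    edges = [(i, i + 1) for i in range(n - 1)]
    dists = [h] * (n - 1)
    kinds = [LOCAL] * (n - 1)
    if spec.periodic and n > 2:
        edges.append((0, n - 1))
        dists.append(h)
        kinds.append(LOCAL)
    for i, j, sf in spec.nonlocal_edges:
        edges.append((i, j))
        dists.append(abs(j - i) * h / sf)
        kinds.append(TRACT)
    coords = None
    if not spec.periodic:
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * h
    return MetricGraph(
        n_vertices=n,
        edges=np.array(edges),
        distances=np.array(dists),
        coords=coords,
        edge_kind=tuple(kinds),
    )


@dataclass(frozen=True)
class ToyConnectomeSpec:
    """Reduced-scale two-hemisphere connectome.

    Each hemisphere is a triangulated sphere with ``n_per_hemisphere``
    vertices (random points on the sphere, convex-hull triangulation) of
    radius ``radius`` meters; hemisphere centers sit ``separation`` meters
    apart so the meshes are physically separate.  ``n_tracts`` random
    tract edges (a mix of inter- and intra-hemispheric) connect them;
    each tract's path length is the endpoint chord times a curvature
    factor in [1.1, 1.6], divided by ``speed_factor``.
    """

    n_per_hemisphere: int = 80
    n_tracts: int = 40
    speed_factor: float = DEFAULT_SPEED_FACTOR
    seed: int = 0
    radius: float = 0.05
    separation: float = 0.13

    def __post_init__(self):
        if self.n_per_hemisphere < 6:
            raise ValueError("need at least 6 vertices per hemisphere")
        if self.speed_factor < 1:
            raise ValueError("speed_factor must be >= 1")


def _sphere_mesh_edges(n: int, radius: float, center: np.ndarray,
                       rng: np.random.Generator):
    """Random points on a sphere plus their convex-hull triangulation edges."""
    z = rng.standard_normal((n, 3))
    pts = radius * z / np.linalg.norm(z, axis=1, keepdims=True)
    hull = scipy.spatial.ConvexHull(pts)
    pairs = set()
    for simplex in hull.simplices:
        a, b, c = int(simplex[0]), int(simplex[1]), int(simplex[2])
        for u, v in ((a, b), (b, c), (a, c)):
            pairs.add((min(u, v), max(u, v)))
    return pts + center, sorted(pairs)


def make_toy_connectome(spec: ToyConnectomeSpec) -> MetricGraph:
    """Generate the two-hemisphere toy connectome (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_hemisphere
    off = spec.separation / 2.0
    left, le = _sphere_mesh_edges(n, spec.radius, np.array([-off, 0.0, 0.0]), rng)
    right, re_ = _sphere_mesh_edges(n, spec.radius, np.array([off, 0.0, 0.0]), rng)
    coords = np.vstack([left, right])
    edges = [(i, j) for i, j in le] + [(i + n, j + n) for i, j in re_]
    kinds = [LOCAL] * len(edges)
    existing = set(edges)
    dists = [float(np.linalg.norm(coords[i] - coords[j])) for i, j in edges]
    n_total = 2 * n
    added = 0
    while added < spec.n_tracts:
        i, j = rng.integers(0, n_total, size=2)
        i, j = int(min(i, j)), int(max(i, j))
        if i == j or (i, j) in existing:
            continue
        chord = float(np.linalg.norm(coords[i] - coords[j]))
        path = chord * float(rng.uniform(1.1, 1.6))
        edges.append((i, j))
        dists.append(path / spec.speed_factor)
        kinds.append(TRACT)
        existing.add((i, j))
        added += 1
    return MetricGraph(
        n_vertices=n_total,
        edges=np.array(edges),
        distances=np.array(dists),
        coords=coords,
        edge_kind=tuple(kinds),
    )


@dataclass(frozen=True)
class RegimePreset:
    """A parameter set plus the graph configuration realizing one regime."""

    name: str
    params: WilsonCowanParams
    n_vertices: int = 1000
    spacing: float = 1e-4
    nonlocal_edges: tuple = ()

    def line_spec(self, n_vertices: Optional[int] = None,
                  spacing: Optional[float] = None) -> LineGraphSpec:
        return LineGraphSpec(
            n_vertices=n_vertices or self.n_vertices,
            spacing=spacing if spacing is not None else self.spacing,
            nonlocal_edges=self.nonlocal_edges,
        )

    def graph(self, **kw) -> MetricGraph:
        return make_line_graph(self.line_spec(**kw))


# Calibrated by numerical search over the stability window (see module
# docstring); the same coupling/kernel set realizes broadband, resonance
# and instability purely through the vertex spacing.
_BASE = WilsonCowanParams(
    tau_e=0.01, tau_i=0.01,
    d_e=1.0, d_i=1.0,
    alpha_ee=10.78, alpha_ie=14.2, alpha_ei=14.2, alpha_ii=10.8,
    sigma_ee=0.01327, sigma_ie=1.37e-3, sigma_ei=1.37e-3, sigma_ii=0.05774,
    p=0.5 * (14.2 - 10.78), q=0.5 * (10.8 - 14.2),
    sigma_noise=1e-3,
)

#: non-local edge of the rescue experiments: vertices (250, 750), speed 200
RESCUE_EDGE = (250, 750, DEFAULT_SPEED_FACTOR)

#: the spacing sweep realizing broadband -> resonance -> instability
H_SWEEP = (1e-5, 1e-4, 2e-4)


def regime_presets() -> dict:
    """Named Wilson-Cowan regime presets on the 1000-vertex line graph."""
    return {
        "broadband": RegimePreset("broadband", _BASE, spacing=1e-5),
        "resonance": RegimePreset("resonance", _BASE, spacing=1e-4),
        "oscillatory_instability": RegimePreset(
            "oscillatory_instability", _BASE, spacing=2e-4),
        "rescued": RegimePreset(
            "rescued", _BASE, spacing=2e-4, nonlocal_edges=(RESCUE_EDGE,)),
        "long_range_inhibition": RegimePreset(
            "long_range_inhibition",
            _BASE.replace(sigma_ie=_BASE.sigma_ie * 20.0),
            spacing=2e-4, nonlocal_edges=(RESCUE_EDGE,)),
    }
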