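"""Metric graphs, their Laplacians, and the graph Fourier transform.

A *metric graph* is an undirected graph whose edges carry physical lengths
(in meters).  Two Laplacians are provided: the combinatorial (binary)
Laplacian, which only sees topology, and the distance-weighted Laplacian

    Delta = A - D,    A_ij = Ã_ij / M_ij**2,   D_ii = sum_j A_ij,

whose adjacency weights are inverse squared edge lengths.  With this sign
convention Delta is negative semidefinite: its eigenvalues play the role of
``-k**2`` of the continuum Laplace operator, so spatial-frequency content
lives at strongly negative eigenvalues.  The orthonormal eigenvectors define
the graph Fourier transform (GFT); on grid graphs they reduce to discrete
Fourier modes, on cortical meshes they are the "connectome harmonics".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "MetricGraph",
    "LaplacianSpectrum",
    "binary_adjacency",
    "combinatorial_laplacian",
    "weighted_laplacian",
    "eigendecompose",
    "gft",
    "igft",
    "read_edge_list",
    "write_edge_list",
    "read_off_mesh",
]

#: eigenvalues above this are considered positive round-off violations
_EIG_TOL = 1e-10

LOCAL = "local"
TRACT = "tract"


class InvalidMetricError(ValueError):
    """Raised when an edge length is non-positive or non-finite."""


@dataclass(frozen=True)
class MetricGraph:
    """Undirected graph with per-edge metric lengths.

    Parameters
    ----------
    n_vertices : int
        Number of vertices (0-based indexing).
    edges : (m, 2) int array
        Unordered vertex pairs, no self-loops, no duplicates.
    distances : (m,) float array
        Metric length of each edge in meters; strictly positive and finite.
    coords : (n, 3) float array, optional
        Vertex positions in meters.  When present, every edge labeled
        ``"local"`` must have its length equal to the Euclidean distance
        between its endpoints.
    edge_kind : sequence of str, optional
        Per-edge label, ``"local"`` or ``"tract"``.  Tract edges model
        fast (myelinated) long-range connections whose effective length is
        shorter than the Euclidean gap they bridge.
    """

    n_vertices: int
    edges: np.ndarray
    distances: np.ndarray
    coords: Optional[np.ndarray] = None
    edge_kind: Optional[tuple] = None

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        dists = np.asarray(self.distances, dtype=float).reshape(-1)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "distances", dists)
        if self.n_vertices <= 0:
            raise ValueError("n_vertices must be positive")
        if len(edges) != len(dists):
            raise ValueError("edges and distances length mismatch")
        if len(edges):
            if edges.min() < 0 or edges.max() >= self.n_vertices:
                raise ValueError("edge index out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            canon = np.sort(edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError("duplicate edges")
        if np.any(~np.isfinite(dists)) or np.any(dists <= 0):
            raise InvalidMetricError("edge lengths must be positive and finite")
        if self.edge_kind is not None:
            kinds = tuple(self.edge_kind)
            if len(kinds) != len(edges):
                raise ValueError("edge_kind length mismatch")
            object.__setattr__(self, "edge_kind", kinds)
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float).reshape(self.n_vertices, -1)
            object.__setattr__(self, "coords", coords)
            self._check_local_metric()

    def _check_local_metric(self):
        if not len(self.edges):
            return
        if self.edge_kind is None:
            local = np.ones(len(self.edges), dtype=bool)
        else:
            local = np.array([k == LOCAL for k in self.edge_kind])
        if not local.any():
            return
        e = self.edges[local]
        d = self.distances[local]
        eu = np.linalg.norm(self.coords[e[:, 0]] - self.coords[e[:, 1]], axis=1)
        if not np.allclose(d, eu, rtol=1e-12, atol=1e-15):
            raise InvalidMetricError(
                "local edge lengths deviate from Euclidean endpoint distances"
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # Laplacians as methods, mirroring the module-level functions
    def binary_adjacency(self) -> np.ndarray:
        return binary_adjacency(self)

    def combinatorial_laplacian(self) -> np.ndarray:
        return combinatorial_laplacian(self)

    def weighted_laplacian(self) -> np.ndarray:
        return weighted_laplacian(self)

    def spectrum(self, n_modes: Optional[int] = None) -> "LaplacianSpectrum":
        return eigendecompose(self.weighted_laplacian(), n_modes=n_modes)


def _accumulate(n, edges, weights):
    m = np.zeros((n, n))
    if len(edges):
        i, j = edges[:, 0], edges[:, 1]
        m[i, j] += weights
        m[j, i] += weights
    return m


def binary_adjacency(graph: MetricGraph) -> np.ndarray:
    """0/1 adjacency matrix Ã (symmetric, zero diagonal)."""
    return _accumulate(graph.n_vertices, graph.edges, np.ones(graph.n_edges))


def combinatorial_laplacian(graph: MetricGraph) -> np.ndarray:
    """Binary Laplacian Ã - D̃; blind to edge lengths."""
    a = binary_adjacency(graph)
    return a - np.diag(a.sum(axis=1))


def weighted_laplacian(graph: MetricGraph) -> np.ndarray:
    """Distance-weighted Laplacian A - D with A_ij = 1/M_ij**2.

    Negative semidefinite with zero row sums; the constant vector spans
    the kernel on each connected component.
    """
    if np.any(graph.distances <= 0):
        raise InvalidMetricError("edge lengths must be positive")
    a = _accumulate(graph.n_vertices, graph.edges, 1.0 / graph.distances**2)
    return a - np.diag(a.sum(axis=1))


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Eigendecomposition of a graph Laplacian.

    ``eigenvalues`` are sorted non-increasing, so index 0 is the constant
    (DC) mode with eigenvalue 0 and larger indices carry finer spatial
    detail.  ``eigenvectors`` columns are orthonormal and pair with the
    eigenvalues.  Eigenvector signs are fixed deterministically: the
    largest-magnitude entry of each column is made positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def gft(self, signal: np.ndarray) -> np.ndarray:
        return gft(signal, self)

    def igft(self, coeffs: np.ndarray) -> np.ndarray:
        return igft(coeffs, self)

    def save(self, path) -> None:
        np.savez(path, eigenvalues=self.eigenvalues, eigenvectors=self.eigenvectors)

    @classmethod
    def load(cls, path) -> "LaplacianSpectrum":
        with np.load(path) as data:
            return cls(
                eigenvalues=np.array(data["eigenvalues"]),
                eigenvectors=np.array(data["eigenvectors"]),
            )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # deterministic sign: largest-|entry| of each column positive
    # (argmax takes the first occurrence on exact ties)
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigendecompose(
    laplacian: np.ndarray, n_modes: Optional[int] = None
) -> LaplacianSpectrum:
    """Diagonalize a (negative semidefinite) graph Laplacian.

    Parameters
    ----------
    laplacian : (n, n) symmetric array
    n_modes : int, optional
        If given, compute only the ``n_modes`` eigenpairs closest to zero
        (the smoothest modes), via a Lanczos solver with a fixed starting
        vector so results are reproducible.  Values agree with the dense
        decomposition for the modes computed.
    """
    lap = np.asarray(laplacian, dtype=float)
    if lap.ndim != 2 or lap.shape[0] != lap.shape[1]:
        raise ValueError("laplacian must be square")
    scale = np.abs(lap).max() or 1.0
    if not np.allclose(lap, lap.T, atol=1e-12 * scale):
        raise ValueError("laplacian must be symmetric")
    n = lap.shape[0]
    if n_modes is None or n_modes >= n:
        vals, vecs = np.linalg.eigh(lap)
        order = np.argsort(-vals, kind="stable")
        vals, vecs = vals[order], vecs[:, order]
    else:
        # fixed pseudo-random start vector keeps Lanczos reproducible
        v0 = np.random.default_rng(0).standard_normal(n)
        vals, vecs = spla.eigsh(sp.csr_matrix(lap), k=n_modes, which="LA", v0=v0)
        order = np.argsort(-vals, kind="stable")
        vals, vecs = vals[order], vecs[:, order]
    return LaplacianSpectrum(eigenvalues=vals, eigenvectors=_fix_signs(vecs))


def gft(signal: np.ndarray, spectrum: LaplacianSpectrum) -> np.ndarray:
    """Graph Fourier transform: project a vertex signal onto the eigenbasis."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != spectrum.n_vertices:
        raise ValueError(
            f"signal first dimension {signal.shape[0]} != n_vertices "
            f"{spectrum.n_vertices}"
        )
    return spectrum.eigenvectors.T @ signal


def igft(coeffs: np.ndarray, spectrum: LaplacianSpectrum) -> np.ndarray:
    """Inverse graph Fourier transform."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[0] != spectrum.n_modes:
        raise ValueError(
            f"coefficient first dimension {coeffs.shape[0]} != n_modes "
            f"{spectrum.n_modes}"
        )
    return spectrum.eigenvectors @ coeffs


# ---------------------------------------------------------------------------
# plain-text interchange formats


def write_edge_list(graph: MetricGraph, path) -> None:
    """Tab-separated edge list: vertex_i, vertex_j, distance_m, kind."""
    kinds = graph.edge_kind or (LOCAL,) * graph.n_edges
    lines = ["# vertex_i\tvertex_j\tdistance_m\tkind", f"# n_vertices={graph.n_vertices}"]
    for (i, j), d, k in zip(graph.edges, graph.distances, kinds):
        lines.append(f"{i}\t{j}\t{float(d)!r}\t{k}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_edge_list(path, n_vertices: Optional[int] = None) -> MetricGraph:
    """Read the tab-separated edge-list format (0-based indices, '#' headers)."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    edges, dists, kinds = [], [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "n_vertices=" in line and n_vertices is None:
                n_vertices = int(line.split("n_vertices=")[1])
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed edge-list line: {line!r}")
        edges.append((int(parts[0]), int(parts[1])))
        dists.append(float(parts[2]))
        kinds.append(parts[3] if len(parts) > 3 else LOCAL)
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if n_vertices is None:
        n_vertices = int(edges.max()) + 1 if len(edges) else 1
    return MetricGraph(
        n_vertices=n_vertices,
        edges=edges,
        distances=np.asarray(dists),
        edge_kind=tuple(kinds),
    )


def read_off_mesh(path, tracts: Optional[Sequence[tuple]] = None) -> MetricGraph:
    """Build a MetricGraph from an OFF-style triangle mesh.

    Edges are the unique triangle sides, with Euclidean lengths taken from
    the vertex coordinates.  ``tracts`` optionally adds long-range edges as
    ``(i, j, length_m)`` triples labeled ``"tract"``.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    tokens: list[str] = []
    for line in lines:
        line = line.split("#")[0].strip()
        if line:
            tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    coords = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    pairs = set()
    for _ in range(nf):
        cnt = int(tokens[pos])
        face = [int(t) for t in tokens[pos + 1 : pos + 1 + cnt]]
        pos += 1 + cnt
        for a, b in zip(face, face[1:] + face[:1]):
            pairs.add((min(a, b), max(a, b)))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    dists = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    kinds = [LOCAL] * len(edges)
    if tracts:
        extra = np.array([(i, j) for i, j, _ in tracts], dtype=np.int64)
        extra_d = np.array([d for _, _, d in tracts], dtype=float)
        edges = np.vstack([edges, extra])
        dists = np.concatenate([dists, extra_d])
        kinds += [TRACT] * len(extra)
    return MetricGraph(
        n_vertices=nv,
        edges=edges,
        distances=dists,
        coords=coords,
        edge_kind=tuple(kinds),
    )
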