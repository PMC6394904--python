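"""Spatial domains: the periodic pollen-equator ring and the microspore sphere surface.

The single size descriptor throughout is the *front-view area* a (um^2) --
the projected disc area of the grain as imaged, a = pi R^2.  The 1D ring is
the full equatorial circumference of that sphere with periodic topology;
the sphere is the whole surface (total area 4a).

Discrete Laplacians: the ring uses the exact spectral operator (applied via
FFT, with a matching second-order stencil available for direct use); the
sphere uses the cotangent-weight Laplace-Beltrami operator with lumped
barycentric mass on a subdivided icosahedral mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh

from .model import TuringReport

__all__ = [
    "RingDomain",
    "SphereDomain",
    "ring_from_front_area",
    "sphere_from_front_area",
    "apply_laplacian",
    "admissible_modes",
    "refine_domain",
    "interpolate_to_refined",
]


@dataclass(frozen=True)
class RingDomain:
    """Uniformly discretized periodic circle of circumference 2 pi R."""

    front_area: float
    n_nodes: int

    @property
    def radius(self) -> float:
        return math.sqrt(self.front_area / math.pi)

    @property
    def length(self) -> float:
        return 2.0 * math.pi * self.radius

    @property
    def node_positions(self) -> np.ndarray:
        """Arc-length coordinates, half-open in [0, length)."""
        return np.arange(self.n_nodes) * (self.length / self.n_nodes)

    @property
    def wavenumbers(self) -> np.ndarray:
        """rfft wavenumbers (1/um) matching real fields on the nodes."""
        return 2.0 * math.pi * np.fft.rfftfreq(self.n_nodes, d=self.length / self.n_nodes)

    @property
    def node_weights(self) -> np.ndarray:
        return np.full(self.n_nodes, self.length / self.n_nodes)


class SphereDomain:
    """Icosphere surface mesh of radius R = sqrt(front_area / pi).

    ``resolution`` is the icosphere subdivision level; vertex count is
    10 * 4^resolution + 2.  The cotangent stiffness matrix K (positive
    semi-definite) and lumped mass vector are assembled once; the discrete
    Laplace-Beltrami operator is f -> -K f / mass.
    """

    def __init__(self, front_area: float, resolution: int = 4):
        if front_area <= 0:
            raise ValueError("front-view area must be positive")
        self.front_area = float(front_area)
        self.resolution = int(resolution)
        self.radius = math.sqrt(front_area / math.pi)
        base = trimesh.creation.icosphere(subdivisions=self.resolution, radius=1.0)
        unit = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
        self.node_positions = unit * self.radius
        self.faces = np.asarray(base.faces)
        self.n_nodes = len(self.node_positions)
        self._assemble()

    def _assemble(self) -> None:
        V, F = self.node_positions, self.faces
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for t in range(3):
            i, j, k = F[:, t], F[:, (t + 1) % 3], F[:, (t + 2) % 3]
            e1, e2 = V[i] - V[k], V[j] - V[k]
            double_area = np.linalg.norm(np.cross(e1, e2), axis=1)
            cot = np.einsum("ij,ij->i", e1, e2) / double_area
            rows += [i, j]
            cols += [j, i]
            vals += [0.5 * cot, 0.5 * cot]
        W = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        ).tocsr()
        self.stiffness = (sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W).tocsc()
        fa = 0.5 * np.linalg.norm(
            np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]]), axis=1
        )
        mass = np.zeros(n)
        for t in range(3):
            mass += np.bincount(F[:, t], weights=fa / 3.0, minlength=n)
        self.node_weights = mass

    @property
    def surface_area(self) -> float:
        return float(self.node_weights.sum())

    def edges(self) -> np.ndarray:
        """Unique undirected vertex adjacency edges (m, 2)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def export_mesh(self, path: str) -> None:
        """Write the surface mesh in a standard format (by file extension, e.g. .obj)."""
        trimesh.Trimesh(vertices=self.node_positions, faces=self.faces, process=False).export(path)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SphereDomain(front_area={self.front_area}, resolution={self.resolution}, "
            f"n_nodes={self.n_nodes})"
        )


def ring_from_front_area(area: float, n_nodes: int = 256) -> RingDomain:
    """Ring of circumference 2 sqrt(pi a) from front-view area a."""
    if area <= 0:
        raise ValueError("front-view area must be positive")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return RingDomain(front_area=float(area), n_nodes=int(n_nodes))


def sphere_from_front_area(area: float, resolution: int = 4) -> SphereDomain:
    return SphereDomain(front_area=area, resolution=resolution)


def apply_laplacian(domain, values: np.ndarray) -> np.ndarray:
    """Discrete Laplacian (ring, spectral) or Laplace-Beltrami (sphere, cotangent)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (domain.n_nodes,):
        raise ValueError(f"field shape {values.shape} does not match domain ({domain.n_nodes},)")
    if isinstance(domain, RingDomain):
        k = domain.wavenumbers
        return np.fft.irfft(-(k**2) * np.fft.rfft(values), domain.n_nodes)
    return -(domain.stiffness @ values) / domain.node_weights


def admissible_modes(domain, turing: TuringReport) -> set[int]:
    """Linearly unstable mode indices.

    Ring: integers m with (2 pi m / L)^2 inside the unstable band.
    Sphere: spherical-harmonic degrees l with l(l+1)/R^2 inside the band.
    """
    if not turing.satisfied:
        return set()
    out: set[int] = set()
    if isinstance(domain, RingDomain):
        L = domain.length
        m_hi = int(L * math.sqrt(turing.k2_plus) / (2 * math.pi)) + 2
        for m in range(1, m_hi + 1):
            if turing.k2_minus < (2 * math.pi * m / L) ** 2 < turing.k2_plus:
                out.add(m)
    else:
        R2 = domain.radius**2
        l_hi = int(math.sqrt(turing.k2_plus * R2)) + 2
        for l in range(1, l_hi + 1):
            if turing.k2_minus < l * (l + 1) / R2 < turing.k2_plus:
                out.add(l)
    return out


def refine_domain(domain):
    """Return the same geometry at doubled resolution."""
    if isinstance(domain, RingDomain):
        return RingDomain(domain.front_area, 2 * domain.n_nodes)
    return SphereDomain(domain.front_area, domain.resolution + 1)


def interpolate_to_refined(domain, fine, values: np.ndarray) -> np.ndarray:
    """Transfer a node field from ``domain`` onto its refinement ``fine``.

    Ring fields are band-limited (Fourier) interpolated; sphere fields keep
    coarse-vertex values and average edge endpoints onto the inserted
    midpoint vertices (Loop-refinement vertex ordering: the first
    ``domain.n_nodes`` fine vertices coincide with the coarse vertices up
    to radial projection, found by nearest-neighbour matching).
    """
    values = np.asarray(values, dtype=float)
    if isinstance(domain, RingDomain):
        spec = np.fft.rfft(values)
        return np.fft.irfft(spec, fine.n_nodes) * (fine.n_nodes / domain.n_nodes)
    from scipy.spatial import cKDTree

    coarse_unit = domain.node_positions / domain.radius
    fine_unit = fine.node_positions / fine.radius
    tree = cKDTree(coarse_unit)
    dist, idx = tree.query(fine_unit, k=2)
    out = np.empty(fine.n_nodes)
    coincident = dist[:, 0] < 1e-6
    out[coincident] = values[idx[coincident, 0]]
    mid = ~coincident
    out[mid] = 0.5 * (values[idx[mid, 0]] + values[idx[mid, 1]])
    return out
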