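"""Steady-state pattern taxonomy: spike counts and geometry categories.

Maps an activator field to one of: none, equatorial (k spikes on a great
circle), polar (two near-antipodal spikes), tetrahedral (four spikes at
tetrahedron corners), other_spikes, ring (elevated concentration along a
full great circle), spike_plus_ring, elongated_tetra_edges (six ridges on
tetrahedron edges), or failed (diverged run).

All decision constants are named fields of :class:`ClassifierConfig` so
their sensitivity can be probed; the defaults operationalize a
by-inspection taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .domains import RingDomain, SphereDomain
from .simulate import Field

__all__ = [
    "ClassifierConfig",
    "PatternLabel",
    "find_components",
    "classify_pattern",
    "count_spikes_ring",
    "failed_label",
]

#: Tetrahedral angle, arccos(-1/3), degrees.
TETRA_ANGLE = 109.47122063449069


@dataclass(frozen=True)
class ClassifierConfig:
    threshold_frac: float = 0.5       # component threshold, fraction of max(A)
    contrast_gate: float = 2.0        # patterned requires max(A) >= gate * A*
    valley_gate: float = 0.5          # patterned requires min(A) <= gate * A*
    ring_extent_deg: float = 300.0    # great-circle angular coverage for a ring
    elongation_ratio: float = 3.0     # major/minor extent for an elongated component
    angle_tol_deg: float = 15.0       # tolerance on tetrahedral / coplanar geometry
    polar_angle_deg: float = 150.0    # two spikes separated at least this -> polar
    min_component_frac: float = 0.03  # drop components smaller than this x largest
    min_component_nodes: int = 3      # drop mesh-resolution-scale fragments


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class PatternLabel:
    n_spikes: int
    geometry: str
    spike_centers: list = dfield(default_factory=list)
    metadata: dict = dfield(default_factory=dict)

    def as_tuple(self) -> tuple:
        return (self.n_spikes, self.geometry)


def failed_label() -> PatternLabel:
    return PatternLabel(0, "failed")


def _ring_runs(above: np.ndarray) -> list[np.ndarray]:
    """Maximal circular runs of True indices."""
    n = len(above)
    if above.all():
        return [np.arange(n)]
    if not above.any():
        return []
    starts = np.where(above & ~np.roll(above, 1))[0]
    runs = []
    for s in starts:
        idx = [s]
        j = (s + 1) % n
        while above[j]:
            idx.append(j)
            j = (j + 1) % n
        runs.append(np.array(idx))
    return runs


def find_components(field: Field, config: ClassifierConfig = DEFAULT_CONFIG) -> list[dict]:
    """Connected super-threshold components with centroid/area/extent summaries.

    Threshold is ``threshold_frac * max(A)``.  Sphere components use mesh
    vertex adjacency; ring components are periodic runs.  Components below
    ``min_component_frac`` of the largest component's area are discarded
    as noise fragments.
    """
    A = field.A
    thr = config.threshold_frac * A.max()
    above = A > thr
    dom = field.domain

    if isinstance(dom, RingDomain):
        runs = _ring_runs(above)
        w = dom.length / dom.n_nodes
        comps = [
            {"idx": r, "area": len(r) * w, "position": float(np.mean(dom.node_positions[r]))}
            for r in runs
        ]
        comps = [c for c in comps if len(c["idx"]) >= config.min_component_nodes]
        if comps:
            amax = max(c["area"] for c in comps)
            comps = [c for c in comps if c["area"] >= config.min_component_frac * amax]
        return comps

    edges = dom.edges()
    keep = above[edges[:, 0]] & above[edges[:, 1]]
    e = edges[keep]
    n = dom.n_nodes
    adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    _, labels = csgraph.connected_components(adj + adj.T, directed=False)
    comps = []
    for c in np.unique(labels[above]):
        idx = np.where((labels == c) & above)[0]
        w = dom.node_weights[idx] * (A[idx] - thr)
        centroid = (dom.node_positions[idx] * w[:, None]).sum(axis=0)
        norm = np.linalg.norm(centroid)
        centroid = centroid / norm if norm > 0 else dom.node_positions[idx[0]] / dom.radius
        comps.append(
            {
                "idx": idx,
                "area": float(dom.node_weights[idx].sum()),
                "centroid": centroid,  # unit vector
                "extent_deg": _great_circle_extent(dom, idx),
                "aspect": _aspect_ratio(dom, idx),
            }
        )
    comps = [c for c in comps if len(c["idx"]) >= config.min_component_nodes]
    if comps:
        amax = max(c["area"] for c in comps)
        comps = [c for c in comps if c["area"] >= config.min_component_frac * amax]
    return comps


def _great_circle_extent(dom: SphereDomain, idx: np.ndarray) -> float:
    """Angular coverage (deg) of a component around its best-fit great circle."""
    X = dom.node_positions[idx] / dom.radius
    if len(X) < 3:
        return 0.0
    normal = np.linalg.eigh(X.T @ X)[1][:, 0]
    P = X - np.outer(X @ normal, normal)
    norms = np.linalg.norm(P, axis=1)
    P = P[norms > 1e-9] / norms[norms > 1e-9, None]
    if len(P) < 2:
        return 0.0
    u = P[0]
    v = np.cross(normal, u)
    ang = np.sort(np.arctan2(P @ v, P @ u))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(360.0 - np.degrees(gaps.max()))


def _aspect_ratio(dom: SphereDomain, idx: np.ndarray) -> float:
    """Major/minor principal extent of a component (from centered position PCA)."""
    X = dom.node_positions[idx]
    if len(X) < 3:
        return 1.0
    Xc = X - X.mean(axis=0)
    evals = np.linalg.eigvalsh(Xc.T @ Xc / len(X))
    major, minor = evals[2], evals[1]
    if minor <= 0:
        return np.inf
    return float(np.sqrt(major / minor))


def count_spikes_ring(field: Field, config: ClassifierConfig = DEFAULT_CONFIG) -> int:
    """Number of super-threshold maxima on the periodic ring.

    Counts maximal runs above ``threshold_frac * max(A)`` (plateaus and
    maxima closer than one bump width merge into a single run).
    """
    comps = find_components(field, config)
    if len(comps) == 1 and len(comps[0]["idx"]) == field.domain.n_nodes:
        return 0  # homogeneous: everything super-threshold
    return len(comps)


def _unpatterned(A: np.ndarray, A_star: float, config: ClassifierConfig) -> bool:
    return A.max() < config.contrast_gate * A_star or A.min() > config.valley_gate * A_star


def classify_pattern(
    field: Field, A_star: float, config: ClassifierConfig = DEFAULT_CONFIG
) -> PatternLabel:
    """Decision cascade from contrast gate through rings, elongation and spike geometry."""
    A = field.A
    if not np.all(np.isfinite(A)):
        return failed_label()
    dom = field.domain

    if isinstance(dom, RingDomain):
        if _unpatterned(A, A_star, config):
            return PatternLabel(0, "none", metadata={"contrast": float(A.max() / A_star)})
        comps = find_components(field, config)
        k = len(comps)
        geometry = "equatorial" if k >= 2 else ("other_spikes" if k == 1 else "none")
        return PatternLabel(k, geometry, spike_centers=[c["position"] for c in comps])

    if _unpatterned(A, A_star, config):
        return PatternLabel(0, "none", metadata={"contrast": float(A.max() / A_star)})
    comps = find_components(field, config)
    if not comps:
        return PatternLabel(0, "none")

    rings = [c for c in comps if c["extent_deg"] >= config.ring_extent_deg]
    spikes = [c for c in comps if c["extent_deg"] < config.ring_extent_deg]
    meta = {"n_components": len(comps), "contrast": float(A.max() / A_star)}
    if len(rings) == 1 and not spikes:
        return PatternLabel(0, "ring", metadata=meta)
    if len(rings) == 1 and len(spikes) == 1:
        return PatternLabel(1, "spike_plus_ring", spike_centers=[spikes[0]["centroid"]], metadata=meta)
    if len(rings) >= 1:
        return PatternLabel(len(spikes), "other_spikes", metadata=meta)

    elongated = [c for c in comps if c["aspect"] >= config.elongation_ratio]
    if len(elongated) == 6 and len(comps) == 6:
        # six ridges on tetrahedron edges pair up antipodally (edge midpoints
        # of a regular tetrahedron form an octahedron)
        cents = np.array([c["centroid"] for c in comps])
        dots = cents @ cents.T
        if all(np.min(dots[i]) < -np.cos(np.radians(2 * config.angle_tol_deg)) for i in range(6)):
            return PatternLabel(6, "elongated_tetra_edges", metadata=meta)

    cents = [c["centroid"] for c in comps]
    k = len(cents)
    centers = list(cents)
    if k == 4 and _is_tetrahedral(cents, config):
        return PatternLabel(4, "tetrahedral", spike_centers=centers, metadata=meta)
    if k == 2:
        sep = np.degrees(np.arccos(np.clip(np.dot(cents[0], cents[1]), -1, 1)))
        geometry = "polar" if sep >= config.polar_angle_deg else "equatorial"
        return PatternLabel(2, geometry, spike_centers=centers, metadata=meta)
    if k >= 3 and _is_coplanar_with_center(cents, config):
        return PatternLabel(k, "equatorial", spike_centers=centers, metadata=meta)
    if k == 1:
        return PatternLabel(1, "polar", spike_centers=centers, metadata=meta)
    return PatternLabel(k, "other_spikes", spike_centers=centers, metadata=meta)


def _is_tetrahedral(cents, config) -> bool:
    angs = [
        np.degrees(np.arccos(np.clip(np.dot(cents[i], cents[j]), -1, 1)))
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    return all(abs(a - TETRA_ANGLE) <= config.angle_tol_deg for a in angs)


def _is_coplanar_with_center(cents, config) -> bool:
    """All centroids within angle_tol of one great-circle plane through the center."""
    X = np.array(cents)
    normal = np.linalg.eigh(X.T @ X)[1][:, 0]
    off = np.degrees(np.arcsin(np.clip(np.abs(X @ normal), -1, 1)))
    return bool(np.all(off <= config.angle_tol_deg))
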