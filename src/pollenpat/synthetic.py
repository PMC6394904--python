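"""Labeled ground-truth fields for classifier validation.

Static steady-state-like activator fields for every taxonomy class --
spike sets, rings, ridge patterns -- built from geometric templates on a
baseline A*, with peak height 4 A* (comfortably above the classifier's
contrast gate) and optional uniform noise expressed as a fraction of the
template peak.  Each instance is randomly rotated so classifier tests also
exercise rotation invariance.  These are not solver outputs; they emulate
the morphology of converged patterns only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import GMParameters, steady_state
from .domains import RingDomain, SphereDomain
from .simulate import Field
from .classify import PatternLabel
from .stimuli import _TETRA

__all__ = ["LabeledField", "SPHERE_CLASSES", "make_labeled_field", "fixture_suite"]

#: Sphere taxonomy classes the generator can produce, with ground truth
#: (n_spikes, geometry).  "other_spikes" follows the six-spike catalog
#: entry: four spikes on a great circle plus two at the poles.
SPHERE_CLASSES = {
    "none": (0, "none"),
    "polar": (2, "polar"),
    "equatorial-3": (3, "equatorial"),
    "equatorial-4": (4, "equatorial"),
    "equatorial-5": (5, "equatorial"),
    "tetrahedral": (4, "tetrahedral"),
    "other_spikes": (6, "other_spikes"),
    "ring": (0, "ring"),
    "spike_plus_ring": (1, "spike_plus_ring"),
    "elongated_tetra_edges": (6, "elongated_tetra_edges"),
}

_PEAK_FACTOR = 4.0   # template peak, in units of A*
_BASE_FACTOR = 0.05  # valley baseline, in units of A* (converged patterns
                     # deplete the activator to near zero between spikes)
_BUMP_SIGMA = 2.5    # um, compact spike width
_BAND_SIGMA = 2.0    # um, ring band width
_RIDGE_SIGMA = 1.6   # um, elongated ridge cross-section (kept wider than the
                     # campaign-mesh vertex spacing so ridges are resolved)
_RIDGE_HALF_ARC = math.radians(30.0)  # ridge half-length along a tetra edge


@dataclass
class LabeledField:
    field: Field
    true_label: PatternLabel
    generator_params: dict


def _rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation from QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _bumps(dom: SphereDomain, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Max-combined Gaussian caps (chord metric) of unit height."""
    out = np.zeros(dom.n_nodes)
    for c in centers:
        d2 = np.sum((dom.node_positions - c) ** 2, axis=1)
        out = np.maximum(out, np.exp(-d2 / (2 * sigma**2)))
    return out


def _ridge(dom: SphereDomain, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unit-height ridge along the middle of the great-circle arc u->v."""
    R = dom.radius
    angle = math.acos(np.clip(np.dot(u, v), -1, 1))
    mid = 0.5 * angle
    ts = np.linspace(mid - _RIDGE_HALF_ARC, mid + _RIDGE_HALF_ARC, 15)
    w = v - np.dot(u, v) * u
    w /= np.linalg.norm(w)
    pts = R * (np.outer(np.cos(ts), u) + np.outer(np.sin(ts), w))
    out = np.zeros(dom.n_nodes)
    for p in pts:
        d2 = np.sum((dom.node_positions - p) ** 2, axis=1)
        out = np.maximum(out, np.exp(-d2 / (2 * _RIDGE_SIGMA**2)))
    return out


def _sphere_template(dom: SphereDomain, cls: str, rot: np.ndarray) -> np.ndarray:
    R = dom.radius
    X = dom.node_positions

    def equatorial(k: int) -> np.ndarray:
        ang = 2 * np.pi * np.arange(k) / k
        return np.column_stack([np.cos(ang), np.sin(ang), np.zeros(k)])

    if cls == "none":
        return np.zeros(dom.n_nodes)
    if cls == "polar":
        centers = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    elif cls.startswith("equatorial-"):
        centers = equatorial(int(cls.split("-")[1]))
    elif cls == "tetrahedral":
        centers = _TETRA
    elif cls == "other_spikes":
        centers = np.vstack([equatorial(4), [[0, 0, 1.0], [0, 0, -1.0]]])
    elif cls == "ring":
        z = (X @ rot[:, 2])
        return np.exp(-(z**2) / (2 * _BAND_SIGMA**2))
    elif cls == "spike_plus_ring":
        z = X @ rot[:, 2]
        band = np.exp(-(z**2) / (2 * _BAND_SIGMA**2))
        spike = _bumps(dom, (R * rot[:, 2])[None, :], _BUMP_SIGMA)
        return np.maximum(band, spike)
    elif cls == "elongated_tetra_edges":
        verts = _TETRA @ rot.T
        out = np.zeros(dom.n_nodes)
        for i in range(4):
            for j in range(i + 1, 4):
                out = np.maximum(out, _ridge(dom, verts[i], verts[j]))
        return out
    else:
        raise ValueError(f"unknown sphere taxonomy class {cls!r}")
    return _bumps(dom, R * (centers @ rot.T), _BUMP_SIGMA)


def make_labeled_field(
    domain,
    label_request,
    noise_fraction: float = 0.0,
    seed: int = 0,
    params: GMParameters | None = None,
) -> LabeledField:
    """Build one labeled field.

    ``label_request``: a sphere class name from :data:`SPHERE_CLASSES`, or
    an integer spike count for a ring domain.  Noise is uniform within
    +/- ``noise_fraction`` of the template peak height.  Same seed, same
    field.
    """
    params = params or GMParameters()
    ss = steady_state(params)
    rng = np.random.default_rng(seed)
    peak = _PEAK_FACTOR * ss.A_star

    if isinstance(domain, RingDomain):
        k = int(label_request)
        if k < 1:
            raise ValueError("ring spike count must be >= 1")
        x = domain.node_positions
        L = domain.length
        offset = rng.uniform(0, L)
        template = np.zeros(domain.n_nodes)
        for j in range(k):
            c = (offset + j * L / k) % L
            d = np.minimum(np.abs(x - c), L - np.abs(x - c))
            template = np.maximum(template, np.exp(-(d**2) / (2 * _BUMP_SIGMA**2)))
        true = PatternLabel(k, "equatorial" if k >= 2 else "other_spikes")
    else:
        cls = str(label_request)
        if cls not in SPHERE_CLASSES:
            raise ValueError(f"unknown taxonomy class {cls!r}")
        rot = _rotation(rng)
        template = _sphere_template(domain, cls, rot)
        true = PatternLabel(*SPHERE_CLASSES[cls])

    base = _BASE_FACTOR * ss.A_star
    A = base + (peak - base) * template
    if noise_fraction:
        A = A + rng.uniform(-noise_fraction * peak, noise_fraction * peak, domain.n_nodes)
    A = np.maximum(A, 0.0)
    field = Field(domain, A, np.full(domain.n_nodes, ss.H_star), 0.0)
    return LabeledField(
        field=field,
        true_label=true,
        generator_params={
            "request": label_request,
            "noise_fraction": noise_fraction,
            "seed": seed,
            "bump_sigma": _BUMP_SIGMA,
            "peak_factor": _PEAK_FACTOR,
        },
    )


def fixture_suite(
    seed: int = 0,
    per_class: int = 20,
    areas: tuple = (550.0, 750.0),
    resolution: int = 3,
    noise_fraction: float = 0.0,
    n_ring_nodes: int = 256,
) -> list[LabeledField]:
    """Deterministic labeled suite covering every taxonomy class on both domain sizes.

    ``per_class`` instances of each sphere class (split across the two
    areas) plus ring-domain spike fields with 2..5 spikes.
    """
    rng = np.random.default_rng(seed)
    suite: list[LabeledField] = []
    spheres = {a: SphereDomain(a, resolution) for a in areas}
    rings = {a: RingDomain(a, n_ring_nodes) for a in areas}
    for cls in SPHERE_CLASSES:
        for i in range(per_class):
            area = areas[i % len(areas)]
            suite.append(
                make_labeled_field(
                    spheres[area], cls, noise_fraction, seed=int(rng.integers(2**31))
                )
            )
    for k in (2, 3, 4, 5):
        for i in range(per_class):
            area = areas[i % len(areas)]
            suite.append(
                make_labeled_field(
                    rings[area], k, noise_fraction, seed=int(rng.integers(2**31))
                )
            )
    return suite
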