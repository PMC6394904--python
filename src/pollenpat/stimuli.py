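"""Stimulus fields: pre-patterning cues applied to the activator on the sphere.

A transient stimulus is added once to the activator's initial condition
(amplitude in uM); a continuous stimulus is a time-invariant forcing F(x)
added to dA/dt for the whole run (amplitude in uM/s).  The inhibitor is
never stimulated.  Each spike is a Gaussian bump
``amplitude * exp(-|x - x0|^2)`` in Euclidean (chord) distance with the
fixed unit (1 um) length scale; the ring pattern is a band around the
equator, ``amplitude * exp(-z^2)`` with z the coordinate along the polar
axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .domains import SphereDomain

__all__ = ["StimulusSpec", "PATTERNS", "gaussian_bump", "pattern_centers", "build_stimulus"]

PATTERNS = (
    "1-spike",
    "2-spike",
    "3-spike",
    "4-spike",
    "tetrahedral",
    "ring",
    "uniform",
)

#: Regular tetrahedron vertices on the unit sphere.
_TETRA = np.array(
    [
        [0.0, 0.0, 1.0],
        [2 * math.sqrt(2) / 3, 0.0, -1.0 / 3],
        [-math.sqrt(2) / 3, math.sqrt(2.0 / 3), -1.0 / 3],
        [-math.sqrt(2) / 3, -math.sqrt(2.0 / 3), -1.0 / 3],
    ]
)


@dataclass(frozen=True)
class StimulusSpec:
    """A named stimulus pattern with amplitude and application mode.

    mode: "transient" (initial-condition perturbation, uM) or
    "continuous" (forcing, uM/s).  pattern: k-spike equatorial
    ("1-spike".."4-spike"), "tetrahedral", "ring", or "uniform"
    (spatially constant, the unpatterned control).
    """

    mode: str
    pattern: str
    amplitude: float

    def __post_init__(self) -> None:
        if self.mode not in ("transient", "continuous"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown stimulus pattern {self.pattern!r}")
        if not self.amplitude > 0:
            raise ValueError("stimulus amplitude must be positive")


def gaussian_bump(domain: SphereDomain, center, amplitude: float) -> np.ndarray:
    """Gaussian spike around a surface point, unit (1 um) width, chord metric."""
    center = np.asarray(center, dtype=float)
    if abs(np.linalg.norm(center) - domain.radius) > 1e-6 * domain.radius:
        raise ValueError("stimulus center must lie on the sphere surface")
    d2 = np.sum((domain.node_positions - center) ** 2, axis=1)
    return amplitude * np.exp(-d2)


def pattern_centers(domain: SphereDomain, pattern: str) -> np.ndarray:
    """Spike center coordinates for a pattern (empty for ring/uniform)."""
    R = domain.radius
    if pattern.endswith("-spike"):
        k = int(pattern[0])
        ang = 2 * np.pi * np.arange(k) / k
        return R * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(k)])
    if pattern == "tetrahedral":
        return R * _TETRA
    return np.zeros((0, 3))


def build_stimulus(domain: SphereDomain, spec: StimulusSpec) -> np.ndarray:
    """Per-node stimulus field for a spec (uM for transient, uM/s for continuous)."""
    if not isinstance(domain, SphereDomain):
        raise ValueError("stimuli are defined on the sphere surface only")
    if spec.pattern == "uniform":
        return np.full(domain.n_nodes, spec.amplitude)
    if spec.pattern == "ring":
        z = domain.node_positions[:, 2]
        return spec.amplitude * np.exp(-(z**2))
    out = np.zeros(domain.n_nodes)
    for center in pattern_centers(domain, spec.pattern):
        out += gaussian_bump(domain, center, spec.amplitude)
    return out
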