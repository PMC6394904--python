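"""Gierer-Meinhardt reaction kinetics and linear (Turing) stability analysis.

The model couples a short-range activator ``A`` and a long-range inhibitor
``H`` (concentrations in uM)::

    dA/dt = D_A lap(A) - mu_A A + rho_1 (A + rho_A)^2 / H
    dH/dt = D_H lap(H) - mu_H H + rho_2 A^2 + rho_H

This module holds everything that can be done without a spatial domain:
the reaction terms, the diffusion-free homogeneous steady state, its
linearization, the two-species Turing instability criteria, the dispersion
relation, and single-parameter scaling utilities used by the kinetics
sweeps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GMParameters",
    "SteadyState",
    "Linearization",
    "TuringReport",
    "reaction_terms",
    "steady_state",
    "linearize",
    "turing_check",
    "dispersion_rate",
    "scale_parameter",
    "turing_factor_interval",
    "SCALABLE_PARAMETERS",
]

#: Parameter names accepted by :func:`scale_parameter`.  ``rho`` scales the
#: two reaction efficiencies rho_1 and rho_2 jointly; they share one
#: magnitude and differ only in units.
SCALABLE_PARAMETERS = ("D_A", "D_H", "mu_A", "mu_H", "rho", "rho_A", "rho_H")


@dataclass(frozen=True)
class GMParameters:
    """The eight kinetic constants of the activator-inhibitor system.

    Defaults are the wild-type parametrization that produces three
    equatorial spikes on the 550 um^2 domain.

    Units: diffusivities um^2/s, decays 1/s, rho_1 1/s, rho_2 1/(uM s),
    rho_A uM, rho_H uM/s.
    """

    D_A: float = 1.1
    D_H: float = 54.0
    mu_A: float = 0.21
    mu_H: float = 0.6
    rho_1: float = 0.2
    rho_2: float = 0.2
    rho_A: float = 0.003
    rho_H: float = 0.0001

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"parameter {name} must be strictly positive, got {value}")

    def to_text(self) -> str:
        """Serialize as flat ``key = value`` lines."""
        return "\n".join(f"{k} = {v!r}" for k, v in asdict(self).items()) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GMParameters":
        kv = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = float(value)
        return cls(**kv)


@dataclass(frozen=True)
class SteadyState:
    """Diffusion-free homogeneous steady state (uM)."""

    A_star: float
    H_star: float


@dataclass(frozen=True)
class Linearization:
    """Jacobian of the reaction terms at the steady state.

    f_* are the activator-equation partials, g_* the inhibitor-equation
    partials.  For an activator-inhibitor system f_A > 0 (self-activation),
    f_H < 0 (inhibition) and g_A > 0 (activation of the inhibitor).
    """

    f_A: float
    f_H: float
    g_A: float
    g_H: float

    @property
    def trace(self) -> float:
        return self.f_A + self.g_H

    @property
    def det(self) -> float:
        return self.f_A * self.g_H - self.f_H * self.g_A


@dataclass(frozen=True)
class TuringReport:
    """Outcome of the two-species Turing-instability criteria.

    ``k2_minus``/``k2_plus`` bound the unstable squared-wavenumber band
    (1/um^2); they are ``None`` unless all four criteria hold.
    """

    stable_without_diffusion: bool
    diffusion_driven_instability: bool
    k2_minus: float | None
    k2_plus: float | None

    @property
    def satisfied(self) -> bool:
        return self.stable_without_diffusion and self.diffusion_driven_instability

    def to_json(self) -> str:
        return json.dumps(
            {
                "stable_without_diffusion": self.stable_without_diffusion,
                "diffusion_driven_instability": self.diffusion_driven_instability,
                "k2_minus": self.k2_minus,
                "k2_plus": self.k2_plus,
                "satisfied": self.satisfied,
            },
            indent=2,
        )


def reaction_terms(params: GMParameters, A, H):
    """Reaction (non-diffusive) parts of dA/dt and dH/dt in uM/s.

    Accepts scalars or arrays.  Raises ``ValueError`` when any H <= 0,
    since the activator autocatalysis divides by the inhibitor.
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("inhibitor concentration must be positive (division by H)")
    dA = -params.mu_A * A + params.rho_1 * (A + params.rho_A) ** 2 / H
    dH = -params.mu_H * H + params.rho_2 * A**2 + params.rho_H
    if dA.ndim == 0:
        return float(dA), float(dH)
    return dA, dH


def steady_state(params: GMParameters, residual_tol: float = 1e-10) -> SteadyState:
    """Positive root of the diffusion-free system.

    With the basal terms rho_A = rho_H = 0 the root has the closed form
    A* = rho_1 mu_H / (rho_2 mu_A), H* = rho_2 A*^2 / mu_H; with Table-style
    small basal terms the numeric root lies within ~1% of it.  The closed
    form brackets the bisection search.
    """
    p = params

    def balance(A: float) -> float:
        H = (p.rho_2 * A * A + p.rho_H) / p.mu_H
        return -p.mu_A * A + p.rho_1 * (A + p.rho_A) ** 2 / H

    A0 = p.rho_1 * p.mu_H / (p.rho_2 * p.mu_A)
    lo, hi = 1e-12 * A0, 1e6 * A0
    if not (balance(lo) > 0 > balance(hi)):
        raise ValueError(
            "no positive diffusion-free steady state found "
            f"(balance({lo:g}) = {balance(lo):g}, balance({hi:g}) = {balance(hi):g})"
        )
    A_star = brentq(balance, lo, hi, xtol=1e-15, rtol=1e-15)
    H_star = (p.rho_2 * A_star * A_star + p.rho_H) / p.mu_H
    dA, dH = reaction_terms(p, A_star, H_star)
    if max(abs(dA), abs(dH)) > residual_tol:
        raise ValueError(f"steady-state residual {max(abs(dA), abs(dH)):g} exceeds {residual_tol:g}")
    return SteadyState(A_star=A_star, H_star=H_star)


def linearize(params: GMParameters, ss: SteadyState) -> Linearization:
    """Analytic Jacobian of :func:`reaction_terms` at (A*, H*)."""
    p, A, H = params, ss.A_star, ss.H_star
    return Linearization(
        f_A=2 * p.rho_1 * (A + p.rho_A) / H - p.mu_A,
        f_H=-p.rho_1 * (A + p.rho_A) ** 2 / H**2,
        g_A=2 * p.rho_2 * A,
        g_H=-p.mu_H,  # the inhibitor equation is linear in H
    )


def turing_check(params: GMParameters) -> TuringReport:
    """Evaluate the four standard two-species Turing criteria.

    Diffusion-driven instability of a reaction-stable state requires
    trace < 0, det > 0, D_H f_A + D_A g_H > 0 and
    (D_H f_A + D_A g_H)^2 > 4 D_A D_H det.  When satisfied, the unstable
    band (k2_minus, k2_plus) consists of the roots of
    D_A D_H k^4 - (D_H f_A + D_A g_H) k^2 + det = 0.
    """
    try:
        ss = steady_state(params)
    except ValueError:
        return TuringReport(False, False, None, None)
    lin = linearize(params, ss)
    stable = lin.trace < 0 and lin.det > 0
    b = params.D_H * lin.f_A + params.D_A * lin.g_H
    disc = b * b - 4 * params.D_A * params.D_H * lin.det
    unstable = stable and b > 0 and disc > 0
    if not unstable:
        return TuringReport(stable, False, None, None)
    sq = math.sqrt(disc)
    denom = 2 * params.D_A * params.D_H
    return TuringReport(stable, True, (b - sq) / denom, (b + sq) / denom)


def dispersion_rate(params: GMParameters, ss: SteadyState, k2: float) -> float:
    """Largest real part of the growth rate of a mode with squared wavenumber k2.

    Eigenvalue of [[f_A - D_A k2, f_H], [g_A, g_H - D_H k2]].
    """
    if k2 < 0:
        raise ValueError("squared wavenumber must be non-negative")
    lin = linearize(params, ss)
    a11 = lin.f_A - params.D_A * k2
    a22 = lin.g_H - params.D_H * k2
    tr, det = a11 + a22, a11 * a22 - lin.f_H * lin.g_A
    disc = tr * tr - 4 * det
    if disc >= 0:
        return 0.5 * (tr + math.sqrt(disc))
    return 0.5 * tr


def scale_parameter(params: GMParameters, name: str, factor: float) -> GMParameters:
    """Return a copy with one parameter (or the joint ``rho`` pair) scaled."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    if name == "rho":
        return replace(params, rho_1=params.rho_1 * factor, rho_2=params.rho_2 * factor)
    if name not in ("D_A", "D_H", "mu_A", "mu_H", "rho_1", "rho_2", "rho_A", "rho_H"):
        raise ValueError(f"unknown parameter name {name!r}")
    return replace(params, **{name: getattr(params, name) * factor})


def turing_factor_interval(
    params: GMParameters,
    name: str,
    scan_range: tuple[float, float] = (1e-4, 1e4),
    grid_points: int = 400,
    rel_precision: float = 1e-3,
) -> tuple[float, float]:
    """Contiguous interval of scaling factors around 1.0 keeping the Turing criteria satisfied.

    Scans a log-spaced factor grid, then refines each endpoint by bisection
    to relative precision ``rel_precision``.  Endpoints falling on the scan
    boundary mean the satisfying region extends at least that far.
    """
    if not turing_check(params).satisfied:
        raise ValueError("base parameters must satisfy the Turing criteria")

    def ok(factor: float) -> bool:
        try:
            return turing_check(scale_parameter(params, name, factor)).satisfied
        except ValueError:
            return False

    grid = np.logspace(math.log10(scan_range[0]), math.log10(scan_range[1]), grid_points)
    grid = np.unique(np.append(grid, 1.0))
    sat = np.array([ok(f) for f in grid])
    i1 = int(np.argmin(np.abs(grid - 1.0)))
    lo_i = i1
    while lo_i > 0 and sat[lo_i - 1]:
        lo_i -= 1
    hi_i = i1
    while hi_i < len(grid) - 1 and sat[hi_i + 1]:
        hi_i += 1

    def bisect(good: float, bad: float) -> float:
        while abs(bad - good) / good > rel_precision:
            mid = math.sqrt(good * bad)
            if ok(mid):
                good = mid
            else:
                bad = mid
        return good

    low = grid[lo_i] if lo_i == 0 else bisect(grid[lo_i], grid[lo_i - 1])
    high = grid[hi_i] if hi_i == len(grid) - 1 else bisect(grid[hi_i], grid[hi_i + 1])
    return float(low), float(high)
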