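"""Time integration of the activator-inhibitor system to steady state.

Two steppers, both treating the stiff linear part (diffusion + linear
decay) implicitly or exactly so that step sizes are set by accuracy, not
by diffusive stability:

* ring: ETD2RK (Cox-Matthews) in Fourier space -- the linear factor
  exp((-D k^2 - mu) dt) is exact, the nonlinear reaction is second order;
* sphere: backward-Euler IMEX on the cotangent Laplacian with a two-step
  Adams-Bashforth treatment of the nonlinear reaction.  The scheme is
  L-stable and its fixed points are exact discrete steady states.

Both use a local-error-based adaptive step size.  Runs end when the
maximum relative rate of change stays below ``steady_tol`` for a
``steady_window`` of model time, when ``t_max`` is reached, or when the
state leaves the finite/bounded regime (recorded as diverged, never
raised).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .model import GMParameters, steady_state
from .domains import RingDomain, SphereDomain

__all__ = ["Field", "SimConfig", "SimResult", "initial_condition", "integrate", "run_one"]


@dataclass
class Field:
    """Activator/inhibitor concentrations (uM) on domain nodes at one time."""

    domain: object
    A: np.ndarray
    H: np.ndarray
    time: float = 0.0

    def copy(self) -> "Field":
        return Field(self.domain, self.A.copy(), self.H.copy(), self.time)


@dataclass
class SimConfig:
    """Simulation controls.

    noise_amp: half-width (uM) of the uniform noise added to the initial
    conditions at every node.  steady_tol: relative rate threshold (1/s,
    scaled by A*) that must hold for steady_window seconds of model time.
    step_tol: target local truncation error per step (relative to A*).
    """

    noise_amp: float = 5e-4
    seed: object = 0
    t_max: float = 1e5
    steady_tol: float = 1e-6
    steady_window: float = 10.0
    dt_init: float = 0.05
    dt_max: float = 2.0
    dt_linear: float = 0.5
    step_tol: float = 1e-4
    divergence_factor: float = 1e6

    def __post_init__(self) -> None:
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be non-negative")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be positive")


@dataclass
class SimResult:
    final: Field
    converged: bool
    diverged: bool
    elapsed_model_time: float
    n_steps: int = 0
    settings: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.converged and self.diverged)


def initial_condition(
    params: GMParameters,
    domain,
    config: SimConfig,
    transient_stimulus: Optional[np.ndarray] = None,
) -> Field:
    """Near-homogeneous initial state: (A*, H*) plus per-node uniform noise.

    A transient stimulus field (uM) is added to the activator only.  Nodes
    pushed negative are clipped to zero with a warning.
    """
    ss = steady_state(params)
    rng = np.random.default_rng(config.seed)
    n = domain.n_nodes
    A = ss.A_star + rng.uniform(-config.noise_amp, config.noise_amp, n)
    H = ss.H_star + rng.uniform(-config.noise_amp, config.noise_amp, n)
    if transient_stimulus is not None:
        A = A + np.asarray(transient_stimulus, dtype=float)
    if np.any(A < 0) or np.any(H <= 0):
        warnings.warn("initial condition clipped to keep concentrations non-negative")
        A = np.maximum(A, 0.0)
        H = np.maximum(H, 1e-12)
    return Field(domain, A, H, 0.0)


def _steady_update(rate, t, config, window_state, confirmations):
    """Steady-state detector: two consecutive confirmation windows.

    A near-homogeneous perturbation can pass through a rate trough while
    still growing (stiff modes decay before the instability amplifies),
    so one sub-threshold window is not enough: the relative rate must
    stay below ``steady_tol`` and not increase by more than 20% across
    two successive ``steady_window`` spans.

    Returns (steady, window_state, confirmations); ``window_state`` is
    (window start time, rate at window start) or None.
    """
    if rate >= config.steady_tol:
        return False, None, 0
    if window_state is None:
        return False, (t, rate), confirmations
    t0, rate_ref = window_state
    if t - t0 < config.steady_window:
        return False, window_state, confirmations
    if rate <= 1.2 * rate_ref:
        return confirmations + 1 >= 2, (t, rate), confirmations + 1
    return False, (t, rate), 0


def _phi1(z: np.ndarray) -> np.ndarray:
    small = np.abs(z) < 1e-5
    zs = np.where(small, 1.0, z)
    return np.where(small, 1 + z / 2 + z * z / 6, np.expm1(zs) / zs)


def _phi2(z: np.ndarray) -> np.ndarray:
    small = np.abs(z) < 1e-4
    zs = np.where(small, 1.0, z)
    return np.where(small, 0.5 + z / 6 + z * z / 24, (np.expm1(zs) - zs) / (zs * zs))


def _integrate_ring(params, field, config, forcing):
    p = params
    dom: RingDomain = field.domain
    n = dom.n_nodes
    k2 = dom.wavenumbers**2
    LA = -(p.D_A * k2 + p.mu_A)
    LH = -(p.D_H * k2 + p.mu_H)
    A, H = field.A.copy(), np.maximum(field.H.copy(), 1e-12)
    Ah, Hh = np.fft.rfft(A), np.fft.rfft(H)
    Astar = steady_state(p).A_star
    F = 0.0 if forcing is None else np.asarray(forcing, dtype=float)

    t, dt, nstep = field.time, config.dt_init, 0
    ok_since, confirmations = None, 0
    last_rate = np.inf
    while t < config.t_max:
        NA = p.rho_1 * (A + p.rho_A) ** 2 / H + F
        NH = p.rho_2 * A * A + p.rho_H
        NAh, NHh = np.fft.rfft(NA), np.fft.rfft(NH)
        zA, zH = LA * dt, LH * dt
        A1h = np.exp(zA) * Ah + dt * _phi1(zA) * NAh
        H1h = np.exp(zH) * Hh + dt * _phi1(zH) * NHh
        A1, H1 = np.fft.irfft(A1h, n), np.fft.irfft(H1h, n)
        H1c = np.maximum(H1, 1e-12)
        NA1 = p.rho_1 * (A1 + p.rho_A) ** 2 / H1c + F
        NH1 = p.rho_2 * A1 * A1 + p.rho_H
        A2h = A1h + dt * _phi2(zA) * (np.fft.rfft(NA1) - NAh)
        H2h = H1h + dt * _phi2(zH) * (np.fft.rfft(NH1) - NHh)
        A2, H2 = np.fft.irfft(A2h, n), np.fft.irfft(H2h, n)

        err = max(np.max(np.abs(A2 - A1)), np.max(np.abs(H2 - H1))) / Astar
        if not np.isfinite(err) or np.max(np.abs(A2)) > config.divergence_factor * Astar:
            final = Field(dom, A, H, t)
            return SimResult(final, False, True, t, nstep)
        # The step-count/merge competition between near-degenerate modes is
        # decided while the pattern saturates; resolve that window with a
        # tenfold tighter error target (label distributions are converged
        # in the target there, unlike at the base tolerance).
        saturating = np.max(np.abs(A - Astar)) > 0.5 * Astar and last_rate > 100 * config.steady_tol
        tol_eff = 0.1 * config.step_tol if saturating else config.step_tol
        if err > tol_eff and dt > config.dt_init / 16:
            dt = max(dt * 0.5, config.dt_init / 16)
            continue
        A, H, Ah, Hh = A2, np.maximum(H2, 1e-12), A2h, H2h
        t += dt
        nstep += 1
        if err < 0.2 * tol_eff:
            dt = min(dt * 1.5, config.dt_max)

        if nstep % 10 == 0:
            dAdt = np.fft.irfft(LA * Ah, n) + p.rho_1 * (A + p.rho_A) ** 2 / H + F
            dHdt = np.fft.irfft(LH * Hh, n) + p.rho_2 * A * A + p.rho_H
            rate = max(np.max(np.abs(dAdt)), np.max(np.abs(dHdt))) / Astar
            last_rate = rate
            steady, ok_since, confirmations = _steady_update(
                rate, t, config, ok_since, confirmations
            )
            if steady:
                return SimResult(Field(dom, A, H, t), True, False, t, nstep)
    return SimResult(Field(dom, A, H, t), False, False, t, nstep)


def _integrate_sphere(params, field, config, forcing):
    p = params
    dom: SphereDomain = field.domain
    K, mass = dom.stiffness, dom.node_weights
    Mdiag = sp.diags(mass)
    Astar = steady_state(p).A_star
    F = 0.0 if forcing is None else np.asarray(forcing, dtype=float)
    A, H = field.A.copy(), np.maximum(field.H.copy(), 1e-12)

    lu_cache: dict[float, tuple] = {}

    def factors(dt):
        if dt not in lu_cache:
            lu_cache[dt] = (
                splu((Mdiag + dt * (p.D_A * K + p.mu_A * Mdiag)).tocsc()),
                splu((Mdiag + dt * (p.D_H * K + p.mu_H * Mdiag)).tocsc()),
            )
        return lu_cache[dt]

    t, dt, nstep = field.time, config.dt_init, 0
    NAp = NHp = None
    ok_since, confirmations = None, 0
    while t < config.t_max:
        # Resolve the linear mode-competition phase accurately; once the
        # pattern amplitude is finite the L-stable scheme may take long
        # steps (its fixed points are exact discrete steady states).
        cap = config.dt_linear if np.max(np.abs(A - Astar)) < 0.5 * Astar else 4 * config.dt_max
        if dt > cap:
            dt = cap
            NAp = NHp = None
        luA, luH = factors(dt)
        NA = p.rho_1 * (A + p.rho_A) ** 2 / H + F
        NH = p.rho_2 * A * A + p.rho_H
        if NAp is None:
            NAe, NHe = NA, NH
        else:
            NAe, NHe = 1.5 * NA - 0.5 * NAp, 1.5 * NH - 0.5 * NHp
        A2 = luA.solve(mass * (A + dt * NAe))
        H2 = luH.solve(mass * (H + dt * NHe))
        if not np.all(np.isfinite(A2)) or np.max(np.abs(A2)) > config.divergence_factor * Astar:
            return SimResult(Field(dom, A, H, t), False, True, t, nstep)

        rate = max(np.max(np.abs(A2 - A)), np.max(np.abs(H2 - H))) / (dt * Astar)
        est = 0.0 if NAp is None else 0.5 * dt * max(
            np.max(np.abs(NA - NAp)), np.max(np.abs(NH - NHp))
        ) / Astar
        NAp, NHp = NA, NH
        A, H = A2, np.maximum(H2, 1e-12)
        t += dt
        nstep += 1
        # In the quasi-steady tail (slow mesh-pinned drift of a formed
        # pattern) only the fixed point matters, so the error target is
        # relaxed tenfold to let the step size grow.
        tol_eff = config.step_tol * (10.0 if rate < 100 * config.steady_tol else 1.0)
        if est > tol_eff:
            dt = max(dt * 0.5, config.dt_init)
            NAp = NHp = None  # restart the multistep history
        elif dt < cap and nstep % 32 == 0 and 4 * est < tol_eff:
            # a doubled step would still meet the error target (est ~ dt^2)
            dt = min(dt * 2.0, cap)
            NAp = NHp = None

        steady, ok_since, confirmations = _steady_update(
            rate, t, config, ok_since, confirmations
        )
        if steady:
            return SimResult(Field(dom, A, H, t), True, False, t, nstep)
    return SimResult(Field(dom, A, H, t), False, False, t, nstep)


def integrate(
    params: GMParameters,
    field: Field,
    config: SimConfig,
    continuous_stimulus: Optional[np.ndarray] = None,
) -> SimResult:
    """Advance the (optionally forced) system until steady state.

    ``continuous_stimulus`` is a per-node forcing F(x) in uM/s added to the
    activator equation for the whole run; the inhibitor is never forced.
    """
    if continuous_stimulus is not None and np.shape(continuous_stimulus) != (field.domain.n_nodes,):
        raise ValueError("continuous stimulus shape does not match the domain")
    if isinstance(field.domain, RingDomain):
        res = _integrate_ring(params, field, config, continuous_stimulus)
    else:
        res = _integrate_sphere(params, field, config, continuous_stimulus)
    res.settings = {
        "noise_amp": config.noise_amp,
        "seed": repr(config.seed),
        "t_max": config.t_max,
        "steady_tol": config.steady_tol,
    }
    return res


def run_one(params: GMParameters, domain, config: SimConfig, stimulus_spec=None):
    """One replicate: initial condition, integration, classification.

    Returns ``(SimResult, PatternLabel)``; a diverged run is labeled
    ``failed`` rather than raising.
    """
    from .classify import classify_pattern, failed_label
    from .stimuli import build_stimulus

    transient = continuous = None
    if stimulus_spec is not None:
        stim_field = build_stimulus(domain, stimulus_spec)
        if stimulus_spec.mode == "transient":
            transient = stim_field
        else:
            continuous = stim_field
    field = initial_condition(params, domain, config, transient_stimulus=transient)
    result = integrate(params, field, config, continuous_stimulus=continuous)
    if result.diverged:
        label = failed_label()
    else:
        label = classify_pattern(result.final, A_star=steady_state(params).A_star)
    return result, label
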