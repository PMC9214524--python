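"""Langevin dynamics of a chemically active polar particle (CAPP).

A droplet is a point particle with position ``r`` and unit orientation
``n`` that self-propels at speed ``V0`` along ``n`` and couples to a
chemorepellent concentration field ``c(r, t)`` through an effective force
and an aligning torque:

    dr/dt = V0 n - alpha grad(c) + sqrt(2 D_t) xi_t
    dn/dt = Omega n x (n x grad(c)) + sqrt(2 D_r) n x xi_r

Both couplings are positive for chemorepulsion: ``alpha > 0`` pushes the
droplet down the gradient, ``Omega > 0`` rotates ``n`` away from it.  The
vector identity n x (n x g) = n (n.g) - g makes the torque the tangential
projection of ``-Omega grad(c)``; in 2D the deterministic turn rate is
``theta_dot = -Omega (grad(c) . n_perp)`` with ``n_perp`` being ``n``
rotated by +90 deg.

Since the field module computes ``c`` with unit emission strength, the
couplings used here are the lumped experimental products Omega*c0
(``omega_c0``, µm²/s) and alpha*c0 (``alpha_c0``, µm³/s).

Integration is Euler-Maruyama with post-step renormalisation of ``n``;
rotational noise acts on the polar angle in 2D and as a tangential
Gaussian kick in 3D, so |n| = 1 is preserved by construction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["ParticleState", "DynamicsParams", "Trajectory", "step", "simulate"]


@dataclasses.dataclass
class ParticleState:
    """Position (µm), unit orientation, and clock (s) of one droplet."""

    r: np.ndarray
    n: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.r.shape != self.n.shape or self.r.ndim != 1:
            raise ValueError("r and n must be 1-D vectors of equal dimension")


@dataclasses.dataclass(frozen=True)
class DynamicsParams:
    """CAPP parameters (µm, s, rad units).

    Defaults are the experimentally measured values: swimming speed
    V0 = 25 µm/s, lumped couplings omega_c0 = 7e3 µm²/s and
    alpha_c0 = 3e4 µm³/s (medians of the single-event fits), negligible
    translational diffusion, and D_r = 0 (0.01 rad²/s is the measured
    upper bound).
    """

    V0: float = 25.0
    alpha_c0: float = 3.0e4
    omega_c0: float = 7.0e3
    D_t: float = 0.0
    D_r: float = 0.0
    dt: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("V0 must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_t < 0 or self.D_r < 0:
            raise ValueError("diffusion coefficients must be non-negative")


@dataclasses.dataclass
class Trajectory:
    """Sampled path of one droplet: times (s), positions (µm), orientations."""

    droplet_id: int | str
    t: np.ndarray
    r: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.r.shape[1]


def _rotate2d(n: np.ndarray, angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([ca * n[0] - sa * n[1], sa * n[0] + ca * n[1]])


def step(state: ParticleState, field, p: DynamicsParams, rng: np.random.Generator) -> ParticleState:
    """One Euler-Maruyama step in the given concentration field.

    ``field(r, t) -> (c, grad_c)``.  Raises on a non-unit input orientation
    (beyond 1e-6) or a NaN field; warns when the deterministic rotation per
    step exceeds 0.5 rad (dt too large for the local gradient).
    """
    n = state.n
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("input orientation must be a unit vector")
    c, grad = field(state.r, state.t)
    grad = np.asarray(grad, dtype=float)
    if not np.isfinite(c) or not np.all(np.isfinite(grad)):
        raise ValueError("field returned a non-finite value")
    gnorm = float(np.linalg.norm(grad))
    if p.omega_c0 * gnorm * p.dt > 0.5:
        warnings.warn("deterministic rotation per step exceeds 0.5 rad; reduce dt",
                      RuntimeWarning, stacklevel=2)

    dt = p.dt
    r_new = state.r + (p.V0 * n - p.alpha_c0 * grad) * dt
    if p.D_t > 0:
        r_new = r_new + np.sqrt(2.0 * p.D_t * dt) * rng.standard_normal(state.r.size)

    if n.size == 2:
        n_perp = np.array([-n[1], n[0]])
        dtheta = -p.omega_c0 * float(grad @ n_perp) * dt
        if p.D_r > 0:
            dtheta += np.sqrt(2.0 * p.D_r * dt) * rng.standard_normal()
        n_new = _rotate2d(n, dtheta)
    else:
        n_new = n + p.omega_c0 * (n * float(n @ grad) - grad) * dt
        if p.D_r > 0:
            xi = rng.standard_normal(3)
            n_new = n_new + np.sqrt(2.0 * p.D_r * dt) * (xi - n * float(n @ xi))
        n_new = n_new / np.linalg.norm(n_new)
    n_new = n_new / np.linalg.norm(n_new)
    return ParticleState(r_new, n_new, state.t + dt)


def simulate(
    state0: ParticleState,
    field,
    p: DynamicsParams,
    duration: float,
    record_every: int = 1,
    droplet_id: int | str = 0,
) -> Trajectory:
    """Integrate for ``duration`` seconds; deterministic given ``p.seed``.

    The trajectory is sampled every ``record_every`` steps (plus the
    initial state).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(p.seed)
    n_steps = int(round(duration / p.dt))
    ts = [state0.t]
    rs = [state0.r.copy()]
    ns = [state0.n.copy()]
    state = state0
    for k in range(1, n_steps + 1):
        state = step(state, field, p, rng)
        if k % record_every == 0 or k == n_steps:
            ts.append(state.t)
            rs.append(state.r.copy())
            ns.append(state.n.copy())
    return Trajectory(droplet_id, np.array(ts), np.vstack(rs), np.vstack(ns))
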