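"""Estimation of the lumped chemotactic couplings from single events.

Each delayed-collision event is fitted individually: the CAPP model is
integrated forward (noise off, static trail cross-section frozen at the
event's lag) from the first observed sample, and the mean squared distance
between observed and simulated positions at the observed sample times is
minimised over (omega_c0, alpha_c0).  The objective uses position
residuals only; speed and turn-rate series serve as posterior checks.

The optimiser is a derivative-free simplex (Nelder-Mead) on log10
parameters with box bounds, restarted from several log-spaced initial
points because the forward model is non-smooth at the crossing/reflection
boundary.  Dataset-level estimates are component-wise medians over the
converged per-event fits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from . import _fast
from .dynamics import DynamicsParams
from .events import InteractionEvent
from .field import FieldParams

__all__ = ["FitResult", "fit_event", "median_couplings", "DEFAULT_BOUNDS"]

DEFAULT_BOUNDS = ((1e1, 1e6), (1e2, 1e7))  # (omega_c0 µm²/s, alpha_c0 µm³/s)


@dataclasses.dataclass
class FitResult:
    """Per-event coupling estimate."""

    event_id: int | str
    omega_hat: float
    alpha_hat: float
    loss: float  # mean squared position residual, µm²
    converged: bool
    n_starts: int = 0
    message: str = ""


def _initial_heading(xy: np.ndarray, k: int = 5) -> np.ndarray:
    """Robust initial heading from the first few samples (PCA direction,
    oriented along the time order)."""
    pts = xy[: max(2, min(k, len(xy)))]
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    u = vt[0]
    if float(u @ (pts[-1] - pts[0])) < 0:
        u = -u
    return u / np.linalg.norm(u)


def _forward_positions(event, p: DynamicsParams, fp: FieldParams,
                       omega: float, alpha: float,
                       n0: np.ndarray | None = None) -> np.ndarray:
    """Noise-free forward CAPP positions at the event's observed times."""
    t_obs = event.t - event.t[0]
    xy0 = event.xy[0]
    if n0 is None:
        n0 = _initial_heading(event.xy)
    duration = float(t_obs[-1])
    max_steps = int(np.ceil(duration / p.dt)) + 1
    t, x, y, _, _, _ = _fast.integrate_event(
        xy0[0], xy0[1], n0[0], n0[1],
        p.V0, alpha, omega, 0.0, 0.0, p.dt,
        fp.q, fp.D, fp.t_off, event.delta_t, 0.0, False,
        1e30, max_steps, 0, False,  # no band exit, no noise
        0.0, np.inf,
    )
    xs = np.interp(t_obs, t, x)
    ys = np.interp(t_obs, t, y)
    return np.column_stack([xs, ys])


def fit_event(
    event: InteractionEvent,
    p_fixed: DynamicsParams,
    fp: FieldParams,
    init: tuple[float, float] | None = None,
    bounds=DEFAULT_BOUNDS,
    n_starts: int = 5,
    event_id: int | str = 0,
) -> FitResult:
    """Fit (omega_c0, alpha_c0) to one observed event trajectory.

    Requires >= 20 samples inside the interaction band.  Events whose loss
    is flat in the couplings (no gradient signal) are returned flagged
    ``converged=False`` with message "unidentifiable"; failure to converge
    after multistart returns the best loss, flagged, not an exception.
    """
    if event.xy is None or len(event.t) < 20:
        raise ValueError("event must carry >= 20 observed samples inside the band")
    obs = np.asarray(event.xy, dtype=float)
    n_guess = _initial_heading(obs)
    theta_guess = float(np.arctan2(n_guess[1], n_guess[0]))

    def loss(x):
        # x = (log10 omega, log10 alpha, heading correction in rad); the
        # observed initial heading is noisy, so it is co-fitted as a nuisance
        omega = 10.0 ** x[0]
        alpha = 10.0 ** x[1]
        th = theta_guess + x[2]
        n0 = np.array([np.cos(th), np.sin(th)])
        sim = _forward_positions(event, p_fixed, fp, omega, alpha, n0=n0)
        resid = sim - obs
        return float(np.mean(np.einsum("ij,ij->i", resid, resid)))

    (olo, ohi), (alo, ahi) = bounds
    lb = np.array([np.log10(olo), np.log10(alo), -0.3])
    ub = np.array([np.log10(ohi), np.log10(ahi), 0.3])

    # identifiability probe over the coupling box (heading at the guess)
    probes = [lb, ub, np.array([lb[0], ub[1], 0.0]),
              np.array([ub[0], lb[1], 0.0]), 0.5 * (lb + ub)]
    probes = [np.array([q[0], q[1], 0.0]) for q in probes]
    pvals = [loss(q) for q in probes]
    if max(pvals) - min(pvals) <= 1e-9 * (1.0 + min(pvals)):
        return FitResult(event_id, float("nan"), float("nan"),
                         float(min(pvals)), False, 0, "unidentifiable")

    fracs = np.linspace(0.15, 0.85, n_starts)
    starts = [np.array([lb[0] + f * (ub[0] - lb[0]),
                        lb[1] + f * (ub[1] - lb[1]), 0.0]) for f in fracs]
    if init is not None:
        starts.insert(0, np.array([*np.log10(np.asarray(init, float)), 0.0]))
    best = None
    for x0 in starts:
        res = minimize(
            loss, x0, method="Nelder-Mead",
            bounds=list(zip(lb, ub)),
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 900},
        )
        if best is None or res.fun < best.fun:
            best = res
    omega_hat = float(10.0 ** best.x[0])
    alpha_hat = float(10.0 ** best.x[1])
    return FitResult(event_id, omega_hat, alpha_hat, float(best.fun),
                     bool(best.success), len(starts),
                     "" if best.success else "simplex did not converge")


def median_couplings(fits) -> tuple[float, float]:
    """Component-wise medians of (omega_hat, alpha_hat) over converged fits."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits")
    return (
        float(np.median([f.omega_hat for f in conv])),
        float(np.median([f.alpha_hat for f in conv])),
    )
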