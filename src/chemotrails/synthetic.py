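"""Synthetic-data generators for every stage of the pipeline.

These generators replace the experimental inputs: diffusing Gaussian
trail-intensity profile series (fluorescence analysis), single delayed
collision trajectory pairs with known incidence angle and lag (event
detection and coupling fits), and multi-droplet trajectory sets at
prescribed number densities (collective caging analysis).  Every generator
attaches a ground-truth record and is bit-reproducible from (parameters,
seed).

Observation noise is additive Gaussian position noise (default sigma =
1 µm, the sub-pixel tracking scale; 2% of the 50 µm droplet diameter)
applied to saved trajectories only, never to the dynamics, and
multiplicative intensity noise on the profiles.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .events import D_MAX_DEFAULT, simulate_event
from .field import FieldParams, intensity_profile
from .fluorescence import ProfileSeries

__all__ = ["GroundTruth", "gen_profiles", "gen_event_pair", "gen_collective"]

POSITION_NOISE_DEFAULT = 1.0  # µm


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic dataset."""

    params: dict
    seed: int

    def to_json(self, path=None) -> str:
        payload = json.dumps({"params": self.params, "seed": self.seed},
                             indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(params=obj["params"], seed=obj["seed"])


def gen_profiles(
    D: float = 52.5,
    t_off: float = 20.0,
    times=None,
    x_grid=None,
    noise_frac: float = 0.05,
    I0: float = 1000.0,
    floor: float | None = None,
    seed: int = 0,
) -> ProfileSeries:
    """Synthetic trail-fluorescence profile series.

    Default geometry matches the quantification experiment: 20 slices at
    5-100 s after droplet passage on a ±300 µm line with 1 µm spacing.
    ``intensity = model * (1 + noise_frac * xi) + floor`` with a constant
    additive floor (default 0.1% of the initial peak).
    """
    times = np.linspace(5.0, 100.0, 20) if times is None else np.asarray(times, float)
    x_grid = np.arange(-300.0, 301.0, 1.0) if x_grid is None else np.asarray(x_grid, float)
    if times.size == 0 or x_grid.size == 0:
        raise ValueError("times and x_grid must be non-empty")
    if np.any(times <= 0):
        raise ValueError("profile times must be positive")
    fp = FieldParams(D=D, t_off=t_off)
    model = np.vstack([intensity_profile(x_grid, t, I0, fp) for t in times])
    if floor is None:
        floor = 1e-3 * float(model.max())
    rng = np.random.default_rng(seed)
    noisy = model * (1.0 + noise_frac * rng.standard_normal(model.shape)) + floor
    gt = GroundTruth(
        params={"D": D, "t_off": t_off, "I0": I0, "noise_frac": noise_frac,
                "floor": floor},
        seed=seed,
    )
    return ProfileSeries(x=x_grid, times=times, intensity=noisy,
                         ground_truth=dataclasses.asdict(gt))


def gen_event_pair(
    theta_inc: float,
    delta_t: float,
    p: DynamicsParams,
    fp: FieldParams,
    position_noise: float = POSITION_NOISE_DEFAULT,
    seed: int = 0,
    d_max: float = D_MAX_DEFAULT,
    sample_dt: float = 0.5,
    trail_mode: str = "static",
    leader_margin: float = 3.0,
):
    """One synthetic delayed collision: leader + follower trajectory table.

    The leader moves straight along x at V0 laying the trail; the follower
    is launched to hit the leader's path at ``theta_inc``.  The leader's
    timeline is set so that it passes the follower's actual meeting point
    (crossing or closest approach) exactly ``delta_t`` seconds before the
    follower does, making the nominal lag the physically measured one.
    Observation noise is added to the saved positions only.

    Returns ``(table, ground_truth, event)`` where ``event`` is the clean
    simulated InteractionEvent.
    """
    ev = simulate_event(theta_inc, delta_t, p, fp, trail_mode=trail_mode,
                        d_max=d_max)
    # actual meeting point on the follower path: crossing of y=0 or closest approach
    y = ev.xy[:, 1]
    sign_change = np.flatnonzero(np.sign(y[:-1]) * np.sign(y[1:]) < 0)
    if sign_change.size:
        k = int(sign_change[0])
        w = y[k] / (y[k] - y[k + 1])
        x_meet = float(ev.xy[k, 0] + w * (ev.xy[k + 1, 0] - ev.xy[k, 0]))
        t_meet = float(ev.t[k] + w * (ev.t[k + 1] - ev.t[k]))
    else:
        k = int(np.argmin(np.abs(y)))
        x_meet = float(ev.xy[k, 0])
        t_meet = float(ev.t[k])

    # follower resampled at the tracking cadence; the simulated path stops
    # right at the interaction band edge, so continue it ballistically along
    # the final heading (the gradient there is negligible) so the recorded
    # track clearly exits the band
    tail = 30.0
    t_sim = ev.t
    x_sim = ev.xy[:, 0]
    y_sim = ev.xy[:, 1]
    vx_end = (x_sim[-1] - x_sim[-2]) / (t_sim[-1] - t_sim[-2])
    vy_end = (y_sim[-1] - y_sim[-2]) / (t_sim[-1] - t_sim[-2])
    tF = np.arange(t_sim[0], t_sim[-1] + tail, sample_dt)
    xF = np.interp(tF, t_sim, x_sim)
    yF = np.interp(tF, t_sim, y_sim)
    beyond = tF > t_sim[-1]
    xF[beyond] = x_sim[-1] + vx_end * (tF[beyond] - t_sim[-1])
    yF[beyond] = y_sim[-1] + vy_end * (tF[beyond] - t_sim[-1])

    # leader passes x_meet at time t_meet - delta_t, moving +x at V0
    t_pass = t_meet - delta_t
    span = leader_margin * d_max
    tL = np.arange(t_pass - span / p.V0, t_pass + span / p.V0, sample_dt)
    xL = x_meet + p.V0 * (tL - t_pass)
    yL = np.zeros_like(xL)

    t_shift = min(tL[0], tF[0])
    rng = np.random.default_rng(seed)
    rows = []
    for did, (tt, xx, yy) in enumerate([(tL, xL, yL), (tF, xF, yF)]):
        xx = xx + position_noise * rng.standard_normal(xx.size)
        yy = yy + position_noise * rng.standard_normal(yy.size)
        rows.append(pd.DataFrame({"droplet_id": did, "t": tt - t_shift,
                                  "x": xx, "y": yy}))
    table = pd.concat(rows, ignore_index=True)
    gt = GroundTruth(
        params={"theta_inc": theta_inc, "delta_t": delta_t, "V0": p.V0,
                "omega_c0": p.omega_c0, "alpha_c0": p.alpha_c0,
                "D": fp.D, "t_off": fp.t_off, "D_r": p.D_r,
                "position_noise": position_noise, "outcome": ev.outcome},
        seed=seed,
    )
    return table, gt, ev


def gen_collective(cfg, seed: int = 0):
    """Multi-droplet trajectory set at a prescribed number density.

    Thin wrapper around :func:`chemotrails.collective.simulate_collective`
    with the seed overridden; returns ``(table, trails, ground_truth)``.
    """
    from .collective import simulate_collective

    cfg = dataclasses.replace(cfg, seed=seed)
    table, trails = simulate_collective(cfg)
    gt = GroundTruth(
        params={"dimension": cfg.dimension, "box_size": cfg.box_size,
                "number_density": cfg.number_density, "duration": cfg.duration,
                "V0": cfg.dynamics.V0, "omega_c0": cfg.dynamics.omega_c0,
                "alpha_c0": cfg.dynamics.alpha_c0, "D_r": cfg.dynamics.D_r,
                "D": cfg.field.D, "t_off": cfg.field.t_off},
        seed=seed,
    )
    return table, trails, gt
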