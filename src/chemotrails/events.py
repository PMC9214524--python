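"""Single droplet-trail "delayed collision" events.

A following droplet meets the trail of a leading droplet at an incidence
angle ``theta_inc`` (folded to (0, pi/2]: the two approach sides are
equivalent by symmetry) and a time lag ``delta_t`` (the interval between
the two droplets passing the meeting point).  An interaction starts and
ends when the unsigned distance between the follower and the trail centre
line crosses the threshold ``d_max`` (220 µm).  Two outcomes occur:

* crossing   - the follower exits the interaction band on the side
               opposite its entry;
* reflection - it exits on the entry side (the marginal trajectory whose
               turning point sits exactly at the trail centre is counted
               as a reflection).

The critical lag separating the outcomes at each angle, Delta_t*(theta),
is the separatrix; its rotational-noise uncertainty band is
``delta_theta = sqrt(2 D_r T)`` with approach time
``T = d_max / (V0 sin theta)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _fast
from .dynamics import DynamicsParams
from .field import FieldParams

__all__ = [
    "InteractionEvent",
    "SeparatrixCurve",
    "simulate_event",
    "classify_event",
    "separatrix",
    "detect_interactions",
    "D_MAX_DEFAULT",
]

D_MAX_DEFAULT = 220.0  # µm, interaction-band half width


@dataclasses.dataclass
class InteractionEvent:
    """One delayed collision between a follower and a leader's trail.

    Series are restricted to the window where |d| <= d_max.  ``xy`` holds
    the follower positions in the trail frame (x along the trail, y the
    signed distance, positive on the incoming side).
    """

    theta_inc: float
    delta_t: float
    t0: float
    t: np.ndarray
    d: np.ndarray
    speed: np.ndarray
    turn_rate: np.ndarray
    outcome: str
    max_turn_rate: float
    xy: np.ndarray | None = None
    leader_id: int | str | None = None
    follower_id: int | str | None = None
    d_max: float = D_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not (0 < self.theta_inc <= np.pi / 2 + 1e-12):
            raise ValueError("theta_inc must lie in (0, pi/2]")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


@dataclasses.dataclass
class SeparatrixCurve:
    """Critical lag delta_t_star(theta) and rotational-noise band delta_theta."""

    theta_inc: np.ndarray
    delta_t_star: np.ndarray  # NaN where no reflection occurs in the bracket
    delta_theta: np.ndarray


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinking."""
    if window <= 1 or x.size < 3:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def _series_from_track(t, x, y, window: int = 5):
    """Speed and turn-rate series: centered differences of the positions,
    then a moving-average smooth of the velocity components (edge-safe for
    constant-velocity tracks)."""
    vx = _smooth(np.gradient(np.asarray(x, float), t), window)
    vy = _smooth(np.gradient(np.asarray(y, float), t), window)
    speed = np.hypot(vx, vy)
    theta = np.unwrap(np.arctan2(vy, vx))
    turn = np.gradient(theta, t)
    return speed, turn


def simulate_event(
    theta_inc: float,
    delta_t: float,
    p: DynamicsParams,
    fp: FieldParams,
    trail_mode: str = "static",
    d_max: float = D_MAX_DEFAULT,
    with_noise: bool = False,
    max_time: float = 3600.0,
    side: int = 1,
    record_window: int = 5,
) -> InteractionEvent:
    """Simulate a delayed collision against a straight trail along x.

    The follower starts at signed distance ``side * d_max`` heading toward
    the trail at ``theta_inc``; noise is off by default.  ``trail_mode``
    "static" freezes the Gaussian cross-section at lag ``delta_t`` for the
    whole encounter; "aging" lets the width grow in real time (the lag
    equals ``delta_t`` at the nominal meeting time).  A droplet whose speed
    stays below 5% of V0 for more than 60 s is flagged "trapped".
    """
    if not (0 < theta_inc <= np.pi / 2):
        raise ValueError("theta_inc must lie in (0, pi/2]")
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if trail_mode not in ("static", "aging"):
        raise ValueError("trail_mode must be 'static' or 'aging'")
    if side not in (1, -1):
        raise ValueError("side must be +1 or -1")
    t_app = d_max / (p.V0 * np.sin(theta_inc))
    max_steps = int(max_time / p.dt)
    t, x, y, nx, ny, status = _fast.integrate_event(
        0.0, side * d_max, np.cos(theta_inc), -side * np.sin(theta_inc),
        p.V0, p.alpha_c0, p.omega_c0, p.D_t, p.D_r, p.dt,
        fp.q, fp.D, fp.t_off, delta_t, t_app, trail_mode == "aging",
        d_max, max_steps, p.seed % 2**31, with_noise,
        0.05, 60.0,
    )
    d = side * y  # signed distance, positive on the incoming side
    if status == _fast.TRAPPED:
        outcome = "trapped"
    elif status == _fast.UNRESOLVED:
        outcome = "unresolved"
    else:
        outcome = "reflection" if d[-1] > 0 else "crossing"
    speed, turn = _series_from_track(t, x, y, record_window)
    inband = np.abs(d) <= d_max
    max_turn = float(np.max(np.abs(turn[inband]))) if np.any(inband) else 0.0
    return InteractionEvent(
        theta_inc=theta_inc,
        delta_t=delta_t,
        t0=t_app,
        t=t[inband],
        d=d[inband],
        speed=speed[inband],
        turn_rate=turn[inband],
        outcome=outcome,
        max_turn_rate=max_turn,
        xy=np.column_stack([x, y])[inband],
        d_max=d_max,
    )


def classify_event(trajectory, trail_line, d_max: float = D_MAX_DEFAULT,
                   y_tol: float = 1e-3) -> str:
    """Classify a trajectory against a straight trail centre line.

    ``trajectory`` is an (K, 2) position array (or an object with an ``r``
    attribute); ``trail_line`` is ``(point, direction)``.  Crossing iff the
    path exits the |d| <= d_max band on the side opposite its entry;
    reflection iff on the entry side; a turning point within ``y_tol`` of
    the centre counts as a reflection.  Returns "unresolved" when the path
    never exits the band.
    """
    xy = np.asarray(getattr(trajectory, "r", trajectory), dtype=float)
    p0, u = trail_line
    u = np.asarray(u, float) / np.linalg.norm(u)
    rel = xy - np.asarray(p0, float)
    d = rel[:, 0] * (-u[1]) + rel[:, 1] * u[0]  # signed perpendicular distance
    inside = np.abs(d) <= d_max
    if not np.any(inside):
        raise ValueError("trajectory never enters the interaction band")
    i0 = int(np.argmax(inside))
    after = np.nonzero(~inside[i0:])[0]
    if after.size == 0:
        return "unresolved"
    i1 = i0 + int(after[0])
    entry_sign = np.sign(d[i0]) if d[i0] != 0 else (np.sign(d[max(i0 - 1, 0)]) or 1.0)
    # exit side decides; a marginal turning point within y_tol of the centre
    # exits on the entry side and is therefore a reflection by this rule
    if entry_sign * d[i1] < -y_tol:
        return "crossing"
    return "reflection"


def separatrix(
    theta_grid,
    p: DynamicsParams,
    fp: FieldParams,
    d_max: float = D_MAX_DEFAULT,
    bracket: tuple[float, float] = (1.0, 600.0),
    tol: float = 0.5,
    D_r_band: float = 0.01,
    trail_mode: str = "static",
) -> SeparatrixCurve:
    """Critical lag delta_t*(theta) between reflection and crossing.

    At each angle the outcome is reflection below and crossing above the
    critical lag (the noise-free outcome is monotone in the lag, which the
    bracketing step verifies); delta_t* is located by bisection to ``tol``
    seconds.  Angles where the bracket endpoints do not straddle the switch
    get NaN (reported as absent, never extrapolated).  The noise band is
    ``delta_theta = sqrt(2 D_r_band d_max / (V0 sin theta))``.
    """
    theta_grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    stars = np.full(theta_grid.size, np.nan)

    def reflects(theta, lag):
        ev = simulate_event(theta, lag, p, fp, trail_mode=trail_mode, d_max=d_max)
        return ev.outcome in ("reflection", "trapped")

    for j, theta in enumerate(theta_grid):
        lo, hi = bracket
        if not reflects(theta, lo) or reflects(theta, hi):
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if reflects(theta, mid):
                lo = mid
            else:
                hi = mid
        stars[j] = 0.5 * (lo + hi)
    band = np.sqrt(2.0 * D_r_band * d_max / (p.V0 * np.sin(theta_grid)))
    return SeparatrixCurve(theta_grid, stars, band)


def _polyline_arc_distance(points: np.ndarray, poly: np.ndarray):
    """Distance from each query point to a polyline and the arc length of
    the nearest point.  Returns (dist (K,), arc (K,))."""
    a = poly[:-1]  # (S, 2)
    seg = poly[1:] - a
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2[seg_len2 == 0] = 1e-300
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(np.einsum("ij,ij->i", seg, seg)))])
    rel = points[:, None, :] - a[None, :, :]  # (K, S, 2)
    tpar = np.clip(np.einsum("ksj,sj->ks", rel, seg) / seg_len2, 0.0, 1.0)
    proj = a[None, :, :] + tpar[:, :, None] * seg[None, :, :]
    diff = points[:, None, :] - proj
    dist2 = np.einsum("ksj,ksj->ks", diff, diff)
    idx = np.argmin(dist2, axis=1)
    k = np.arange(points.shape[0])
    dist = np.sqrt(dist2[k, idx])
    arc = cum[idx] + tpar[k, idx] * np.sqrt(seg_len2[idx])
    return dist, arc


def _fit_line(points: np.ndarray):
    """Least-squares straight line through points: (centroid, unit direction)."""
    c = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0]


def detect_interactions(
    trajectories,
    d_max: float = D_MAX_DEFAULT,
    smooth_window: int = 5,
    min_samples: int = 3,
) -> list[InteractionEvent]:
    """Extract delayed-collision events from a set of trajectories.

    ``trajectories`` is a mapping id -> (t, xy) or a pandas DataFrame with
    columns droplet_id, t, x, y.  For every ordered (leader, follower)
    pair, contiguous windows where the follower is within ``d_max`` of the
    leader's path are examined; the meeting point is the follower's
    path-intersection with (or closest approach to) the leader's path, the
    lag is the difference of the two passage times (events with
    non-positive lag are discarded), and the incidence angle is measured
    between the follower's heading at band entry and the leader's fitted
    straight path, folded to (0, pi/2].
    """
    tracks = _as_tracks(trajectories)
    events: list[InteractionEvent] = []
    ids = list(tracks)
    for lid in ids:
        tL, rL = tracks[lid]
        if len(tL) < 2:
            continue
        arcL = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(rL, axis=0), axis=1))])
        for fid in ids:
            if fid == lid:
                continue
            tF, rF = tracks[fid]
            if len(tF) < min_samples:
                continue
            dist, arc = _polyline_arc_distance(rF, rL)
            inside = dist <= d_max
            if not np.any(inside):
                continue
            # contiguous in-band windows
            edges = np.flatnonzero(np.diff(inside.astype(int)))
            starts = [int(np.argmax(inside))] if inside[0] else []
            starts += [int(e) + 1 for e in edges if not inside[e]]
            for i0 in starts:
                rest = np.nonzero(~inside[i0:])[0]
                i1 = i0 + int(rest[0]) if rest.size else len(tF) - 1
                if i1 - i0 + 1 < min_samples:
                    continue
                ev = _build_event(
                    lid, fid, tL, rL, arcL, tF, rF, dist, arc,
                    i0, i1, bool(rest.size), d_max, smooth_window,
                )
                if ev is not None:
                    events.append(ev)
    return events


def _as_tracks(trajectories):
    if hasattr(trajectories, "groupby"):
        out = {}
        for did, g in trajectories.groupby("droplet_id"):
            g = g.sort_values("t")
            out[did] = (g["t"].to_numpy(float), g[["x", "y"]].to_numpy(float))
        return out
    out = {}
    for did, val in trajectories.items():
        if hasattr(val, "r"):
            out[did] = (np.asarray(val.t, float), np.asarray(val.r, float)[:, :2])
        else:
            t, xy = val
            out[did] = (np.asarray(t, float), np.asarray(xy, float))
    return out


def _build_event(lid, fid, tL, rL, arcL, tF, rF, dist, arc, i0, i1, exits,
                 d_max, window):
    sl = slice(i0, i1 + 1)
    # meeting point on the follower path: sign change of the signed distance
    # to the fitted leader line if present, else the closest approach
    s_center = arc[i0 + int(np.argmin(dist[sl]))]
    near = np.abs(arcL - s_center) <= d_max + 100.0
    if near.sum() < 2:
        near = np.argsort(np.abs(arcL - s_center))[:2]
    p0, u = _fit_line(rL[near])
    dsigned = (rF - p0) @ np.array([-u[1], u[0]])
    sign_change = np.flatnonzero(np.sign(dsigned[sl][:-1]) * np.sign(dsigned[sl][1:]) < 0)
    if sign_change.size:
        k = i0 + int(sign_change[0])
        w = dsigned[k] / (dsigned[k] - dsigned[k + 1])
        t0 = float(tF[k] + w * (tF[k + 1] - tF[k]))
        s_meet = float(arc[k] + w * (arc[k + 1] - arc[k]))
    else:
        k = i0 + int(np.argmin(np.abs(dsigned[sl])))
        t0 = float(tF[k])
        s_meet = float(arc[k])
    t_leader = float(np.interp(s_meet, arcL, tL))
    delta_t = t0 - t_leader
    if delta_t <= 0:
        return None
    # incidence angle: follower heading at band entry vs leader line
    j0 = max(i0, 1)
    head = rF[min(j0 + 1, len(tF) - 1)] - rF[j0 - 1]
    norm = np.linalg.norm(head)
    if norm == 0:
        return None
    cosang = abs(float(head @ u)) / norm
    theta = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta = min(max(theta, 1e-9), np.pi / 2)
    if float(head @ u) < 0:  # orient the trail axis along the follower's motion
        u = -u
        dsigned = -dsigned
    entry_sign = np.sign(dsigned[i0]) or 1.0
    d_series = entry_sign * dsigned
    # trail-frame coordinates (x along the leader line, y = signed distance)
    xy_frame = np.column_stack([(rF - p0) @ u, d_series])
    speed, turn = _series_from_track(tF, rF[:, 0], rF[:, 1], window)
    if exits:
        outcome = "crossing" if d_series[i1] < 0 else "reflection"
    else:
        outcome = "unresolved"
    return InteractionEvent(
        theta_inc=theta,
        delta_t=float(delta_t),
        t0=t0,
        t=tF[sl],
        d=d_series[sl],
        speed=speed[sl],
        turn_rate=turn[sl],
        outcome=outcome,
        max_turn_rate=float(np.max(np.abs(turn[sl]))),
        xy=xy_frame[sl],
        leader_id=lid,
        follower_id=fid,
        d_max=d_max,
    )
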