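"""Collective dynamics of trail-depositing droplets: chemotactic self-caging.

N chemically active polar particles move in a periodic square (or cubic)
box.  Each droplet deposits trail elements at a fixed cadence; every
droplet feels the superposed diffusion kernels of all deposited elements
(including its own past trail, excluding the most recent ``tau_self``
seconds of it, which would otherwise act as a spurious self-propelling
wake on the discretised path).  The ensemble mean squared displacement is
measured from the start of the run,

    MSD(t) = (1/N) sum_i |r_i(t) - r_i(t0)|^2,

without averaging over time origins because the chemical landscape ages
and the process is not stationary.  At low density the MSD is ballistic
(~t^2); at high density the trail network transiently traps droplets and
the MSD develops a plateau ("history caging") followed by cage escape and
a crossover toward diffusive scaling.

Caging is detected on the local log-log slope of the MSD: the caging onset
is the first lag where the smoothed local exponent drops below 0.5, the
escape is the subsequent lag where it rises back above 0.5, and the
plateau height is the median MSD in between.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import _fast
from .dynamics import DynamicsParams
from .field import FieldParams, TrailRecord

__all__ = [
    "CollectiveConfig",
    "MsdCurve",
    "simulate_collective",
    "ensemble_msd",
    "detect_caging",
    "neighborhood_history",
]


@dataclasses.dataclass
class CollectiveConfig:
    """Configuration of a collective trail-caging run.

    ``number_density`` is per mm² in 2D and per mm³ in 3D; ``box_size`` is
    in µm and must be at least four kernel widths at the memory cutoff
    (4 sqrt(4 D T_mem)) so a trail never wraps onto itself.
    """

    dimension: int = 2
    box_size: float = 2000.0
    number_density: float = 7.4
    duration: float = 300.0
    seed: int = 0
    dynamics: DynamicsParams = dataclasses.field(default_factory=DynamicsParams)
    field: FieldParams = dataclasses.field(default_factory=FieldParams)
    dt_deposit: float = 0.5
    tau_self: float = 4.0
    field_update_every: int = 5
    record_every: int = 10
    placement: str = "uniform"

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        width = np.sqrt(4.0 * self.field.D * self.field.T_mem)
        if self.box_size < 4.0 * width:
            raise ValueError(
                f"box_size must be >= 4x the kernel width at T_mem ({4 * width:.0f} µm)"
            )
        if self.n_droplets < 1:
            raise ValueError("density and box give N < 1")

    @property
    def n_droplets(self) -> int:
        volume_mm = (self.box_size / 1000.0) ** self.dimension
        return max(1, int(round(self.number_density * volume_mm)))


@dataclasses.dataclass
class MsdCurve:
    """Ensemble MSD vs lag with caging markers (filled by detect_caging)."""

    lags: np.ndarray
    msd: np.ndarray
    local_exponent: np.ndarray | None = None
    crossover_to_caging: float | None = None
    crossover_to_escape: float | None = None
    plateau_height: float | None = None


def simulate_collective(cfg: CollectiveConfig):
    """Run the collective Brownian-dynamics simulation.

    Returns ``(table, trails)``: a trajectory DataFrame with columns
    droplet_id, t, x, y[, z], nx, ny[, nz] (positions unwrapped) and the
    list of deposited TrailRecords.  Bit-identical for identical config and
    seed.
    """
    if cfg.dimension == 3:
        return _simulate_3d(cfg)
    p = cfg.dynamics
    fp = cfg.field
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_droplets
    box = cfg.box_size
    pos = rng.uniform(0.0, box, size=(N, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=N)
    n_steps = int(round(cfg.duration / p.dt))
    dep_stride = max(1, int(round(cfg.dt_deposit / p.dt)))
    n_dep = N * (n_steps // dep_stride + 2)
    seg_x = np.empty(n_dep)
    seg_y = np.empty(n_dep)
    seg_t = np.empty(n_dep)
    seg_w = np.empty(n_dep)
    seg_owner = np.empty(n_dep, dtype=np.int64)
    n_seg = 0
    last_dep_pos = pos.copy()
    last_dep_t = 0.0
    ids = np.arange(N, dtype=np.int64)
    gx = np.zeros(N)
    gy = np.zeros(N)
    rec_t = [0.0]
    rec_pos = [pos.copy()]
    rec_theta = [theta.copy()]
    dep_records: list[list] = [[(0.0, pos[i].copy())] for i in range(N)]
    max_step_len = 0.25 * box

    t = 0.0
    for k in range(1, n_steps + 1):
        if (k - 1) % cfg.field_update_every == 0 and n_seg > 0:
            _, gx, gy = _fast.field_all_2d(
                pos[:, 0], pos[:, 1], ids, t,
                seg_x, seg_y, seg_t, seg_w, seg_owner, n_seg,
                fp.D, fp.t_off, fp.T_mem, fp.R_max, cfg.tau_self, box,
            )
        nx = np.cos(theta)
        ny = np.sin(theta)
        dx = (p.V0 * nx - p.alpha_c0 * gx) * p.dt
        dy = (p.V0 * ny - p.alpha_c0 * gy) * p.dt
        if p.D_t > 0:
            dx = dx + np.sqrt(2 * p.D_t * p.dt) * rng.standard_normal(N)
            dy = dy + np.sqrt(2 * p.D_t * p.dt) * rng.standard_normal(N)
        if np.max(dx * dx + dy * dy) > max_step_len**2:
            raise RuntimeError(
                "field query overflow: single-step displacement exceeds box/4; "
                "reduce dt or the couplings"
            )
        pos[:, 0] += dx
        pos[:, 1] += dy
        # torque on the polar angle: theta_dot = -omega (grad . n_perp)
        dtheta = -p.omega_c0 * (gx * (-ny) + gy * nx) * p.dt
        if p.D_r > 0:
            dtheta = dtheta + np.sqrt(2 * p.D_r * p.dt) * rng.standard_normal(N)
        theta = theta + dtheta
        t = k * p.dt
        if k % dep_stride == 0:
            mid = 0.5 * (pos + last_dep_pos)
            ds = np.linalg.norm(pos - last_dep_pos, axis=1)
            tm = 0.5 * (t + last_dep_t)
            sl = slice(n_seg, n_seg + N)
            seg_x[sl] = mid[:, 0]
            seg_y[sl] = mid[:, 1]
            seg_t[sl] = tm
            seg_w[sl] = fp.q * ds
            seg_owner[sl] = ids
            n_seg += N
            last_dep_pos = pos.copy()
            last_dep_t = t
            for i in range(N):
                dep_records[i].append((t, pos[i].copy()))
        if k % cfg.record_every == 0 or k == n_steps:
            rec_t.append(t)
            rec_pos.append(pos.copy())
            rec_theta.append(theta.copy())

    tarr = np.array(rec_t)
    parr = np.array(rec_pos)  # (K, N, 2)
    tharr = np.array(rec_theta)
    frames = []
    for i in range(N):
        frames.append(pd.DataFrame({
            "droplet_id": i,
            "t": tarr,
            "x": parr[:, i, 0],
            "y": parr[:, i, 1],
            "nx": np.cos(tharr[:, i]),
            "ny": np.sin(tharr[:, i]),
        }))
    table = pd.concat(frames, ignore_index=True)
    trails = [
        TrailRecord(i, np.array([s[0] for s in dep_records[i]]),
                    np.array([s[1] for s in dep_records[i]]))
        for i in range(N)
    ]
    return table, trails


def _simulate_3d(cfg: CollectiveConfig):
    """Exploratory 3D mode: 2D-calibrated couplings with the 3D kernel."""
    p = cfg.dynamics
    fp = cfg.field
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_droplets
    box = cfg.box_size
    pos = rng.uniform(0.0, box, size=(N, 3))
    n = rng.standard_normal((N, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    n_steps = int(round(cfg.duration / p.dt))
    dep_stride = max(1, int(round(cfg.dt_deposit / p.dt)))
    n_dep = N * (n_steps // dep_stride + 2)
    seg_pos = np.empty((n_dep, 3))
    seg_t = np.empty(n_dep)
    seg_w = np.empty(n_dep)
    seg_owner = np.empty(n_dep, dtype=np.int64)
    n_seg = 0
    last_dep_pos = pos.copy()
    last_dep_t = 0.0
    ids = np.arange(N, dtype=np.int64)
    g = np.zeros((N, 3))
    rec = [(0.0, pos.copy(), n.copy())]
    t = 0.0
    for k in range(1, n_steps + 1):
        if (k - 1) % cfg.field_update_every == 0 and n_seg > 0:
            _, g = _fast.field_all_3d(
                pos, ids, t, seg_pos, seg_t, seg_w, seg_owner, n_seg,
                fp.D, fp.t_off, fp.T_mem, fp.R_max, cfg.tau_self, box,
            )
        disp = (p.V0 * n - p.alpha_c0 * g) * p.dt
        if p.D_t > 0:
            disp = disp + np.sqrt(2 * p.D_t * p.dt) * rng.standard_normal((N, 3))
        pos = pos + disp
        dn = p.omega_c0 * (n * np.einsum("ij,ij->i", n, g)[:, None] - g) * p.dt
        if p.D_r > 0:
            xi = rng.standard_normal((N, 3))
            xi -= n * np.einsum("ij,ij->i", n, xi)[:, None]
            dn = dn + np.sqrt(2 * p.D_r * p.dt) * xi
        n = n + dn
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        t = k * p.dt
        if k % dep_stride == 0:
            mid = 0.5 * (pos + last_dep_pos)
            ds = np.linalg.norm(pos - last_dep_pos, axis=1)
            sl = slice(n_seg, n_seg + N)
            seg_pos[sl] = mid
            seg_t[sl] = 0.5 * (t + last_dep_t)
            seg_w[sl] = fp.q * ds
            seg_owner[sl] = ids
            n_seg += N
            last_dep_pos = pos.copy()
            last_dep_t = t
        if k % cfg.record_every == 0 or k == n_steps:
            rec.append((t, pos.copy(), n.copy()))
    frames = []
    for i in range(N):
        frames.append(pd.DataFrame({
            "droplet_id": i,
            "t": [s[0] for s in rec],
            "x": [s[1][i, 0] for s in rec],
            "y": [s[1][i, 1] for s in rec],
            "z": [s[1][i, 2] for s in rec],
            "nx": [s[2][i, 0] for s in rec],
            "ny": [s[2][i, 1] for s in rec],
            "nz": [s[2][i, 2] for s in rec],
        }))
    table = pd.concat(frames, ignore_index=True)
    trails: list[TrailRecord] = []
    return table, trails


def _position_columns(table: pd.DataFrame) -> list[str]:
    return ["x", "y", "z"] if "z" in table.columns else ["x", "y"]


def ensemble_msd(trajectories, t0: float = 0.0, n_per_decade: int = 20) -> MsdCurve:
    """Ensemble MSD from each droplet's position at ``t0`` (Eq.-style
    average over droplets, no time-origin averaging).

    ``trajectories`` is a trajectory DataFrame or a mapping id -> (t, xy).
    Droplets are resampled onto the common recorded grid by linear
    interpolation; single-sample trajectories are excluded with a warning.
    Lags are thinned to about ``n_per_decade`` log-spaced points (the first
    point is lag 0 with MSD 0).
    """
    if isinstance(trajectories, pd.DataFrame):
        tracks = {
            did: (g.sort_values("t")["t"].to_numpy(float),
                  g.sort_values("t")[_position_columns(trajectories)].to_numpy(float))
            for did, g in trajectories.groupby("droplet_id")
        }
    else:
        tracks = {k: (np.asarray(v[0], float), np.asarray(v[1], float))
                  for k, v in trajectories.items()}
    usable = {}
    for did, (t, r) in tracks.items():
        keep = t >= t0
        if keep.sum() < 2:
            warnings.warn(f"droplet {did}: fewer than two samples after t0; excluded")
            continue
        usable[did] = (t[keep], r[keep])
    if not usable:
        raise ValueError("no usable trajectories")
    # common grid: times of the shortest usable track
    ref = min(usable.values(), key=lambda v: v[0][-1])[0]
    disp2 = np.zeros(ref.size)
    for t, r in usable.values():
        ri = np.column_stack([np.interp(ref, t, r[:, j]) for j in range(r.shape[1])])
        d = ri - ri[0]
        disp2 += np.einsum("ij,ij->i", d, d)
    msd = disp2 / len(usable)
    lags = ref - ref[0]
    # log-spaced thinning
    if lags.size > 3:
        pos = lags > 0
        lmin, lmax = lags[pos].min(), lags[-1]
        n_pts = max(4, int(np.ceil(np.log10(lmax / lmin) * n_per_decade)))
        targets = np.geomspace(lmin, lmax, n_pts)
        idx = np.unique(np.searchsorted(lags, targets))
        idx = idx[idx < lags.size]
        idx = np.unique(np.concatenate([[0], idx, [lags.size - 1]]))
        lags, msd = lags[idx], msd[idx]
    return MsdCurve(lags=lags, msd=msd)


def detect_caging(curve: MsdCurve, threshold: float = 0.5, window: int = 5):
    """Locate caging onset, cage escape, and plateau height on an MSD curve.

    The local exponent is the centred slope of log MSD vs log lag over a
    ``window``-point window.  Onset = first lag with exponent below
    ``threshold``; escape = first subsequent lag back above it; plateau =
    median MSD between them (to the end of the curve if no escape).  Absent
    regimes are returned as None.  Fills the curve's fields and returns
    ``(crossover_to_caging, crossover_to_escape, plateau_height)``.
    """
    good = (curve.lags > 0) & (curve.msd > 0)
    lags = curve.lags[good]
    msd = curve.msd[good]
    if lags.size < window + 2:
        raise ValueError("MSD curve too short for exponent analysis")
    if lags[-1] / lags[0] < 50:
        warnings.warn("MSD curve spans less than ~2 decades in lag; "
                      "crossover detection may be unreliable")
    ll = np.log(lags)
    lm = np.log(msd)
    half = window // 2
    centers = np.arange(half, lags.size - half)
    expo = np.empty(centers.size)
    for j, c in enumerate(centers):
        sl = slice(c - half, c + half + 1)
        A = np.vstack([ll[sl], np.ones(window)]).T
        expo[j] = np.linalg.lstsq(A, lm[sl], rcond=None)[0][0]
    expo = np.clip(expo, -0.5, 2.5)
    curve.local_exponent = expo
    exp_lags = lags[centers]
    below = expo < threshold
    onset = escape = plateau = None
    if np.any(below):
        i_on = int(np.argmax(below))
        onset = float(exp_lags[i_on])
        above_after = np.nonzero(expo[i_on:] > threshold)[0]
        i_off = i_on + int(above_after[0]) if above_after.size else expo.size
        if above_after.size:
            escape = float(exp_lags[i_off])
        in_cage = (lags >= onset) & (lags <= (escape if escape else lags[-1]))
        plateau = float(np.median(msd[in_cage]))
    curve.crossover_to_caging = onset
    curve.crossover_to_escape = escape
    curve.plateau_height = plateau
    return onset, escape, plateau


def neighborhood_history(
    trajectories,
    focal_id,
    d_window: float = 220.0,
    t_window: float = 50.0,
) -> pd.DataFrame:
    """Other-droplet samples inside a trailing spatiotemporal window.

    For each sample (t0, r0) of the focal droplet, returns every sample of
    every other droplet with ``|r - r0| <= d_window`` and
    ``0 < t0 - t <= t_window`` — the recent passage history that builds the
    cage around the focal droplet.
    """
    if isinstance(trajectories, pd.DataFrame):
        df = trajectories
    else:
        rows = []
        for did, (t, r) in trajectories.items():
            rows.append(pd.DataFrame({"droplet_id": did, "t": t,
                                      "x": r[:, 0], "y": r[:, 1]}))
        df = pd.concat(rows, ignore_index=True)
    if focal_id not in set(df["droplet_id"]):
        raise KeyError(f"unknown focal droplet id {focal_id!r}")
    cols = _position_columns(df)
    focal = df[df["droplet_id"] == focal_id].sort_values("t")
    others = df[df["droplet_id"] != focal_id].sort_values("t").reset_index(drop=True)
    ot = others["t"].to_numpy(float)
    opos = others[cols].to_numpy(float)
    out = []
    for _, row in focal.iterrows():
        t0 = float(row["t"])
        r0 = row[cols].to_numpy(float)
        lo = np.searchsorted(ot, t0 - t_window)
        hi = np.searchsorted(ot, t0, side="left")
        if hi <= lo:
            continue
        sub = opos[lo:hi]
        dist = np.linalg.norm(sub - r0, axis=1)
        near = (dist <= d_window) & (ot[lo:hi] < t0)
        if np.any(near):
            sel = others.iloc[lo:hi][near].copy()
            sel.insert(0, "focal_t", t0)
            sel["distance"] = dist[near]
            out.append(sel)
    if not out:
        return pd.DataFrame(columns=["focal_t", "droplet_id", "t", *cols, "distance"])
    return pd.concat(out, ignore_index=True)
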