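"""Numba-compiled inner loops: single-event integration and collective field sums.

These are private kernels; the public surface lives in events.py and
collective.py.  All use Euler-Maruyama with the same discretisation as
dynamics.step (2D, orientation advanced on the polar angle).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by integrate_event
EXITED = 0
TRAPPED = 2
UNRESOLVED = 3


@njit(cache=True)
def integrate_event(
    x0, y0, nx0, ny0,
    V0, alpha, omega, D_t, D_r, dt,
    q, D, t_off, delta_t, t_app, aging,
    d_max, max_steps, seed, use_noise,
    slow_frac, slow_time,
):
    """Integrate one droplet against a straight trail laid along the x axis.

    The trail cross-section is a 1-D Gaussian of width sqrt(2 D tau) with
    tau = delta_t + t_off frozen ("static" mode, aging = False) or growing
    in real time such that tau = delta_t at the nominal encounter time
    t = t_app ("aging" mode).  Integration stops when |y| > d_max, when the
    swimming speed stays below slow_frac*V0 for longer than slow_time
    (status TRAPPED), or after max_steps (status UNRESOLVED).

    Returns (t, x, y, nx, ny, status) with arrays truncated to the number
    of recorded samples (including the initial state).
    """
    if use_noise:
        np.random.seed(seed)
    ts = np.empty(max_steps + 1)
    xs = np.empty(max_steps + 1)
    ys = np.empty(max_steps + 1)
    nxs = np.empty(max_steps + 1)
    nys = np.empty(max_steps + 1)
    x = x0
    y = y0
    nx = nx0
    ny = ny0
    t = 0.0
    ts[0] = t
    xs[0] = x
    ys[0] = y
    nxs[0] = nx
    nys[0] = ny
    m = 1
    status = UNRESOLVED
    slow_acc = 0.0
    sqrt2Dt = np.sqrt(2.0 * D_t * dt)
    sqrt2Dr = np.sqrt(2.0 * D_r * dt)
    for _ in range(max_steps):
        if aging:
            tau = delta_t - t_app + t + t_off
        else:
            tau = delta_t + t_off
        if tau > 1e-12:
            s = 4.0 * D * tau
            c = q / np.sqrt(np.pi * s) * np.exp(-(y * y) / s)
            gy = -2.0 * y / s * c
        else:
            gy = 0.0
        vx = V0 * nx
        vy = V0 * ny - alpha * gy
        speed = np.sqrt(vx * vx + vy * vy)
        if speed < slow_frac * V0:
            slow_acc += dt
            if slow_acc > slow_time:
                status = TRAPPED
                break
        else:
            slow_acc = 0.0
        x += vx * dt
        y += vy * dt
        if use_noise and D_t > 0.0:
            x += sqrt2Dt * np.random.normal()
            y += sqrt2Dt * np.random.normal()
        # torque: theta_dot = -omega * (grad . n_perp), grad = (0, gy), n_perp = (-ny, nx)
        dtheta = -omega * gy * nx * dt
        if use_noise and D_r > 0.0:
            dtheta += sqrt2Dr * np.random.normal()
        ca = np.cos(dtheta)
        sa = np.sin(dtheta)
        nx, ny = ca * nx - sa * ny, sa * nx + ca * ny
        norm = np.sqrt(nx * nx + ny * ny)
        nx /= norm
        ny /= norm
        t += dt
        ts[m] = t
        xs[m] = x
        ys[m] = y
        nxs[m] = nx
        nys[m] = ny
        m += 1
        if abs(y) > d_max:
            status = EXITED
            break
    return ts[:m], xs[:m], ys[:m], nxs[:m], nys[:m], status


@njit(cache=True)
def field_all_2d(
    px, py, ids, t,
    seg_x, seg_y, seg_t, seg_w, seg_owner, n_seg,
    D, t_off, T_mem, R_max, tau_self, box,
):
    """Concentration and gradient at N droplet positions from trail segments.

    Minimum-image convention in a periodic square box of side ``box``
    (box <= 0 disables wrapping).  A droplet ignores its own segments
    younger than ``tau_self``.
    """
    N = px.size
    c = np.zeros(N)
    gx = np.zeros(N)
    gy = np.zeros(N)
    R2 = R_max * R_max
    for i in range(N):
        own = ids[i]
        ci = 0.0
        gxi = 0.0
        gyi = 0.0
        for k in range(n_seg):
            age = t - seg_t[k]
            if age <= 0.0 or age > T_mem:
                continue
            if seg_owner[k] == own and age < tau_self:
                continue
            dx = px[i] - seg_x[k]
            dy = py[i] - seg_y[k]
            if box > 0.0:
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
            r2 = dx * dx + dy * dy
            if r2 > R2:
                continue
            denom = 4.0 * D * (age + t_off)
            a = seg_w[k] / (np.pi * denom) * np.exp(-r2 / denom)
            ci += a
            f = -2.0 * a / denom
            gxi += f * dx
            gyi += f * dy
        c[i] = ci
        gx[i] = gxi
        gy[i] = gyi
    return c, gx, gy


@njit(cache=True)
def field_all_3d(
    pos, ids, t,
    seg_pos, seg_t, seg_w, seg_owner, n_seg,
    D, t_off, T_mem, R_max, tau_self, box,
):
    """3D analogue of field_all_2d with the (4 pi D tau)**(3/2) kernel."""
    N = pos.shape[0]
    c = np.zeros(N)
    g = np.zeros((N, 3))
    R2 = R_max * R_max
    for i in range(N):
        own = ids[i]
        for k in range(n_seg):
            age = t - seg_t[k]
            if age <= 0.0 or age > T_mem:
                continue
            if seg_owner[k] == own and age < tau_self:
                continue
            dx = pos[i, 0] - seg_pos[k, 0]
            dy = pos[i, 1] - seg_pos[k, 1]
            dz = pos[i, 2] - seg_pos[k, 2]
            if box > 0.0:
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > R2:
                continue
            denom = 4.0 * D * (age + t_off)
            a = seg_w[k] / (np.pi * denom) ** 1.5 * np.exp(-r2 / denom)
            c[i] += a
            f = -2.0 * a / denom
            g[i, 0] += f * dx
            g[i, 1] += f * dy
            g[i, 2] += f * dz
    return c, g
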