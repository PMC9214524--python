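"""Chemorepellent concentration fields left behind by swimming droplets.

A self-propelled droplet sheds oil-filled surfactant micelles along its
path.  The micelles act as a chemorepellent for other droplets and spread
by molecular diffusion, so the trail of a droplet is modelled as a line of
instantaneous point sources.  Each emitted element of trail length ``ds``
contributes the free-space diffusion kernel

    dc(r, t) = q ds / (4 pi D (t - t' + t_off))**(dim/2)
               * exp(-|r - r'|^2 / (4 D (t - t' + t_off)))

where ``t'`` and ``r'`` are the emission time and position, ``D`` the
micelle diffusivity and ``t_off`` a finite-source time offset: the droplet
(diameter ~50 µm) is not a point source, so a freshly laid trail element
already has the width of a point source that has diffused for ``t_off``
(default 20 s).

The cross-section of a long straight trail is then a 1-D Gaussian

    c(y, tau) = q / sqrt(4 pi D (tau + t_off)) * exp(-y^2 / (4 D (tau + t_off)))

with ``y`` the signed distance from the trail centre line and ``tau`` the
time since the droplet passed.  Its peak decays as (tau + t_off)**(-1/2)
and its integral over ``y`` is conserved.

Units are fixed package-wide: µm, s, rad.  With the default unit emission
rate ``q = 1`` per unit trail length the field carries units of 1/µm (2D)
and the lumped experimental couplings Omega*c0 [µm²/s] and alpha*c0
[µm³/s] multiply the computed gradient directly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "FieldParams",
    "TrailRecord",
    "trail_cross_section",
    "cross_section_gradient",
    "intensity_profile",
    "field_superposition",
    "static_cross_section_field",
]


@dataclasses.dataclass(frozen=True)
class FieldParams:
    """Parameters of the chemorepellent field.

    Attributes
    ----------
    D : float
        Micelle diffusivity, µm²/s.
    t_off : float
        Finite-source time offset added to every kernel age, s.
    q : float
        Emission per unit trail length (dimensionless scale of c).
    T_mem : float
        Trail memory: emitted elements older than this are dropped, s.
    R_max : float or None
        Spatial cutoff for kernel sums, µm.  ``None`` selects
        ``5 * sqrt(4 D T_mem)`` (relative contributions beyond are < 1e-6).
    ds_max : float
        Maximum trail sample spacing before kernel quadrature, µm.
    """

    D: float = 52.5
    t_off: float = 20.0
    q: float = 1.0
    T_mem: float = 600.0
    R_max: float | None = None
    ds_max: float = 25.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusivity D must be positive")
        if self.t_off < 0:
            raise ValueError("source offset t_off must be non-negative")
        if self.q <= 0:
            raise ValueError("deposition strength q must be positive")
        if self.T_mem <= 0:
            raise ValueError("memory cutoff T_mem must be positive")
        if self.ds_max <= 0:
            raise ValueError("ds_max must be positive")
        if self.R_max is None:
            object.__setattr__(self, "R_max",
                               float(5.0 * np.sqrt(4.0 * self.D * self.T_mem)))
        elif self.R_max <= 0:
            raise ValueError("spatial cutoff R_max must be positive")


def _tau_eff(lag, fp: FieldParams):
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag since passage must be non-negative")
    return lag + fp.t_off


def trail_cross_section(y, lag, fp: FieldParams):
    """Concentration across a straight trail.

    Parameters
    ----------
    y : array_like
        Signed distance from the trail centre line, µm.
    lag : array_like
        Time since the droplet passed, s (>= 0).
    fp : FieldParams

    Returns
    -------
    ndarray or float
        ``q / sqrt(4 pi D (lag + t_off)) * exp(-y² / (4 D (lag + t_off)))``.
    """
    tau = _tau_eff(lag, fp)
    y = np.asarray(y, dtype=float)
    s = 4.0 * fp.D * tau
    out = fp.q / np.sqrt(np.pi * s) * np.exp(-(y * y) / s)
    return out if out.ndim else float(out)


def cross_section_gradient(y, lag, fp: FieldParams):
    """d/dy of :func:`trail_cross_section` (1/µm per µm).

    Odd in ``y``; zero at the trail centre; |gradient| is maximal at
    ``y = sqrt(2 D (lag + t_off))``.
    """
    tau = _tau_eff(lag, fp)
    y = np.asarray(y, dtype=float)
    s = 4.0 * fp.D * tau
    out = -2.0 * y / s * (fp.q / np.sqrt(np.pi * s) * np.exp(-(y * y) / s))
    return out if out.ndim else float(out)


def intensity_profile(x, t, I0, fp: FieldParams):
    """Fluorescence intensity across the trail of a moving point source.

    The droplet is approximated as a point source moving at constant speed
    and emitting fluorescent chemorepellent at a constant rate; on a fixed
    line perpendicular to the trail the intensity is Gaussian with variance
    ``2 D (t + t_off)`` and peak height proportional to
    ``(t + t_off)**(-1/2)``.

    Parameters
    ----------
    x : array_like
        Position along the section line, µm.
    t : array_like
        Time since droplet passage, s (>= 0).
    I0 : float
        Intensity scale, a.u.; ``I0 = 0`` gives an identically zero profile.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since passage must be non-negative")
    tau = t + fp.t_off
    x = np.asarray(x, dtype=float)
    s = 4.0 * fp.D * tau
    out = I0 / np.sqrt(np.pi * s) * np.exp(-(x * x) / s)
    return out if out.ndim else float(out)


@dataclasses.dataclass
class TrailRecord:
    """Time-stamped emission path of one droplet.

    ``times`` must be strictly increasing; positions are (M, dim) in µm.
    """

    droplet_id: int | str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("emission times must be strictly increasing")

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def resample(self, ds_max: float) -> "TrailRecord":
        """Insert samples so consecutive spacing is <= ``ds_max``."""
        if self.times.size < 2:
            return TrailRecord(self.droplet_id, self.times.copy(), self.positions.copy())
        ts = [self.times[:1]]
        ps = [self.positions[:1]]
        for k in range(len(self.times) - 1):
            seg = self.positions[k + 1] - self.positions[k]
            length = float(np.linalg.norm(seg))
            nsub = max(1, int(np.ceil(length / ds_max)))
            frac = np.arange(1, nsub + 1) / nsub
            ts.append(self.times[k] + frac * (self.times[k + 1] - self.times[k]))
            ps.append(self.positions[k] + frac[:, None] * seg)
        return TrailRecord(self.droplet_id, np.concatenate(ts), np.vstack(ps))

    def segments(self, fp: FieldParams):
        """Midpoint-rule quadrature elements: (midpoints, mid-times, weights).

        The trail is first resampled to ``fp.ds_max``; each consecutive pair
        becomes one element of weight ``q * ds`` located at the segment
        midpoint with the mean emission time.
        """
        tr = self.resample(fp.ds_max)
        if tr.times.size < 2:
            return (
                np.empty((0, self.dim)),
                np.empty(0),
                np.empty(0),
            )
        mid = 0.5 * (tr.positions[1:] + tr.positions[:-1])
        tmid = 0.5 * (tr.times[1:] + tr.times[:-1])
        ds = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        return mid, tmid, fp.q * ds


def _min_image(delta: np.ndarray, box: float | None) -> np.ndarray:
    if box is not None:
        delta = delta - box * np.rint(delta / box)
    return delta


def field_superposition(
    r,
    t: float,
    trails: Sequence[TrailRecord],
    fp: FieldParams,
    box: float | None = None,
):
    """Superposed concentration and gradient of a set of trails.

    Each quadrature element contributes the free-space diffusion kernel
    ``w / (4 pi D tau)**(dim/2) * exp(-|r-r'|²/(4 D tau))`` with
    ``tau = t - t' + t_off``.  Elements emitted at or after ``t``, older
    than ``T_mem`` or farther than ``R_max`` are skipped.  Fields of
    individual trails superimpose linearly.

    Returns ``(c, grad_c)``; an empty trail list gives ``(0.0, zeros)``.
    """
    r = np.asarray(r, dtype=float)
    dim = r.shape[-1]
    c = 0.0
    grad = np.zeros(dim)
    for trail in trails:
        mid, tmid, w = trail.segments(fp)
        if mid.size == 0:
            continue
        age = t - tmid
        keep = (age > 0) & (age <= fp.T_mem)
        if not np.any(keep):
            continue
        delta = _min_image(r - mid[keep], box)
        r2 = np.einsum("ij,ij->i", delta, delta)
        within = r2 <= fp.R_max * fp.R_max
        if not np.any(within):
            continue
        delta = delta[within]
        r2 = r2[within]
        denom = 4.0 * fp.D * (age[keep][within] + fp.t_off)
        amp = w[keep][within] / (np.pi * denom) ** (dim / 2.0) * np.exp(-r2 / denom)
        c += float(amp.sum())
        grad += (amp * (-2.0 / denom)) @ delta
    return c, grad


def static_cross_section_field(delta_t: float, fp: FieldParams, axis: int = 1):
    """Field callable for a frozen straight-trail cross-section.

    Returns ``field(r, t) -> (c, grad)`` where the concentration depends
    only on the coordinate ``r[axis]`` (signed distance from the trail laid
    along the other axis) with the Gaussian width frozen at lag ``delta_t``.
    Used for single delayed-collision studies.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")

    def field(r, t):
        y = float(np.asarray(r, dtype=float)[axis])
        c = trail_cross_section(y, delta_t, fp)
        grad = np.zeros(np.asarray(r).shape[-1])
        grad[axis] = cross_section_gradient(y, delta_t, fp)
        return c, grad

    return field
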