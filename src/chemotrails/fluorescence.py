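"""Chemorepellent diffusivity from trail fluorescence cross-sections.

The fluorescent intensity measured along a fixed line perpendicular to a
droplet's trail is Gaussian at every time slice; for a point source moving
at constant speed the variance grows linearly,

    sigma^2(t) = 2 D (t + t_off),

and the peak height decays as (t + t_off)^(-1/2).  The primary estimator
fits a Gaussian (with a constant background) to every slice and regresses
the fitted variances on time: slope/2 gives D and intercept/slope the
finite-source offset t_off.  A joint nonlinear fit of the full space-time
model is available as a cross-check, and the log peak vs log(t + t_off)
slope is reported as a diagnostic (expected -1/2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = ["ProfileSeries", "TrailDiffusivityFit", "fit_profile_series",
           "fit_profile_series_joint"]


@dataclasses.dataclass
class ProfileSeries:
    """Time-resolved intensity profiles across a trail.

    ``intensity`` has shape (n_times, n_positions); times are seconds since
    droplet passage and must be strictly increasing.
    """

    x: np.ndarray
    times: np.ndarray
    intensity: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("profile times must be strictly increasing")
        if self.intensity.shape != (self.times.size, self.x.size):
            raise ValueError("intensity must have shape (n_times, n_positions)")


@dataclasses.dataclass
class TrailDiffusivityFit:
    """Result of the variance-regression diffusivity estimate."""

    D_hat: float
    t_off_hat: float
    ok: bool
    amplitude: np.ndarray
    center: np.ndarray
    variance: np.ndarray
    background: np.ndarray
    var_slope: float
    var_intercept: float
    peak_decay_slope: float
    message: str = ""


def _gauss_bg(x, A, mu, sigma, b):
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + b


def _fit_slice(x, I, saturation_quantile=None):
    mask = np.ones(x.size, dtype=bool)
    if saturation_quantile is not None:
        mask = I <= np.quantile(I, saturation_quantile)
    xs, Is = x[mask], I[mask]
    b0 = float(np.median(np.concatenate([Is[:5], Is[-5:]])))
    A0 = max(float(Is.max() - b0), 1e-12)
    mu0 = float(xs[np.argmax(Is)])
    w = np.clip(Is - b0, 0, None)
    if w.sum() > 0:
        var0 = float(np.sum(w * (xs - mu0) ** 2) / w.sum())
    else:
        var0 = float((xs[-1] - xs[0]) ** 2 / 12)
    sig0 = max(np.sqrt(var0), 1e-3)
    try:
        popt, _ = curve_fit(
            _gauss_bg, xs, Is,
            p0=[A0, mu0, sig0, b0],
            bounds=([0, xs[0], 1e-6, -np.inf], [np.inf, xs[-1], np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return None
    return popt  # A, mu, sigma, b


def fit_profile_series(
    ps: ProfileSeries,
    saturation_quantile: float | None = None,
) -> TrailDiffusivityFit:
    """Per-slice Gaussian fits followed by variance-vs-time regression.

    Requires at least 5 time slices.  Saturated samples above
    ``saturation_quantile`` of each slice can be masked (overexposed
    droplet region).  A non-positive regression slope (no spreading) is a
    flagged failure, not an exception.
    """
    if ps.times.size < 5:
        raise ValueError("need at least 5 time slices")
    K = ps.times.size
    A = np.full(K, np.nan)
    mu = np.full(K, np.nan)
    var = np.full(K, np.nan)
    bg = np.full(K, np.nan)
    for k in range(K):
        popt = _fit_slice(ps.x, ps.intensity[k], saturation_quantile)
        if popt is not None:
            A[k], mu[k], sig, bg[k] = popt
            var[k] = sig * sig
    good = np.isfinite(var) & (var > 0)
    if good.sum() < 3:
        return TrailDiffusivityFit(np.nan, np.nan, False, A, mu, var, bg,
                                   np.nan, np.nan, np.nan,
                                   "too few successful slice fits")
    reg = linregress(ps.times[good], var[good])
    slope, intercept = float(reg.slope), float(reg.intercept)
    if slope <= 0:
        return TrailDiffusivityFit(np.nan, np.nan, False, A, mu, var, bg,
                                   slope, intercept, np.nan,
                                   "variance does not grow with time")
    D_hat = slope / 2.0
    t_off_hat = intercept / slope
    peak = linregress(np.log(ps.times[good] + max(t_off_hat, 0.0)),
                      np.log(np.clip(A[good], 1e-300, None)))
    return TrailDiffusivityFit(D_hat, t_off_hat, True, A, mu, var, bg,
                               slope, intercept, float(peak.slope))


def fit_profile_series_joint(ps: ProfileSeries) -> tuple[float, float]:
    """Joint nonlinear fit of I(x,t) = A0/sqrt(4 pi D (t+t_off)) exp(...) + b.

    Cross-check for the variance-regression estimator; returns
    ``(D_hat, t_off_hat)``.
    """
    T, X = np.meshgrid(ps.times, ps.x, indexing="ij")

    def model(_, A0, D, t_off, b):
        s = 4.0 * D * (T + t_off)
        return (A0 / np.sqrt(np.pi * s) * np.exp(-(X**2) / s)).ravel()

    I = ps.intensity.ravel()
    scale = float(ps.intensity.max()) * np.sqrt(4 * np.pi * 50.0 * (ps.times[0] + 20.0))
    popt, _ = curve_fit(
        model, None, I,
        p0=[scale, 50.0, 20.0, float(np.median(ps.intensity[:, :5]))],
        bounds=([0, 1e-3, 0, -np.inf], [np.inf, 1e4, 1e3, np.inf]),
        maxfev=20000,
    )
    return float(popt[1]), float(popt[2])
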