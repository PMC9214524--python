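"""Characteristic timescales and lengths of trail-mediated interactions."""

from __future__ import annotations

__all__ = ["tau_diffusion", "tau_advection", "persistence_length", "max_cage_lag"]


def tau_diffusion(a_drop: float, D: float) -> float:
    """Trail-spreading timescale a²/D (s): time for the chemorepellent to
    diffuse over one droplet diameter ``a_drop`` (µm) at diffusivity ``D``
    (µm²/s)."""
    if a_drop <= 0 or D <= 0:
        raise ValueError("a_drop and D must be positive")
    return a_drop**2 / D


def tau_advection(a_drop: float, V0: float) -> float:
    """Advective timescale a/V0 (s): time for a droplet to travel its own
    diameter."""
    if a_drop <= 0 or V0 <= 0:
        raise ValueError("a_drop and V0 must be positive")
    return a_drop / V0


def persistence_length(V0: float, D_r: float) -> float:
    """Orientational persistence length V0/D_r (µm)."""
    if V0 <= 0 or D_r <= 0:
        raise ValueError("V0 and D_r must be positive")
    return V0 / D_r


def max_cage_lag(l_cage: float, V0: float) -> float:
    """Longest trail age probed inside a cage of size ``l_cage``: l/V0 (s)."""
    if l_cage <= 0 or V0 <= 0:
        raise ValueError("l_cage and V0 must be positive")
    return l_cage / V0
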