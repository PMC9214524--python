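# chemotrails

Simulation and analysis of **chemorepulsive autochemotaxis** in active
emulsions: self-propelled oil droplets that shed a trail of oil-filled
surfactant micelles, a chemorepellent that reorients and repels other
droplets long after the hydrodynamic wake has decayed.  The package
implements the full computational pipeline of such a study — trail-field
construction, single "delayed collision" analysis, coupling-constant
fitting, collective simulations showing **chemotactic self-caging**, and
the trail-fluorescence diffusivity estimator — with synthetic-data
generators standing in for the experimental inputs.

## Model

Each droplet is a chemically active polar particle (CAPP) with position
**r** and unit orientation **n**:

    dr/dt = V0 n − α ∇c + √(2 D_t) ξ_t
    dn/dt = Ω n × (n × ∇c) + √(2 D_r) n × ξ_r

with swimming speed `V0 ≈ 25 µm/s`, chemotactic force coupling `α > 0`
(direct repulsion from the trail) and alignment coupling `Ω > 0` (the
torque that turns **n** away from the gradient).  The concentration field
`c(r, t)` is a superposition of 2-D diffusion kernels along every
droplet's past path,

    c(r, t) = Σ q ds / (4π D (t − t′ + t_off)) · exp(−|r − r′|² / (4 D (t − t′ + t_off))),

with micelle diffusivity `D = 52.5 µm²/s` and a finite-source offset
`t_off = 20 s` (the droplet is not a point source).  The cross-section of
a straight trail is a Gaussian whose variance grows as `2 D (τ + t_off)`
and whose peak decays as `(τ + t_off)^(−1/2)`.  The field is computed with
unit emission strength, so the couplings used everywhere are the lumped
products `Ω·c0 = 7·10³ µm²/s` and `α·c0 = 3·10⁴ µm³/s` (medians of
single-event fits).

A following droplet meeting a trail of age Δt at incidence angle θ either
**crosses** it or is **reflected**; the critical lag Δt*(θ) (the
*separatrix*) separates the outcomes.  In crowded systems the evolving
trail network transiently arrests droplets — *chemotactic self-caging* —
visible as a plateau in the ensemble mean squared displacement,
`MSD(t) = (1/N) Σᵢ |rᵢ(t) − rᵢ(t₀)|²`.

## Worked example

```python
import numpy as np
import chemotrails as ct

fp, p = ct.FieldParams(), ct.DynamicsParams()

# one delayed collision: 45° incidence, 10 s lag
ev = ct.simulate_event(np.pi / 4, 10.0, p, fp)
print(ev.outcome, round(ev.max_turn_rate, 3), round(ev.speed.min(), 1))
# -> reflection 0.274 24.6

# the crossing/reflection separatrix
sep = ct.separatrix(np.radians([45, 60, 75]), p, fp)
print(np.round(sep.delta_t_star, 1))   # -> [277.2 135.1  46.2]
print(np.round(sep.delta_theta, 3))    # -> [0.499 0.451 0.427]

# recover the micelle diffusivity from synthetic fluorescence profiles
ps = ct.gen_profiles(D=52.5, t_off=20.0, noise_frac=0.05, seed=1)
fit = ct.fit_profile_series(ps)
print(round(fit.D_hat, 1), round(fit.t_off_hat, 1))
# -> 52.6 19.9  (values vary slightly with the noise seed)
```

The event output says that a droplet hitting a 10-s-old trail at 45° is
reflected, turning at up to ~0.27 rad/s while its speed dips from 25 to
~24.6 µm/s before the turning point; the separatrix shows the critical
lag shrinking from ~277 s at 45° to ~46 s at 75° incidence, with the
rotational-noise band δθ = √(2 D_r d_max / (V0 sin θ)) of ~0.4–0.5 rad.
The fluorescence fit recovers the generating diffusivity and source
offset from noisy Gaussian profile series.

A command-line pipeline wraps the same functions:

```bash
chemotrails --seed 1 --outdir out synth profiles
chemotrails --outdir out trail-fit out/profiles.csv
chemotrails --outdir out diagram --theta-grid 45,60,75
chemotrails --seed 1 --outdir out simulate-collective --density 7.4 --duration 300
chemotrails --outdir out msd out/collective_trajectories.csv
```

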