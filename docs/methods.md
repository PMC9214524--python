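# Methods

## Model

The package simulates active droplets as chemically active polar particles
(CAPPs): point particles with a self-propulsion axis **n**, an effective
chemotactic force `−α ∇c`, and an aligning torque `Ω n × (n × ∇c)` that in
2D reduces to the turn rate `θ̇ = −Ω (∇c · n⊥)`.  Both couplings are
positive for a chemorepellent.  A possible third CAPP coupling (a force
projected along the particle axis) is omitted; the two-coupling model
already reproduces the single-event phenomenology.  The model is "dry":
hydrodynamic and chemoadvective interactions are absorbed into the two
couplings, which is justified on timescales longer than the advective time
a/V0 ≈ 2 s.

### Concentration field and normalization

Trails are lines of instantaneous point sources.  Every emitted element of
path length ds contributes the free-space diffusion kernel
`q·ds/(4πD τ̃)^(dim/2) · exp(−|r−r′|²/(4D τ̃))` with effective age
`τ̃ = t − t′ + t_off`.  The additive offset `t_off = 20 s` accounts for the
droplet's finite size: a fresh trail element already has the width of a
point source aged by t_off, which matches the fluorescence observation that
peak intensities follow `(t + 20 s)^(−1/2)`.

The absolute concentration scale is not observable; the package fixes
`q = 1` (unit emission per unit trail length), which gives the 2-D field
units of 1/µm and makes the *lumped* couplings `Ω·c0` (µm²/s) and `α·c0`
(µm³/s) multiply the computed gradient with exact dimensions.  The default
coupling values are the medians of the single-event fits, `Ω·c0 = 7·10³
µm²/s` and `α·c0 = 3·10⁴ µm³/s`.  Because the normalization convention
behind those printed medians is not fully specified, they should be read
as order-of-magnitude calibrations: under `q = 1` they reproduce the
qualitative interaction diagram (reflection at small lag, crossing at
large lag, crossing favoured at high incidence) with turn rates of
0.1–0.7 rad/s and a speed dip of a few percent during reflections.  See
"Known limitations" for the consequence at the collective level.

Quasi-2D treatment: the 50-µm cell height is assumed vertically mixed, so
diffusion is purely in-plane.  The vertical equilibration time h²/D ≈ 45 s
is comparable to the lags of interest; this is a deliberate simplification.

### Parameters (defaults)

| parameter | default | units | origin |
|---|---|---|---|
| V0 | 25 | µm/s | measured swimming speed |
| Ω·c0 | 7·10³ | µm²/s | median of single-event fits |
| α·c0 | 3·10⁴ | µm³/s | median of single-event fits |
| D (micelle) | 52.5 | µm²/s | trail-fluorescence fit |
| t_off | 20 | s | finite-source offset |
| D_t | 0 | µm²/s | negligible experimentally |
| D_r | 0 (0.01 bound) | rad²/s | ballistic dilute trajectories |
| dt | 0.02 | s | V0·dt = 0.5 µm ≪ 65 µm kernel width |
| d_max | 220 | µm | interaction-band threshold |
| T_mem | 600 | s | trail memory cutoff |
| R_max | 5·√(4·D·T_mem) | µm | kernel spatial cutoff (<1e-6 of a fresh peak) |
| ds_max | 25 | µm | trail quadrature spacing (half a droplet diameter) |

## Numerical choices

* **Integrator**: Euler–Maruyama with post-step renormalisation of **n**;
  rotational noise acts on the polar angle in 2D (3D: tangential Gaussian
  kick), so |n| = 1 holds by construction.  Torque is applied before
  noise; the ordering is O(dt)-irrelevant.
* **Trail quadrature**: midpoint rule on segments resampled to ≤ 25 µm;
  the narrowest kernel (√(4·D·t_off) ≈ 65 µm) is well resolved.
* **Single events** use a static 1-D Gaussian cross-section frozen at the
  encounter lag (an "aging" mode with real-time growth is available for
  sensitivity checks).  Exactly perpendicular incidence is a measure-zero
  unstable case with zero torque (∇c ∥ n); the separatrix is therefore
  evaluated on grids with θ < 90°.
* **Separatrix**: bisection on the lag in [1, 600] s to 0.5 s; outcomes
  outside the bracket are reported absent, never extrapolated.  The noise
  band is δθ = √(2·D_r·T) with approach time T = d_max/(V0 sin θ); the
  square root makes the expression dimensionally a rotational-diffusion
  standard deviation.
* **Event series**: speed and turn rate are centred differences of the
  track with a 5-sample moving average on the velocity components
  (edge-safe: constant-velocity tracks stay exactly constant).
* **Coupling fits**: position-only least squares at the observed sample
  times; derivative-free simplex on log10 couplings with box bounds
  [10, 10⁶] µm²/s × [10², 10⁷] µm³/s, ≥ 5 log-spaced restarts (the forward
  model is non-smooth at the crossing/reflection boundary).  The initial
  heading is co-fitted as a nuisance parameter (±0.3 rad) because a heading
  estimated from a handful of noisy samples otherwise dominates the
  residuals.  Events whose loss is flat across the coupling box are
  flagged unidentifiable.  Dataset estimates are per-event medians.
* **Collective runs**: periodic square box (default 2×2 mm; must exceed
  four kernel widths at T_mem), minimum-image convention, droplets are
  points (volume fraction ~10⁻² makes contacts rare).  Trail elements are
  deposited every 0.5 s (12.5 µm at V0).  A droplet ignores its own trail
  younger than τ_self = 2a/V0 = 4 s — the discretised fresh wake would act
  as a spurious thrust — but interacts with its older trail, which is what
  eventually pushes it out of a cage.  The field and gradient are
  re-evaluated every 5 integrator steps (0.1 s; droplets move 2.5 µm
  between updates, far below the kernel width).
* **MSD**: ensemble average from each droplet's position at t₀, no
  time-origin averaging (the chemical landscape ages, so the process is
  non-stationary).  Curves are thinned to ~20 log-spaced lags per decade.
* **Caging detection**: local exponent = centred slope of log MSD vs log
  lag over a 5-point window; caging onset is the first lag with exponent
  < 0.5, escape the next lag back above 0.5, plateau height the median MSD
  in between.  0.5 separates a plateau (≈0) from diffusion (≈1).

## Synthetic data

The generators emulate the study's inputs with known ground truth:

* **Profile series** — the moving-point-source Gaussian intensity model on
  a ±300 µm section line, 20 slices at 5–100 s, with multiplicative
  Gaussian noise (default 5%) and a small constant floor.
* **Event pairs** — a leader laying a straight trail and a follower
  simulated in it; the leader's timeline is fixed so it passes the
  follower's actual meeting point exactly Δt earlier, so the nominal lag
  is the physically measured one.  Observation noise (default σ = 1 µm,
  the sub-pixel tracking scale) is added to saved positions only, never to
  the dynamics.
* **Collective sets** — wrappers around the collective simulator at
  prescribed number densities.

Every generator attaches a ground-truth record and is bit-reproducible
from (parameters, seed).  What the generators do *not* emulate: trail
widening in the leader's near wake, trail curvature, droplet
polydispersity, hydrodynamic near-field effects, and the pre-existing
chemical history of a real sample.  Passing round-trip tests therefore
demonstrates the self-consistency of the pipeline, not the absence of
those real-data effects.

## Problem sizes

The test suite and the acceptance script run scaled study conditions
chosen as realistic working sizes: the fluorescence recovery uses 100
seeded repeats of the 20-slice series; the collective acceptance run uses
60 droplets at n = 7.4 mm⁻² for 300 s at dt = 0.02 s (a ~2.85 mm periodic
box); property checks use 15–30 droplets in a 2-mm box.  Monte-Carlo
checks (orientational decorrelation, effective diffusivity, coupling
recovery) use 8–2000 replicates depending on the estimator variance.

## Known limitations

* The collective caging *scale* is normalization-sensitive.  With q = 1
  and the median couplings, a virgin-field periodic simulation at
  n = 7.4 mm⁻² develops subdiffusive caging episodes (local MSD exponent
  dropping to ~0.5–0.9) but arrests at MSD levels of ~10⁶ µm² rather than
  the ~10⁵ µm² seen experimentally; equivalently, droplets cross a few
  cage walls before confinement.  Strengthening the field scale deepens
  caging but simultaneously pushes the separatrix beyond the observed lag
  range (reflection-only interaction diagrams), so no single scale
  reproduces both observables quantitatively.  The package keeps the
  separatrix-consistent scale and reports the collective MSD level as
  computed.
* 3D collective mode reuses the 2D-calibrated couplings with a 3D kernel
  and is exploratory.
* No hydrodynamic interactions, finite droplet size, wall rectification,
  or advection–diffusion around the droplet interface.
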