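# slbkin

Quantitative single-molecule kinetics of two-mode receptor–membrane binding,
built around the system in which it was first dissected: the bacterial SRP
receptor FtsY on supported lipid bilayers (SLBs). FtsY contacts the membrane
in two kinetically distinct modes — a *Dynamic* mode that dissociates fast
(k₋₁ ≈ 14 s⁻¹) and a *Stable* mode that dissociates ~200-fold more slowly
(k₋₂ ≈ 0.081 s⁻¹) — and assembly with SRP switches the conformational
equilibrium from overwhelmingly Dynamic to overwhelmingly Stable. `slbkin`
implements the full analysis chain for this kind of data, exercised on
synthetic single-molecule TIRF trajectories with known ground truth:

* **`synthetic_trajectories`** — generates smTIRF-like movies from a
  four-state kinetic model (cytosol/membrane × Dynamic/Stable): Poisson
  membrane arrivals with per-mode intensity f·k·[P]·A, competing
  exponential dissociation/photobleaching, frame-quantized dwells, 2D
  Brownian motion while bound, movie-end censoring, and the quality-control
  filters used on real tracks (zero-mobility and unstable-intensity
  rejection).
* **`survival_stats`** — the time-averaged survival probability
  P_survival(j) = ⟨N(i,j)/N(i,1)⟩ᵢ, where N(i,j) counts trajectories present
  at frame i that last another j frames; its constrained bi-exponential fit
  P₁e^(−k₋₁t) + P₂e^(−k₋₂t) with P₁+P₂ = 1; lifetime-cutoff (τ = 0.25 s)
  mode classification; apparent association rates from cumulative arrival
  counts; and a photobleaching control fit.
* **`two_mode_solver`** — the coupled thermodynamic model: from apparent
  association rates of two conditions (free receptor and SRP-bound complex)
  and the dissociation constants, solve 1 = k₁,app/(K₁k₋₁) + k₂,app/(K₂k₋₂)
  (one equation per condition) for K₁, K₂, k₁, k₂; then K_cyto = f₂/f₁,
  K_mem = P₂/P₁, with fₓ = (Pₓ/Kₓ) renormalized. The construction closes the
  thermodynamic cycle K_cyto·K₂ = K_mem·K₁ identically.
* **`route_kinetics`** — the five-state targeting model
  {early, closed} × {cytosol, membrane} + targeted, integrated as
  dP/dt = R·P by matrix exponential, comparing the route through the Dynamic
  mode (bind first, rearrange on the membrane 25× faster) against the
  Stable-only route (rearrange in the cytosol, then bind slowly).
* **`ensemble_fits`** — the surrounding bulk assays: hyperbolic saturation
  fits (GTPase turnover kcat/Km, translocation Vmax/K₁/₂) and
  single-exponential stopped-flow rearrangement time courses.
* **`pipeline` / `cli`** — one-command orchestration of
  simulate → survival/classify/associate → solve → routes with deterministic
  seeding (`slbkin pipeline --config cfg.yaml --out outdir`).

## Worked example

Simulate twenty 1000-frame movies (20 ms/frame) of the free receptor at
10 µM over a 6 µm² observation area, estimate the survival curve, and fit
the two-mode dissociation model:

```python
import dataclasses
import slbkin as sk

truth = dataclasses.replace(sk.FREE_RECEPTOR_TRUTH, conc=10.0)
movies = sk.simulate_movies(truth, sk.ImagingConfig(seed=7, n_frames=1000), 20)
curve = sk.compute_survival(movies)
fit = sk.fit_biexponential(curve)
pops = sk.classify_modes(movies, cutoff=0.25)
print(f"events: {sum(len(m) for m in movies)}")
print(f"k_off1 = {fit.fast_rate:.2f} 1/s   k_off2 = {fit.slow_rate:.3f} 1/s")
print(f"amplitudes: P1 = {fit.P1:.3f}, P2 = {fit.P2:.3f}")
print(f"cutoff populations: Dynamic = {pops.P1:.3f}, Stable = {pops.P2:.3f}")
```

prints

```
events: 63154
k_off1 = 14.56 1/s   k_off2 = 0.097 1/s
amplitudes: P1 = 0.180, P2 = 0.820
cutoff populations: Dynamic = 0.892, Stable = 0.108
```

The fast dissociation rate comes back within 4% of the generator truth
(14 s⁻¹). The two population readouts deliberately measure different things:
the fit amplitudes are occupancy-weighted (a long-lived molecule is present
in many counting windows, so the Stable mode dominates the curve even though
only 8% of *arrivals* are Stable), while the cutoff classification counts
trajectories and therefore tracks the arrival fractions (89% Dynamic here,
truth 92%). The slow rate sits against the 20 s observation window and is
flagged accordingly (`fit.k_off2_near_window_limit`) — it is a lower bound
on the Stable mode's kinetic stability, not a precise estimate; recovering
it well requires longer movies (see `docs/methods.md`).

The thermodynamic and route-level consequences of the measured rates:

```python
ratio = sk.membrane_mode_bias(1.2, 0.115, 14.0, 0.081)
print(f"K_mem/K_cyto = {ratio:.1f}")

cmp = sk.compare_routes(sk.RouteRates())
print(f"targeted at 5 s: dynamic = {cmp.targeted_at_5s['dynamic']:.3f}, "
      f"stable-only = {cmp.targeted_at_5s['stable_only']:.3f}")
print(f"half-completion ratio (stable-only / dynamic) = {cmp.completion_time_ratios[0.5]:.2f}")
```

```
K_mem/K_cyto = 16.6
targeted at 5 s: dynamic = 0.795, stable-only = 0.176
half-completion ratio (stable-only / dynamic) = 3.74
```

So the Dynamic→Stable transition is ~17-fold more favorable on the membrane
than in the cytosol, and a targeting route that exploits the Dynamic mode
reaches the membrane-bound, activated state several-fold faster than one
restricted to the Stable mode — which stays below 50% completion at the
5 s mark relevant for co-translational targeting.

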