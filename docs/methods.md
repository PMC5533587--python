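# Methods

## The kinetic model

A receptor in solution samples two conformations that bind a supported
lipid bilayer in distinct modes: conformation 1 binds in the *Dynamic* mode
(association rate constant k₁, dissociation k₋₁), conformation 2 in the
*Stable* mode (k₂, k₋₂ with k₋₂ ≤ k₋₁). With solution fractions f₁ + f₂ = 1
and total concentration [P] over an observed membrane area A, membrane
arrivals in mode x form a Poisson process with intensity

    λₓ = fₓ · kₓ · [P] · A        (events/s).

Each binding event draws an exponential dwell with rate k₋ₓ + k_bleach
(photobleaching competes with dissociation and truncates the track), the
molecule diffuses on the membrane (2D Brownian steps, variance 2·D·dt per
axis per frame), and the movie ends at frame m, censoring whatever is still
bound. The solution phase is treated as an undepleted, well-mixed reservoir
— membrane-bound material is a negligible fraction of the total — so
arrivals are drawn directly from the λₓ and no solution-side exchange is
simulated per molecule. Membrane-bound molecules do not interconvert
between modes by default, matching the assumption of the two-component
dwell analysis; `ImagingConfig(mode_switching=True)` enables
detailed-balance-consistent interconversion for stress-testing estimators
against that assumption.

### Frame quantization

A camera integrating over frames of length dt detects a molecule in every
frame it overlaps. A dwell of duration τ beginning at its arrival frame is
recorded as ⌈τ/dt⌉ consecutive bound frames, and the reported lifetime is
n_frames_bound × dt. Quantization matters: it is what makes the survival
estimator's discrete lag axis exact (below), and it adds about half a frame
(~10 ms at 20 ms/frame) to naive mean-lifetime estimates.

## Survival probability estimation

Define N(i, j) as the number of trajectories present at frame i that last
through frame i + j − 1 (so N(i, 1) is the occupancy of frame i). The
survival probability at lag j is the average of N(i, j)/N(i, 1) over all
window starts i = 1..m−j+1 with N(i, 1) > 0; replicate movies (independent
observation areas) are pooled by summing their window counts. No censoring
or photobleaching correction is applied — censored tracks contribute to
every window they span — and the generator's truth labels are what allow
the tests to quantify the resulting biases instead.

Two properties of this estimator drive the design decisions downstream:

1. **The lag axis maps to t = (j − 1)·dt.** Lag j = 1 means "present at
   frame i", i.e. survival for zero additional time, so P_survival(t=0) = 1
   exactly. With this mapping, and because exponential dwells are
   memoryless, the expectation of the estimator at each lag is *exactly*
   Σₓ wₓ·e^(−k₋ₓ·(j−1)·dt): the fitted rates carry no discretization bias,
   and the fitted amplitudes sum to one, which is what makes the
   constrained fit below self-consistent. (Mapping lag j to j·dt instead
   would inflate each amplitude by e^(k₋ₓ·dt) — a 30% distortion of the
   fast component at k₋₁·dt = 0.28 — and push an O(k·dt) bias into the
   fast rate through the amplitude constraint.)
2. **Amplitudes are occupancy-weighted.** Sampling "molecules present at
   frame i" is length-biased: mode x contributes weight
   wₓ ∝ aₓ/(1 − e^(−k₋ₓ·dt)) ≈ aₓ/(k₋ₓ·dt), where aₓ is its arrival
   fraction. A mode with 8% of arrivals but 170-fold longer dwells
   dominates the curve. The lifetime-cutoff classification (below) counts
   trajectories and therefore estimates arrival fractions; the two
   population readouts are reported side by side and agree only when the
   dwell contrast is mild. Both are exposed because both are used in
   practice.

## Bi-exponential fitting

P_survival(t) is fit by nonlinear least squares (lmfit/MINPACK) to
P₁e^(−k₋₁t) + P₂e^(−k₋₂t) with the constraint P₁ + P₂ = 1 built into the
parametrization (P_survival(0) = 1 forces it), multi-started from a fixed
log-spaced grid of rate pairs, with the slow/fast ordering enforced by a
post-hoc swap. The fit is unweighted by default; weighting by √n_windows is
available but off.

**Lag range.** Only lags whose window count is at least 75% of the maximum
are fit by default (`min_window_support=0.75`, i.e. roughly the first
quarter of the movie). The longest lags are estimated from a shrinking,
strongly correlated set of early window starts, over which the
occupancy weights of the two modes drift systematically (the movie starts
empty and the Stable pool equilibrates on the 1/k₋₂ timescale, comparable
to the movie length); feeding those lags into an unweighted fit corrupted
the fast rate by tens of percent in simulation. Within the retained lag
range the estimator is an exact two-exponential in expectation, and rate
recovery on synthetic data is accurate to a few percent.
`min_window_support=0` restores full-curve fitting.

**Identifiability.** Two exponential components are resolved only when both
amplitudes are appreciable and the rates are separated. When the best fit
has a component amplitude below 1%, a rate-separation factor under 3, or a
minor (<10%) component whose rate falls outside the observable band
(slower than 1/t_max or faster than the frame rate), the fit is flagged
`effectively_single`, refit as a single exponential, and reported with
P₁ = 1 and both rate accessors (`fast_rate`, `slow_rate`) returning the one
resolved rate. This situation is not hypothetical: under the SRP-complex
condition the fast mode's occupancy-weighted amplitude is ~0.06%, so the
survival curve is single-exponential for all practical purposes and only
the slow rate is measurable from it.

**Observation-window limit.** A fitted slow rate within a factor of 3 of
1/(movie duration) is flagged (`k_off2_near_window_limit`): it is a lower
bound on the Stable mode's kinetic stability rather than a converged
estimate. Recovering k₋₂ ≈ 0.081 s⁻¹ accurately requires extending the
movie to ~100 s (5000 frames), which is what the long-window study
condition does.

## Mode classification and association kinetics

Trajectories with lifetime strictly greater than τ = 0.25 s are classified
Stable, the rest Dynamic (a tie at exactly the cutoff counts as Dynamic;
at 20 ms/frame the cutoff is not reachable by a lifetime tie in practice).
With dwell constants separated ~170-fold the misclassification rate is a
few percent in each direction (e^(−14·0.25) ≈ 3% of Dynamic dwells outlast
the cutoff; ~2% of Stable dwells do not reach it), so the classified
fractions track the generator's arrival fractions to within ~3 points.

Apparent association rate constants are the slopes of cumulative
new-trajectory counts versus time, split by cutoff class, regressed by
least squares through the origin (the count starts at zero by
construction) over the full movie, normalized by total concentration.
They are *apparent* because they fold in the unknown solution fraction of
each conformation — which is exactly what the two-mode solver inverts.
Classes with fewer than 10 events carry a wide-error flag. The
misclassification leakage (3% of a 10-fold larger Dynamic arrival flux is
not small relative to an 8% Stable flux) is the dominant error in the
minor class's apparent rate; it propagates into the solved equilibria in
the end-to-end pipeline and is the main reason recovered fold-changes are
compressed relative to truth at default problem sizes.

## The two-mode thermodynamic solver

With Kₓ = kₓ/k₋ₓ and mass conservation fₓ summing to one in each
condition, each measured condition (free receptor; SRP-bound complex)
gives one linear relation 1 = k₁,app/(K₁k₋₁) + k₂,app/(K₂k₋₂). The two
conditions form a 2×2 linear system in x = 1/(K₁k₋₁), y = 1/(K₂k₋₂),
solvable when the apparent-rate vectors are not proportional; the solver
reports the system's condition number and refuses to report above 10⁶, and
rejects non-positive solutions as model-inconsistent data. Solution
fractions follow as fₓ = (Pₓ/Kₓ)/Σ(P/K) (renormalization enforces mass
conservation on top of the raw relation), and the conformational
equilibria as K_cyto = f₂/f₁, K_mem = P₂/P₁. The thermodynamic cycle
K_cyto·K₂ = K_mem·K₁ closes identically by construction; the residual is
reported as a numerical check, and the SRP-induced shift is identical
measured in solution or on the membrane for the same reason.

Unit convention: all Kₓ are dimensionless ratios of apparent association
to dissociation rates at the reference condition of the measurements
(1 µM protein, 6 µm² observation area). Only ratios of K's enter the
reported quantities (fold changes, K_mem/K_cyto), so the convention
cancels where it matters; absolute K's should be read only relative to
that reference state.

## The five-state targeting-route model

States: {early, closed} × {cytosol, membrane} plus an absorbing targeted
state. The Stable-only route rearranges early→closed in the cytosol
(k_switch,cyto, measured 0.3–0.6 s⁻¹; default 0.45, the midpoint) and then
binds the membrane in the Stable mode (k*₂ = 0.115 s⁻¹ apparent at the
reference condition, k₋₂ = 0.081 s⁻¹). The Dynamic route binds first in
the Dynamic mode (k*₁ = 1.2 s⁻¹, k₋₁ = 14 s⁻¹) and rearranges on the
membrane, 25-fold faster than in solution. Both finish with a downstream
sink at 0.7 s⁻¹ from the membrane-bound closed state. Rearrangement steps
are irreversible — the rearrangement is strongly favorable and no reverse
rates are measured — and that assumption is recorded here rather than
hidden. The apparent association constants are used directly as
per-second rates at the reference condition (their printed unit
annotation does not resolve dimensionally; the reference-state convention
above absorbs it).

Populations evolve as dP/dt = R·P with R the generator matrix (columns sum
to zero; targeted is absorbing). On the default uniform grid (0–20 s,
10 ms steps) the step propagator e^(R·Δt) is computed once and applied
recursively — exact for a time-homogeneous linear system — and verified in
the tests against a 20 000-walker Gillespie simulation and, for the
irreversible chain, against the closed-form convolution of exponentials.

No single metric defines how much "faster" one route is, so the comparison
report exposes the targeted fraction at 5 s, the 25/50/75% completion
times, and their ratios, plus a pointwise dominance check of the Dynamic
route over the Stable-only route. One caveat discovered in testing and
worth keeping in mind: on the *combined* network, increasing the cytosolic
rearrangement rate can *decrease* early targeting, because it diverts flux
from the fast membrane-first branch onto the slow cytosol-first branch.
Forward-rate monotonicity holds within each route, not across the union.

## Ensemble assay fits

Saturation data (GTPase turnover vs receptor concentration, Eq-form
v = kcat·c/(Km + c); translocation efficiency, v = Vmax·c/(K½ + c)) are fit
by unweighted nonlinear least squares with A₀ = max response and K₀ at the
half-max concentration. Data confined to the linear regime identify only
A/K; such fits return `wide_error=True` rather than pretending both
parameters are measured. Stopped-flow rearrangement time courses are fit
to single exponentials (rising or decaying, autodetected from the trend),
with a flag for clearly non-monotone traces; no baseline correction is
applied before fitting.

## Default study conditions of the generator

The generator's defaults are the study conditions, fixed once:

| quantity | value | basis |
|---|---|---|
| k₋₁, k₋₂ | 14, 0.081 s⁻¹ | measured dwell constants of the two modes |
| k₁/k₂ | 10 | measured association-rate contrast |
| arrival fractions (free) | 0.92 / 0.08 | >90% of free-receptor events are Dynamic |
| arrival fractions (complex) | 0.08 / 0.92 | mirror condition, Stable-dominated |
| dt, m | 20 ms, 1000 frames | imaging conditions (100 s movies for the slow-rate condition) |
| area | 6 µm² | observation area |
| bleach rate | 0.005 s⁻¹ | slow relative to k₋₂ (16-fold), as a control must show |
| D | 1.0 µm²/s | typical lipid-anchored protein; affects QC only |
| k₁ absolute scale | 4.5 µM⁻¹µm⁻²s⁻¹ | ~315 arrivals per 20 s movie at 1 µM/6 µm² |

Given k₁/k₂ = 10, the arrival fractions fix the solution fractions at
f = (23/43, 20/43) for the free receptor and (1/116, 115/116) for the
complex, which places the conformational-equilibrium shift at 132-fold and
K₂/K₁ (= K_mem/K_cyto) at 17.3 — consistent with the ~130-fold and
≥14-fold figures the rate arithmetic gives directly. Replicate movies are
spawned from one seed via independent child RNG streams; every stochastic
stage is reproducible from the single top-level seed.

Problem sizes used by the acceptance script and the heavier tests: the
fast-rate condition pools 20 movies of 1000 frames at 10 µM (~60 000
events); the slow-rate condition pools 10 movies of 5000 frames at 2 µM
(~5 800 events). Both recover their target rate well inside the stated
bands across seeds (fast ≤4%, slow ≤9% observed over 10 seeds, the slow
figure including the deliberate ~6% photobleaching contribution, since the
estimator applies no bleach correction).

## What the synthetic data does and does not emulate

Emulated: Poisson arrival statistics with conformation-resolved
intensities, competing exponential dissociation and photobleaching,
frame quantization, movie-end censoring, membrane diffusion, intensity
noise, immobile-artifact and noisy-track QC, movie-to-movie pooling.

Not emulated: spot detection and particle linking (tracks are emitted
directly, so linking errors, blinking-induced track splits and
localization noise are absent); TIRF excitation-depth and field
inhomogeneity; molecule-to-molecule brightness variation; membrane
crowding or binding-site depletion; solution-side conformational exchange
during a binding event. Passing tests therefore demonstrate correctness of
the *analysis chain* under the stated stochastic model, not robustness to
tracking artifacts in real movies — the QC filters are faithful in form
but exercised here only against injected caricatures of the artifacts they
remove.

## Numerical choices

* Survival estimator: exact integer window counting via cumulative
  histograms, O(m²) over lags with incremental active-set maintenance;
  verified against brute-force window enumeration on 200 random instances.
* Bi-exponential fit: ≤16 multi-starts from a log-spaced rate grid between
  1/(3·t_max) and 1/t_min; MINPACK least squares; best residual wins.
* Two-mode solver: direct 2×2 solve; condition-number ceiling 10⁶.
* Route integration: `scipy.linalg.expm` of the step propagator on uniform
  grids (per-point exponentials otherwise); conservation holds to 1e-9.
* Ties and degeneracies: lifetime exactly at the cutoff → Dynamic;
  zero-mobility test skipped for single-frame tracks (undefined
  displacement, passed through flagged); zero total arrival intensity →
  empty set with a warning flag rather than an exception.

## Known limitations

* The survival amplitudes and the cutoff populations estimate different
  weightings (occupancy vs arrival) and genuinely disagree when the dwell
  contrast is large; consumers must choose the readout that matches their
  question. The solver accepts whichever populations the caller supplies.
* k₋₂ from a 20 s movie is a window-limited lower-bound estimate and is
  flagged as such, and the recovered slow rate always contains the
  (uncorrected) photobleaching rate additively.
* Cutoff misclassification leaks a few percent of the majority class's
  arrival flux into the minority class's apparent association rate, which
  compresses recovered fold-changes at realistic event counts.
* The route model inherits the irreversible-rearrangement assumption and
  the reference-state unit convention; its absolute completion times are
  only as meaningful as the apparent rates fed into it.
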