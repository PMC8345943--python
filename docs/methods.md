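# Methods

## The mechanical model

A double-stranded DNA molecule of n base pairs is represented as two chains
of rotating pendulums.  Pendulum i of chain j is the nitrogenous base at
position i, rotating about the sugar–phosphate backbone by an angle φⱼᵢ(t)
(counterclockwise, unwrapped — angles accumulate and are never reduced
mod 2π, because the chain-mean observable and the trajectory plots require
the accumulated rotation).  Chain 1 carries the input sequence, chain 2 its
base-wise Watson–Crick complement; at rest φ₁ᵢ = 0 and φ₂ᵢ = π.

Newton's equation for each pendulum balances four torques:

* **backbone torsion** — Kⱼᵢ[φⱼ,ᵢ₋₁ − 2φⱼᵢ + φⱼ,ᵢ₊₁] for interior sites;
  the first and last base see only their single neighbour (free ends), a
  single pair has no torsional term at all;
* **hydrogen-bond elasticity** of the pair, built from an on-site term
  ∝ k₁₂ᵢRᵢ(R₁ᵢ+R₂ᵢ)·sin φ and a cross term ∝ k₁₂ᵢR₁ᵢR₂ᵢ·sin(φ₁ᵢ−φ₂ᵢ);
* **viscous dissipation** −βⱼᵢ·dφⱼᵢ/dt from the surrounding liquid, with β
  taken from each pendulum's own base type on both chains;
* an **external drive** F₀·cos ωt, applied with identical amplitude and
  phase to every pendulum of both chains (ω = 0 gives a constant torque
  switched on at t = 0).

Open states are outside the model's scope: the elastic pair coupling never
breaks, so no hydrogen-bond rupture or bubble formation can occur.

### The two chain-2 sign conventions

The chain-1 pair torque is
−k₁₂R₁(R₁+R₂)·sin φ₁ − k₁₂R₁R₂·sin(φ₁−φ₂).  For chain 2 the package ships
two variants, selected at system construction:

* `as_printed` (default): +k₁₂R₁(R₁+R₂)·sin φ₂ − k₁₂R₁R₂·sin(φ₁−φ₂).
  This sign structure makes the rest state (0, π) of a homoduplex linearly
  stable, but it is *not* the gradient of any potential — the model is
  non-conservative even with β = 0.  A consequence worth knowing:
  sufficiently heterogeneous sequences make the rest state linearly
  *unstable* (complex Jacobian eigenvalues with positive real part; a
  random 100-mer reaches growth rates ~10¹¹ s⁻¹, and even some trimers
  such as GTC are unstable).  Any drive then seeds large self-sustained
  oscillations that saturate nonlinearly — this is precisely the regime in
  which the molecule oscillates at its own characteristic frequency rather
  than at the drive frequency.
* `potential_consistent`: −k₁₂R₂(R₁+R₂)·sin φ₂ + k₁₂R₁R₂·sin(φ₁−φ₂), the
  negative gradient of the pair energy
  k₁₂[R₁(R₁+R₂)(1−cos φ₁) + R₂(R₁+R₂)(1−cos φ₂) + R₁R₂(1−cos(φ₁−φ₂))].
  With β = 0 and F₀ = 0 the dynamics conserve the total energy exactly,
  which is what makes quantitative integrator validation possible.  The
  price: (0, π) sits at a maximum of the on-site chain-2 term, so the rest
  state is a saddle and chain-2 pendulums roll toward the potential minimum
  once perturbed.

Boundary equations are in both variants the one-neighbour specialization
of the interior equations — the minimal reading that makes the six printed
equations mutually consistent.

`total_energy` is restricted to homopolymer sequences under
`potential_consistent`: with site-varying K the discrete torsional force
Kᵢ[φᵢ₋₁−2φᵢ+φᵢ₊₁] is not the gradient of a symmetric spring energy, and
the printed chain-2 torque derives from no potential, so an "energy" in
those cases would not be conserved by the exact dynamics either.

### Exact equilibrium arithmetic

Chain-2 pair torques are evaluated through ψ₂ = φ₂ − π using the exact
trigonometric identities sin φ₂ = −sin ψ₂ and sin(φ₁−φ₂) = −sin(φ₁−ψ₂).
At the equilibrium state this yields sin(0) = 0 *exactly* in floating
point (whereas sin(π) ≈ 1.2·10⁻¹⁶), so the right-hand side vanishes
identically and the equilibrium is a bit-exact fixed point of the
integrator.  Without this, rounding noise at the saddle of the
conservative variant would amplify at ~10¹² s⁻¹ and overflow within a
nanosecond of simulated time.

## Parameters

Defaults (SI, converted once from the published scaled table):

| base | I (kg·m²) | R (m) | K (J) | β (J·s) |
|------|-----------|-------|-------|---------|
| A | 7.61e-44 | 5.80e-10 | 2.35e-18 | 4.25e-34 |
| T | 4.86e-44 | 4.80e-10 | 1.61e-18 | 2.91e-34 |
| G | 8.22e-44 | 5.70e-10 | 2.27e-18 | 4.10e-34 |
| C | 4.11e-44 | 4.70e-10 | 1.54e-18 | 2.79e-34 |

Pair stiffness k₁₂: 6.20e-2 N/m for A·T, 9.60e-2 N/m for G·C (a property
of the pair, identical from either chain).  β = 0 is allowed as the
conservative limit.  Drive defaults: F₀ = 0.5·10⁻²² J; the sweep ladder is
ω ∈ {10¹¹, 5·10¹⁰, 10¹⁰, 5·10⁹, 10⁹, 10⁸, 0} s⁻¹.  Custom tables load
from YAML (per-base I, R, K, beta; per-pair k12; SI units).

## Integration

The Cauchy problem (4n first-order equations, equilibrium initial data) is
solved with classical fixed-step RK4.  The default dt = 10⁻¹⁴ s resolves
the stiffest linearized mode of the default table — the zone-edge
torsional oscillation at √(4K/I) ≈ 1.1·10¹³ rad/s — with ω·dt ≈ 0.11,
comfortably inside RK4's stability region; empirical convergence order is
4.0–4.2 against an adaptive DOP853 reference at rtol 10⁻¹².  At this step
the recorded *angle* trajectories of small stable systems agree with the
reference to ~10⁻⁹ relative sup-norm over 1 ns; velocity components carry
~10⁻⁴ relative truncation from the zone-edge modes (reducing that to 10⁻⁶
would need dt ≈ 1.5·10⁻¹⁵ s, a 7× cost increase that no shipped observable
requires, since all observables are angle-based).  Energy of the
conservative variant drifts by ~10⁻⁹ relative over 10⁵ steps.

`verify_step_size` automates the accuracy check behind the default:
it halves dt until the post-cutoff chain-mean amplitude changes by less
than 0.1% (on chaotic systems only this aggregate is compared, since
individual trajectories diverge under refinement).

Recording keeps the chain-mean series always, per-site states optionally;
the default stride caps a run at 10⁵ snapshots.  Integration is
deterministic — no randomness exists anywhere in the solver — and a
non-finite state aborts with the step index, time and max |φ|.

Two execution paths produce the same trajectories: a pure-numpy stepper
and a numba-compiled kernel (default when numba is importable; ~70 s for a
980-pair, 5·10⁵-step run on one core).  The adaptive DOP853 integrator is
a validation oracle only, never a production path.

## Observables

* **Mean angular deviation** φ̄(t) = (1/n)Σᵢφᵢ(t), the unweighted site
  mean of a chain — the primary observable.  (The unweighted mean is the
  only average expressible from the model state alone and matches the
  one-curve-per-run presentation of trajectory figures.)
* **Transient cutoff**: summaries exclude t < 0.5 ns by default; in that
  window runs at different drive frequencies are indistinguishable.
* **Amplitude**: half the peak-to-trough range of the mean-subtracted
  post-cutoff segment.  The signals are non-sinusoidal and non-stationary,
  so a range-based estimate matches what the trajectory plots show; √2·RMS
  and max-|deviation| estimators are available, and the substitution
  report tabulates all three so ratio claims can be checked for
  sensitivity to the estimator choice.
* **Dominant frequency**: maximal peak of the Hann-windowed periodogram of
  the detrended post-cutoff segment.  Reportable bins must complete at
  least two full cycles over the segment (bins 0 and 1 are excluded — one
  cycle is indistinguishable from a trend); the resolution is
  ±1/(segment duration).  Frequencies are ordinary frequencies (cycles/s);
  drive frequencies compare via f = ω/2π.
* **Time-resolved frequency**: the same estimator on sliding windows; a
  descriptive diagnostic only — no quantitative claims attach to it.

## The synthetic-sequence generator

`random_sequence(n, gc_fraction, seed)` draws i.i.d. bases with
P(G) = P(C) = gc/2, P(A) = P(T) = (1−gc)/2.  The gene-scale experiments
use n = 980 and gc = 0.5, emulating a heterogeneous gene-length sequence.
What it does *not* emulate: codon structure, repeats, local GC skew, or
the actual base order of any real gene.  Amplitude ratios and variant
orderings depend on the exact base order of the background sequence, so
results on the synthetic stand-in validate the machinery and the
qualitative physics; reproducing the numbers of a particular real gene
(e.g. interferon alpha 17) requires supplying that gene's FASTA.

## Experiment scales

Tests run at desk scale (n ≈ 20–120, t_end = 1–5 ns, a few minutes in
total).  The acceptance script runs the sweep and substitution batteries
at gene scale (n = 980, t_end = 5 ns, dt = 10⁻¹⁴ s) — the package's chosen
study conditions — which completes in roughly a quarter hour on one core.

## Design choices on genuinely open points

* **Substitution coordinates**: the 40- and 100-base homopolymer blocks
  are centered in the sequence (1-based 471–510 and 441–540 in a 980-mer),
  preserving the stated block lengths as the controlled variable.
* **Which chain-2 sign rules**: both shipped (see above) rather than
  guessing a single "intended" form; `as_printed` is the default for
  fidelity, `potential_consistent` exists for energy-based validation.
* **Dissipation indexing**: β is per pendulum, keyed by the pendulum's own
  base on its own chain.
* **Drive masking**: the drive is global; no per-site mask is applied by
  default.
* **Linearized single-pair frequency**: the oscillation of a perturbed
  undamped A·T pair is checked against the eigenfrequencies of the full
  2-dof linearization about (0, π) — for the printed variant,
  ω² ∈ {6.166·10¹¹, 1.017·10¹²} rad²/s⁴ roots with the φ₁-dominant mode at
  9.81·10¹⁰ Hz.  A single-dof formula that freezes the partner base
  misstates this frequency by tens of percent; the coupled linearization
  is the correct reference.

## Known limitations

* The printed variant's non-conservative sign structure has no energy
  functional; quantitative energy statements exist only for homopolymers
  under `potential_consistent`.
* Heterogeneous sequences under the printed variant are linearly unstable
  and saturate into deterministic chaos: individual trajectories are then
  sensitive to step size and arithmetic order, and only statistical /
  spectral summaries (amplitude, dominant frequency) are meaningful —
  oracle sup-norm comparisons are restricted to linearly stable systems.
* The two chains are structurally non-interchangeable (chain 2 rests at π,
  and the printed variant's on-site prefactor uses R₁ on both chains), so
  a poly-A duplex and its poly-T complement do not produce mirrored
  dynamics; only the build-level coefficient swap holds.
* No open states, no helicoidal or stacking terms, no thermal noise, no
  hydrodynamics beyond linear drag.
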