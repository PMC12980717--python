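# Methods

## Model

The simulator works in a finite electronic active space: the ground
state |0⟩ (energy fixed to 0) and N−1 excited eigenstates |λ⟩ of the
field-free Hamiltonian, specified by excitation energies E_λ and the
full transition-dipole matrix ⟨λ′|μ̂|λ⟩ (real, symmetric, atomic
units).  These data normally come from an excited-state
electronic-structure calculation; the package consumes them as input
and never computes them.  All internal quantities are Hartree atomic
units; interfaces accept eV, fs and W/cm².

The wave function |Ψ(t)⟩ = Σ_λ C_λ(t)|λ⟩ evolves under

    H(t)[λ′,λ] = E_λ δ_{λ′λ} − F(t)·⟨λ′|μ̂|λ⟩,

with a sum of up to three identical Gaussian-envelope cosine pulses

    F(t) = Σ_i F₀ cos(ω(t−t_i) − φ_i) exp(−(t−t_i)²/2δ²).

δ is the Gaussian σ (no FWHM reinterpretation).  The pulse amplitude is
derived from intensity as F₀ = √(I/I_au), I_au = 3.50944758·10¹⁶ W/cm².
All pulses share one polarization axis ê; the detected signal is the
scalar projection P·ê of P(t) = ⟨Ψ|μ̂|Ψ⟩.  Orientational averaging is
not implemented: the simulation is for a single fixed molecular
orientation.

## Propagator

Time stepping is the explicit leapfrog (second-order Euler) scheme

    C(t+δt) = C(t−δt) − 2i δt H(t) C(t),

default δt = 0.0242 fs.  Two numerical properties of this scheme are
handled explicitly:

* **Bootstrap.**  The scheme needs C(−δt).  Each leapfrog eigenmode
  rotates at the numerical frequency arcsin(E δt)/δt; initializing with
  the physical exp(+iHδt) excites the parasitic computational mode with
  amplitude ~(Eδt)³/6, visible as a norm oscillation.  C(−δt) is
  therefore generated by a single fourth-order step of the
  scheme-matched generator arcsin(δtH) ≈ δtH + (δtH)³/6, keeping the
  parasitic admixture at O((Eδt)⁵).  The same restart is used after a
  quantum jump.
* **Dispersion-true frequency axes.**  A coherence of energy E
  oscillates at arcsin(Eδt)/δt in the stored trajectory (for the
  default grids a ~+0.04 eV shift at 5.6 eV).  After the Fourier
  transforms the frequency axes are mapped through the exact inverse
  sin(ωδt)/δt (linearly continued beyond ωδt = 1.2 to keep the axis
  monotonic; signal content lies far below that boundary), so peaks
  appear at the physical energies without requiring a smaller step.

A stability guard rejects δt·E_max > 0.9 and a norm monitor aborts when
| |C|² − 1 | exceeds 10⁻³ (configurable), advising a smaller step.

Propagation is batched: all scan coordinates (delay τ, phase setting,
stochastic trajectory) of one population time run as one linear-algebra
stream.  The single-trajectory API is the batch of size one, so serial
and batched paths are bit-identical.

## Open system: stochastic pure dephasing

Environment-induced decoherence uses the Markovian stochastic
Schrödinger equation restricted to pure-dephasing channels, realized by
the Monte-Carlo wave-function (quantum-jump) algorithm.  The default
channel set has one diagonal operator per state,

    S_λ = √(γ/2) (1 − 2|λ⟩⟨λ|),

whose jump flips the sign of C_λ and leaves every population untouched.
An alternative pairwise set S_{ab} = √(γ/2)(|a⟩⟨a| − |b⟩⟨b|)
(`channel_mode="per_pair"`) is available but off by default.

Two exact algebraic facts shape the implementation:

* For either channel set Σ_q S_q†S_q ∝ 1, so the deterministic
  non-Hermitian norm decay between jumps integrates exactly to a scalar
  factor and the jump times form a Poisson process at the total channel
  rate (leapfrog itself would be unstable for a non-Hermitian term;
  the factorization avoids that without approximation).  Channel
  selection at an event uses the standard ‖S_q|Ψ⟩‖² weights.
* For a state pair (a,b), *both* channels a and b flip the relative
  sign, so the ensemble coherence decays at rate 2γ, not γ.  The
  user-facing parameter is the dephasing time T2, defined operationally
  as the 1/e time of a field-free coherence; the package calibrates
  γ = 1/(2T2) so this holds exactly (verified against the analytic
  Lindblad solution).  The literal mapping γ = 1/T2 is available with
  `t2_convention="literal"` and yields a T2/2 coherence lifetime.

RNG substreams derive from SeedSequence((seed, τ-index, trajectory)),
so any single trajectory is reproducible in isolation and results are
independent of batching.  The same jump realizations are reused across
the 12 phase settings of a scan point — the phase-cycling combination
then cancels stochastic noise common to settings — and across the
population times of one campaign, which makes the T-dependence of any
tracked feature a common-random-numbers comparison: the trajectory
noise enters every T point coherently and largely drops out of fitted
T-trends (measurably smaller lifetime-fit errors at equal cost).  The
ensemble average is taken before component extraction.

**Branched propagation.**  All population times of a campaign share
the pulse-1/2 history, so the campaign driver propagates the batch
once up to a snapshot at t₂ + 5.5δ (every envelope below e^−15),
crosses the field-free gap to t₃ − 5.5δ analytically — each eigenmode
advances by its exact leapfrog per-step phase arcsin(Eδt), and the
diagonal dephasing jumps commute with the free flight, entering as
accumulated channel products — and steps only the pulse-3/detection
window per T.  This is exact for the propagated physical mode (the
~10⁻⁵ parasitic admixture is common-mode and cancels in phase
cycling; direct and branched maps agree to ~10⁻⁵ relative for closed
dynamics).  When the pulses can overlap (T < 11δ) the driver falls
back to direct full-span propagation, so small-T maps retain all
pulse-overlap effects.

## Phase cycling

The total polarization from a three-pulse run is decomposed in the
carrier phases, P(t, φ) = Σ P_{lmn}(t) e^{i(lφ₁+mφ₂+nφ₃)}; the
rephasing signal is the (−1,+1,+1) component and the nonrephasing
signal (+1,−1,+1).  The built-in 12-setting scheme (φ₂ = 0 throughout,
φ₁, φ₃ on a π/2 grid) combines the twelve phase-dependent runs with
fixed complex weights and normalization 1/8.  Applying the weight rows
to analytic phase exponentials — and, independently, comparing with a
full n³ phase-grid discrete-Fourier oracle — fixes the row assignment
(the row conventionally labelled "II" isolates the rephasing component
under the series convention above) and characterizes the residual
aliasing exactly: the rephasing row also picks up i·P_{(l,n)≡(−1,−1)}
(a counter-rotating term that lands on the opposite detection-frequency
branch) and (1+i)·P_{(l,n)≡(1,±2)} (fifth-order/double-quantum terms,
negligible at the working intensity).  On the physical branch the
extraction agrees with the pure phase-matched component to a few per
mille at I = 5.01·10⁹ W/cm².

## Spectra

For each τ the detection-time trace is resliced to t′ = t − t₃ (delays
are snapped to the propagation grid so t₃ falls exactly on a stored
sample).  The maps are

    S_R(ω₁,T,ω₃)  = i ∫dτ ∫dt′ e^{−iω₁τ} e^{+iω₃t′} S_R(τ,T,t′),
    S_NR(ω₁,T,ω₃) = i ∫dτ ∫dt′ e^{+iω₁τ} e^{+iω₃t′} S_NR(τ,T,t′),

realized as half-axis rectangle-rule FFTs with zero padding (default
2×) and a time-domain Gaussian window on both axes implementing
spectral broadening (config `broadening_ev`, FWHM, default 0.05 eV —
the width is a display choice, recorded in the output metadata).  The
absorptive spectrum is Re(S_R + S_NR); with both components the
dispersive wings cancel along ω₁.

The extracted components are complex one-sided signals (the
phase-matching selection fixes the rotation sense), so a τ step of
0.5–1 fs supports the 4–8 eV content without sign ambiguity; each
frequency axis spans one sampling period and is unfolded by an integer
number of periods so the pulse carrier lies in the displayed window
(the bandpass/undersampling convention of one-sided detection).  Maps
are cropped to a display window of ±2.5 eV around the carrier by
default; the counter-rotating alias branch lies far outside it.

Peak finding reports local extrema above a threshold fraction of the
map maximum with a minimum-separation footprint; positive peaks are
bleach/stimulated-emission type, negative ones excited-state
absorption.  Cross-peak tracking samples the signed absorptive value at
the nearest grid point per population time (|value| behind a flag); the
damped-cosine fit A·cos(Ωt+φ)e^{−t/τ_d}+c uses multi-start
Levenberg-Marquardt (Ω seeded from the dominant discrete-Fourier
component; phase and decay-time start grids) and reports asymptotic
standard errors.

## Grids and presets

Campaign grids are made commensurate: the step is adjusted to
τ_step/round(τ_step/δt_requested) (< 1% from the default step) and T,
t₁ (= 5δ after the start) and the detection stride are snapped to step
multiples, keeping the τ axis uniform for the FFT.  Presets:

* benzene-like: 2 states, δ = 2 fs, ω = 5.61 eV, T = 100 fs,
  τ 0–100/0.5 fs (fast: 1 fs), detection window 180 fs.
* chlorophyll-like: 3 states, δ = 5 fs, ω = 2.31 eV, T = 100 fs,
  window 500 fs (fast: τ 0–60/0.8 fs, window 250 fs — the window sets
  the 0.017 eV probe resolution needed to separate 2.27 from 2.31 eV).
* dimer: 6 states, δ = 2 fs, ω = 5.47 eV; closed-system preset with
  four population times; open-system preset with T2 = 60 fs, 17
  population times in 5–95 fs and 100 trajectories (fast: 50
  trajectories, τ 0–36/0.55 fs, window 60 fs).

All pulses use I = 5.01·10⁹ W/cm².  The fast variants are the package's
desk-scale grids: they keep every resolution that the reported
quantities need (peak separations, beat periods) while reducing the
τ span and trajectory count.

## Synthetic fixtures: what they do and do not emulate

The three bundled systems reproduce only excitation energies stated for
the corresponding molecules (benzene bright state 5.61 eV; a
chlorophyll-type S1 at 2.31 eV with an S1-anchored upper state
2.27 eV above it; five dimer states at 4.96–6.18 eV).  Transition-
dipole magnitudes are a package choice (1.0 a.u. along z, scalable);
peak *positions* in the weak-field regime are invariant to this choice,
peak *amplitude ratios* are not.  Real systems differ in ways the
fixtures deliberately omit: many more states, heterogeneous oscillator
strengths, excited-excited couplings beyond the single ESA channel,
vibronic progressions, and orientational disorder.  Passing tests
therefore validate the propagation/extraction/transform machinery and
the energy placement of spectral features, not quantitative intensities
of any real molecule.

One consequence worth stating explicitly: for the equal-dipole dimer
fixture the diagonal peaks of the absorptive map are *not* constant in
the population time.  The nonrephasing coherence pathway (bra
excitation during T, bra de-excitation by the third pulse) terminates
on the diagonal, so a V-type system with equal dipoles shows diagonal
beats of the same order as the cross-peak beats (tens of percent
here).  Near-constant diagonals arise only when one transition
dominates (population terms ∝ μ⁴ of the bright state outweigh
coherence terms ∝ μ_b²μ_b′²), as in heterogeneous multi-state systems.
The test suite keeps the strict constancy check for documentation; it
fails for this fixture, by physics rather than by defect.

## Numerical choices and degenerate inputs

* Dipole symmetry tolerance 10⁻¹⁰ (validation error names the pair);
  energies must be non-negative, sorted, ground exactly 0; n ≥ 2.
* Norm tolerance 10⁻³; check every 250 steps.
* Jump times snapped to the nearest step (δt ≪ 1/rate by orders of
  magnitude); zero-norm states after a jump are an error.
* Zero-amplitude sequences propagate trivially (polarization axis falls
  back to z for the projection).
* Fit requires ≥ 5 points; non-convergence from all starts raises with
  diagnostics; decay excursions through τ_d = 0 are clipped inside the
  model to keep the optimizer finite.
* τ = T = 0 and overlapping pulses are allowed (pulse-overlap effects
  are part of the model); negative delays are rejected.

## Known limitations

* No orientational/isotropic averaging, no vibronic or nuclear degrees
  of freedom, no relaxation (population-decay) channels, no
  non-Markovian memory.
* Single-quantum detection only: the scheme resolves the two
  phase-matched third-order components; double-quantum (l+m+n = 2)
  signals are out of scope.
* The leapfrog dispersion correction is exact for free-evolution
  frequencies measured against the ground state; differences of two
  excited-state corrections (e.g. an ESA coherence) retain an O(δt²)
  residual, well under a grid spacing at the default step.
* Peak positions carry the finite-grid resolution 2π/(τ span) and
  2π/(detection window); the acceptance checks use exactly these
  spacings as their tolerance.
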