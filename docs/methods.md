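# Methods

## The network model

Each of the N = 78 regions is a lumped alpha-rhythm neural mass with one
excitatory and one inhibitory population.  Three synaptic pathways per mass
are realised as linear filters with biexponential impulse response
`h(τ) = A(e^{−aτ} − e^{−bτ})` (τ ≥ 0, else 0):

| pathway | kernel | input |
|---|---|---|
| external/network → excitatory | EPSP (A 1.6 mV, a 55 s⁻¹, b 605 s⁻¹) | `P(t) + S·Σⱼ wᵢⱼ Eⱼ(t−T)` |
| inhibitory → excitatory | IPSP (A 32 mV, a 27.5 s⁻¹, b 55 s⁻¹) | `C2·Iᵢ(t)` |
| excitatory → inhibitory | EPSP | `C1·Eᵢ(t)` |

with `Ve = (EPSP response) − (IPSP response)` and `Vi = (E→I response)`.
Population pulse densities are `E = S[Ve − Vd1]` and `I = S[Vi − Vd2]`,
where `S[·]` is the two-branch exponential sigmoid with maximum rate
`2g = 50 spikes/s`.  The transmitted inter-mass
signal is the excitatory pulse density, delayed `T = 2 ms` (one sample) and
scaled by the global gain `S` times the structural weight — the natural
choice given that inter-mass coupling is excitatory with delay `T` and
strength `S`; potentials are not exchanged between masses.

**Integration.**  Each biexponential kernel is the impulse response of
`y'' + (a+b)y' + ab·y = A(b−a)x`, advanced as two first-order states by
explicit fixed-step Euler at `dt = 2 ms`.  The stiffest rate (`b_e =
605 s⁻¹`) gives `dt·b = 1.21 < 2`, inside the Euler stability region.  All
states start at zero and the first 1000 samples (2 s) are discarded as
burn-in, after which the delay loop and filters carry no memory of the
initial condition.

**Noise.**  The thalamic drive is `P(t) = P + noise·η(t)` with `η`
independent standard Gaussian per region and step (`P = 480 spikes/s`,
`noise = 1.0`).  The Gaussian choice is isolated in one place in
`simulate` and can be swapped; nothing downstream assumes it.

**Default parameters** (mV, s, spikes/s): `dt 0.002, P 480, noise 1.0,
A_e 1.6, A_i 32, a_e 55, b_e 605, a_i 27.5, b_i 55, g 25, q 0.34, Vd1 7,
Vd2 7 (swept 6–8 by 0.5), C1 32, C2 3, S 1 (swept 0–2 by 0.5), T 0.002,
N 78`.  At these defaults the decoupled deterministic mass settles to a
fixed point and the noise-driven network shows a ~9–10 Hz spectral peak,
i.e. resting-state alpha-like activity.

**E-I ratio.**  `E/(E+I)` of time-averaged pulse densities per region,
averaged over regions.  For display along a `Vd2` sweep, the whole-brain
mean E and I rates are min-max normalised *across the sweep* before forming
the ratio (`StudyResult.ei_curve`), which stretches the curve to [0, 1];
the raw per-model ratio is what the monotonicity analyses use, since
min-max normalisation depends on the sweep endpoints while the raw ratio
does not.

## The synthetic connectome

Downstream analyses need a structural graph with clear hubs.  The generator
draws edges independently with probability ∝ θᵢθⱼ, θᵢ = i^(−1/hub_exponent)
(a Chung–Lu expected-degree construction), bridges any disconnected
components, gives edges lognormal(0, 0.4) weights, and rescales the matrix
to a target mean weighted degree.  Defaults: 78 regions, edge density 0.15,
hub exponent 2 (max:min weighted degree well above the 3:1 needed for a
meaningful hub/non-hub contrast), mean degree 3.0.

**Coupling-scale calibration.**  The physical scale of structural weights
is arbitrary in this model class; only the product `S·W` matters.  The mean
degree 3.0 was fixed — once, before any statistical analysis — by requiring
the placement the study design states: the balanced model (`Vd2 7, S 1`)
sits near (just below) the network's synchrony transition, and the
transition is crossed within the sweep grids.  Measured by mean pairwise
EEG correlation, the balanced model sits on the rising edge (≈0.4), the
low-E-I model (`Vd2 6.5`) is clearly subcritical (≈0.003) and the high-E-I
model (`Vd2 7.5`) supercritical (≈0.98).  This calibration uses only the
synchrony curve, not any downstream readout.

**What the generator does not emulate:** spatial embedding and distance-
dependent connection probability, hemispheric symmetry, community
structure, and the specific degree sequence of an empirical DTI matrix.
Passing tests on this graph therefore demonstrate that the *pipeline*
reproduces the qualitative E-I phenomenology on a hub-heavy network; exact
regression magnitudes on an empirical connectome are expected to differ
(read_connectome accepts any delimited matrix for that purpose).

## Symbolic dynamics

Signals are band-pass filtered, symbolised, then measured.

- **Filtering** — zero-phase Butterworth (order 4, applied forward and
  backward with `sosfiltfilt`).  A linear-phase FIR design at the 0.5 Hz
  lower band edge would need a filter nearly as long as the 4096-sample
  epoch, so an IIR zero-phase design is used; stop-band suppression of a
  2 Hz tone through the 6–13 Hz band exceeds 90% (tested), and zero-phase
  filtering guarantees ordinal patterns are not displaced in time.
- **Symbolisation** — embedding vectors of n = 4 samples spaced τ apart,
  windows advancing one sample, each mapped to the lexicographic rank of
  its stable argsort (ties rank by temporal order).  n! = 24 ≪ 4093 symbols
  per epoch, satisfying the usual sample-size recommendation.  τ selects
  the time scale; the study grid is (0.5–70 Hz, τ=1), (6–13 Hz, τ=1),
  (0.5–70 Hz, τ=50).
- **PE** — Shannon entropy of the symbol histogram / ln 24.
- **Volume-conduction mask** — co-occurrence cells where the two patterns
  are identical, or where one is the amplitude inversion (reversed argsort)
  of the other, are excluded: instantaneous linear mixing of a common
  source produces exactly those pairs.  The mask removes 48 of the 576
  joint states, leaving 528 admissible ones.  It is applied to both wsMI
  (as zero weights) and JPE_inv (mask + renormalise), with the uncorrected
  variants available behind a flag.
- **wsMI** — Σ w(x,y)·p(x,y)·ln[p(x,y)/(p(x)p(y))] / ln 24, weights 0 on
  masked cells, 1 elsewhere.  Zero for a signal with itself and with its
  sign-inverse; ≈0 for independent streams.
- **JPE_inv** — 1 − H(joint, masked, renormalised)/ln 528.  Equals 0 for
  independent maximally-variable streams and grows with coupling and with
  joint regularity.
- Natural logarithms with explicit normalisation constants throughout;
  0·ln 0 := 0.

## Statistics

Functional degree is the mean off-diagonal connectivity per region.  The
HDI is the OLS slope of (perturbed − reference) degree on reference degree,
reported with offset, R², F = R²(N−2)/(1−R²) on df (1, N−2), and p.  The
regression x-axis is always the balanced-model degree; the index is not
antisymmetric under swapping the two conditions.

Whole-brain comparisons use Student's t (pooled variance — group sizes are
equal by design: one observation per run, n = 10 per model) with pooled-SD
Cohen's d; Welch is available behind a flag.  Sweep-level associations use
Pearson's r with run-level observations (n = 50 at S = 1) by default and a
model-level (n = 5) variant.  Regional comparisons use Mann–Whitney U
across runs per region (n = 10 vs 10), corrected per family of 78 regions
by the two-stage linear step-up FDR procedure at q = 1%.

## Study protocol and problem sizes

Ten independent seeded runs of 4096 recorded samples (8.192 s each,
81.92 s per model in total) per grid cell; seeds derive from
`SeedSequence(base_seed, spawn_key=(vd2_index, s_index, run))`, so any
single cell is recomputable in isolation and everything is bitwise
reproducible.  The test suite and the acceptance script analyse the S = 1
column of the grid (5 models × 10 runs × 3 conditions, ≈1 minute on one
CPU); the full 5 × 5 grid runs through `run_study`/the `sweep` CLI in a few
minutes.

## Known limitations

- Homogeneous `Vd2` across regions; no region-specific pathology maps.
- One-sample (2 ms) conduction delay for all pairs; no distance-dependent
  delays.
- The synthetic connectome's caveats above; empirical matrices can be
  supplied but are not bundled.
- Explicit Euler is first-order; the alpha peak location shifts by a few
  percent relative to finer-step integration (the study's qualitative
  contrasts are insensitive to this).
- wsMI's relationship to E-I is non-monotone near the synchrony transition
  (an inverted-U), so only PE and JPE_inv carry directional expectations
  across the whole sweep.
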