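# Methods

## Model and assumptions

The package describes a single, non-interacting motor as a discrete-time,
continuous-space random walk with two motility states, *motion* and *wait*.
Switching is Markovian with constant per-step probabilities κ_w
(motion → wait) and κ_m (wait → motion); residence times are therefore
geometric — the discrete counterpart of the exponential lifetimes observed
for active transport phases — with means 1/κ_w and 1/κ_m steps.  The state
sequence is a two-state Markov chain with relaxation factor
r = 1 − κ_w − κ_m and stationary motion occupancy s = κ_m/(κ_m + κ_w).

Two transport geometries share this switching core:

* **Single filament.**  Motion is unidirectional; a waiting motor does not
  move (detached-but-diffusing phases are out of scope).  Displacement:
  x(n) = Σ σᵢ ℓᵢ with σᵢ the motion indicator and ℓᵢ i.i.d. step lengths.
* **Network.**  The filament network is coarse-grained away: its geometry
  enters only through the segment-length distribution f(ℓ) between
  junctions and the symmetric turn-angle distribution R(φ) at junctions.
  At each motion step the motor keeps its direction with processivity p,
  otherwise turns by a draw from R; *waits do not decorrelate direction*
  (the motor sits at a junction on its current filament).  Initial direction
  is isotropic.  No explicit junction graph or filament dynamics are
  simulated; the stochastic description is the model.

Ordering convention: the state of step n results from one kernel application
to the state at n − 1, and the displacement of step n uses the
post-transition state; no step is taken at n = 0.  Consequences: a motion
start with κ_w = 1 never moves, and a pure waiting start with κ_w = 0 has
motion probability P_i = 1 − (1 − κ_m)^i at step i.

## Exact moments

Both engines evaluate the same correlation sum

    ⟨r²(n)⟩ = ⟨ℓ²⟩ Σ_{i≤n} P_i + 2⟨ℓ⟩² Σ_{i<j≤n} P_i g(j−i),

with P_i = q_m(i) = s + (q_m0 − s) rⁱ.  On a single filament g(k) is the
motion→motion return probability s + (1 − s) rᵏ.  On a network each motion
step in (i, j] retains a factor A = p + (1 − p)E[cos φ] of direction
correlation, so g(k) is the motion component of Mᵏ applied to the unit
motion vector, with the persistence-weighted transfer matrix
M = [[A(1−κ_w), Aκ_m], [κ_w, 1−κ_m]].  A = 1 reduces the network engine to
the single-filament one identically; only A and λ = ⟨ℓ²⟩/⟨ℓ⟩² enter the
MSD, never the full shapes of R and f.

Asymptotics follow in closed form: MSD → (s⟨ℓ⟩)² n² on a filament, and on a
network (A < 1) MSD/n → s⟨ℓ⟩² Γ with Γ(λ, A) = λ + 2A/(1−A), because the
summed direction correlation Σ_k g(k) from a moving state equals A/(1−A)
independently of the switching rates (a two-line solve of (I−M)w = M e_m).
D_∞ = s v ⟨ℓ⟩ Γ/4 uses the 2D normalization MSD = 4Dt and the tick
convention below.

## Numerical choices

* The double sum is a discrete convolution of P with g; it is evaluated
  with `np.convolve` (exact direct summation) up to horizon 2048 and with
  `scipy.signal.fftconvolve` beyond, giving O(n log n) cost and ~10⁻¹³
  relative accuracy at n = 10⁶ — far below every tolerance used.  Direct
  cumulative sums over explicit power arrays avoid the cancellation that
  closed-form geometric sums suffer as |r| → 1.
* Network correlations g(k) come from the eigendecomposition of the 2×2
  transfer matrix (complex pairs handled, result real by symmetry), with a
  direct iteration fallback when the spectrum is degenerate within 10⁻⁸.
* α(n) uses natural logarithms of successive integer steps; the initial
  exponent α* = log₂(MSD(2)/MSD(1)) is exposed by the analytic modules.
* Crossover detection is *sustained*: n_c = 1 + the last step violating
  |α − target| < ε within the horizon (ε defaults to 10⁻²).  A first-crossing
  rule would fire spuriously when α overshoots its asymptote (waiting-start
  super-ballistic transients).  Non-converged cells in phase scans are
  flagged and hold the horizon as a lower bound — never interpolated.
* Degenerate inputs raise typed errors rather than returning NaN: frozen
  chain (κ_w = κ_m = 0, no stationary law), MSD(1) = 0 (undefined α*),
  A = 1 in D_∞ (ballistic divergence), asymmetric turn samplers (the moment
  algebra assumes E[sin φ] = 0; rejected at 5σ on 2·10⁴ screening draws
  rather than silently projected).
* The waiting-start continuous-time MSD v²[t² − 2t/κ − 2expm1(−κt)/κ²] is
  written through `expm1`, keeping the t³ regime accurate down to t ≈ 10⁻⁴/κ;
  the local log-log slope helper uses a centred difference, which below
  t ≈ 10⁻⁵/κ starts to amplify rounding noise (measure no smaller).

## Simulation

The Monte Carlo simulator is the package's empirical check, not its engine.
Walkers advance in fixed chunks of 16384, each chunk drawing from its own
Philox stream spawned from the master seed: results are bit-reproducible,
independent of execution order, and a prefix of walkers is unchanged when
the ensemble grows.  Per step each walker draws one uniform for the state
kernel, then (network) a keep/turn uniform and a turn angle, then a step
length; draws are made for all walkers to keep streams aligned, and unused
draws are statistically irrelevant.  MSD standard errors come from the
ensemble variance of the squared displacement.  Default ensembles of 10⁶
walkers match the analytic curves to fractions of a percent; the test suite
uses 10⁵ (and 2–5·10⁴ for quick checks) with 3-standard-error gates, with
recording on a log-spaced grid of ≤ 64 steps.

What the simulator emulates — and what it does not: it realizes exactly the
idealized two-state chain the analytic engines integrate, so agreement
validates the algebra, not the biology.  Features of real motor data that
are outside both (and hence untested by passing tests): motor–motor
exclusion, cargo tug-of-war, detached diffusing phases, non-Markovian
residence times, 3D geometry, and chemomechanical stepping substructure.

## Units and physical scales

Lengths are model units; ⟨ℓ⟩ is the step (filament) or mesh (network) size.
Every tick — motion *or* wait — lasts the motion-step duration ⟨ℓ⟩/v with v
the motor speed, e.g. 8 ms per 8 nm step at 1 µm/s, 0.1 s per 100 nm mesh
segment.  This single-tick convention is what `steps_to_time` implements and
is adequate for order-of-magnitude statements; pauses with a different
intrinsic timescale would need a two-clock extension.  For the
microtubule-like regime (κ_w = 0.9, κ_m = 0.01, A = 0.99) the package
reproduces the qualitative sub→super non-monotone exponent transient, but no
quantitative crossover time is claimed because the tick convention there is
under-determined.

## Validation architecture

Three independent routes to every MSD: the analytic engines, a 2ⁿ
state-sequence enumeration (shipped in `runpause.oracle`, probability
normalization asserted to 10⁻¹² on every call, horizons capped at 16/14),
and the simulator.  The test suite pins engines to enumeration at 10⁻¹²
over randomized sweeps including boundary rates, and ensembles to engines
within 3 standard errors.  Scans in tests and the acceptance script use
horizons of 8192 (grids), 10⁵–10⁶ (asymptotic laws) and 10⁵ walkers —
chosen so every checked quantity is converged at its stated tolerance while
a full run stays in tens of seconds.

## Design notes and limitations

* λ is defined as ⟨ℓ²⟩/⟨ℓ⟩² (λ = 1 iff constant step); A = p + (1−p)R̂ is
  the normative combination of processivity and anisotropy — it reproduces
  all special cases (isotropic non-processive A = 0; aligned or fully
  processive A = 1) and is the only combination the moments depend on.
* The square-lattice comparison is realized as turns uniform on
  {0°, +90°, −90°} (no direct reversal), the symmetric lattice turn set with
  R̂ = 1/3, giving the initial-exponent range [log₂(8/3) ≈ 1.415, 2] as p
  runs from 0 to 1.
* Super-ballistic transients (α > 2) require a *macroscopic* occupancy
  deficit: ensembles started below the stationary occupancy s accelerate as
  walkers are injected into motion, but for q_m0 marginally below s the
  overshoot amplitude vanishes and can be completely masked by pausing.
  The package asserts the iff-structure of this effect over the
  initial-condition study grid (κ_w ∈ {0, 0.1}, κ_m = 0.001,
  q_m0 ∈ {0, 0.2, 0.5, 0.8, 1}), not for arbitrary parameter corners.
* At κ_w = κ_m = 1 the chain alternates deterministically (r = −1) and the
  exponent oscillates indefinitely: crossover detection correctly reports
  non-convergence; phase grids should avoid that corner or expect the flag.
* Negative anisotropies (backward-peaked turning) are supported by the
  engines and oracle; only the one-parameter `turns_from_anisotropy`
  convenience (uniform / wrapped-normal / forward delta) is restricted to
  A ≥ 0 — build negative-R̂ models with `discrete_turns`.
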