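# Methods

## Model structure

The estimator is a Rao-Blackwellized particle filter over a single "hard"
parameter, the internal gravity magnitude |g|, discretized on a uniform grid
(default 0.05–5.00 g in 0.01 g steps).  All other perceptual states —
angular velocity ω̂, linear acceleration â, gravity direction ĝ — are
propagated analytically by internal-model observers, one per grid value,
advanced in lockstep on a single shared (noisy) afference stream.  Running
one stateful observer per grid value is mathematically equivalent to
re-simulating each conditioned observer from t = 0 whenever a particle
lands on that value, at a fraction of the cost; particles are therefore
just indices into the observer bank.

### Observer

Head frame is x-forward / y-left / z-up; world z is up, and the perceived
gravity state ĝ stores the upward reaction vector (stationary upright at
1 g senses specific force (0, 0, 1) g).  Per integration step dt (default
0.05 model s):

- canal sensor and internal canal model: first-order high-pass of angular
  velocity, τ_canal = 5.7 s, discretized with the exponential (exact-pole)
  coefficient α = exp(−dt/τ) so the internal model matches the sensor
  exactly when ω̂ tracks ω;
- otolith sensor: specific force with identity dynamics;
- conflicts: e_ω = canal afference − expected canal; f̂ = â + ĝ;
  e_a = w ∘ (oto − f̂); e_f = w ∘ (û_meas × û_exp) (unit GIF directions,
  set to zero when either norm < 1e−9, relevant only near 0 g, which is out
  of scope);
- updates: ω̂ += dt (k_ω e_ω + k_fω e_f); ĝ is rotated by
  dt (−ω̂ − k_f e_f) — the −ω̂ term transports a world-fixed vector through
  head rotation, the −k_f e_f term rotates the expected GIF toward the
  measurement (the cross-product order above makes that sign negative) —
  and then rescaled to the conditioning hypothesis magnitude;
  â += dt (k_a e_a − â/τ_a).

Gains (k_ω, k_f, k_fω, k_a) = (8, 4, 8, 4) and τ_a = 1 s are
literature-style defaults, not fitted values.  The per-axis conflict weights
w default to (1, 2, 1): doubling the interaural-shear component of the
otolith conflict implements differential weighting of otolith stimulation.
Because w multiplies the *conflict* (which vanishes at any matched fixed
point), perception is exact whenever the hypothesis matches the true
gravity; during magnitude mismatch the asymmetry biases the quasi-static
tilt equilibrium toward perceived tilt ≈ actual tilt × (g_true/x_hyp).
That yields roll-tilt overestimation in unadapted hypergravity (the
G-excess illusion) and underestimation in hypogravity, resolving as the
gravity estimate adapts.  Neutral weights (1, 1, 1) restore the unweighted
observer, whose tilt percept tracks actual tilt at every gravity level.

Sensory noise is white with power-spectral-density height 1e−8 (per-sample
variance = power/dt, making trajectories dt-invariant in distribution).  At
dt = 0.05 this is a ~4.5e−4 unit disturbance, small relative to the
conflict scale — the filter's stochasticity is dominated by resampling and
the jitter kernel.

### Likelihood

Hypotheses are scored on the reduced conflict vector
e = [‖e_a‖, ‖e_f‖, ‖e_ω‖], averaged over the filter interval Δk (default
0.5 model s, 10 observer steps) to smooth the sinusoidal phase of the
stimulus out of the evidence.  ε = eᵀS⁻¹e and
p(y|x) = (2π)^(−3/2)|S|^(−1/2)exp(−ε/2).  S = diag(0.02 g, 0.1, 0.05 rad/s)²
is a modeling constant, not a measured noise covariance: its diagonal sets
how sharply likelihood decays with conflict in each channel and therefore
the adaptation rate and the tightness of the converged estimate.  The
0.02 g acceleration-channel scale puts the likelihood half-width at a few
grid bins (steady conflict for a mismatch Δ is ≈ Δ/5 after the â leak
absorbs its share), so the converged MAP jitters by only 1–4 bins; a much
larger value would leave the likelihood nearly flat within ±0.1 g and let
the resampled cloud random-walk far from the truth.

Weight updates run in log space (likelihoods for a 3 g mismatch underflow
to zero in linear space); the recorded per-particle likelihoods are the
linear densities, which is what the HML recursion consumes — its decay
toward zero under total surprise is what drives exploration.

### Memory kernel

- HML_k = (1 − 1/(1+f))·HML_{k−1} + (1/(1+f))·max p(y|x), f = 1 (each step
  halves the memory), initialized at the zero-conflict density ceiling so
  runs start in exploitation.
- σ_jitter = clip(c/HML^χ₁, 0.005, 1.0) g with χ₁ = 1 and c = 3.0
  density·g units; c is chosen so the *adapted* likelihood scale (~600
  density units under the default S, reflecting residual dynamic conflict)
  maps to the minimum width, i.e. exploitation means a 1–2 bin search.
- Harmony threshold ν = 2 ln 2 ≈ 1.386: the NIS at which a step's
  likelihood falls to half its ceiling.  Measured adapted central NIS is
  0.07–0.4 across 0.5–4 g under the roll stimulus, so converged states at
  every simulated level are harmonious with margin, while a 0.1 g mismatch
  (NIS ≳ 1.6) is not.
- LTM window T_wind = 400 model s with Δk = 0.5 (N_wind = 800), long enough
  that a level learned one 120 s schedule segment ago is still remembered
  at the next transition, short enough that memory measurably ceases within
  the fig3-style run.  Entries are time-stamped and pruned by age, so
  learned states decay even while the filter explores elsewhere.
- Mixture weight W = sigmoid(σ·χ₂) − ½ with χ₂ = 4: W ≈ 0.005 in
  exploitation (σ = 0.005) and ≈ 0.48 at full exploration (σ = 1), so the
  memory is consulted essentially only while searching.

One W per step (HML and σ are defined over the whole hypothesis set, not
per particle).  Resampling is multinomial at every step (systematic
available via config); the transition draw, the resampling draw and the
sensory noise use three named RNG streams spawned from one seed, so
toggling the LTM or the resampling scheme leaves the noise realization
untouched — the basis for all paired comparisons.

### Central observer

The central observer is the bank observer at the current MAP grid value:
its state is continuous (no restart transient) and the conditioning
switches with the MAP.  Its interval-averaged NIS is the harmony statistic,
and its ĝ yields the perceived roll/pitch reported at full dt resolution.
The percept attributed to an interval uses the MAP available at the start
of that interval (causal reporting).

## Scenarios

The reference stimulus is passive sinusoidal roll tilt at 1 rad/s
(0.159 Hz) with 10°/s peak angular velocity, i.e. 10° peak displacement
(the peak-velocity reading of the stimulus is adopted; a 10° displacement
reading would only rescale the conflicts).  Gravity schedules step among
{0.5, 1, 2, 4} g, always starting at 1 g.  Segment duration defaults to
120 model s — more than five times the observed 1→4 g adaptation time under
default constants — so learned states form before each transition.  All
times are *model* seconds: no parameter has been fitted to human adaptation
time courses, and absolute durations carry no empirical claim.

## What the synthetic stimulus does and does not cover

The generator produces ideal passive roll-tilt motion with instantaneous
gravity steps, stationary white sensory noise, and no inter-individual
variability; visual and somatosensory channels, active movement and
efference copies, 0 g otolith reinterpretation, and signal-dependent
vestibular noise are all outside the model.  Tests passing on these
scenarios show the inference and memory machinery behaves as designed; they
do not validate the model against human data.

## Numerical choices and degenerate inputs

- Quaternion truth integration with per-step renormalization; observer ĝ
  updated by a first-order rotation then rescaled to the hypothesis
  magnitude (the rescaling also enforces the magnitude constraint).
- MAP ties break to the lowest gravity value (deterministic).
- The discretized STM Gaussian and the STM/LTM mixture are renormalized to
  unit mass on the grid; the δ-functions of the LTM density are single-bin
  indicators at 0.01 g.
- The sigmoid weight is clamped one float below ½ to keep W < ½ strict
  under saturation.
- An off-grid initial gravity is snapped to the nearest bin with a warning;
  non-uniform time grids, non-finite inputs, non-positive-definite S, and a
  filter step that is not an integer multiple of dt are rejected.

## The exhaustive-filter check

`brute_force_reference` propagates the full grid distribution through the
exact transition kernel and the same likelihoods (no sampling) — the
N_s → ∞ limit of the particle filter.  Its HML maximizes over bins with
predicted mass ≥ 1/N_s, the bins a particle set of the configured size
would be expected to populate.  The consistency check runs a 1 → 1.15 g
step on a 50-bin grid (0.80–1.29 g), noise off, 90 model s: in this regime
importance weights stay representative and the 10⁴-particle filter tracks
the exact posterior to a mean total-variation distance of ~0.02–0.05.
Across a sharp 1 → 4-style step the exact filter legitimately outruns any
finite particle set through the underflow-sharp likelihood region — a known
particle-filter degeneracy, not an implementation artifact.

## Known limitations

- Exact repeatability of a run requires the same platform BLAS; all
  reported checks use statistics robust to last-bit differences.
- With W > 0 whenever σ > 0, the transition kernel with a populated LTM is
  never *exactly* the pure STM kernel, so paired runs with and without LTM
  diverge microscopically even before any gravity transition (the MAP stays
  pinned at the true level in both; only its ±1-bin flicker pattern
  differs).
- The converged MAP flickers within ±2–4 bins of the true level because
  adjacent-bin likelihood ratios are near unity; summaries over windows
  (median, band membership) are the intended readouts.
- Microgravity (0 g) transitions, multimodal percept merging, and learned
  states for parameters other than |g| are out of scope.
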