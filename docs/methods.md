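# Methods

## The network model

A single-layer recurrent network of N rate neurons represents a 100°-wide
strip of space; neuron *i* has preferred angle θ_i = 0.1·i − 50° (N = 1000,
0.1° spacing). Excitatory and inhibitory populations are collapsed into one
equivalent population coupled by a difference-of-Gaussians kernel, so each
neuron excites its neighbors within ~σ₁ and inhibits a wider surround ~σ₂.
Dynamics are synchronous discrete-time: the net input is the external drive
plus the recurrent drive, and the firing rate follows by divisive
normalization. Two normalization variants are implemented as code paths of
the same update loop:

* **threshold-linear** (exponent 1): `u = [a]₊ / (1 + mean[a]₊)`. Weak
  normalization: several activity hills can coexist, which is what lets the
  network report *two* sources.
* **squared** (exponent 2): `u = a² / (1 + mean a²)`. Strong normalization:
  iterating the square amplifies the tallest hill until it alone survives
  (winner-take-all), so this variant fuses the cues at any disparity. It is
  kept as the baseline the linear model is contrasted with.

A third named configuration, `network-noinhib`, is the linear model with
M₂ = 0; without lateral inhibition the two input bumps always melt into one,
so it too cannot report independent causes. It is a parameter setting, not a
separate code path.

The external input is presented for the first five steps (t = 0…4), with
`a(0) = h` and `u(0) = 0`; recurrence contributes from step 1 on (the
literal reading of the update equation), and from step 5 the network runs
free. The alternative reading — feed-forward only during the window — can be
probed by setting `input_steps: 1`.

### Timescale and stopping rule

No iteration count is inherent to the model, so the package fixes
`max_steps = 100` with `tol = 1e−9` on the sup-norm change of `u`, checked
only after the input window (the map changes at t = 5, so earlier
stationarity would be spurious). Hill *formation* completes within a few
tens of steps; afterwards the state creeps along the attractor — coexisting
hills repel through the inhibitory surround at ~10⁻³ per step, a fused hill
drifts at ~10⁻⁶ per step — so strict 1e−9 convergence is often not reached
at step 100. That is the model's own physics, not a numerical defect: the
run is flagged `converged=False` and the state at step 100 is read out.
Reading out at a fixed horizon makes the repulsion between segregated hills
(the negative bias) well-defined; letting the network run much longer would
slowly exaggerate it.

## Stimulus and noise model

The drive is a sum of two Gaussian bumps, amplitude/width (10, 1°) for
vision and (10, 2°) for audition, so the visual peak is twice the auditory
peak — vision is the more reliable cue, which is what produces visual
capture. Bump centers are the *sensed* positions, drawn per trial as
x_V ~ N(S_V, 3²) and x_A ~ N(S_A, 6.5²); draws outside the strip are
rejected and redrawn (vanishingly rare with the default geometry). On top of
the mean profile each neuron gets independent Gaussian noise with variance
equal to its mean drive (a variance-equals-mean stand-in for spiking noise);
the noise is drawn once per trial and the same `h` is presented on all five
input steps. `h` is not rectified — the threshold-linear normalization does
that. Poisson spiking and asynchronous cue onset are out of scope.

## Readout

Bumps are detected on the final rate vector: local maxima above 10 % of the
global maximum, merged when closer than 3° (= σ₂ — maxima within the
inhibition range are one hill), each refined to the center of mass of its
contiguous supra-threshold region (split at the valley when two kept peaks
share a region). On converged states the COM and the raw peak coincide to
well under a grid step (measured < 0.01° on the default fused state), so the
choice between "cap coordinate" and COM is immaterial; COM is kept for its
sub-grid resolution. One bump ⇒ C = 1 and both position estimates equal the
bump position; two bumps ⇒ C = 2, and the bump nearer the sensed auditory
position is the auditory estimate (ties go to the shorter bump, audition
being the weaker drive; an alternative weakest-bump rule is selectable).
States with 0 or ≥ 3 bumps — possible only under extreme noise or degenerate
parameters — are flagged invalid, logged, and excluded from averages.

The localization bias (Ŝ_A − S_A)/(S_V − S_A) is averaged per disparity
*conditionally* on the verdict, with SEM = sd/√n per class; empty classes
are reported missing, never zero. The single pooled number quoted for the
fused class averages all C = 1 trials across the disparity grid with equal
trial weight (the per-disparity values are also reported, so other poolings
can be formed from the output).

## Integration thresholds

With all noise off the verdict is a deterministic step function of the
disparity D (sources placed symmetrically at ±D/2). The network threshold
D₀ is that switch point, found by coarse scan plus bisection to 0.05°
(default D₀ ≈ 9.6°). The proportion of fused trials under noise then follows
in closed form, I(D) = Φ((D+D₀)/s) − Φ((D−D₀)/s) with s = √(3² + 6.5²),
because the sensed disparity is Gaussian about D; the Monte-Carlo unity
curve and this closed form agree within binomial error, which is the
package's main self-consistency check.

The Bayesian observer's threshold has the closed form
D₀ = √(2Σ·ln[a·p_co/((1−p_co)√(2πΣ))]), Σ = σ_V²+σ_A², cross-checked
against root-finding on the posterior to 1e−9. When the log argument is
below 1 the observer never integrates and the threshold is reported as 0
with a warning; p_co = 1 gives +∞. The source-range width is set to
a = 100°, matching the width of the network's strip (the natural choice for
comparing the two models); it is recorded in every output manifest. A
posterior of exactly ½ counts as C = 1 (a measure-zero tie that must be
deterministic).

## Design choices that were genuinely open

* **Non-periodic strip.** Angular distance is the plain difference; the
  model describes a bounded strip, not a ring. All experiment drivers keep
  sources within ±35° so bumps stay ≥ 5σ₂ from the edges.
* **Pooling of the fused-class bias** is by trial count (each fused trial
  weighs equally); an unweighted average of per-disparity means gives a
  value ~3 points higher.
* **Seeding.** A master seed spawns one `SeedSequence` child per trial,
  indexed by counter; per-trial outputs are bitwise reproducible and
  trivially parallelizable.
* **Dense weights.** The N×N kernel (8 MB at N = 1000) is built once per
  model and reused across trials; no sparsity machinery is warranted.

## What the generator does and does not emulate

All experiments run on synthetic stimuli drawn from the model's own noise
assumptions — Gaussian sensory scatter of the cue positions and
variance-equals-mean input noise. Passing tests therefore show that the
*network dynamics* reproduce the fusion/segregation statistics and bias
structure that these noise assumptions imply; they do not validate the noise
assumptions against physiology, cover temporal disparities, audibility/
visibility manipulations, or real psychophysical data (no fitting procedure
is included).

## Problem sizes

The packaged test suite uses 500 trials for the unity proportion at 5°
disparity, 120 trials per disparity for the conditional-bias checks, 60 for
the squared-normalization control, and 200 per disparity for the
curve-vs-closed-form comparison, with Monte-Carlo tolerances scaled as
1/√n; `scripts/acceptance.py` runs the full 500 trials per disparity
everywhere (a few minutes on one CPU).

## Known limitations

* The fixed 100-step horizon makes the magnitude of the segregated-class
  (negative) bias horizon-dependent; its sign and disparity ordering are
  robust.
* Bump detection assumes the smoothness of converged states; on raw noisy
  profiles with shoulders near the merge radius it can over-count.
* The observer-vs-network comparison is qualitative by construction: the
  two models' noise parameters are matched by role, not fitted.
* Edge effects appear if sources are placed within ~15° of the strip ends;
  the drivers refuse disparities that would do so symmetrically.
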