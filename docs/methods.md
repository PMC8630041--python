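# Methods

## The task and the model

The package simulates and analyzes a two-alternative contrast-detection
task. Two 4.8 × 4.8 deg fields of 16 vertical bars flank fixation; each
bar's contrast refreshes at 30 Hz as independent Gaussian noise with RMS
contrast 0.1, for 8000 ms. One field additionally carries a target whose
log10 contrast ramps linearly,

    log10 C_target(t) = min(α t − 3, 0),

with t the frame number (33.3 ms per unit) and α ∈ {0.05, 0.1, 0.2}: the
target starts at contrast 10⁻³ and saturates at 1 after 3/α frames. The
observer presses a button for the side containing the target; the
response-locked classification image (CI) is the map of noise weights
obtained by averaging the recorded noise contrast, separately for the
chosen and unchosen field, at each lag backward from the response:

    MeanKernel(x, ℓ) = μ₁(x, ℓ) − μ₀(x, ℓ).

The *impact curves* are this kernel averaged over the two central
(target) bars and over their two flanking bars.

The model observer has two stages.

**Perceptual front end** — a space–time separable linear filter
F(x,t) = F_s(x)·F_t(t), with a difference-of-Gaussians in space
(center width σ_c, surround width σ_s, surround weight σ_c²/σ_s², x in
0.04-deg pixels) and an n-stage biphasic impulse response in time,

    F_t(t) = (1/n! − B (t/τ)² / (n+2)!) (t/τ)ⁿ exp(−t/τ),

with t in frames. Each field's contrast movie (rasterized to the pixel
grid, bars spanning alternately 7 and 8 samples) is convolved with this
kernel, zero-padded in space and causal in time.

**Decision stage** — a leaky accumulator on the differential evidence

    ΔR(t) = Σ_x |R_left(x,t)| − Σ_x |R_right(x,t)|,
    S(T)  = Σ_{t≤T} (γ^{T−t} ΔR(t) + ε_t),

with ε_t ~ N(0, ε²). The first frame with S ≥ b is a "left" decision,
S ≤ −b "right"; the button press follows 250 ms later. As written, the
leak discounts the evidence term only and the internal noise accumulates
as an undiscounted random walk; a `leak_internal_noise` switch discounts
both (not the default).

## Parameters, units and defaults

| name | meaning | unit | default |
|---|---|---|---|
| σ_c | DoG center SD | 0.04-deg pixels | 4.15 |
| σ_s | DoG surround SD | pixels | 17.4 |
| n | temporal filter stages | — | 5 (never fitted) |
| τ | temporal time constant | frames (33.3 ms) | 1.360 |
| B | negative-phase amplitude ratio | — | 0.47 |
| γ | per-frame evidence retention | — | 0.046 |
| b | decision bound | evidence units | 496.5 |
| ε | internal noise SD per frame | evidence units | 49.6 |
| — | motor delay | ms | 250 |

The defaults are the fitted constants for this task. γ = 0.046 implies a
near-memoryless accumulator: the momentary evidence is essentially
ΔR(T) riding on the internal-noise random walk, which is what gives the
model its broad RT distributions.

**Input scale.** The filters in the two equations above carry no free
gain, so b and ε are only interpretable relative to a fixed input
normalization. The package feeds the stimulus to the filters in units of
the nominal noise RMS (`ModelParams.input_gain = 1/0.1 = 10`, i.e. the
noise enters as unit-variance deviates). This is the scale on which the
default b and ε produce task-appropriate behavior: with the slow ramp
the simulated mean RTs are ≈ 2140/1380/940 ms for α = 0.05/0.1/0.2
(decreasing in α), error rates 14/5/1 %, and essentially no timeouts.
On a raw-contrast scale (gain 1) the same constants leave the
accumulator dominated by its internal noise — chance-level choices and
no kernel structure — so unit-RMS input is treated as the model's
convention, not a tunable.

## Discretization and numerics

- Time is discretized at the 30 Hz noise refresh. Noise frames are
  zero-order-hold, so the discrete temporal weight at lag s is the
  window integral ∫_s^{s+1} F_t dt, evaluated in closed form with
  regularized incomplete gamma functions (pointwise sampling of F_t
  would retard the kernel by about half a frame). The kernel is
  truncated below 10⁻⁶ of its peak (~30 frames at default τ).
- Spatial convolution exploits that bar contrast is constant within a
  bar: filtering equals `W @ C` with a precomputed (120 × 16) weight
  matrix; this matches the direct rasterized convolution to float
  tolerance and is the batch simulator's fast path.
- Boundary crossing is detected on the frame grid, no sub-frame
  interpolation. A crossing while completing frame index k (0-based)
  gives RT = (k+1)·33.3 ms + 250 ms.
- Lag 0 of the response-locked kernel is the frame during which the
  crossing occurred; the lag axis is reported in ms as
  ℓ·33.3 + motor back-shift (default 250 ms), so simulated kernels
  share the axis of button-press-locked data.
- Kernel cells with fewer than `min_count` (default 10) contributing
  trials are reported missing (NaN), never zero; error and timeout
  trials are recorded but excluded by the analysis stage.
- Clipping of displayed contrast to [−1, 1] applies to the combined
  noise + target signal; the noise-only record used by the CI is kept
  pre-clip (clipping never fires on noise alone at 10σ).

## Simulation-based fitting

`CIObserverModel` holds target central/adjacent impact curves and a
fixed stimulus ensemble generated once from `sim_seed`; `objective()`
simulates that ensemble under a candidate parameter vector and returns
the squared error summed over both curves' unmasked lags. Because the
ensemble (stimulus and internal-noise streams) is frozen — common
random numbers — the objective is a deterministic function of the
parameters. Fitting is done on the α = 0.05 condition, with n fixed
to 5. Positive parameters are searched in log space, γ in logit space,
B linearly with a penalty below 0; infeasible vectors (σ_s ≤ σ_c)
return a large penalty instead of raising.

The optimizer is Nelder–Mead with multi-starts: each restart begins at
the base vector with every free parameter perturbed by an independent
U(0.5, 2) factor (so recovery runs never start at the truth), followed
by polish restarts from the best point whose initial simplexes step
20 % → 10 % → 5 %. The polish stage matters: crossing frames are
discrete, so the objective's valley floor is slightly rugged and a
default-size simplex can stall 20–35 % from the optimum.

**Parameter recovery.** `parameter_recovery` simulates a synthetic
experiment from known parameters, computes its impact curves, refits,
and reports per-parameter relative error. By default the refit shares
the stimulus ensemble with the synthetic experiment (matched seeds), so
the Monte-Carlo noise of the target curves cancels exactly against the
simulated curves and the objective's zero sits at the true parameters;
the check then isolates identifiability of the curve statistic and the
optimizer. This matters because the fully out-of-sample problem is
noise-limited at realistic sizes: with 2000 target trials the
impact-curve sampling error (~0.002 per point, against lobe amplitudes
of 0.003–0.005) displaces the objective minimum by ≥50 % along single
parameters, so out-of-sample tolerances at these sizes say more about
the noise than about the estimator. With matched seeds, the reduced
three-parameter recovery (σ_c, B, γ free; 2000 trials) returns σ_c and
B to within ~2 %. γ is different: the impact-curve statistic is nearly
degenerate along a curved (σ_c, B, γ) trade-off — a joint move of
(+1 %, −1 %, −41 %) costs only ~5·10⁻⁶ in summed squared error, and
the slight simulation ruggedness turns that trade-off surface into
separated local minima (Nelder–Mead, Powell and coordinate line
searches all terminate there). From impact curves at this problem
size, γ is recoverable only to roughly ±40 %; pinning it down would
require a statistic that weights recent-frame evidence differently,
such as jointly fitting the RT-split curves.

## What the simulated kernels show

On ≥ 10⁴ trials at α = 0.05 with the default parameters the central
impact curve is biphasic: a positive lobe peaking at 383 ms before the
button press and a negative lobe with its minimum near 600–650 ms (axis
includes the 250-ms motor back-shift). The flanking-bar curve is
center-reversed at the long-lag end and attenuated. Splitting trials by
RT within condition (overlapping 50 % windows: fastest half, middle
half, slowest half) reproduces the characteristic dependence: the
positive lobe is larger for short-RT trials, the negative lobe larger
for long-RT trials — fast decisions ride the filter's positive phase
before its negative phase can act, slow decisions accumulate the
negative phase while earlier evidence has leaked away.

These timings sit about one 33-ms bin later than the ~300 ms peak and
~500 ms trough reported for human observers in this paradigm. No
admissible reading of the printed model moved both features earlier:
the lag-axis convention is fixed, the input scale (above) does not
shift the timing by more than a bin, and alternative leak readings make
the trough later still. The residual lateness is consistent with the
original analysis pipeline having used a faster effective temporal
filter than Eq.-style F_t with τ = 1.36 at 33 ms per unit; the package
follows the printed specification and reports its own timings.

## The synthetic-data generator and its limits

The stimulus module *is* the data source: there are no deposited human
data, so every analysis here runs on model-generated trials whose
statistical structure (independent Gaussian bar noise, ramping target,
recorded noise/choice/RT triples, errors and timeouts flagged) mirrors
the experiment. What passing tests demonstrate is therefore internal
consistency — the estimators recover what the generator and observer
put in — not fidelity to human observers: the generator contains no
lapses, no RT-dependent criterion shifts, no spatial inhomogeneity of
attention, and a single fixed motor delay. Error rates at the slow ramp
(14 % at α = 0.05) exceed the human 3 %, since no parameter here was
refit to human data.

## Problem sizes used by the shipped checks

The acceptance script simulates 12 000 trials (in batches of 4000) for
the kernel timings, enough that each curve point's Monte-Carlo error
(~0.0008) resolves both lobes; the test suite uses 12 000 trials for
the kernel/RT-split checks, 2000-trial recovery with 2000-trial
objective ensembles, and 800 trials per condition for RT ordering.

## Known limitations

- b and ε are comparable across studies only under this package's
  input-scale convention.
- No likelihood-based (full RT distribution) fitting; no bootstrap
  uncertainty on fitted parameters (hooks exist in the results object).
- The variance (second-moment) kernel is provided but, as with the
  mean kernel's source experiment, shows no clear structure under this
  generator.
- Across-observer averaging is a plain unweighted mean with
  across-observer SE.
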