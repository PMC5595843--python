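# Methods

## Network model

The model is a feed-forward, two-layer description of one orientation
hypercolumn and its surround. First-layer ("simple") cells are tuned
separably to orientation, spatial frequency and contrast; their rates drive
a second layer through iso-feature Gaussian weights — excitation from
within the hypercolumn, inhibition pooled from `n_s = 6` surrounding
hypercolumns that all see the same (uniform) surround stimulus. The
second-layer membrane follows a conductance-based equation whose steady
state, `v = (v_e g_e + v_i g_i)/(1 + g_e + g_i)`, is used directly; the
time constant `τ` is retained only so tests can verify that forward
integration of the dynamics converges to the same fixed point. Rates are
rectified-linear above the threshold `T`. There are no recurrent loops: the
surround influences the centre in one pass.

Fixed constants (`v1_core.FixedParams`): `n_s = 6`, `n = 2`, `A = 2`,
`σ_SF = 1` octave, `m = 1`, `T = 1`, `I_c = 1`, `v_e = 14/3`,
`v_i = −2/3`. Feature grids: preferred orientations every 2° over one 180°
period; preferred SFs every ¼ octave from 0.5 to 64 c/d; contrast
semi-saturations log-spaced, with neurons above `c_k = 1000` pruned (they
cannot reach half their asymptote at any physical contrast).

### Orientation dimension

Orientation tuning is a wrapped Gaussian (period 180°, five wrap images,
truncation error < 1e−12 for widths up to 40°), normalised to 1 at the
preferred orientation. Connection widths are entangled with the tuning
widths and fixed at half of them (`σ_θ^{c,s} = σ_θ/2`). Connection weights
carry unit mass over the orientation circle, so the conductance driven by a
Gaussian population profile is the Gaussian convolution

    g ∝ (σ_θ / √(σ_θ² + (σ_θ/2)²)) · exp(−½ Δ² / (σ_θ² + (σ_θ/2)²)),

which the package evaluates both in closed form and by direct grid
summation; the two agree to ~1e−14 relative error because the trapezoid sum
of a smooth periodic function is spectrally exact. The closed form is the
default inside fitting loops (it is ~100× cheaper).

### SF dimension and contrast

The first-layer SF tuning width shrinks with preferred SF as
`σ_SF(f_j) = exp(−(f_j − 2)/0.2)` octaves. Taken literally this decays
extremely fast — by 4 c/d the width is ~5·10⁻⁵ octaves, far below any
practical grid spacing — so the SF-dimension drive is computed with the
same continuous Gaussian-convolution expression as the orientation
dimension rather than a grid sum (a discrete sum is meaningless below the
grid scale). Because connection and tuning widths scale together
(`σ_SF^{c,s} = σ_SF/2`), the convolution factor at the preferred SF is the
scale-free constant `2/√5`, which keeps the detection pathway well defined
at every SF. The contrast dimension collapses into the input amplitude:
`A_{c,s} = A · C_norm(c; c_k)` with the normalised hyperbolic ratio (equal
to 1 at full contrast). For the tilt configuration (both gratings at ~full
contrast) this is simply `A = 2`.

Because the normalised hyperbolic ratio no longer reaches half-maximum at
`c_k` itself, the half-amplitude contrast is recomputed as
`c_½^n = c_k^n / (1 + 2 c_k^n)`; the package exposes this and tests the
identity to 1e−9.

## Tilt decoding and the bias convention

Perceived orientation is the vector average of second-layer rates on
doubled angles (the only rotation-equivariant mean for an axial variable);
raw rates are used as weights, not baseline-subtracted ones. The reported
bias is the *perceived vertical*: `bias(SO) = −decode(θ_c = 0, θ_s = SO)`,
which is positive toward the surround in the direct-repulsion range and
antisymmetric in SO by the reflection symmetry of the network. A
first-order approximation (`decode` evaluated at a vertical target rather
than root-solving for the orientation that decodes to zero) is used; the
psychometric midpoint inherits this value. Surrounds at ±75° engage the
indirect effect, which this V1-level model does not capture; they are
excluded from all model fitting.

## Detection noise model

The decision variable at each SF is the rate of the neuron preferring the
stimulus SF with the best semi-saturation constant `c_k^min(f)`; the
no-signal rate is zero (the network is subthreshold at zero contrast).
Rate variance is Poisson-like with a spontaneous floor, divided by a
population pooling factor:

    Var(R) = (R + r0) / n_pool,      r0 = 1,  n_pool = 50 (config keys
    detection.r0_floor, detection.n_pool)

The pooling factor reflects that a spatially extended grating is detected
by many statistically independent neurons across the hypercolumns it
covers, not by a single cell. It also sets the model's operating range:
with `n_pool = 1` the two-interval midpoint requires `d′ ≈ 0.95`, i.e. a
single-neuron rate of ~1.9 against a rectified maximum of ~2.0, so the CSF
would be unmeasurable for any inhibition strong enough to produce
degree-scale tilt biases. With `n_pool = 50` the CSF stays measurable up to
`I_inh ≈ 0.25` with peak sensitivities in the behavioural range (≈ 45–100),
which is the regime the two-stage fit needs. Threshold contrast is found by
bisection on log10-contrast (tolerance 1e−4 log units); SFs whose midpoint
is unreachable at full contrast are reported as not measurable (NaN
sensitivity) rather than extrapolated.

## Descriptive fits and the 3-key design

Detection sessions use three keys (interval 1 / interval 2 / undecided).
The guess rate is never fitted: it comes from the session's third-key
proportion via `γ = max(0, (1 − p3/0.7)/2)` — 50% for a subject who never
declares indecision, lower with heavier usage. In the likelihood, undecided
trials contribute half a correct and half an incorrect pseudo-trial (their
primary information, the guess rate, enters through `p3`); this treatment
is isolated in one function (`psychofit.undecided_loglik_weights`) so it
can be swapped. Tilt sessions use clockwise / counter-clockwise / not-seen
keys; not-seen trials are removed before fitting and summarised separately
as the surround-suppression proportion, pooled over opposite surrounds
(with a 1/120 guard when logit-transforming proportions). Thresholds of
opposite surrounds are tied, and bias summaries use the half-difference
between opposite surrounds, which cancels any constant response bias.

All psychometric functions share the logistic slope factor `log(21/4)`, so
that one spread unit above the midpoint lies at exactly `21/25 = 84%` of
the range — the 16–84% spread convention. Lapse rates are fixed at 1%.

Fitting is bounded maximum likelihood (flat-prior MAP over configurable
boxes), optimised by deterministic multi-start Nelder-Mead through a
sigmoid box transform, so refits of permuted data are identical up to
floating-point summation order. The model stages start from a 3×3×3 coarse
grid and run the simplex from the best three corners. Search boxes:
`I_inh ∈ [0, 5]`, `σ_θ ∈ [2°, 60°]`, `c_min ∈ [1e−4, 1]`, `a ∈ [0.1, 5]`,
`b ∈ [0.2, 32]`. `−log(ML)` is reported at the point estimate with no
complexity penalty.

## Simulated observers and staircases

The staircase engine implements the weighted up-down rule: level moves
down by `down_step` after the tracked response, up by `up_step` otherwise,
converging where `p = up/(up + down)`. Tilt blocks run two strictly
alternating tracks per surround (Up/Down 2/5 and 5/2 degrees, tracking
~29% and ~71% clockwise), 30 trials each over seven surrounds
(0, ±15, ±30, ±75) — 420 trials; each track starts 10° on the far side of
its convergence point. Detection sessions run one staircase per SF over the
standard 11-SF ladder (0.71–22.63 c/d), 15 trials each (165 total), with
steps of 4.5/8 (even-indexed SFs) or 1.5/7 (odd-indexed) times the base
10%-contrast log-unit (`log10(1.1)`), a 3× down-step boost on the first
four trials, and the listed alternating high/low start contrasts.
Third-key presses are scored at random for the staircase update (as the
protocol prescribes) but recorded as undecided/not-seen.

Observer response generation layers lapse, seen, and guess states; the
undecided-key propensity in the guess state (`key3_rate`, drawn from
[0.4, 0.9] in cohorts) reproduces realistic session-level third-key
proportions (~0.5). Surround suppression is emulated by a separable field,
maximal for iso-oriented surrounds and rising with SF. Cohorts draw AE eyes
with broad orientation tuning (σ_θ ~ N(24°, 4°)) versus NAE/NTE
(~N(14°, 2.5°)); amblyopes' eyes span `I_inh ∈ [0.03, 0.20]` — which
*mechanically* anti-correlates their generated low-SF sensitivity with
inhibition through the CSF model — while NTE sensitivity differences are
driven by `c_min ∈ [0.012, 0.05]` at mild inhibition. These regimes are the
package's study conditions; every random draw flows from one seeded
generator per session and is logged, so sessions are byte-identical under a
fixed seed.

What the generator does *not* emulate: learning and fatigue across blocks,
reaction times, eye movements, crowding, second-order stimuli, and the
indirect (±75°) tilt effect as a genuine perceptual process (model-based
observers simply extend the model's bias curve there). Passing recovery
tests therefore demonstrates internal consistency of the pipeline under
the stated generative assumptions, not validity of those assumptions for
real observers.

## Numerical notes

* Staircase convergence probes evaluate the observer's probability at the
  mean converged level; the probe observer's spread (25°) is deliberately
  wide relative to the steps, otherwise the skewed stationary level
  distribution Jensen-biases that readout below the tracked point.
* Decoding an all-zero or resultant-free population raises an error;
  fitting objectives translate this into a large penalty (it occurs only
  when inhibition silences the population at implausible parameter
  corners).
* Grid edges: orientations live on [−90°, +88°] inclusive; decoded angles
  are reported in (−90°, +90°].
* Recovery at the protocol's session sizes (one 420-trial tilt block):
  median σ_θ error is below 15%; single sessions can miss by more —
  `I_inh` and `σ_θ` trade off through the bias curve and are only fully
  separated by multi-session or noise-free data (the self-consistency test
  recovers both within 5% from exact probabilities).

## Known limitations

* The model is purely feed-forward; recurrent surround dynamics,
  contrast-dependent surround modulation, and any indirect tilt effect are
  out of scope.
* The closed-form conductance is implemented for the orientation-only
  (tilt) configuration; the SF pathway uses the continuous convolution
  factor rather than a printed closed form whose constants do not scale to
  the literal SF-width rule.
* `n_pool` and `r0` are effective noise parameters, not measured
  quantities; conclusions about absolute sensitivity scale depend on them
  (relative comparisons across eyes do not, as all eyes share them).
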