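# Methods

## The dual-horizon model

The simulator formalises a mechanistic account of abnormal aspect-ratio
(spatial-relationship) perception in cyclotorted eyes. Its assumptions, in
the order the pipeline applies them:

1. **Stimulus geometry.** The distal stimulus is an axis-aligned ellipse
   whose eccentricity is the signed percent interaxis ratio
   IR = 100·(f_x − f_y)/max(f_x, f_y). "Size" is operationalised as the
   arithmetic mean of the two full axes, held at 300 arcmin for every IR
   level; this keeps overall extent nearly constant and makes the IR → axes
   map uniquely invertible. (Alternative readings of "size" — area-equivalent
   diameter, the long axis — would change the axes by < 1% at threshold-level
   IR and nothing qualitative.)
2. **Retinal encoding.** The proximal stimulus is represented by 360
   boundary detectors at uniformly spaced elevations (1° spacing). Each
   detector carries antagonistic coding weights for the two cortical pools
   that analyse aspect ratio: s_v = |sin φ_r|, s_h = |cos φ_r|, with φ_r the
   detector's angle from the *retinal* horizon. Sinusoidal projection
   weights are the minimal form whose radius-weighted sums track the
   stimulus's vertical/horizontal extents.
3. **Torsion.** A torsion of λ degrees (positive = incyclotorsion, right-eye
   convention) rotates spatial coordinates into the retinal frame by −λ and
   adds a signed offset V_λ = gain·λ to every detector's V weight (clipped
   at zero). The two hemiretinal sign rules — upward shift of the retinal
   horizon on the temporal side equals downward shift on the nasal side —
   collapse to this single signed scalar. V_λ is linear in λ: the minimal
   reading of "proportional", and the one that makes the cohort prediction
   monotone. An `offset_mode="symmetric"` variant subtracts V_λ from the H
   weights as well (the "hyperactivation of the H-pool" description); the
   two modes agree to first order in V_λ, and the symmetric mode satisfies
   the exact mirror identity perceived(IR, −λ) = −perceived(−IR, +λ).
4. **Readout.** The percept inverts the *untorted* encoder: a strictly
   monotone map from log(H/V) to IR, built once at λ = 0 over IR ∈ [−60, 60]
   in 0.1 steps (monotone PCHIP interpolation). Isotropy at zero torsion
   therefore holds by construction, and torsion effects are deviations from
   a verified baseline. A normal baseline anisotropy (slightly better
   vertical discrimination in healthy observers) is not modelled by default;
   its magnitude is unknown and it would only add a constant offset to the
   criterion of one axis.
5. **Decision.** The observer adds zero-mean Gaussian noise (σ) to the
   percept and answers circle / horizontal / vertical with a symmetric
   circle band of half-width *criterion*; boundary ties are "circle". No
   lapse rate by default (configurable). The closed-form category
   probabilities are one-dimensional normal tail integrals, which gives an
   analytic threshold oracle by root-bracketing.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| stimulus size | 300 | arcmin | task definition; constant across IR |
| n_detectors | 360 | – | 1° spacing; percept changes < 1e-4 IR% on doubling |
| σ (noise) | 2 | IR% | places untorted thresholds in the single digits |
| criterion | 3 | IR% | untorted 50% threshold = criterion exactly |
| V_λ gain | 0.0017 | per degree | see below |
| torsion range | −2.5 … +2.0 | degrees | the clinical range the cohort emulates |
| cohort size | 9 | subjects | the small-sample design under study |
| observer jitter | 0.2 / 0.2 | IR% (SD of σ, criterion) | between-subject variability |

**The gain is the model's one free parameter.** The calibrated readout is
steep — ≈ 300 IR% per unit of log pool ratio near the circle — so small
pool imbalances produce large percept shifts. The default 0.0017/deg yields
a percept sensitivity of ≈ 0.8 IR% per degree of torsion, which (i) keeps
the horizontal threshold positive and in the low single digits
(≈ 1.0 → 4.6 IR%) across the ±2.5° clinical range, consistent with a
*slight* threshold elevation rather than frank blindness to horizontal
eccentricity, and (ii) keeps the effect resolvable by a staircase whose
final step is 1 IR%. At the 50% performance level the analytic horizontal
threshold is simply criterion + 0.8·λ.

## Staircase design

The 4-2-1 procedure tracks |IR| of one axis with a one-down/one-up rule, so
it converges on the 50% point of P(correct). Steps shrink 4 → 2 → 1 IR%
after every 2 reversals; levels are clipped to [0.25, 60] IR%. The run
terminates after 16 reversals (or 120 trials, flagged unconverged — in
practice runs take ~35 trials) and the estimate is the mean of the last 10
reversal levels. These termination choices were set by validating the
estimator against the analytic oracle: the suprathreshold start (12 IR%)
leaves a decaying transient over roughly the first six reversals, so
averaging windows that reach into them inherit a +0.4…+1 IR% bias, while
the last 10 of 16 reversals are all post-transient and balanced between
tops and bottoms (residual bias ≤ 0.1 IR% away from the level floor, ≈ +0.4
IR% in the worst case where the true threshold approaches the floor). The
independent constant-stimuli oracle fits a cumulative-normal psychometric
function by probit maximum likelihood; under this observer model
P(correct | level) is *exactly* cumulative normal at λ = 0, so the fit and
the closed form agree to sampling error.

## Numerical choices

- **Arc-averaged pool weights.** Each detector stands for a 1° arc of the
  boundary; its weight is the mean of the clipped SR value over that arc
  (16 midpoint subsamples). Point evaluation would let the zero-clipping
  kink near the horizon alias against the detector grid, making pool sums
  (and, after the ×300 readout slope, percepts) sensitive to detector count
  at the 1e-3 IR% level; arc averaging reduces this to < 1e-4 IR%.
- **Calibration interpolation** is monotone cubic (PCHIP) with linear tail
  extrapolation; strict monotonicity of the grid is asserted at build time.
- **Tie-breaks.** A percept exactly at ±criterion is "circle"; a detector
  exactly on the vertical midline is "temporal".
- **Degenerate inputs** raise typed errors: non-positive axes, |IR| ≥ 100,
  fewer than 8 detectors, negative gain, |λ| > 15°, a silenced H pool,
  non-monotone calibration, unreachable performance targets, constant-input
  correlations, cohorts smaller than 3.
- **Seeding.** Every stochastic entry point takes an explicit
  `numpy.random.Generator` or integer seed. The cohort driver fans a master
  seed out as `default_rng([seed, subject, eye, axis])`, so any single
  staircase is replayable in isolation; the trial log doubles as an audit
  record that `replay_staircase` can re-derive from the response sequence.

## What the synthetic cohort does and does not emulate

The generator reproduces the *design* of the motivating study: nine
subjects, one torted eye each with torsion uniform over −2.5…+2°, fellow
eye untorted, horizontal and vertical thresholds per eye, and a Pearson
correlation (exact t-transform p, n−2 df) between affected-eye torsion and
affected-eye horizontal threshold, with the fellow eye as the built-in null.
Between-subject variability is a small additive jitter on σ and criterion
(SD 0.2 IR%, truncated at 0.5); real observers differ in many more ways
(acuity, attention, fixation stability, torsion measurement error), none of
which are modelled. Passing tests therefore show that the *pipeline*
recovers the associations its own generative model implies — a strong
affected-eye correlation (median r ≈ 0.85 at the default design) and a
nominal 5% false-positive rate when the causal gain is silenced — not that
any particular clinical r value is reproduced. Individual patient torsions
and thresholds from the original sample are published only as a figure and
are not machine-readable, so no fit to real data ships with the package
(the `measure_cohort`/`pearson` hooks accept external values).

## Known limitations

- Three-dimensional ocular kinematics (Listing's law), vergence, head tilt
  and fixational torsion drift are outside the frame model; λ is a single
  static angle.
- Luminance, contrast, spatial-frequency content and the 200 ms
  presentation are not rendered; the model starts at the boundary-detector
  abstraction.
- The signed-λ convention (positive = incyclotorsion, right eye) is a
  documented choice; the physiological predictions fix the behaviour, not
  the label, and a sign flip is a one-line config change.
- The correlation is computed on signed torsion against the signed-axis
  threshold by default; an absolute-torsion variant is exposed
  (`use_abs_torsion`) because figure-level data cannot settle which the
  original analysis used.
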