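# Methods

## Geometry

Targets are positions on the horizontal midline, so a pixel offset `d`
from screen center subtends `atan(d · pitch / D)` degrees, not the
`2·atan(d/2D)` subtense of an extent; at the magnitudes involved the two
differ by < 0.01°. Square pixels are assumed, so the pitch follows from
the diagonal and the pixel aspect ratio:
`pitch = 584.2 mm · (16/√337) / 1920 ≈ 0.2652 mm/px`, giving
100 px ≈ 2.337° at 650 mm viewing distance. `degree_to_pixel` is the
exact inverse; positions beyond the panel's horizontal edge trigger a
warning rather than an error, since off-screen coordinates can legally
appear in intermediate computation.

The six trial intervals (1500/200/1300/1500/2500/700 ms) sum to 7700 ms;
40 trials make a 308 s ≈ 5.1 min session. Schedules are uniform shuffles
of the 10-per-position multiset under a caller-supplied seed, with no
run-length constraint.

## Synthetic gaze model

The generator produces the *conditions the pipeline is specified for*:
250 Hz binocular recordings of the 40-trial paradigm with known per-trial
ground truth.

**Saccade kinematics.** Position follows a minimum-jerk profile
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`. A strict minimum-jerk movement of amplitude
`A` and duration `D` peaks at `1.875·A/D`, which cannot simultaneously
satisfy both classical main-sequence rules (duration `2.2A + 21` ms and
peak `V_max(1 − e^{−A/c})`). We therefore keep the shape and set
`D = max(2.2A + 21, 1.875A/V_peak)`: the waveform's true peak is the
main-sequence value whenever that branch binds (it does at all paradigm
amplitudes for the defaults `V_max = 500 °/s`, `c = 14°`), and the
duration rule acts as a floor for fast parameterisations. Time-to-peak is
`D/2` by symmetry. Amplitudes under 0.1° are rejected as sub-resolution.

**Trial structure.** Outcomes are drawn per trial from the profile's
(early, late, omission) probabilities, remainder = correct. Correct
trials: MGS latency ~ Normal truncated to [80, 1200] ms, amplitude =
gain × eccentricity with gain ~ Normal truncated to [0.2, 1.5]; a
corrective VGS onto the target is made in the confirmation interval when
the MGS misses by ≥ 0.1°; gaze returns to center 120 ms into the
intertrial blank. Error trials break fixation with a 3–8° saccade to a
random side, onset drawn 90–270 ms (early) or 340–1250 ms (late) after
flash onset, returning to center 500 ms later. The margins around the
300 ms early/late boundary are a realism choice — human fixation breaks
are not timed to the millisecond — and they keep ground-truth labels
well-defined under the ±(sample period + half window) onset jitter any
velocity-threshold detector exhibits.

**Noise.** Per-eye fixation noise is stationary AR(1) Gaussian noise with
a 100 ms time constant, scaled to the requested marginal SD. White noise
at a 0.3° marginal SD would imply a windowed-velocity noise SD of
~15 °/s and a ~13 % spurious crossing rate of the 30 °/s threshold —
behaviour no video eye tracker shows, because tracker error is dominated
by slow drift. The AR(1) model reproduces the realistic decomposition:
0.3° marginal SD with ~0.08° sample-to-sample jitter. The two eyes are
the cyclopean signal displaced ±half the interocular offset; blinks are
uniform-onset runs of binocular invalid samples (the pipeline consumes
only validity semantics, so no vertical blink artifact is modelled).

**Cohorts.** Covariates use plausible marginals for a post-stroke cohort
(age ~ Normal(59.9, 10.9) truncated to 18–80, 77 % male, MoCA ~ 24 ± 3,
HADS subscales ~ 6–7 ± 3, log-normal Color-Trails times, etc.). Target
Spearman correlations between covariates and subject-level *generating*
parameters (error probabilities, latency means, gain, omission) are
induced by a Gaussian copula (latent Pearson `2 sin(πρ/6)`), so any
downstream recovery is a genuine end-to-end test rather than a tautology;
infeasible (non-PSD) matrices are rejected. Defaults couple age to late
errors (ρ = 0.327) and omissions (0.274) and anxiety to early errors
(0.325). An alternative linear mode sets the late-error probability (in
percent) to `30 + slope·(age − 60) + N(0, 5)`, clipped to [0.5, 70], for
regression-recovery experiments with a defined true slope. With
`signals=False` the generator stops at per-trial outcome draws and
returns the five session rates directly — the behavioural level, used
for statistical calibration at scale.

**What the generator does not emulate:** smooth pursuit, vertical or
oblique saccades, glissades/post-saccadic oscillations, pupil dynamics,
head motion, calibration drift, and saccade curvature. Passing recovery
tests therefore demonstrate correctness of the *pipeline logic* under the
stated signal model, not robustness to every artifact of real recordings.

## Preprocessing and event detection

Gap fill interpolates per-eye invalid runs of ≤ 75 ms linearly when both
flanks are valid; edge runs and longer runs stay gaps; the operation is
idempotent, and interpolated samples count as valid downstream (that is
the purpose of gap fill). Eye averaging takes the binocular mean, falls
back to the single valid eye, and marks samples with neither eye invalid;
no smoothing is applied. Windowed velocity over 20 ms uses endpoints
`i − ⌊w/2⌋` and `i + ⌈w/2⌉` (w = 5 samples at 250 Hz), so the span is
exactly the window; the angle between endpoints is the Euclidean distance
in (x°, y°), which differs negligibly from the exact visual angle below
20°. Velocity is undefined where any sample in the span is invalid or out
of range — such samples terminate events without joining any.

I-VT uses an **inclusive** threshold (samples at exactly 30 °/s are
saccadic); saccade offset is one sample period after the last
above-threshold sample, the end position is the sample at offset time
when valid. Fixation merging iterates left-to-right until stable, measures
separation offset-to-onset, absorbs intervening short saccades/gaps, and
weights merged centroids by duration. The 60 ms minimum fixation bound is
inclusive (a 60 ms fixation is kept); shorter fixations are relabelled
`unknown` rather than deleted so the timeline stays complete.

A note on units: velocities are canonically °/s; the literal °/ms
convention some vendor exports use is available as `velocity_deg_ms`
(× 10⁻³).

## Trial layer

The pre-flash check is applied over the full window
`[flash − 60 ms, flash)` rather than the single instant 60 ms before
flash — more robust, and it contains the instant. The error window ends
with the memorization phase (flash + 1500 ms), and the early/late
boundary is early ⇔ onset ≤ 300 ms (configurable). The MGS must head
toward the cued side — a movement away from the cue is not a saccade
"toward the remembered location" — but the requirement can be switched
off. Error saccades carry no clean-history or start-position requirement
(they are fixation breaks, not analysed saccades); only the 1° amplitude
floor applies, to avoid counting noise. VGS latency is anchored at
confirmation-dot onset. Mean velocity is the mean of per-sample windowed
velocities across the event (an amplitude/duration variant would be a
one-line change but is not exposed).

Rate denominators are deliberately asymmetric, following the indicator
definitions: %MGS is referred to **all session trials**, the other four
rates to **valid trials**; %TotalErrorRate = %EarlyErrorRate +
%LateErrorRate holds exactly by construction. Summaries flag subjects
with fewer than 7 valid trials as unusable; with zero valid trials the
valid-denominator rates are NaN. Near/far SDs are sample SDs (n − 1).

## Statistics

Spearman p-values use the t approximation on n − 2 df (scipy); pairwise
deletion for correlations, listwise for the regression — matching common
practice and keeping a 62-subject, 7-predictor design on (7, 54) df. No
multiplicity correction is applied by default (raw p at α = 0.05), with a
Benjamini–Hochberg switch. Gender is coded 0 = female, 1 = male so a
positive coefficient means a higher male rate. VIF is computed from
`1/(1 − R²_j)` directly so perfect collinearity can be reported as a
flagged infinity; rank-deficient designs are rejected with the offending
predictor named. Diagnostics: Breusch–Pagan (homoscedasticity),
Jarque–Bera (residual normality), Durbin–Watson (independence, flagged
outside [1.5, 2.5]), and a linearity heuristic testing the correlation of
residuals with squared fitted values.

## I/O and determinism

Timestamps are integer microseconds internally (exact at 4 ms steps),
milliseconds at all interfaces. The gaze TSV dialect writes positions
with 4 decimals, validity as 0/1, and empty fields for missing positions;
reading a canonical file and rewriting it is byte-identical. Beyond the
spec'd columns the dialect carries `target_side`/`target_ecc_deg` per
sample, so a file is self-describing — the trial layer needs the target
position and a sidecar schedule file would be a second point of failure;
a caller-supplied schedule remains supported. The whole chain is
deterministic under a fixed seed.

## Problem sizes

The validation experiments use sizes chosen to give tight sampling bands
at interactive runtimes: 5 noise-free and 10 noisy sessions (200/400
trials) for label recovery, 25 sessions (1000 trials) for rate recovery
against the binomial 95 % band, n = 200 subjects for slope/correlation
recovery, and 200 cohorts × 25 covariate-metric pairs (5000 tests) for
the null calibration of the α = 0.05 rejection rate.

## Known limitations

- The I-VT onset estimate is biased early by up to half the velocity
  window; latencies inherit a ~10 ms systematic underestimate relative to
  the physical movement onset. All comparisons in the package are
  internally consistent, but absolute latencies should be interpreted
  with this in mind.
- The 20 ms windowed peak velocity underestimates the waveform peak by
  ~5 % for a 10° minimum-jerk saccade (window-averaging bias); the
  detector is compared against a dense-grid *windowed* oracle, not the
  raw analytic peak.
- Corrective saccades near the 1° amplitude floor sit close to the 30 °/s
  detection limit; %CorrVGS is conservative for subjects with gain ≈ 1.
- The copula induces rank correlations on generating parameters; the
  observed-rate correlations are attenuated by binomial trial noise
  (40 trials/subject), so recovered ρ is expected somewhat below target.
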