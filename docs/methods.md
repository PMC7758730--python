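# Methods

This note records the modeling assumptions, parameter choices, and numerical
decisions behind `wfstate`, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The compressed representation

Movies are stored as a truncated SVD `S ≈ U V` with `U` orthonormal
(pixels × k) and `V` singular-value-scaled (k × time), so `Uₙ · V` is
directly the fluorescence of pixel *n*. We keep `V = Λ Bᵀ` rather than
unit-norm right singular vectors so that spectral formulas written on pixel
traces transfer verbatim to the compressed domain. Truncation defaults to
k = 500 (capped at matrix rank); the sign ambiguity of each component is
fixed by forcing its largest-magnitude spatial entry positive. Coordinates
are 0-based `(row, col)` with row-major flattening, and every window/slice in
the package is half-open `[start, end)`.

No mean-centering is applied before the decomposition. Whether to center is
genuinely open; not centering keeps `U V` an exact movie reconstruction and
leaves DC power in the 0 Hz bin, where the band selection never looks.
Centered analysis can be had by subtracting a baseline upstream.

## Spectra and band power

Component spectra are one-sided discrete Fourier transforms scaled so that
`Σ_ω |V̂ᵢ(ω)|² = Σ_t Vᵢ(t)²` exactly (power, not density). Band power sums
the bins with `low ≤ f ≤ high` inclusive — with 0.7–2 s quiescent windows the
bin spacing is 0.5–1.4 Hz, so edge-bin membership materially matters; a
tolerance of 10⁻⁶ bin spacings absorbs floating-point error in the estimated
frame rate. Defaults: rectangular taper (a Hann taper is available by flag)
and no zero padding, because the short quiescent windows leave no spectral
resolution to spare (this is also why the state band starts at 3 Hz). Band
sums are comparable across windows only at equal window length; the trialwise
analyses therefore always compare distributions over trials, and the
cross-session quantity is power in dB relative to the session mean.

The per-pixel band-power map is assembled as `P = rowwise(U · C · Uᵀ)` with
`C = Σ_band V̂ V̂ᴴ`, costing `O(k²·bins + pixels·k²)` and bounded memory; the
test suite checks exact agreement (1e-8 relative) with a dense per-pixel
periodogram at full rank.

Difference maps are `10·log₁₀(P_a/P_b)` with two masks: pixels below the
20th percentile of time-averaged power (blanks pixels outside the brain),
and zero-denominator pixels (flagged, never infinite).

## Hemodynamic correction

The correction subtracts a per-pixel multiple of the raw calcium-independent
signal; the filtering (linear detrend → 4th-order zero-phase Butterworth
high-pass at 0.01 Hz → 4th-order zero-phase band-pass at 9–13 Hz) exists
only to *estimate* the multiple where the artifact dominates. No intercept is
fit: both signals are detrended and high-passed, so their means vanish. The
regression is assembled from k×k component cross-products.

Channel alignment deserves a note. With alternate-frame illumination the two
channels share one frame rate and differ by a constant half-frame delay.
Linear interpolation of the hemodynamic channel onto the calcium clock
attenuates a band at frequency *f* by `cos(π f / fs)` — about 0.55 at 11 Hz
and 35 Hz frames — which inflates the estimated gains by its inverse (≈1.8×).
We therefore align by an exact Fourier fractional-delay shift whenever the
clocks are a constant offset apart, and fall back to linear interpolation
otherwise. With this alignment the injected gain maps are recovered with
r > 0.999 and slope ≈ 0.998.

Sessions recorded without a hemodynamic channel pass through unchanged and
are tagged `uncorrected`.

## Behavior and state tables

Trial classes: Correct/Incorrect Choice (wheel response inside the response
window), Miss (no response when a stimulus required one), Correct
Reject/False Alarm (zero-contrast trials). Responses recorded outside the
response window mark the trial invalid (flagged and excluded, never silently
fixed). State is measured strictly within the enforced quiescent window;
windows shorter than 0.7 s are excluded (exactly 0.7 s is included), and the
per-session accounting `included + excluded + invalid = raw` is asserted on
every table build. Post-outcome analyses reuse the same machinery on the
following trial's quiescent window via a trial-lag parameter.

Percentile curves use distribution percentiles of the session's trial powers
(linear interpolation between order statistics), with bins
`[0,20), [20,40), [40,60), [60,80), [80,100]`; a fraction-of-maximum variant
is available behind a flag. Rates within each bin are complementary by
construction (`%Choice + %Miss = 100` over stimulus trials, etc.) and that
invariant is checked on every call. Equal-contrast trials are excluded from
the Correct-vs-Incorrect comparison because the task rewards them at random.

Reaction times (go cue → response) are residualized per contrast pair before
correlating with power. The pupil ANCOVA fits one common slope and
per-condition intercepts; the condition effect is the intercept difference,
with its OLS standard error and t-test p-value.

### Mixed models

The population claims are fitted as nested mixed models: fixed condition and
area effects, with area-dependent random offsets for genotype, subject within
genotype, and session within subject. `statsmodels`' `MixedLM` cannot fit
three nested levels of unstructured area covariances, so each level enters as
an independent variance component (one variance per level × area cell) under
a single top-level group, fitted by maximum likelihood. The contract kept is
the fixed-effect structure and a calibrated condition test: on null
simulations with random genotype/subject/session offsets, the condition
effect is declared significant in ≈5% of runs (recomputed by the acceptance
script). With a single session the random effects are unidentifiable and the
fit collapses, exactly, to OLS of `power ~ cond + area`.

The percentile–behavior model (`response ~ 1 + powerPercentile +
(1|session)`, logistic link) is fitted with the variational Bayes mixed GLM;
slope, CI, and p derive from the posterior mean and SD, and complete
separation is reported explicitly.

## Electrophysiology

MUA is histogrammed at 35 Hz and smoothed with a normalized Gaussian window
(SD 25 ms by default; unconstrained by any stated value, configurable). The
smoothing uses a circular boundary so the kernel mass stays inside the trace
and the mean rate is preserved exactly; pre-smoothing counts conserve the
total spike count.

Fano factors are computed per trial as `F = var(X)/mean(X)` with the sample
variance (n−1), over population counts in 1/35 s sub-bins tiling the
quiescent window. The ensemble over which the variance is taken is genuinely
ambiguous; sub-bin tiling within the trial makes F a per-trial quantity that
rises with within-trial rate fluctuations (the synchronization signature) and
equals 1 for Poisson spiking — both properties are tested.

Coherence is Welch magnitude-squared coherence (Hann, 50% overlap); its bias
floor for independent signals is ≈1/n_segments, and estimates are clipped to
[0, 1]. The light-artifact cleaner aligns LFP segments at pulse onsets,
subtracts the pre-onset baseline, builds a running median over 500 pulses as
the template, and subtracts it; overlapping segments are truncated with a
warning. The spike-prediction filter is a ridge regression from lagged
temporal components to the MUA rate (penalty chosen on a log-spaced grid by
contiguous-fold cross-validation), reported as a rank-1 spatial map ×
temporal kernel factorization plus the cross-validated prediction
correlation; a `max_components` cap bounds the design matrix on long
sessions.

## Decoding

Population vectors are spike counts per unit in a 100 ms window (50–150 ms
post-stimulus). Before any two conditions are compared, trial counts are
equalized per contrast level by seeded random subsampling of the larger
condition (levels missing from either condition are dropped and logged), and
the per-contrast balance is asserted after the fact. The decoder is
L2-penalized logistic regression, stratified 5-fold CV, with the penalty
chosen by inner CV on a fixed log-spaced grid; accuracy is the headline
number and log-loss is reported alongside. Median state splits assign trials
strictly below/above the median and exclude ties, keeping "below and above
the median" literal.

## The synthetic session generator

The generator is first-class, tested code that defines the study conditions:

- **Timing.** 35 Hz per channel, clocks offset by half a frame period;
  pre-quiescent baseline 0.5–3 s plus quiescence 0.5–2 s uniform (total 1–5 s
  baseline); go cue 0.3–0.8 s post-stimulus; response window 1.5–5 s;
  contrasts {0, 25, 50, 100}%.
- **Latent state.** A lag-1 autoregressive sequence across trials (default
  coefficient 0.8, unit marginal variance), held constant within each trial —
  per-trial constancy keeps recovery tests unambiguous.
- **State → power.** The 3–6 Hz component is narrowband-filtered Gaussian
  noise (irregular and rhythmic, avoiding pure-tone leakage artifacts) whose
  per-trial amplitude is `10^(α·s/20)`. α is calibrated by quadrature and
  bisection so that the dB ratio of condition-mean powers equals the
  configured Choice−Miss target (−1.5 dB by default) exactly under the
  outcome model — the calibration equation is checked against an independent
  dense-grid integration in the tests.
- **State → behavior.** Miss probability is `sigmoid(b₀ + β·s)` with β = 1.5
  and b₀ solved for a 30% marginal Miss rate; False Alarms use the opposite
  state sign (desynchronization promotes responding). Reaction times rise
  with the state and fall with contrast. Pupil diameter is a scaled mixture
  of the state and independent slow noise hitting a configured correlation
  (−0.5 by default: small pupil ↔ synchronized).
- **Artifact.** Narrowband noise around 11 Hz enters the calcium channel
  through a smooth per-pixel gain map and the hemodynamic channel gain-free;
  the hemodynamic channel carries no calcium bleed-through — sufficient for
  testing the correction's contract, not a spectroscopic model.
- **Spikes.** MUA is an inhomogeneous Poisson process whose rate follows the
  fluorescence at one pixel low-pass filtered below 8 Hz (negative rates are
  clipped and logged); contrast-tuned units fire transiently 50–150 ms
  post-stimulus, independently of the state, for decoder tests. The LFP is
  the rate trace plus noise.
- **Determinism.** All randomness flows from one root seed through named
  child streams (state/trials/movie/spikes/pupil), so identical seeds give
  bit-identical sessions and components can be regenerated independently.

What the generator does **not** emulate: vasculature, motion and
photobleaching artifacts, calcium bleed-through into the hemodynamic channel,
1/f noise (sensor noise is white — the noise spectrum of real recordings is
not established, so the minimal assumption is made and flagged), multi-area
connectivity, and video-based pupil segmentation. Passing tests therefore
demonstrate correctness of the *computations* under these conditions, not
robustness to every artifact of real data.

## Validation problem sizes

The recovery experiments in `wfstate.validation` use sizes chosen to make
each effect measurable with comfortable statistical margin on a single core:
hemodynamic gain recovery over 20 sessions of 50 trials (12×12 grid);
Choice−Miss effect recovery as the mean over 10 full-pipeline sessions of
200 trials (10×10 grid) — a single 200-trial session estimates the −1.5 dB
effect with SD ≈ 0.38 dB from trial sampling alone, so the per-session check
is on the cohort mean, mirroring how multi-experiment averages are reported;
mixed-model calibration over 50 null simulations of 8 sessions × 60 trials;
and the Fano/decoder dissociation over 20 sessions of 240 trials with
deliberately weakened contrast tuning so the decoder runs below ceiling,
where a state effect on decoding could actually show.

## Interfaces

The library is the interface: the numbered scripts under `analysis/` are the
shell entry points, each a thin driver over one pipeline stage, and no
console-script wrappers are installed. Movies, stores, spikes, and maps
persist to HDF5 (`/U`, `/V`, `/sv`, `/timestamps` plus metadata for stores);
trial tables and pupil traces to CSV; configurations round-trip through
YAML.

## Known limitations

- The nested mixed model uses independent variance components per
  level × area cell rather than unstructured per-level covariances; strongly
  correlated area offsets within a level are absorbed only approximately.
- The percentile GLMM's variational posterior can understate uncertainty in
  very small samples; the separation flag marks the degenerate cases.
- Compressed-domain filtering assumes the movie is well represented at the
  chosen rank; with aggressive truncation the heartbeat-band regression sees
  only the retained subspace.
- `condition_diff_db` (dB of the ratio of condition-mean powers) and the
  mixed model on per-trial dB values estimate different functionals of the
  power distribution; under the lognormal-like trial powers the latter is
  larger in magnitude. Both are reported as what they are.
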