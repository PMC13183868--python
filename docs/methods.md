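# Methods

## Scope and model

The package implements an event-detection and event-locked analysis pipeline
for rodent sleep electrophysiology. The unit of analysis is the NREM
micro-arousal: a transient rise in nuchal-EMG tone during NREM sleep,
shorter than 10 s, followed by a direct return to sleep. Detection is
purely EMG-based so the EEG/LFP analyses around the events remain unbiased.
The pipeline presumes the recording has already been sleep-scored into
{wake, NREM, REM} at a fixed epoch length (4 s by convention); it
post-processes that scoring, it does not produce it.

## Detector

**Rescoring.** Maximal runs of non-NREM epochs strictly inside NREM and
shorter than 11 s are relabelled NREM. Mixed wake/REM runs count as one
intrusion. Runs touching the recording boundary, or bounded by non-NREM on
either side, are never rescored: the step exists to fold subjectively scored
micro-arousals back into NREM, and at an episode edge there is no NREM
context to restore. The operation is idempotent and never alters an NREM
label.

**Envelope.** Moving standard deviation (window 0.5 s) → moving mean
(window 1.0 s) → subtract a running median of order 10 000 samples (~39 s at
256 Hz), floored at zero. The moving SD rectifies (and cancels DC bias),
the mean smooths, the median removes tonic drift. The two smoothing windows
are not published constraints; they are this package's defaults and are
configurable. The median is evaluated on a stride of order/16 samples and
linearly interpolated (stride 1 recovers the exact filter); since the median
serves as a baseline an order of magnitude slower than any event, the
strided evaluation is indistinguishable at event timescales and ~50× faster.
A consequence of the median baseline worth knowing: any *stationary* tone
elevation longer than about half the median window is itself absorbed into
the baseline. Brief micro-arousal bursts (≤ 12 s) are unaffected; sustained
wake tone is flattened, and long wake bouts are recovered instead through
the merge rule stitching together the recurring phasic EMG peaks that real
wakefulness produces.

**Threshold.** 2 × the SD of the envelope over NREM samples of the rescored
hypnogram, per recording. NREM scope makes the threshold reflect sleeping
muscle tone plus the arousals themselves rather than wake tone; it also
makes detection invariant to overall amplitude rescaling. The
REM-terminating variant accepts a manual per-recording threshold because
post-REM EMG is more variable across animals.

**Rules, in order.** (1) midpoint-in-NREM gate (midpoint rather than full
containment: filter latency can spill an event a sample over an epoch edge);
(2) merge peaks whose silent gap (offset-to-onset) is < 10 s; (3) omit
*both* members of any pair of events < 20 s apart — neither is surrounded by
undisturbed NREM; (4) exclude events longer than 10 s; (5) exclude events
starting within 4 s after a REM episode end; (6) require 20 s of
uninterrupted NREM immediately before onset and after offset (on the
rescored hypnogram; events near the recording boundary fail this
automatically). Events are reported with onset, duration and the peak of
the rectified envelope.

**Onset accuracy.** The centered smoothing windows bias the threshold
crossing by at most a few hundred milliseconds; at burst SNR 6 the mean
absolute onset error is ~0.13 s. Sub-second bursts cross late (up to
~0.3 s) because smoothing reduces their envelope peak, so accuracy contracts
are stated on the mean error, not per event.

## Spectral analysis

Band-pass: 20th-order Butterworth (1–30 Hz), realized as second-order
sections and applied forward–backward so event-locked latencies are not
shifted (the magnitude response is effectively squared; all response
contracts are stated on the one-pass design). Spectrograms: consecutive
500-ms Hann-tapered windows, zero overlap; the taper is Hann for consistency
with the PSD convention and is configurable. Welch PSD: Hann window, zero
overlap, segment length = rate/0.5 Hz (512 samples at 256 Hz), giving an
exact 0.5-Hz grid. Bands: SWA 1–4, theta 4–10, sigma 12–16, beta 16–30,
gamma 30–80 Hz; SWA starts at 1 Hz to keep movement artefacts around
arousals out of the band. Band power is the mean over in-band bins (the
spectrogram-averaging convention); an integral mode exists for
Parseval-style checks. Peri-event SWA time courses are percent change from
an explicit baseline window (different analyses use −50..−20 s or
−50..−30 s; the window is always a parameter, never hard-coded).
Before/during/after PSDs use [−50, −30), [0, 2) and [5, 10) s relative to
onset; the before-vs-after percent-change spectrum is summarized by its
trapezoidal area over 0.5–8.5 Hz.

## Firing-rate analysis

Rates are spike counts in 1-s bins; the pooled trace sums the (16) channels.
Peri-event traces are averaged across events first, then normalized: the
pooled trace as percent change from the mean over [−20, −10) s, single
channels as (x − mean)/SD with both moments taken from a reference
condition's event-averaged trace (SD over the whole trace, mean over its
first 10 s). Channel classification operates on the event-averaged trace:
increased if the maximum inside [−5, +5) s exceeds baseline
([−15, −5) s) mean + k·SD, decreased if the minimum falls below mean −
k·SD, tie resolved by the larger excursion in SD units; k = 5 for the
sleep-pressure analysis, k = 2 for the duration analysis. The baseline SD
is the sample estimator (ddof = 1): with only 10 baseline bins the
population estimator inflates the false-label rate at k = 5 above 1%,
whereas the sample SD keeps it at ~0.9%.

## Homeostasis statistics

Each eligible event contributes a history point: the fraction of the prior
6 h spent in NREM, post-arousal SWA (mean band power 3–8 s after onset, as
percent of a baseline), and surrounding SWA (±1 min around onset, same
scale). The baseline is the mean NREM SWA over a configurable window,
default the first 6 h of lights-on of the baseline day. Regressions are
ordinary least squares of SWA on percent prior NREM with Pearson r and a
t-based 95% CI of the slope. The slope comparison stacks the two responses
into one regression with a group indicator and tests the group × predictor
interaction — the textbook ANCOVA equal-slopes test, implemented in closed
form. The paired post-vs-surround values from one event share noise across
the two regressions; the procedure is reported as specified and this caveat
is inherited. Pooling events across subjects is the default (a per-subject
option exists via filtering). SWA decline across recovery sleep is the
percent change from the first to the last NREM bout longer than 5 min inside
the recovery window. Repeated-measures one-way ANOVA uses the
subject × condition interaction as error term with Greenhouse–Geisser
epsilon-corrected degrees of freedom (epsilon from the double-centered
condition covariance, floored at 1/(k−1)); pairwise comparisons use the
studentized range with the RM error mean square — the Tukey procedure as
statistical packages apply it after RM-ANOVA. The implementation is
cross-checked against `pingouin.rm_anova` in the test suite. Under exact
sphericity the GG correction is mildly conservative (observed type-I ~3%
at 7 × 3).

## Synthetic recordings

The generator emulates the statistical structure the analyses assume, with
one integer seed split into independent per-signal streams (SeedSequence
spawning), so outputs are bit-reproducible and adding a signal never
perturbs another.

*Hypnogram*: semi-Markov chain over {W, N, R}; lognormal dwells (median,
log-sigma) of (40 s, 1.0), (120 s, 0.8), (60 s, 0.5); transitions W→N 1.0,
N→W 0.8 / N→R 0.2, R→W 0.5 / R→N 0.5; quantized to 4-s epochs; optional
enforced-wake block emulating 6-h sleep deprivation. These dwell scales
produce the fragmented, NREM-dominated light-phase sleep typical of mice.

*EMG*: Gaussian noise with state-dependent tone (SD 1.0 / 0.15 / 0.08 for
W/N/R). Wake tone is multiplied by a smoothed lognormal modulation
(log-sigma 0.6, correlation 2 s): real wake EMG is phasic, and the
detector's bout-stitching depends on that. Micro-arousal bursts are planted
at Poisson rate 0.8/min of NREM, amplitude 6 × the NREM tone (SNR 6),
durations lognormal (median 3 s, log-sigma 0.6) truncated to [0.5, 12] s,
with 50-ms raised-cosine ramps bounding the threshold-crossing error.
Short scored-wake intrusions inside NREM are part of the ground truth too:
after rescoring they are genuine muscle events the detector must report.
Every true event carries flags computed by an independent geometry-only
restatement of the inclusion rules.

*LFP*: 1/f^1.5 background plus a 1–4 Hz narrowband oscillation whose
amplitude follows state gains (N 1.0, W 0.3, R 0.2) times the square root of
a two-time-constant homeostatic process (rise τ 8 h in wake, decay τ 2 h in
NREM — the standard mouse Process-S scales). Around each planted event: a
+30% SWA amplitude ramp over the 10 s before onset, a 60% broadband power
drop during the event, and afterwards the SWA amplitude is pinned so that
post-event SWA equals `250 − 2.0 × (% NREM in the prior 6 h)` percent of
baseline — the planted law the history regression must recover. The rebound
begins when the event's suppression ends.

*Spikes*: 16 channels of inhomogeneous Poisson activity (base rates 10/6/7 Hz
in W/N/R) on a 10-ms grid. Channel profiles: 4 "surge" channels (Gaussian
rate bump ×2.5 peaking 0.7 s before onset), 6 "suppress" channels
(half-cosine dip to ×0.3 over the 3 s after onset), 6 flat.

*History points*: `simulate_history_points` draws points directly from the
planted linear laws (post 250 − 2.0·x, surround 160 − 1.0·x, Gaussian noise
SD 25%, x uniform on 0–60% prior NREM). It is the statistical analogue of
the signal-level generator, used where thousands of regressions are needed
(power, coverage and type-I studies); the signal-level law is verified
separately end-to-end through the LFP at smaller n.

**What passing tests do and do not show.** The generator reproduces the
timing geometry, amplitude statistics and planted effect structure the
pipeline's rules and regressions operate on, so green tests demonstrate the
algorithmic contracts: rule compliance, recovery of known events, correct
normalization and calibrated inference. It does not reproduce spindles,
theta microstructure, volume conduction, scorer disagreement, electrode
artifacts or the infraslow (~0.02 Hz) clustering of real arousals; detection
performance on real recordings therefore depends on data quality in ways
these tests cannot certify.

## Numerical choices and degenerate inputs

Intervals are half-open, times in seconds from recording start. Envelope
smoothing uses reflect padding; a constant envelope (SD 0) yields no peaks;
a recording without NREM has no threshold basis and raises. Regression on a
zero-variance predictor, normalization of a zero-SD channel, and RM-ANOVA
with missing cells raise; a zero-SD classification baseline leaves the
channel unclassified with a warning; noiseless slope comparisons report
p = 1 when the interaction is exactly zero rather than forming a 0/0
t-statistic. Problem sizes in the test and acceptance runs (2-h recordings
for recovery, 15-min recordings for the rule-compliance sweep, 200–1000
simulations for calibration) were chosen as the smallest sizes at which the
Monte-Carlo error is well below the contract margins.

## Known limitations

Purely cortical (EMG-silent) arousals are out of scope by definition.
Detected durations are envelope-crossing durations and run ~0.3–0.6 s longer
than the underlying muscle activity, so events very close to the 10-s cap
may be excluded by smoothing alone. The wake-transition variant relies on
phasic wake EMG; on an artificial recording with perfectly stationary wake
tone longer than ~20 s the median baseline absorbs the bout. EDF files are
read (via `mne`) but not written; bundles are stored as binary arrays with a
JSON sidecar plus text hypnogram/spike/truth tables.
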