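# Methods

This note documents the models, parameters and numerical choices behind
`wormsleep`, what the synthetic data does and does not emulate, and the
design decisions that were genuinely open.

## Activity measure

Activity between consecutive grayscale frames is the sum over pixels of
the absolute intensity difference.  Differences are computed in float64
regardless of input dtype so 8/16-bit camera data cannot wrap around zero.
No background subtraction, denoising or thresholding of the difference
image is applied by default; the measure sums raw differences.  An
optional noise-floor clamp (subtract a constant from every difference
pixel, clip at zero) exists for very noisy cameras but defaults to off.
The measure is symmetric in the frame order, additive over disjoint pixel
regions, and homogeneous of degree one in intensity.

One consequence worth keeping in mind: summing |differences| over the
whole frame amplifies per-pixel noise by the pixel count, so the
noise-only activity floor of an N-pixel frame is ≈ N·σ·2/√π for Gaussian
pixel noise of standard deviation σ.  Detection is unaffected as long as
this floor stays well below wake-level activity (see *Synthetic worm*).

## Detection criterion

Sleep is called on a local window of `window_w` activity values (default
5) when **both** hold, with inclusive comparisons:

* `std(local) ≤ std(global) / k_std`, default `k_std = 40`;
* `mean(local) ≤ mean(global) − (mean(global) − min(global)) / k_mean`,
  default `k_mean = 1.5` (equivalently `((k_mean−1)·mean + min)/k_mean`).

Global statistics are cumulative from the first activity value of the
measurement and are never windowed or reset.  Choices and caveats:

* **Population standard deviation** (divide by n) for both local and
  global std, so a five-value window and the streaming accumulator use the
  same estimator and degenerate cases agree exactly.
* **Streaming statistics** use Welford's online recurrence; the offline
  `batch_detect` recomputes global statistics per frame from prefix-sum
  batch formulas.  The two paths are numerically independent and are
  required (and tested) to produce identical decision sequences.
* **Constant-trace degeneracy**: on an exactly constant trace both bounds
  hold by equality (std 0 ≤ 0, mean c ≤ c), so a constant recording is
  called asleep.  This is inherent to the inclusive criterion and is
  documented rather than patched; real and synthetic wake activity
  fluctuates, which is what the criterion relies on.
* **`k_mean` must exceed 1**: at 1 the rewritten bound collapses to
  `min(global)` with a vanishing mean term; parameter validation rejects
  it.  `window_w = 1` is rejected because a one-sample std is identically
  zero.
* **Warm-up gate** (default 120 frames = 2 min at the 1 s default frame
  interval): no sleep call is permitted before this many values have
  accumulated.  Early global statistics are degenerate — the very first
  window would always satisfy both bounds by equality.  The gate length is
  a package choice, not part of the reference operating point.
* **Refractory gate** (default `window_w` frames after a mechanical
  stimulus): detection is suppressed until the local window has refilled
  with post-stimulus values, so re-detection reflects post-tap behavior.
* **Scale invariance**: every term of both bounds is homogeneous in the
  trace, so rescaling a recording by any positive constant leaves all
  decisions unchanged.

## Closed-loop protocol

In deprivation mode, an asleep decision (outside warm-up/refractory)
triggers a tap train — default 5 taps at 1 s spacing.  Tap times are
staggered to the midpoint between the two nearest frame times, a concrete
rendering of the hardware interlock that prevents a vibration from
blurring an exposure; with the default 1 s frame interval every tap lands
exactly half a frame interval away from the exposures.

After each train the worm's response is assessed over a 10-frame window
following the last tap: it is *responsive* iff the raw sleep criterion is
false for at least one frame of the window (the refractory gate is ignored
there, since it would masquerade as wakefulness).  The worm is
re-stimulated whenever it returns to sleep; if a new detection arrives
while an assessment window is still open, the assessment is finalized from
the frames already collected (at least five, enforced by the refractory
gate) and the next train fires immediately.  After
`max_unresponsive_trains` consecutive unanswered trains (default 3) the
controller switches to an extended, detection-independent protocol — one
train every `train_period_s` (default 60 s) for `duration_s` (default
1800 s) — and then stops stimulating.  The response criterion, the
consecutive-train count and the extended protocol's period/duration are
explicit package inventions (the underlying experimental description gives
none of them numerically); all are configurable and logged.

Control mode replays a text-file schedule (one train per line:
`time_s n_taps interval_s`) irrespective of behavior, with the same
staggering.  Runs are deterministic: identical seed and configuration
produce byte-identical logs.

## Synthetic worm

The generator emulates a single L1 worm in a 190 × 190 µm chamber imaged
at 1 µm/pixel, 1 frame/s by default.  Behavioral model:

* Outside lethargus the worm is awake and pumping; its nose performs a
  bounded random walk with per-frame Rayleigh speeds of mean 16 µm/s and a
  diffusing heading, reflected at the chamber walls.  Because reflections
  fold the path, the *measured* frame-to-frame displacement speed sits
  somewhat below the commanded 16 µm/s (≈13 µm/s at defaults).
* Inside lethargus pumping stops and behavior alternates between motion
  bouts (mean speed 8 µm/s) and sleep bouts (nose displacement exactly
  zero, heading frozen).  Bout durations are exponential — a semi-Markov
  model with memoryless bouts, the simplest structure consistent with
  bout-alternating quiescence; means default to 30 s (sleep) and 15 s
  (motion).
* A tap delivered during a sleep bout wakes the worm into a motion bout
  with the current response probability (initially 1.0); each *answered*
  train decays that probability by ×0.8 (habituation).  Only the first
  effective tap of a train can wake the worm, so the probability after k
  answered trains is exactly 0.8^k.

Timescales are deliberately compressed: a real L1 lethargus lasts hours,
while the default experiment runs 1200 s with lethargus spanning
[240 s, 720 s).  The compression keeps a full wake–lethargus–wake cycle,
a pre-lethargus span longer than the detector warm-up, and bout durations
long relative to the five-frame detection window — the features the
detector and controller actually rely on — while making every experiment
desk-scale.

Rendering: the worm is a bright anisotropic Gaussian blob (amplitude 150
over background 10; σ = 12 µm along the heading, 5 µm across) evaluated on
the pixel grid to sub-pixel accuracy, plus optional Gaussian pixel noise
(σ = 0.2, clipped at zero).  The noise σ is calibrated so the whole-frame
noise-only activity floor (≈ 36 100 px × 0.2 × 2/√π·√2 ≈ 1.1·10⁴) stays
several-fold below wake-level activity (≈ 5–6·10⁴); a calibration test
enforces this.  Behavior and pixel noise consume independent substreams of
one seeded generator, so toggling rendering noise does not perturb the
behavioral trajectory.

What the generator does **not** emulate: worm posture and body shape (the
detector consumes only intensity differences, so a blob suffices), DIC
optics, vibration physics of the tapper (taps act instantaneously on the
behavioral state), developmental timing variability, multi-worm chambers,
and any neuronal (calcium) dynamics.  Passing tests therefore demonstrate
the correctness and internal consistency of the algorithmic pipeline under
a plausible behavioral model — not performance on real recordings.

## Behavioral metrics

* Nose speed: Euclidean per-frame displacement over the frame interval.
* Sleep bouts: maximal runs of frames with speed ≤ ε, default
  ε = 0.5 µm/s — a localization-noise floor at 1 µm/pixel and 1 s frames
  standing in for "no detectable movement"; minimum bout length defaults
  to 1 frame.  Both configurable.
* Lethargus: the single longest non-pumping run; an optional gap-bridging
  parameter (default 0) merges runs separated by ≤ g frames to absorb
  isolated pump-miss frames.
* Sleep summary: totals over bout∩lethargus intersections.
* Detection evaluation: a detection counts as in-lethargus if any asleep
  call falls inside the interval, and as within-tolerance if it falls in
  the 5 minutes before the non-pumping start; the delay is the first
  asleep call at/after lethargus onset.
* Rank correlation: Spearman with average ranks (scipy); constant inputs
  raise a degenerate-input error rather than returning NaN.
* Event-aligned averaging: mean ± s.e.m. across traces at each offset;
  traces whose window overflows are excluded with a warning, never
  silently truncated.

All intervals are half-open `[start, end)` in seconds with 0-based frame
indexing.

## Problem sizes

The test-suite and acceptance-script experiments use the default 1200 s
recording (1199 activity samples) per seed, ten standard seeds for
fixture-based properties, 100 random 500-sample traces for the
streaming/batch equivalence check, and 10⁴ random tuples for the
mean-bound identity.  These sizes are the package's chosen desk-scale
study conditions and are stated here so results can be reproduced exactly.

## Known limitations

* The closed-loop efficacy achievable in simulation is bounded by the
  detection geometry: with a five-frame window at 1 s frames a sleep bout
  runs ~6 s before it can be interrupted, so the deprived sleep fraction
  cannot fall below roughly `6 / (6 + motion-bout mean)` while the worm
  responds, and habituation (×0.8 per answered train) ends effective
  deprivation after ~10–15 answered trains.  Real animals show stronger
  suppression because arousal outlasts a single motion bout — a memoryless
  bout model has no such carry-over.
* The bout count under deprivation *rises* (bouts are truncated and
  restart) even as total sleep falls, again a consequence of
  memorylessness.
* Lethargus timing is imposed by parameters, not emergent, so deprivation
  cannot shorten lethargus in the simulation.
* The constant-trace degeneracy of the inclusive criterion (above) means a
  dead camera feed reads as sleep; the warm-up gate does not protect
  against a recording that is constant throughout.
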