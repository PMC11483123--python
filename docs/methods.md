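# Methods

This note documents the models, rules, and numerical choices behind
`vesiclefuse`, in the order data flows through the pipeline.

## Clock and coordinates

Pixel coordinates are 0-based `(row, col)` with pixel centers at integers;
times are seconds from the first frame; frame *k* at rate *f* covers the
half-open interval `[k/f, (k+1)/f)`, and all epoch intervals are half-open.
ImageJ-style 1-based ROI tables can be imported with `one_based=True`,
which shifts coordinates by −1. Acquisition defaults are 2 Hz and
0.2 µm/pixel, both overridable.

The stimulation paradigm is parameterized as bursts of AP trains: train
duration = APs / rate (e.g. 50 AP at 50 Hz = 1 s), burst span =
`n·train + (n−1)·inter_train`, and the NH4+ dequench epoch starts a
configurable delay (default 50 s) after the end of the last train. The
delay between movie start and the first train defaults to 30 s and is
configurable, since it is only fixed for the fusion assays.

## Synthetic scenes

The simulator emulates the three live assays (fusion, transport, FRAP) with
a shared scene model:

* **Neurites** are smoothed random-walk polylines crossing the field,
  resampled at 1-px arc steps. Walks that re-approach themselves within
  6 px are rejected — a self-approaching path would alias distant arc
  positions in the transverse kymograph reslice.
* **Vesicles** sit on the polylines with lognormal intrinsic brightness
  (median defaulting to 6× the camera noise SD at background — a bright but
  not saturating reporter — and σ = 0.25, modest cargo variability).
  Optional placement controls: a minimum separation (rejection sampling)
  and a fraction placed in sub-PSF overlapping pairs, used to probe the
  pool-counting overlap correction.
* **Quenching and fusion.** A quenched vesicle renders at
  `quench_residual` (default 5%) of its brightness; at its scheduled fusion
  time it steps to full brightness within one frame and decays with
  τ = 2 s. Fusion consumes the vesicle: during the later NH4+ epoch only
  unfused vesicles render at full brightness. Fusion times are drawn from
  a hazard elevated only during stimulation trains (event count per neuron
  Poisson with the preset rate; optional constant spontaneous hazard,
  default 0).
* **Transport.** Mobile vesicles follow run-pause motion: runs at a
  constant speed drawn uniformly from 0.5–2 µm/s (a documented simulator
  choice), run durations 2 s + Exp(4 s) (the 2-s floor guarantees every
  mobile vesicle a 10-s window displacing ≥ 0.75 µm, so ground truth is
  classifiable in the noise-free limit), pauses Exp(4 s). At a neurite
  end a vesicle can `reverse` (default), `park`, or `exit` the imaged
  stretch. The transport presets use `exit`: a punctum that reaches the
  end of the imaged stretch leaves it, as in real recordings of a bounded
  neurite segment; endless reflection would make every mobile punctum
  cross every other punctum many times per recording, a geometry neither
  trackers nor human scorers face in practice.
* **FRAP.** Inside the bleach region, brightness is multiplied by
  `1 − efficiency` from the bleach onset (defaults 0.3 for the
  bleach-resistant pHluorin channel, 0.9 for a red channel). An optional
  uniform exchangeable pool recovers as `1 − eff·exp(−Δt/τ)`, giving a
  closed-form target for the recovery-curve estimator.
* **Camera noise.** EMCCD-style: `Poisson(gain·signal)/gain +
  Normal(0, read SD)`, defaults background 100, gain 1, read SD 2; output
  clipped at 0. A fixed seed yields bit-identical movies.

Condition presets: `WT-like` (fusion rate 6 events/recording),
`KO-like` (18 = 3×, the published fold change), `NPY-like` (mobile
fraction 0.47) and `RPH3A-like` (0.105, the midpoint of the published
7–14% range). Transport presets use a single long neurite (64×256 px),
10 separated puncta, 2-minute recordings, and a constitutively visible
label (as with NH4+-perfused pHluorin or mCherry).

What the simulator does **not** emulate: focus drift, uneven illumination,
vesicle aggregation, axon/dendrite identity, z-dimension, and amplitude
distributions fit to data (the lognormal is a stand-in). Passing tests
therefore demonstrate the correctness of the analysis rules under the
stated optical model, not performance on any particular real dataset.

## Fusion detection

`extract_trace` averages the (2h+1)² ROI box per frame; baseline mean is
the median over the baseline epoch and noise SD is 1.4826×MAD there (robust
to spontaneous events; a floor of 1 camera unit is applied and flagged when
MAD = 0). An event requires (a) ΔF above `k_sd`×SD of a trailing-median
local baseline frozen during supra-threshold runs (k = 2, the 2×SD rule),
(b) rise to peak within ≤ 2 frames ("sudden appearance"; 1 s at 2 Hz), and
(c) a 2-s per-ROI refractory period. Duration is the supra-threshold dwell
time — the duration metric is this package's definition, applied
consistently. Events with onsets inside the NH4+ epoch are excluded;
onsets before the first train are labeled spontaneous. Peak ΔF is measured
against the local (not global) baseline.

Unattended operation replaces manual ROI placement with candidate
detection: the statistic is the difference of two-frame averages of the
spatially smoothed movie (averaging exploits the multi-frame persistence of
the decaying transient), thresholded at 6× its robust SD, with spatial
local-maximum selection, a 3-px border margin (boundary reflection inflates
the smoothed noise variance there), NH4-adjacent frames excluded, and 3-px
deduplication. Each automated ROI carries its trigger frames, and events
from automated ROIs must start within 2 frames of a trigger — the
automated analogue of placing an ROI around a seen event. Manual ROI
tables always take precedence. Events reported by neighboring ROIs within
4 px and 1 s are merged, keeping the higher SNR.

At the simulator's default signal-to-noise this detector measures recall
≈ 0.93–0.98 and precision ≈ 1.0 over hundreds of scheduled events, and
≤ 0.05 spurious events per noise-only recording.

## Pool and released fraction

The NH4+ projection is the median over the epoch's frames (robust to
single-frame noise), background-subtracted by a 21-px median filter; the
residual keeps its negative part so the punctum threshold (4× robust SD)
can be estimated from it. Blobs are segmented by smoothing + thresholding
+ watershed around local maxima; integrated intensities are taken over
footprints expanded 3 px into the background (`expand_labels`), because
supra-threshold footprints clip PSF tails more for dim puncta than bright
ones and would break the quotient's linearity. The single-vesicle unit is
the median integrated intensity over isolated (single-maximum) blobs; each
blob is assigned `max(1, round(I/unit))` vesicles. On scenes with 30% of
vesicles in overlapping pairs, the corrected pool recovers truth with a
median error ≈ 7% across seeds, while naive blob counting errs by ≈ 35%.

The released fraction divides the detected event count by the corrected
pool and is reported unclamped; a zero pool raises rather than returning
an undefined value.

## Kymographs and mobility

Kymographs use the wide-reslice convention: 1-px arc-length sampling with
bilinear interpolation and a transverse maximum across the (odd) width
(mean mode available).

Mobility uses the 3/4 µm in 10 s displacement rule, read as: a punctum is
moving iff some sliding 10-s window shows an endpoint displacement of at
least 0.75 µm ("3/4 µm" is read as 0.75 µm; a whole-recording variant is
available behind `rule="whole"`). Endpoint displacement, not within-window
range, is used because localization jitter aliases into a range statistic.
Tracks shorter than one window fall back to total displacement and are
flagged.

Tracking is the one genuinely hard plumbing problem, and the pipeline is:

1. **Stationary/moving decomposition.** The temporal median profile of the
   kymograph captures every punctum stationary for most of the recording;
   its peaks become immobile puncta directly. The moving residual (data
   minus profile) is tracked with per-column thresholds, which absorb the
   extra variance left under bright ridges.
2. **Linking.** Per-frame 1-D maxima (parabolic sub-pixel refinement) are
   linked globally greedily on distance to a velocity-predicted position
   (prediction resolves crossings; the raw last position catches
   reversals), gate 6 px, gap bridging ≤ 4 frames.
3. **Identity repair.** Tracks are cut where two concurrent tracks come
   within 2 px (the merged peak could belong to either) and at abrupt
   velocity-sign kinks (the signature of an identity swap whose partner
   track had already ended). Segments are re-joined by a velocity-aware
   stitcher (gap ≤ 30 frames, tolerance 6 px + 1 px/frame of gap, edge
   velocity mismatch ≤ 2.5 px/frame, cost = position + 8×velocity
   mismatch). Finally, concurrent tracks that stay within ~1 µm of each
   other for most of their overlap are merged — two puncta that close read
   as a single line in a kymograph.
4. Tracks spanning < 10 s are discarded.

On simulated 2-minute NPY-like recordings this recovers the configured
mobile fraction with a mean bias of under 1 percentage point across
hundreds of tracks. Identity swaps between crossing puncta can still
occur; mobility statistics are identity-agnostic by design.

Co-travel: a moving track co-travels with the other channel when a moving
track there stays within 2 px for ≥ 5 s of *common motion* — frames where
both puncta are locally moving (≥ 0.1 µm/s over ±1 s). The motion
requirement prevents two puncta pausing side by side (e.g. both dwelling
near a neurite end) from counting. The 2 px / 5 s operationalization is
this package's definition. Fractions are reported with the first-named
channel's moving tracks as denominator and NaN when that denominator is
empty.

FRAP curves are mean region intensity per post-bleach frame; normalization
maps the post-bleach minimum to 0 and the maximum to 1 (flagged flat when
the span is below pre-bleach noise); the half-recovery time is the first
0.5 crossing. Normalized curves are invariant to affine intensity scaling.

## Colocalization

Pearson's r over mask pixels; Manders M1/M2 above per-channel thresholds
(default Otsu on the masked intensities; manual override) — M1 is the
fraction of supra-threshold A intensity where B is supra-threshold, M2
symmetric. Object containment dilates each punctum footprint by 1 px and
asks whether a centroid of the other channel falls inside. A neurite mask
should be supplied for fixed images with large empty background, which
otherwise inflates r. Multi-plane inputs are expected as projections.

## Morphometry

Puncta: difference-of-Gaussians enhancement (σ 1 and 3 px), threshold at
background mean + 2×SD, components ≥ 2 px, watershed splitting. The
single-DCV unit is the mode of the first quartile of punctum integrated
intensities — "first quartile" read as the sub-Q1 subset (type-7
quantiles) — estimated as the peak of a Gaussian KDE with Silverman
bandwidth (degenerate subsets use their common value; a histogram mode is
deliberately avoided for bin-width sensitivity). Counts round with floor
1; with fewer than 4 puncta the unit is undefined and the count falls back
to the punctum count, flagged.

Neurite length: masks are thinned (Lee's method for thick masks — it
leaves a straighter ridge than the default thinning and keeps the
rotation anisotropy of a straight neurite within the ≈8% staircase bound;
already single-pixel masks are used as-is), then the length is the sum
over unique 8-neighbor pixel pairs of 1 or √2 pixel spacings, except that
a diagonal edge whose endpoints already share an orthogonal neighbor is
skipped (it is a shortcut across an existing connection, not extra
length). Density = count / length; count-vs-length relations use ordinary
least squares with r².

## Statistics

Screening: per-group Shapiro-Wilk and across-group Levene at α = 0.05;
the parametric path requires every group to pass, and groups of < 3
observations force the non-parametric path. Two groups: unpaired t-test
or Mann-Whitney U. More than two: Kruskal-Wallis omnibus, then Dunn's
pairwise z-tests on pooled tie-corrected ranks with Holm correction (the
family-wise scheme is configurable; Holm is the default because the exact
correction used with "Dunn's correction" is not standardized).
Descriptives follow Tukey boxplot conventions with type-7 quantiles.
Per-experiment normalization divides by the experiment's control-group
mean. Multi-level (animal random effect) models are out of scope; when an
`animal_id` grouping is present the report attaches a warning that a mixed
model may be warranted.

## Reproducibility

Every stochastic component draws from `numpy.random.default_rng` seeded
from explicit configuration; the pipeline refuses configs without seeds,
rerunning a `RunConfig` is byte-identical, and the result bundle includes
a manifest with a configuration hash. Problem sizes used by the validation
suite — 30 neurons per condition for the fold-change check, twenty
2-minute recordings (≈200 tracks) for mobility, ≥ 200 scheduled events for
detector calibration — are the package's chosen verification scale.
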