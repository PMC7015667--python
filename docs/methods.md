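# Methods

`prehear` implements the quantitative analysis stack used to characterize
spontaneous activity in the developing auditory system before hearing
onset: burst firing of spiral ganglion neurons (SGNs) driven by inner hair
cells (IHCs), spontaneous ATP/P2RY1-mediated currents and osmotic
shrinkage (crenation) of inner supporting cells (ISCs), coordinated Ca²⁺
transients in cochlear explants, tonotopically banded events in the
inferior colliculus (IC), and retinal waves in the superior colliculus
(SC). Every stage has a synthetic counterpart in `prehear.synth` so the
whole stack is testable against known ground truth without any recordings.

## Spike trains and burst detection (`prehear.spikes`)

Juxtacellular traces are zero-phase high-pass filtered (2nd-order
Butterworth, default cutoff 10 Hz) and spikes detected by an amplitude
threshold of `threshold_k` (default 5) times the robust noise SD
(1.4826 × MAD of the filtered trace), one spike per suprathreshold
excursion with a 1 ms refractory separation. The filter order/cutoff,
threshold multiplier, and refractory period are package defaults; they are
exposed because real recordings vary in drift and noise.

Interspike intervals (ISIs) are classified into three classes that
partition the positive reals:

- **mini-burst**: ISI < 30 ms
- **burst**: 30 ms ≤ ISI ≤ 1 s (the closed interval; IHC Ca²⁺ spikes drive
  SGN firing preferentially at 75–125 ms intervals, inside this class)
- **non-burst**: ISI > 1 s

A **burst** is a maximal run of consecutive burst/mini-burst intervals
containing at least 10 burst-class intervals. Mini-burst intervals never
break a run and never count toward the 10, but the spikes they contribute
are included in the burst's spike count, and a run may begin or end with
mini-burst intervals (symmetric treatment; the flanking spikes are part of
the burst span). Any non-burst interval terminates a run. The detector is
verified against an exhaustive run-enumeration oracle on random label
sequences.

Summary metrics per analysis window: burst frequency (per minute), mean
burst duration and spikes per burst, mean firing rate (all spikes /
window), and the ISI coefficient of variation. The CV is computed over
*all* ISIs in the window, not only intra-burst ISIs (a `window`-wide
choice; burst-only CV can be obtained by restricting the train). A
homogeneous Poisson train has CV 1; perfectly periodic firing has CV 0;
bursty firing pushes CV well above 1.

## Voltage-clamp currents (`prehear.currents`)

Spontaneous ATP-mediated events appear as fast-rising inward (negative)
deflections with roughly exponential decay on a slowly drifting baseline.
Detection: subtract a 10 s rolling-median baseline, smooth the residual
with a 20 ms moving average, and mark samples dropping more than
`threshold_k` (default 5) × noise SD (1.4826 × MAD of the smoothed
residual) below baseline. Sub-threshold gaps shorter than
`min_separation` (default 0.2 s) are merged so noise cannot split one slow
decay into several events. Event extent runs from the threshold crossing
to the first return within one noise SD of baseline; amplitude is the raw
residual minimum, and charge transfer is the integral of the residual over
the extent (pA·s = pC). The smoothing step is the package's choice where
the upstream procedure was a per-sample threshold: without it, measured
false-positive rates on pure-noise traces were ~0.3 events/min and large
events were double-counted.

The holding current of a measurement period (default length 5 min) is the
95th-percentile sample value of that period — for a cell held below the
reversal of the event conductance, brief inward transients occupy the low
tail, so the 95th percentile tracks the standing current robustly. Tail
currents (the K⁺-sensitive current after stepping to −70 mV) are
summarized per sweep as the mean over a measurement window, default the
final 5 ms of the step, normalized so the mean over designated baseline
sweeps is 0 pA; a `statistic="peak"` flag measures the extremum instead.

## Imaging primitives (`prehear.movie`)

- **ΔF/F₀**: per-pixel F₀ is the 5th percentile of the pixel's trace over
  time (linear interpolation between order statistics); ΔF/F₀ =
  (F − F₀)/F₀. Non-positive baselines raise an error instructing the
  caller to offset the movie.
- **Bleach correction**: fit m(t) = a + b·e^(−t/τ) to the frame-mean
  trace and subtract the decaying component m(t) − m(0) from every pixel.
  Anchoring at the initial brightness (rather than the asymptote a) keeps
  the corrected baseline positive even when fluorescence decays toward
  zero, so ΔF/F₀ remains defined downstream. Non-decaying traces are
  returned unchanged with a warning. The correction is additive, so under
  strong bleaching late event amplitudes remain attenuated by the
  multiplicative decay; with the mild bleaching the generator defaults to
  (≲5 % over a session), amplitudes are preserved within 5 %.
- **Difference movies**: out[k] = frame(k + lag·rate) − frame(k), default
  lag 5 s, used as a transmittance-change index for crenation imaging.
- **Thresholding**: mask = values > mean + k·SD with global scope by
  default (`per_pixel=True` switches to per-pixel statistics). On pure
  Gaussian noise the suprathreshold fraction at k = 3 matches the normal
  tail (≈0.135 %).
- **Region areas**: the binary mask is Gaussian-smoothed (σ = 2 px),
  re-binarized at 0.5, labelled with 8-connectivity, and each region's
  area is pixel count × (µm/px)². The 0.5 re-binarization level and
  8-connectivity are package choices where the border-detection step was
  under-specified.
- **Peak detection**: local maxima above a fixed threshold with a greedy
  minimum separation that keeps the larger peak.

## Cochlear explant analysis (`prehear.cochlea`)

**Crenations**: difference movie → global mean+3SD mask → per-frame count
of suprathreshold pixels with the whole field as one ROI → peaks of the
count trace give events; the mask at each event frame yields areas in µm².
The count trace is smoothed over ~1 s and its peak threshold is
median + 3·1.4826·MAD of the smoothed trace, a robust variant chosen
because sparse large events inflate the trace's global SD above the peaks
themselves; the minimum peak separation is max(min_peak_sep, diff_lag).

**Ca²⁺ transients**: per-ROI (ISC region, individual IHCs, SGN region)
mean-ΔF/F traces thresholded at their own mean + 3 SD; frequency per
minute per compartment; event area by thresholding the ΔF/F frame at the
single peak frame, restricted to the ROI.

**IHC correlations**: Pearson coefficients between raw ΔF/F traces of
every IHC pair (not event-binarized traces); each cell is summarized by
the mean coefficient with its four nearest IHCs by centroid distance
(ties broken by ROI index; edge cells use all available neighbours), and
the group mean averages over cells. Zero-variance traces produce NaN
pairs that are excluded from neighbour means.

## Midbrain analysis (`prehear.midbrain`)

**IC events** are detected on each lobe's mean-ΔF/F trace with a fixed 2 %
ΔF/F threshold — fixed across conditions because the traces are
normalized. Amplitude is the baseline-subtracted peak, the local baseline
being the median of the preceding 5 s; half-width is the full width at
half amplitude with linear interpolation at the crossings. Events whose
suprathreshold coverage of their lobe ROI at the peak frame exceeds 80 %
(strictly) are treated as global (cortical/SC bleed-through) and excluded.

**Bilateral pairs**: left/right events within ±0.5 s are matched greedily
by minimal time difference (ties to the earlier pair), each event used at
most once. The bilateral amplitude ratio is weak/strong ∈ (0, 1]; 1 means
complete inter-lobe synchrony.

**Tonotopic line scans**: a 125 × 50 px rectangle centered on a per-lobe
anchor, rotated ±55°, is sampled per frame with bilinear interpolation and
averaged across its 50 px width, giving a 125-sample profile whose
position axis starts at the lateral end (µm = sample × µm/px). Band peaks
are regional maxima of the (position × time) matrix above 3 % ΔF/F.
Spatial histograms use 25 µm bins; events below the split position count
as lateral, above as medial. The split position is a required input — the
midpoint between the lateral edge and a user-identified single-band locus
— because that landmark is placed per animal; an optional ±50 µm exclusion
zone around the locus removes bifurcation-edge events.

**Retinal waves**: each SC lobe ROI (200 × 150 px) is block-mean
downsampled ×5, ΔF/F-normalized (5th-percentile F₀), and each frame's
all-pixel mean subtracted to remove whole-sample fluorescence swings. A
pixel is active when it exceeds its own temporal mean + 3 SD (computed
over the full recording after mean subtraction). A wave is a maximal run
strictly longer than 1 s during which strictly more than five pixels are
active; its duration is the run length. Note the per-pixel SD definition
implies a pixel active a large fraction of the recording raises its own
threshold; waves are assumed sparse in time, as in the recordings this
emulates.

## Statistics (`prehear.stats`)

D'Agostino's K² omnibus normality test (via `scipy.stats.normaltest`,
n ≥ 8); Student's t tests (paired/unpaired) with Bonferroni adjustment
min(1, p·m) for m comparisons; one-way ANOVA with Tukey HSD post hoc for
multi-condition data. The two-mean sample-size calculation uses the
normal-approximation design formula

n₁ = (z₁₋α/₂ + z_power)² σ² (1 + 1/ratio) / Δ²,

rounded up (α two-sided, default 0.05). For (µ₁ = 10, µ₂ = 7, σ = 2,
ratio = 1, power = 0.8) it returns n = 7 per group. The formula's
simulation oracle is the known-σ z test; the t test at the returned n runs
about two points of power lower, the usual cost of the approximation — an
iterative noncentral-t calculation would return n = 8 here and was
deliberately not used.

## Synthetic data (`prehear.synth`)

The generators define the study conditions under which the stack is
validated; all are deterministic for a fixed seed (independent per-call
random streams), render the noiseless signal from an explicit event
schedule, add noise last, and log every simulated event.

- **Spike trains**: bursts arrive as a dead-time renewal process (dead
  time = expected burst span + 1.2 s, exponential extra gap) whose mean
  inter-onset interval is exactly 60/burst_rate, so rate recovery is
  unbiased while bursts stay resolvable. Bursts have ~Poisson(15) spikes
  (minimum 12), intra-burst ISIs uniform on 75–125 ms, optional
  mini-burst insertions (8–25 ms doublets) at a configurable probability,
  over homogeneous-Poisson tonic firing (default 0.1 Hz).
- **Current traces**: instantaneous-onset, single-exponential-decay inward
  events (default τ = 0.5 s), log-normal amplitudes (mean 100 pA, shape
  0.4) mimicking the heavy-tailed event sizes of ISC recordings; linear
  baseline drift and Gaussian noise (default 2 pA). Event scheduling uses
  the same exact-rate dead-time renewal process (dead time 3τ).
- **Movies** (four modes on a common spec): *ic* — Gaussian bands along a
  ±55° tonotopic axis (default width 100 µm) with an alpha-function time
  course, mirrored contralaterally at the configured bilateral ratio;
  *sc* — slowly drifting high-amplitude disks active for exactly their
  scheduled duration; *crenation* — hard-edged disks with a Hann time
  course on a transmitted-light background; *cochlea* — coordinated
  ISC/IHC/SGN activation with per-IHC noise calibrated analytically so
  hair-cell trace pairs correlate at a target level. Photobleaching is
  multiplicative e^(−t/τ_bleach) applied before additive Gaussian noise.
  Noise statistics of the real recordings are not published, so all noise
  levels are plausible placeholders and remain configurable.

What the generators do **not** emulate: optics (no PSF or scattering),
motion artifacts or registration errors, spatially correlated noise,
biophysics of P2RY1 signalling / K⁺ diffusion / osmotic volume change, and
the anatomical geometry of real IC/SC surfaces. Passing recovery tests
therefore demonstrates correctness of the analysis definitions on data
satisfying their assumptions, not robustness to every artifact of real
recordings.

## Problem sizes

Validation runs use desk-scale problem sizes chosen to give tight
sampling error at interactive run times: parameter recovery averages 30
seeds × 10 min recordings per rate; bilateral-ratio and tonotopic runs
use 5 Hz, 120–160 px-high movies with 40–50 events over 5 min; retinal
wave recovery uses 20 waves over 4 min at 10 Hz. The brute-force burst
oracle is compared on 1,000 random label sequences of length ≤ 80.

## Known limitations

- The subtractive bleach model cannot restore amplitudes attenuated by
  strong multiplicative bleaching (see above).
- Greedy bilateral pairing is not globally optimal when events are denser
  than the pairing window; at the event rates studied (≳4 s apart) it is
  exact.
- The current-event integral slightly underestimates charge for events
  whose tails fall below one noise SD before fully decaying.
- `detect_spikes` assumes positive-going spikes by default; use
  `polarity="neg"`/`"both"` for other recording configurations.
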