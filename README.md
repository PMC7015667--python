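# prehear

Analysis of spontaneous activity in the developing (pre-hearing) auditory
system.

Before hearing onset, inner supporting cells of the cochlea spontaneously
release ATP, depolarize inner hair cells via K⁺ efflux, and drive spiral
ganglion neurons to fire high-frequency bursts that propagate through the
entire auditory pathway. Characterizing this activity requires a stack of
small, precisely defined analyses spread across very different data types
— juxtacellular spike trains, voltage-clamp current traces,
transmitted-light and confocal Ca²⁺ movies of cochlear explants, and in
vivo widefield movies of the midbrain. `prehear` packages that stack for
developmental auditory neuroscientists, with a synthetic-data module that
emulates each recording type with known ground truth so every stage is
testable end to end.

## What it computes

- **Spike trains** (`prehear.spikes`): threshold spike detection on
  high-pass-filtered traces; ISI classification into mini-burst
  (< 30 ms), burst (30 ms – 1 s) and non-burst (> 1 s) intervals; bursts
  as clusters of ≥ 10 consecutive burst intervals (mini-bursts ignored
  for counting, their spikes included); burst frequency/duration/size,
  mean firing rate, ISI coefficient of variation, log-binned ISI
  histograms, 1 s-binned rates.
- **Voltage clamp** (`prehear.currents`): spontaneous inward-event
  detection against a rolling-median baseline with per-epoch
  frequency/amplitude/charge-transfer summaries; per-period holding
  current as the 95th-percentile sample value; baseline-normalized
  tail-current series from voltage-step sweeps.
- **Imaging core** (`prehear.movie`): per-pixel ΔF/F₀ with a
  5th-percentile baseline, single-exponential bleach correction, lagged
  difference movies, mean + k·SD masks, Gaussian-smoothed region areas in
  µm², thresholded peak detection.
- **Cochlear explants** (`prehear.cochlea`): crenation frequency and
  areas from transmitted-light movies; per-compartment (ISC/IHC/SGN)
  Ca²⁺ event statistics; IHC pairwise Pearson correlation with
  nearest-four-neighbour summaries.
- **Midbrain** (`prehear.midbrain`): IC event detection at a fixed 2 %
  ΔF/F threshold with amplitudes and half-widths; bilateral event pairing
  and weak/strong amplitude ratios; 125 × 50 px rotated-rectangle
  tonotopic line scans with 3 % band-peak detection, 25 µm spatial
  histograms and medial/lateral splits; global-event exclusion;
  SC retinal-wave detection (> 5 active downsampled pixels for > 1 s).
- **Statistics** (`prehear.stats`): D'Agostino K² normality test, t tests
  with Bonferroni correction, one-way ANOVA + Tukey HSD, and the
  normal-approximation two-mean sample-size formula
  n = (z₁₋α/₂ + z_power)² σ² (1 + 1/ratio) / Δ².
- **Synthetic data** (`prehear.synth`): seeded generators for all of the
  above with ground-truth event logs.

See `docs/methods.md` for definitions, defaults, and limitations.

## Worked example

Simulate a 10-minute SGN recording bursting at 2/min over sparse tonic
firing, detect bursts, and summarize:

```python
from prehear import classify_isis, detect_bursts, burst_metrics
from prehear import sample_size_two_means, PowerSpec
from prehear.synth import SpikeGenSpec, gen_spike_train

spec = SpikeGenSpec(duration=600.0, burst_rate=2.0, tonic_rate=0.1, seed=42)
train, truth = gen_spike_train(spec)
bursts = detect_bursts(classify_isis(train))
m = burst_metrics(bursts, train, window=600.0)
print(f"simulated bursts: {len(truth)}, detected: {len(bursts)}")
print(f"burst frequency : {m.burst_freq:.2f} /min")
print(f"burst duration  : {m.mean_duration:.2f} s")
print(f"spikes per burst: {m.mean_spikes_per_burst:.1f}")
print(f"mean AP rate    : {m.mean_ap_freq:.2f} Hz")
print(f"ISI CV          : {m.isi_cv:.2f}")
n = sample_size_two_means(PowerSpec(mu1=10, mu2=7, sigma=2))
print(f"animals per group for 80% power: {n}")
```

Output:

```
simulated bursts: 15, detected: 15
burst frequency : 1.50 /min
burst duration  : 1.57 s
spikes per burst: 16.3
mean AP rate    : 0.51 Hz
ISI CV          : 2.42
animals per group for 80% power: 7
```

Every simulated burst is recovered (the realized rate of this particular
600 s draw is 1.5/min). The mean AP rate counts all spikes — burst and
tonic — over the window, and the ISI CV well above 1 reflects bursty
firing; a Poisson train gives CV ≈ 1 and a clock-like train CV = 0. The
last line reproduces the classical design calculation for detecting a
10-vs-7 difference with common SD 2 at 80 % power and two-sided α = 0.05.

The same analyses are available from a shell:

```sh
prehear synth spikes --duration 600 --burst-rate 2 --seed 42 --out spikes.csv
prehear spikes bursts spikes.csv --out bursts.csv
prehear spikes metrics spikes.csv
prehear stats power --mu1 10 --mu2 7 --sigma 2
```

and multi-stage runs are driven by a YAML config via `prehear run
config.yaml --outdir results/` (the exact config used is copied into the
run directory; fixed seeds reproduce outputs byte for byte).

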