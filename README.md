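# sniffcode

Sniff-aligned analysis of how cortical ensembles encode odor **identity**
and odor **intensity** — by firing *rate* or by spike *timing* — in
awake-rodent recordings where every trial is referenced to the first
inhalation of odor.

In higher olfactory areas (lateral entorhinal cortex and hippocampal CA1),
odor-evoked spiking is concentrated in the first ~100 ms of a sniff.
Which odor was presented is carried by *which* neurons increase their
firing rate (a rate/ensemble code), while *how much* odor was presented is
carried largely by *when* responses peak: latencies shift earlier and
populations fire more synchronously as concentration rises, with
magnitudes that differ between principal-cell classes (latency-invariant
"fan-like" cells vs latency-shifting "pyramidal-like" cells). `sniffcode`
implements the full analysis chain needed to make and test such claims,
plus a ground-truth-tagged synthetic-session generator so that every stage
is validated by parameter recovery rather than by eye.

## What's inside

| module | contents |
| --- | --- |
| `sniffcode.synth` | respiration, trial, spike-train and 2AFC-session generator with programmed concentration laws |
| `sniffcode.respiration` | inhalation-onset detection, trial alignment to t0, aligned rasters, optogenetic phototag identification |
| `sniffcode.metrics` | spike-density functions (Gaussian kernel, σ = 10 ms), windowed rates, activated-unit tests vs blank, lifetime sparseness, odd/even cross-validated peak maps |
| `sniffcode.geometry` | pseudopopulation tensors, PCA trajectories, Euclidean-distance discriminability time courses |
| `sniffcode.decoding` | linear SVM (one-vs-one, 20% stratified holdout) with sliding/fixed windows, rate vs binary features, ensemble-size curves |
| `sniffcode.temporal` | peak-time/peak-rate statistics, Spearman concentration trends, pairwise peak-time synchrony, latency-shift regression |
| `sniffcode.behavior` | 2AFC percent correct, cumulative-response d′ time courses, significance onset, LED (silencing) comparisons |
| `sniffcode.pipeline` / CLI | config schema, tidy-CSV formats, provenance manifest, `sniffcode run-all` |

Key statistics, in the field's notation:

- **Lifetime sparseness** of a unit over N odors, from mean rate changes
  r_j (negatives clipped to 0):
  S = [1 − (Σ r_j / N)² / (Σ r_j² / N)] / (1 − 1/N),
  with S = 1 completely selective, S = 0 nonselective.
- **Spike-density function**: each spike contributes a unit-area Gaussian
  (σ = 10 ms); peak time is the earliest argmax in [0, 300) ms after t0.
- **d′** of cumulative 2AFC responses: d′(t) = z(HR(t)) − z(FAR(t)) with a
  log-linear correction (counts + 0.5, totals + 1).
- **Synchrony**: mean |Δ peak time| over pairs of activated cell–odor
  responses, within odor, averaged across odors — decreasing values mean
  more synchronous firing.

## Worked example

Simulate a two-class session (six odors at 0.25/0.33/0.50/1.00 relative
concentration, 25 repetitions each) and run the core analyses:

```python
import numpy as np
import sniffcode as sc
from sniffcode import metrics as met, geometry as geo, temporal as tem

cfg = sc.GeneratorConfig(
    classes={"fan": sc.ClassParams(n_units=50, latency_mean=0.072),
             "pyramidal": sc.ClassParams(n_units=50, latency_mean=0.078,
                                         latency_shift_per_doubling=-0.010)},
    n_odors=6, trials_per_condition=25)
trace, trials, spikes, gt = sc.simulate_session(cfg, seed=7)

onsets = sc.detect_inhalation_onsets(trace)
raster = sc.build_raster(spikes, sc.align_trials(trials, onsets))
activation = sc.activated_units(sc.window_rate(raster, (0.050, 0.100)),
                                raster.trials)

sdf = met.condition_sdf(raster)
keep = (sdf.index["odor_id"] != "blank").to_numpy()
sdf.index, sdf.rate = sdf.index[keep].reset_index(drop=True), sdf.rate[keep]
peaks = tem.peak_stats(sdf, activation=activation, activated_only=True)
peaks = peaks.merge(gt.units, on="unit_id")
for cls in ("fan", "pyramidal"):
    slope, se = tem.latency_shift_regression(peaks[peaks.class_label == cls])
    print(f"{cls} latency shift: {slope*1e3:.1f} +/- {se*1e3:.1f} ms/doubling")

tensor = geo.build_response_tensor(raster, step=0.005)
top = tensor.select(concentration=1.0)
res = sc.decode_fixed(top, top.conditions["odor_id"].to_numpy(),
                      window=(0.050, 0.100), n_repeats=10, seed=0)
print(f"identity decoding: {res.mean_accuracy:.2f} (chance {res.chance:.2f})")
```

prints

```
fan latency shift: -3.9 +/- 4.4 ms/doubling
pyramidal latency shift: -8.6 +/- 3.7 ms/doubling
identity decoding: 0.98 (chance 0.17)
```

The pyramidal-like population recovers its programmed −10 ms/doubling
latency shift (the fan-like estimate is consistent with 0), and odor
identity decodes almost perfectly from early firing rates.  Intensity
decoding from the same rate features averages 0.30 against a chance level
of 0.25 — rates carry little concentration information here — while the
mean pairwise peak-time difference of the same responses falls from
46.9 ms at the lowest concentration to 29.7 ms at the highest: the
population synchronizes as intensity grows, which is the temporal code.

The same chain runs from the shell:

```bash
sniffcode run-all --config my_run.yaml --seed 7 --out results/
```

writing tidy CSVs (activation matrix, sparseness, PCA trajectories and
distances, decoding accuracies, peak statistics, synchrony, d′ curves) and
a provenance manifest; a fixed seed makes the outputs byte-reproducible.

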