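# hipposlice

Quantification toolkit for hippocampal slice electrophysiology and
synapse morphometry:

- **Sharp-wave ripples (SWR)** — detection on 45 Hz low-passed LFP at a
  2.5 SD threshold with an 80 ms refractory rule; SW area by trapezoidal
  integration between mean crossings of the 125 ms event window; ripple
  count/amplitude/frequency from the 120–300 Hz band in a 25 ms window
  at a 3 SD threshold.
- **Carbachol gamma** — averaged periodogram at 0.8192 Hz resolution,
  peak frequency/power and 20–60 Hz integrated power, slice exclusion
  (integrated power < 1e-5 mV² or peak < 20 Hz), and the second positive
  autocorrelation peak of the < 100 Hz low-passed trace.
- **fEPSP / LTP** — slope over the 20–80 % rising phase, input–output
  curves and half-max intensity, paired-pulse ratios at ISIs of
  10/20/50/100/200 ms with mono-exponential tail correction, and LTP
  series normalized to a 100 % baseline with last-10-minute summaries.
- **Morphometry** — six-class spine classifier (branched → filopodia →
  mushroom → stubby → thin → long-thin precedence), density per 50 μm
  and segment → neuron → animal aggregation, polygon-ROI mean intensity
  per μm², puncta detection and two-channel colocalization per 50 μm.
- **Synthetic data** — generators for every input above with exact
  ground truth (implanted SWR events, stationary gamma oscillations,
  evoked sweep series, per-class spine tables, two-channel puncta
  fields), so each stage is verifiable offline.
- **Reporting** — Shapiro–Wilk-gated two-group comparison (t-test vs
  Mann–Whitney U) and an end-to-end simulate → quantify → compare
  pipeline for two-cohort synthetic experiments.

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` with one test per
acceptance criterion (the type-I-control test runs a 200-replicate
pipeline experiment and takes a few minutes).

## CLI

```bash
hipposlice simulate-lfp --duration 120 --fs 10000 --sw-rate 0.2 --seed 1 --out trace.csv
hipposlice swr --input trace.csv --out events.csv
hipposlice gamma --input trace.csv --out metrics.json
hipposlice fepsp --manifest manifest.csv --hfs-time 0 --out-dir fepsp_out/
hipposlice spines --input spines.csv --out classified.csv
hipposlice puncta --image field.tiff --px-size-um 0.2 --threshold 20 --out coloc.json
hipposlice pipeline --seed 1 --out-dir report/
```

LFP traces are CSV (`time_s,mv`) or raw little-endian float32 with a
JSON sidecar; images are multi-page TIFF; tables are CSV.

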