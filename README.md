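# marmoephys

Analysis pipeline for multi-area extracellular recordings combined with
optogenetics and a saccade-based detection task. The package covers:

- **`marmoephys.core`** — shared data model (`RecordingBlock`, `TrialTable`,
  `EyeTrace`, `SpikeCluster`), on-disk formats (flat binary + JSON sidecar,
  CSV trial/eye tables, HDF5 spike clusters), YAML configuration
  (`AnalysisConfig`) and deterministic named random streams (`seeded_rng`).
- **`marmoephys.synth`** — synthetic-data generators with ground truth for
  every pipeline input: laser power waveforms (sinusoidal and tapered square
  pulses), multichannel recordings with visual/opto-entrained units on a
  32-site 25 µm-pitch shank, eye traces with velocity-profiled saccades,
  detection-task sessions with per-condition hit probabilities and a
  homogeneous false-alarm hazard, wedge/annulus receptive-field responses,
  and the deterministic worked-example session used for the acceptance
  targets.
- **`marmoephys.preprocess`** — polyphase resampling (24 414.0625 Hz →
  25 kHz), per-shank common-median re-referencing, spike-band filtering
  (4th-order Butterworth 0.3–6 kHz or 40th-order Chebyshev II 0.3–8 kHz with
  200 dB stopband attenuation), MUA envelope extraction (rectify → 6th-order
  Chebyshev II low-pass, 500 Hz edge, 50 dB → 1 kHz) and event-aligned
  epoching.
- **`marmoephys.modulation`** — baseline z-scoring, MUA modulation
  classification (|z| > 3 AND two-sided KS p < 0.05), single-unit modulation
  (rank-sum + z criterion), Gaussian-smoothed PSTHs, 0.33 ms
  autocorrelograms, von Mises orientation-tuning fits and firing-rate
  stability traces.
- **`marmoephys.qc`** — spike-cluster curation: ≤ 2.5% inter-spike intervals
  below 1.5 ms, peak-channel waveform correlating at r ≥ 0.95 with one of 20
  reference templates, spatial footprint concentrated within < 5 channels;
  trimmed-mean waveform summaries.
- **`marmoephys.rfmap`** — receptive-field mapping: fixation-controlled
  280 ms epochs, 10× median-STD noise rejection, the ≥ 3-wedges-AND-≥ 3-annuli
  paired-t modulation criterion (p < 0.01), and normalized maps with a 0.2
  outline level.
- **`marmoephys.behavior`** — saccade detection (3 ms-σ smoothing, 50 °/s
  velocity threshold, 25 ms endpoint medians), trial-outcome scoring
  (50–500 ms hit window, 800 ms catch fixation), per-condition rates with
  Clopper–Pearson intervals, the resampling correction for the
  unequal-duration catch trials, Yates-corrected pairwise chi-squared tests
  with Benjamini–Hochberg adjustment, and signal-detection-theory d′/c with
  bootstrap confidence intervals and contrast p-values (10 000 replications,
  floor 1/B).

## CLI

```sh
marmoephys simulate session --out trials.csv --n-trials 500 --seed 1
marmoephys simulate eye --trials trials.csv --out eye.csv --seed 1
marmoephys simulate recording --out rawdir --duration 2 --seed 1
marmoephys preprocess --in rawdir --out mua.h5 --design cheby2_40_300_8000
marmoephys modulate --mua mua.h5 --trials trials.csv --mode visual --out mod.csv
marmoephys qc --spikes spikes.h5 --out qc.csv
marmoephys behavior --trials trials.csv --eye eye.csv --out report.json --seed 1
marmoephys sdt --rates rates.csv --b 10000 --seed 1 --out sdt.json
```

`marmoephys simulate session --fig8-fixture` writes the deterministic
worked-example session whose per-condition totals and responder counts match
the published count tables.

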