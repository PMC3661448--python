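# epgkit

Simulation, detection and phenotyping of *C. elegans* electropharyngeogram
(EPG) recordings.

An EPG trace is a single-channel extracellular voltage recording of the
pharyngeal pump cycle. Each pump shows five phases: a small positive `e`
spike leading the large positive excitation spike `E`, a variable number of
small negative `P` waves in the plateau, and the large/small negative
relaxation spikes `R`/`r`. `epgkit` provides:

- **`epgkit.trace`** — the `Trace` container (mV vs seconds, uniform
  sampling) with a diff-friendly two-column CSV format (`#` metadata
  comments, bit-exact round trips) and optional condition schedules
  (serotonin wash-in, ethanol, light epochs).
- **`epgkit.synth`** — a phenomenological EPG generator with per-transient
  ground truth. Shipped phenotype presets (`wt_basal_chip`, `wt_5ht_chip`,
  `eat4_chip`, the conventional-electrode variants, and `tail` for worms
  recorded tail-first) reproduce published per-strain means for pump
  frequency, duration, P-wave count, amplitudes and R/E ratio. Pump onsets
  follow a refractory gamma renewal process whose mean rate is exact;
  condition schedules modulate rate, duration, P intensity and E amplitude.
- **`epgkit.preprocess`** — zero-phase Bessel high-pass for baseline drift
  (designed so the gain at the configured cutoff equals the configured
  attenuation, default 0.5 Hz at −30 dB), running-median baseline
  estimation, and a robust MAD-based SNR estimator.
- **`epgkit.detect`** — pump segmentation and five-phase labeling:
  noise-sigma-scaled thresholds on a smoothed working signal, greedy E–R
  pairing by spike magnitude, matched-filter (Gaussian template + local
  offset) amplitude estimation, and an orientation gate that rejects
  tail-first/low-quality recordings.
- **`epgkit.params`** — the seven per-recording EPG parameters
  (peak-to-peak amplitude, frequency, E→R duration, R→E interval, P waves
  per pump, `e` amplitude, R/E ratio), binned time courses, per-condition
  epoch summaries, and Welch t-tests with the worm as the replication unit.
- **`epgkit.classify`** — wild-type reference bounds (mean ± k·sd, k = 3 by
  default) and worm sorting with the published screening thresholds
  (duration > 0.1445 s AND P/pump < 0.169 ⇒ mutant; the disjunction rule is
  available as a config option), plus a full cohort screening workflow with
  confusion matrices against simulated ground truth.

## CLI

One executable, `epg`, with three subcommands:

```bash
# simulate 5 serotonin-stimulated worms, 120 s each, with ground truth
epg simulate --preset wt_5ht_chip --n 5 --duration 120 --seed 1 --out sim/

# high-pass, detect pumps, compute parameters and time courses
epg analyze sim/*.csv -o analysis/ --bin 30 --plots

# screen a cohort against the published thresholds
epg sort sim/*.csv --thresholds 0.1445 0.169 --rule conjunction \
    --manifest sim/manifest.json -o screen.json

# or fit 3-sigma bounds from wild-type reference recordings
epg sort traces/*.csv --fit-reference analysis/params.json --k 3 -o screen.json
```

`analyze` emits one event table TSV (`worm.events.tsv`), a per-worm
parameter record in `params.json`, and a per-worm time-course CSV.
`sort` writes a JSON screening report with verdicts, counts, the echoed
thresholds/rule, and (when a manifest supplies true labels) a confusion
matrix. Detection and filter settings can be overridden with a YAML config
(`--config cfg.yml`, keys mirror `DetectionConfig`).

## Library quick start

```python
from epgkit import (load_preset, generate_trace, highpass, detect_pumps,
                    compute_parameters, classify)

trace, truth = generate_trace(load_preset("eat4_chip"), duration=600, seed=0)
events = detect_pumps(highpass(trace))
params = compute_parameters(events, trace)
print(params.duration, params.p_per_pump)
print(classify(params).label)        # 'mutant'
```
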