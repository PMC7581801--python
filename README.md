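# dbsweep

Analysis toolkit for systematic deep-brain-stimulation (DBS) parameter
sweeps read out through induced rotational behavior in the
hemi-parkinsonian rat model. The package covers the full desk-side
pipeline:

- **`dbsweep.waveforms`** — charge-balanced biphasic pulse calculus:
  charge per phase for Rect / Sine / Tri / LinDec envelopes,
  charge-equivalent amplitudes across shapes, charge rate (μC/s),
  frequency charge multipliers, the TEED index, and μs-resolution sampling
  of pulses and trains.
- **`dbsweep.protocols`** — the three session timelines (amplitude sweep,
  frequency sweep, charge-matched waveform sweep) with 30-s ON / 45-s OFF
  episode structure and YAML round-tripping.
- **`dbsweep.cohort`** — synthetic cohort generator: latent per-animal
  thresholds, a linear dose–response in effective charge multiplier, a
  50–180 Hz plateau frequency gain, reduced efficacy for non-Rect shapes,
  threshold titration with a dyskinesia exclusion rule, the apomorphine
  lesion challenge, and session simulation (angular trajectory + 2-D
  locomotion in a corner-free bowl).
- **`dbsweep.rotometry`** — per-episode features: max/net rotation, area
  under the rotation–time curve, path length; lesion-success assessment.
- **`dbsweep.similarity`** — Euclidean-distance matrices between
  condition-averaged rotation traces.
- **`dbsweep.stats`** — Pearson correlation on per-level cohort means with
  exact small-n two-tailed significance (closed form at 3 df), and paired
  Rect-vs-alternative waveform t-tests.
- **`dbsweep.io` / `dbsweep.cli`** — text-based readers/writers
  (trajectory CSV, protocol YAML, feature/matrix tables, checksum
  manifest) and the command-line entry points.

## CLI

`dbsweep --help` lists the subcommands. Examples:

```sh
# one charge-balanced Sine pulse, sampled at 1 μs
dbsweep waveform --shape SINE --amp-ua 100 --pw-us 100 --out pulse.csv

# emit an amplitude-paradigm protocol config
dbsweep protocol --paradigm amplitude --i0-ua 60 --out protocol.yaml

# full synthetic run: cohort, titration, sessions, features,
# correlations, ED matrix, manifest
dbsweep run --paradigm amplitude --seed 1 --out out/amplitude

# features for one trajectory / similarity + stats from a run directory
dbsweep features --traj out/amplitude/trajectories/rat000.csv \
    --protocol out/amplitude/protocols/rat000.yaml --out features.csv
dbsweep similarity --run-dir out/amplitude --out ed.csv
dbsweep correlate --features out/amplitude/features.csv \
    --paradigm amplitude --out corr.csv
```

## Conventions

- Units: μA, μs, μC internally; 1 μA·μs = 1 pC. Angles in degrees,
  contralateral rotation positive.
- Episode windows are half-open `[start, end)`; session time origin is the
  first ON onset.
- The TEED index is implemented exactly as printed in the source
  literature (`I²·f·PW/Z`) despite its dimensional oddity for
  current-controlled stimulation; see the docstring.
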