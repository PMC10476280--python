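# tirfkin

Residence-lifetime kinetics for single-molecule TIRF colocalization
experiments, from raw multi-channel movies (or a built-in simulator) to
off-rates, Kaplan–Meier survival curves, and ternary-complex statistics.

## The scientific problem

In a colocalization single-molecule assay, surface-tethered DNA templates are
imaged in one channel (e.g. 647 nm) while fluorescently labeled proteins bind
and release in one or two other channels (e.g. 488/561 nm). Each DNA spot
yields an intensity trace per protein channel; above-background pulses in a
trace are individual residences of a protein on that template. The questions
the package answers:

- **How long do molecules stay?** Residence durations are right-censored by
  the end of the movie and shortened by photobleaching, so survival analysis
  (Kaplan–Meier, log-rank) and censoring-aware rate estimation are required,
  not naive averaging.
- **Does a partner protein stabilize the complex?** Each residence of a
  focal protein is partitioned into time spent with and without a partner
  protein co-resident on the same template ("ternary" vs "non-ternary"
  time), and off-rates are compared between the two pools.
- **How many molecules are in a spot?** Stepwise photobleaching of the
  intensity staircase counts labeled molecules.
- **What fraction of templates are occupied?** Snapshot (endpoint)
  colocalization scores the fraction of DNA spots with a protein spot within
  a match radius.

## The model

Binding at each template is a continuous-time two-state chain: arrivals at
rate `k_on`, and bound intervals ending by the first of two competing
exponential risks — true detachment (`k_off`) or photobleaching
(`k_bleach`), all in events/hour. The observed total loss rate is
`k_off + k_bleach`, and bleach-only controls isolate `k_bleach`. Off-rates
are estimated by the exponential maximum-likelihood estimator
`k = N_off / ΣT` (events per total observed residence time, reported per
hour), which handles right-censored residences naturally. Each focal
residence is split into five interval classes by partner co-residency
(partner already present; co-arrival within a window; before partner
arrival; partner never present; after partner arrival, carried forward), and
a detachment event is assigned to the ternary pool if the residence was ever
ternary.

## Worked example

Simulate a 45-minute acquisition (DNA snapshots every 60 s, protein frames
every 5 s → 541 frames) over 100 templates with two protein channels at
total loss rates 30/h (488) and 20/h (561), then run the full pipeline —
drift correction, spot detection, trace extraction, pulse detection,
residence partitioning, survival statistics:

```python
import json
from tirfkin.schedule import AcquisitionSchedule
from tirfkin.simulate import SimulationParams, SpeciesKinetics, DriftSpec
from tirfkin.workflow import RunConfig, run_timelapse

config = RunConfig(
    schedule=AcquisitionSchedule(2700.0, {"647": 60.0, "488": 5.0, "561": 5.0}),
    simulation=SimulationParams(
        n_spots=100,
        field_size=(256, 256),
        kinetics={
            "488": SpeciesKinetics(k_on=2.0, k_off=28.0, k_bleach=2.0),
            "561": SpeciesKinetics(k_on=2.0, k_off=18.0, k_bleach=2.0),
        },
        drift=DriftSpec(velocity=(0.002, 0.001)),
        seed=42,
    ),
    seed=42,
)
result = run_timelapse(config)
print(json.dumps(result.summary, indent=2, sort_keys=True, default=float))
```

Output (abridged; the run is deterministic for a fixed seed):

```
{
  "k_non_ternary_per_h": 27.903699354081034,
  "k_ternary_per_h": 23.326133909287254,
  "logrank_p": 0.025370115420981987,
  "median_non_ternary_s": 75.0,
  "median_ternary_s": 245.0,
  "n_focal_pulses": 157,
  "n_spots": 100,
  "n_ternary": 17,
  "n_non_ternary": 140,
  "occupancy_fraction": 0.3987823439878234,
  "p_short": 0.6178343949044586,
  "p_long": 0.07006369426751592,
  "residences_per_spot": 1.57
}
```

Reading it: all 100 simulated DNA templates are detected, 157 focal (488)
residences are recovered, 17 of which ever coexisted with a 561 partner on
the same template. The focal off-rate while in the ternary pool (23.3/h) is
lower than in the non-ternary pool (27.9/h) with log-rank p = 0.025, and the
ternary median residence (245 s) exceeds the non-ternary one (75 s) — here
because long residences simply have more opportunity to ever see a partner,
which is exactly the selection effect the partitioned time-normalized rates
are designed to keep honest relative to naive median comparisons.

With `config.outdir` set, the run also writes `spots.csv`, `traces.csv`,
`pulses.csv`, `partitions.csv`, `survival_*.csv`, `summary.json`, and a
`manifest.json` that reproduces the run bit-identically.

## Command line

```
tirfkin simulate  --config config.yaml --outdir movie/      # movie + ground truth
tirfkin timelapse --config config.yaml --outdir out/        # full pipeline
tirfkin stats     out/pulses.csv --n-spots 100              # re-stats, no images
tirfkin endpoint  --config config.yaml --n-fields 4         # snapshot colocalization
```

Exit codes distinguish configuration (2), data (3), and compute (4) errors.

## Reproducing results

```
python -m pytest -q                                   # full suite, ~2 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(schedule arithmetic, pulse-detection oracle equivalence, partition
conservation, off-rate recovery, Kaplan–Meier correctness, log-rank/t-test
calibration, end-to-end imaging recovery, photobleach competing-risk
identities, step counting). The acceptance script recomputes the headline
quantities from scratch under a user-chosen seed; at `--seed 1` it reports,
among others: end-to-end recovered rates 28.97 vs 19.33/h for programmed
30 vs 20/h (log-rank p = 8.8e-6), spot recall 1.0 (n = 200), drift error
0.055 px, pulse-onset accuracy 0.978 within one frame, log-rank/t-test
type-I errors 0.047/0.0455 (n = 2000 each), two-dye step-count accuracy
0.92, and 70.0% endpoint colocalization at 70% programmed occupancy.

See `docs/methods.md` for the underlying models, parameter defaults,
numerical choices, and known limitations.
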