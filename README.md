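# elneuro

Electrical-neuroimaging statistics and Go/NoGo behavioral analysis for
2×2 mixed-design (group × session) ERP training studies, with synthetic-data
generators for every pipeline stage.

The package is aimed at EEG/ERP researchers who analyze inhibitory-control
(Go/NoGo) training interventions with *global* scalp-field statistics rather
than single-electrode amplitudes, and who need the full chain — adaptive task
logic, exclusion rules, behavioral ANOVAs, ERP preprocessing, microstate
segmentation, and time-frame-wise randomization tests — as tested, seedable,
reusable code.

## The statistics at its core

Let `u(t) ∈ R^C` be the average-referenced scalp potential map at timeframe
`t` over `C` electrodes, with spatial mean `ū`.

- **Global field power** — `GFP(t) = sqrt((1/C) Σ_i (u_i − ū)²)`, the spatial
  standard deviation of the map: a reference-free index of response
  *strength*.
- **Global map dissimilarity** — for maps `u, v` scaled to unit GFP after
  average referencing, `GMD = sqrt((1/C) Σ_i (û_i − v̂_i)²) ∈ [0, 2]`, with
  `GMD² = 2(1 − r_spatial)`: an index of field *configuration* that is
  orthogonal to strength (rescaling a map changes GFP, never GMD).
- **TANOVA-style randomization tests** — at every timeframe, the effect
  contrast of GFP values (strength) or the GFP of the contrast map of
  normalized topographies (configuration) is compared with its
  re-randomization distribution (session labels swapped per subject, group
  labels shuffled, or both for the interaction);
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`.
- **Duration threshold** — correction for multiple comparisons over
  timeframes: the minimal run length `L` of consecutive significant
  timeframes such that `P(longest null run ≥ L) ≤ α` under the permutation
  distribution, computed by ranking each permutation inside the pool.
- **Microstate segmentation (AAHC)** — atomize-and-agglomerate hierarchical
  clustering of grand-average topographies; the number of template maps is
  chosen by a cross-validation criterion combined with the Krzanowski–Lai
  criterion, and component (N2/P3) onsets are the start of the template's
  first sufficiently long assignment run — used to lock ERPs across groups
  with different component latencies.
- **Behavioral statistics** — the adaptive response-time threshold
  (running median of previous correct-Go RTs), a fixed-order exclusion
  cascade, 2×2 mixed ANOVA with generalized eta squared
  `η_G² = SS_effect / (SS_effect + SS_subj + SS_sess×subj)`, Holm-corrected
  paired follow-ups with `r = sqrt(t²/(t²+df))`, a BIC-approximated Bayes
  factor `BF01` for the interaction, training-day regressions, and the
  speed–accuracy trade-off correlation.

A synthetic-data module generates 64-channel ERP datasets with quasi-stable
component topographies into which group × session effects can be injected
either as a pure gain change (GFP only) or a pure topographic rotation
(GMD only, GFP preserved to machine precision), plus Go/NoGo trial streams
with the task's exact design (36 Go / 24 NoGo per block, 70/30 cue
contingencies, adaptive deadline, ex-Gaussian RTs, training drifts, coupled
RT/FA changes).

## Worked example

Run the age contrast end-to-end on simulated data with a topographic
interaction injected into the 200–320 ms window of the older group's
post-training session, and a 30 ms latency delay of the older group:

```python
from elneuro.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    contrast="age", out_dir="run_age", seed=7, n_perm=1000,
    n_per_group=16, n_behav_per_group=29,
    erp_effects=[{"kind": "topo", "window_ms": (200.0, 320.0),
                  "group": "older", "session": "post", "angle_deg": 30.0}],
    latency_shift_ms=30.0,
)
out = run_pipeline(cfg)
print((out / "report.txt").read_text())
```

which prints (abridged):

```
## Behavior
trials in/out: 41760/40069; blocks excluded: 18/696; sessions removed: 0
### RT mixed ANOVA
  group        F(1,56) = 43.550, p = 0.0000, ges = 0.4103
  session      F(1,56) = 191.346, p = 0.0000, ges = 0.2646
  interaction  F(1,56) = 0.160, p = 0.6910, ges = 0.0003
  BF01 (interaction) = 9.131
...
speed-accuracy trade-off: r(56) = -0.239, p = 0.0706

## Electrical neuroimaging
segmentation: K = 4
  N2 onset older/pre: 204.7 ms
  N2 onset young/pre: 173.4 ms
gfp interaction: duration threshold = 15 tf
  no supra-duration periods
topo interaction: duration threshold = 21 tf
  POI: 200.8 to 321.9 ms
```

Reading the numbers: the behavioral chain excluded 18 of 696 blocks and kept
the session main effects (everyone speeds up and commits more false alarms
after training) with no RT interaction (`BF01 = 9.1` supports the null). The
segmentation found the older group's N2 onset 31 ms after the young group's
(the injected 30 ms delay, to one timeframe), locked the ERPs accordingly,
and the topographic — but not the GFP — interaction test flagged a sustained
period of interest covering exactly the injected 200–320 ms window.

The same stages are scriptable from the shell:

```sh
elneuro run --config run.yaml
elneuro simulate erp --contrast age --seed 7 --out sim/
elneuro tanova --design sim/ --metric topo --effect interaction --n-perm 5000 --seed 7
elneuro segment --erps sim/ --k 2:8 --component N2 --window 150:350
elneuro behavior --trials trials.csv --out report/
```

## Layout

- `elneuro.field_core` — montages, GFP, GMD, average reference, multiquadric
  bad-channel interpolation
- `elneuro.preprocess` — band-pass filter, epoching, artifact rejection,
  averaging, component locking, TSV/JSON ERP I/O
- `elneuro.randomization` — time-frame randomization tests, duration
  threshold, cluster-extent Monte-Carlo calibration
- `elneuro.microstates` — AAHC segmentation, CV + Krzanowski–Lai model-order
  selection, component onsets
- `elneuro.behavior` — task rules, exclusion cascade, mixed ANOVA, Bayes
  factors, regressions
- `elneuro.simulate` — ERP and Go/NoGo generators (the study conditions)
- `elneuro.pipeline` / `elneuro.cli` — end-to-end contrasts and the
  `elneuro` command

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
numerical choices.
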