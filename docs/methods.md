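# Methods

This note documents the models, defaults, and numerical choices behind
`elneuro`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scalp-field descriptors

GFP is the *population* spatial standard deviation (`1/C`, not `1/(C−1)`).
This convention keeps the GMD bound `[0, 2]` exact and makes
`GMD² = 2(1 − r_spatial)` an identity, which the tests assert to 1e-10.
GMD normalizes each map to unit GFP *per timeframe* after average
referencing ("instantaneous" normalization); a zero-GFP map has no defined
topography and is rejected.

Bad-channel interpolation fits a multiquadric radial basis function
`φ(r) = sqrt(r² + c²)` over the good channels' 3-D positions, one linear
solve shared by all timeframes. Distances are Euclidean (chord), not
geodesic — the simplest faithful multiquadric on a spherical cap. The shape
parameter `c` defaults to the montage's median inter-electrode distance and
is configurable; the interpolant passes through the retained channels
exactly, and on smooth dipolar test fields the single-channel
reconstruction error is below 1% of the field range (asserted in tests).
scipy's `RBFInterpolator` provides the solver; its kernel
parameterization differs from the classical form only by a constant factor
that the fitted weights absorb.

The default montage is the standard 64-channel 10-10 layout (Biosemi
geometry) obtained from mne's bundled montage set at runtime and projected
to the unit sphere. No external downloads are involved.

## Preprocessing chain

- **Filter**: 4th-order Butterworth band-pass (defaults 0.5–40 Hz) applied
  forward–backward (`sosfiltfilt`), so the passband is phase-neutral and
  component latencies are untouched. The order is configurable; the
  effective roll-off of the two-pass application is double the design
  order.
- **Epoching**: half-open window `[start, end)` relative to stimulus onset;
  the timeframe count is `floor((end−start)/1000·srate)`, so shapes are
  reproducible from metadata alone (a −100..700 ms epoch at 256 Hz has 204
  timeframes). Baseline correction subtracts each epoch's own per-channel
  whole-epoch mean. Events whose window leaves the recording are skipped
  and logged, not fatal.
- **Artifact rejection**: an epoch is dropped when any electrode jumps more
  than 30 μV between consecutive timeframes or exceeds 80 μV in absolute
  voltage. Set semantics: order-independent, idempotent; the jump check
  runs post-filtering, pre-averaging, matching the pipeline order.
- **Averaging**: arithmetic mean over surviving trials, then common average
  reference. The reference step at the averaged stage is what all
  statistics consume; upstream hardware referencing is irrelevant to the
  global measures, which are reference-free.
- **Component locking**: ERPs are aligned by integer-timeframe shifts so
  that each cell's component onset maps to the latest onset among cells,
  and all outputs are truncated to the intersection window. Truncation
  rather than padding avoids fabricating data at epoch edges; the retained
  window is reported alongside the shifts.

## Randomization statistics

Subject-condition data enter as average-referenced maps. For the *strength*
metric the per-timeframe feature is scalar GFP; for the *topography* metric
each map is additionally scaled to unit GFP, and the statistic is the GFP
of the effect's contrast map. Both statistics are magnitudes, so tests are
inherently two-sided. Rescaling every map of one design cell changes only
the strength statistic — the orthogonality is exact and asserted on
arbitrary data.

Re-randomization schemes (2×2 mixed design, within factor session, between
factor group):

- **session** — each subject's pre/post labels swap independently with
  probability 1/2 (sign flip of the within-subject difference);
- **group** — group labels are shuffled across subjects;
- **interaction** — both.

These are the standard approximate-exchangeability randomizations for mixed
designs in the topographic-ANOVA literature. p-values follow
`(1 + #{perm ≥ obs}) / (n_perm + 1)` and are never exactly zero. Degenerate
inputs (identical cells) produce exact ties and hence `p = 1`; statistics
below `1e-12` of the feature scale are clamped to exact zero so this holds
under floating-point summation-order noise.

**Duration threshold.** Each permutation's statistic is ranked within the
pooled permutation distribution per timeframe (mid-rank ties), giving a
pseudo p-value series per permutation in O(n_perm) — the rank trick that
avoids nested permutations. The duration threshold is the smallest run
length `L` with `P(longest run of pseudo-p < α) ≥ L) ≤ α`. Runs touching
the epoch edge count like any other; no edge correction. Periods of
interest are observed runs of `p < α` at least `L` long. The test suite
checks the threshold against a brute-force longest-run oracle on
Bernoulli(0.05) sequences (10,000 draws, T = 200) and the dataset-wise
false-positive rate of the corrected topographic interaction test on 200
null datasets (within 0.03 of the nominal 0.05).

**Cluster-extent calibration.** For node graphs (e.g. source grids), iid
standard-normal fields are optionally smoothed with a Gaussian kernel over
graph distance (FWHM in graph units; rows renormalized to unit node
variance so the two-sided node threshold stays calibrated), thresholded,
and the maximal connected supra-threshold cluster recorded per draw; the
returned `Ke` is the smallest size whose exceedance probability is at most
the requested FWER. On a chain graph this reduces to a longest-run problem,
which the tests exploit as an independent oracle.

## Microstate segmentation

AAHC starts from every timeframe as its own cluster and repeatedly
dissolves the cluster contributing least global explained variance
(GEV-weighted squared spatial correlation with its template), reassigning
each orphaned map to the best-correlating remaining cluster. Correlation is
*signed* by default: ERP components have meaningful polarity, unlike
spontaneous-EEG microstates (a polarity-insensitive mode exists and
sign-aligns members before averaging). Solutions are recorded at every K in
the requested range; templates are unit-GFP cluster means; zero-GFP
timeframes are excluded with a warning.

Model order combines two criteria:

- **CV criterion** (minimize): residual variance ×
  `((C−1)/(C−1−K))²`, residuals being the part of each map orthogonal to
  its assigned template.
- **Krzanowski–Lai** (maximize): `KL(K) = |DIFF(K)/DIFF(K+1)|`,
  `DIFF(K) = (K−1)^(2/C) W(K−1) − K^(2/C) W(K)`, with `W(K)` the
  within-cluster sum of squared distances to the cluster mean, computed on
  **unit-GFP** maps. Using normalized maps makes `W` a measure of
  topographic (not amplitude) dispersion; with raw maps the within-block
  amplitude modulation of a component dominates `W` and the criterion stops
  tracking the number of distinct topographies.

The selected K maximizes KL among the K whose CV lies within a 5% relative
band of the CV optimum (ties break toward smaller K). The exact combination
rule used by segmentation toolboxes is not standardized; this band rule is
our documented choice. On noiseless data built from three well-separated
templates in blocks, `W(3) = 0` and the rule recovers K = 3 exactly; at
SNR 5 it recovers K = 3 in ≥ 90% of seeded replicates (both asserted).

Component onsets: within a search window, each template is scored by the
mean potential of its assigned timeframes over a named electrode set
(fronto-central FCz/Fz/Cz/FC1/FC2 for the N2, most negative wins;
centro-parietal CPz/Pz/CP1/CP2 for the P3, most positive wins); the onset
is the first timeframe of the template's first assignment run of at least
20 ms. A missing run raises an explicit "component not found" error.

## Behavioral analysis

The adaptive response-time threshold (RTT) before correct-Go trial `k` is
the median of the block's correct-Go RTs from trials `1..k−1`; the first
correct Go is self-referenced, and any responded Go (fast or late) counts
as correct. The exclusion cascade runs in fixed order: (1) responded trials
with RT < 100 ms are dropped; (2) blocks are excluded for FA rate > 0.7,
miss rate > 0.2, FA rate above the participant-session median + 0.2, or
miss rate above the median + 0.1 — medians over all of that session's
blocks, computed before any exclusion; (3) a session is removed when more
than half its blocks are excluded; (4) hit RTs outside mean ± 2.5 SD per
participant-session are trimmed in a single pass (not iterated). Stage
counts are reported.

The 2×2 mixed ANOVA uses the closed-form sum-of-squares decomposition on
subject sums and differences (exactly additive; asserted to 1e-8 against
the total SS and to 1e-10 against a hand-computed toy decomposition, and
cross-checked against pingouin). Generalized eta squared divides each
effect's SS by itself plus both subject-level error terms. Follow-ups are
paired t-tests per group with `r = sqrt(t²/(t²+df))`, Holm-corrected within
the ANOVA's follow-up family.

`BF01` for the interaction uses the BIC approximation on the two
fixed-effect structures with subject as block, which reduces to
`BF01 = sqrt(n) (RSS_full/RSS_additive)^(n/2)`. This is a large-sample
approximation, not a prior-based integration: only its direction (>1
favors no interaction), its growth with n under additivity, and its
ordering are meaningful, and only those are asserted.

## Synthetic data: what it emulates, and what it does not

The ERP generator builds each subject-session from three component
topographies (occipital early positivity ~120 ms, fronto-central negativity
~250 ms, centro-parietal positivity ~420 ms; Gaussian envelopes; amplitudes
3/−4/5 μV) times a subject gain (SD 0.1), plus spatially smoothed
(FWHM 0.6 chord units, mimicking volume conduction), temporally AR(1)
(ρ = 0.95) noise at SNR 5 (signal RMS / noise RMS at the ERP level).
Defaults: 64 channels, 256 Hz, −100..700 ms, 16 subjects per group.
Injected effects are exact by construction: a gain effect multiplies the
signal inside its window (GFP scales, normalized topography fixed); a
topographic effect rotates each map toward a fixed orthogonal pattern at
unchanged GFP (`u → cosθ·u + sinθ·gfp(u)·b⊥`), so strength-only and
topography-only injections are separable to machine precision. A group
latency shift delays *all* components uniformly — age-like slowing — so
segmentation onset differences equal the injected shift up to timeframe
quantization.

The Go/NoGo generator honors the task design exactly: 6 blocks of 36 Go +
24 NoGo per session, cues assigned by Bayes inversion so Go follows green
with probability 0.70 and red with 0.30 (pinning the green-cue frequency at
0.75; an orange 50% level exists behind a flag for the training app
variant). RTs are centered ex-Gaussians (σ = 45 ms, τ = 75 ms) around
subject-session means; false alarms follow a logistic in standardized time
pressure `(RTT − subject median RT)/100 ms` centered on the subject's FA
rate; misses occur at 0.03. Group-session means and between-subject spreads
default to the emulated study population (older adults 467 ± 42 ms and
12.5% FA before training vs 411 ± 51 ms and 22.2% after; young adults
389 ± 29 ms / 14.8% before vs 345 ± 32 ms / 25.8% after; an active-control
arm 487→433 ms, 12.1→16.5%). Individual session changes in RT and FA are
drawn jointly with correlation −0.45 (SDs 30 ms and 0.06) — the
speed–accuracy trade-off. Training drifts are linear per day (young:
453.4 − 3.69·day ms, FA 15.14 + 0.75·day %; older: 640.09 − 4.81·day ms,
FA 7.58 + 0.73·day %) over 15 days × 12 blocks; with dispersion switched
off the daily means sit on the configured line exactly, so regressions
recover the slopes to machine precision.

Not emulated: single-trial latency jitter and habituation, non-stationary
or muscle/ocular artifacts (the rejection thresholds are exercised by
amplitude statistics of the noise model only), electrode impedance drift,
realistic volume conduction (no forward model — spatial correlation is
geometric smoothing), RT sequential dependencies, and learning within a
session. Passing tests therefore demonstrate the *statistical machinery* —
calibration, orthogonality, recovery, exclusion logic — on data with the
assumed structure, not robustness to every artifact of real recordings.

## Numerical choices and degenerate inputs

- Average-reference tolerance: 1e-9 relative to the map maximum.
- Permutation statistics below 1e-12 of the feature scale are clamped to
  exact zero (ties, hence p = 1, on degenerate data).
- CV residuals are clamped at zero before summing (floating-point
  cancellation can leave −1e-12 on noiseless data); the CV tolerance band
  adds an absolute slack of 1e-12 of the curve scale so a zero-CV optimum
  keeps its band.
- KL at the boundary K values of the evaluated range is undefined (NaN) and
  excluded from selection; `DIFF(K+1) = 0` with `DIFF(K) > 0` yields +inf
  (a perfect elbow), and 0/0 is treated as undefined.
- Ties in permutation ranks use mid-ranks; p never drops below
  `1/(n_perm+1)`.
- The RTT of a block with no prior correct Go is undefined (NaN in the
  trial table); false-alarm pressure falls back to the subject median RT.
- Seeds: every stochastic stage takes an explicit seed or Generator; the
  pipeline derives per-stage seeds from one run seed and logs them in the
  manifest. Identical config + seeds reproduce byte-identical artifacts.

## Problem sizes used by the test and acceptance runs

Calibration and recovery checks run at sizes chosen to make the suite
self-contained on a single CPU: 200 null datasets × 500 permutations at
64 channels × 150 timeframes for the false-positive-rate check; 50 seeded
replicates per injection kind (gain 1.3 in 350–500 ms; 30° rotation in
200–320 ms) at 16 subjects per group and 500 permutations for the
detection/selectivity check; 10,000 Monte-Carlo draws for the longest-run
and cluster-extent oracles. Production analyses would typically use 5,000
permutations (the package default) and the full epoch.

## Known limitations

- The duration-threshold calibration treats the rank-based pseudo p-series
  as exchangeable with the observed series; this is exact for the
  randomization schemes used here but slightly conservative at very small
  n_perm.
- The BIC Bayes factor is not numerically comparable to JZS-prior mixed
  Bayes factors; only qualitative statements transfer.
- The combination rule for CV and KL criteria is one documented choice
  among several in use; on real data the selected K should be inspected
  alongside both curves (stored on the `Segmentation`).
- Behavioral cell means after the exclusion cascade sit slightly below the
  generator's nominal means because 2.5 SD trimming of a right-skewed RT
  distribution removes more of the upper tail; this mirrors what the same
  cascade does to real data.
- `mixed_anova` uses group-size-weighted (classical) sums of squares; with
  unequal groups this matches the weighted-means analysis, not the
  unweighted (Type III) variant.
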