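# Methods

`calrecruit` reimplements, as a tested library, the calcium-imaging
analysis used to quantify epileptiform recruitment of neurons in
astrocyte–neuron co-cultures: fluorescence movies or traces are reduced to
per-culture activity summaries (individual firing rate, number of active
neurons, global firing rate) under basal and 4-aminopyridine (4-AP)
conditions, and those summaries are compared across groups. Because no
recording data are deposited for this experimental system, a first-class
synthetic generator encodes the study conditions and provides ground truth
for every stage.

## The transient model and spike inference

The fluorescence response to one action potential is a single decaying
exponential with amplitude A = 1% dF/F and decay constant tau = 3 s,
superposing linearly (non-saturating dynamics); the same kernel is used for
all cells and recordings. Spikes are inferred by greedy peeling:

1. correlate the residual trace with the unit template and convert to an
   implied least-squares event amplitude at every candidate onset frame
   (template energy is truncated near the trace end, and onsets in the last
   decay constant are ineligible — so little template remains there that
   the amplitude estimate is dominated by noise);
2. take the global maximum; if its implied amplitude reaches the detection
   threshold (default A/2; a noise-adaptive 3×1.4826×MAD alternative is a
   flag), accept an event;
3. re-time the accepted event at the largest one-frame rise within
   ±3 frames of the filter peak. The matched-filter peak of a one-sided
   exponential decays by only ~1/(tau·fr) per frame around the true onset,
   so at realistic noise the argmax jitters by several frames, while the
   instantaneous rise carries the timing information;
4. subtract one fixed-amplitude template at the onset and repeat until no
   candidate passes (or `max_iter = 10 × duration` as a safety valve, which
   sets a non-convergence flag).

Several spikes may stack on the same frame; there is no refractory
constraint. Spike time is the onset frame (no sub-frame interpolation).

## Baseline estimation and normalization

Each trace is smoothed (centered moving average, default 5 frames at
20 frames/s, edge-truncated), and one reference point is taken per 50 s
block: the sample whose smoothed value is closest to the block's 10th
percentile (linear-interpolation percentile convention; earliest sample on
ties), kept at its own time coordinate so the point sits on the slow drift
curve. A cubic spline through the points (degree reduced below 4 points;
interpolating by default — with ~12 points per 10 min window a smoothing
penalty is redundant, though one is exposed), evaluated at every frame,
gives F0. The original, unsmoothed trace is normalized to
`100 × (F − F0) / F0`. A trailing partial block joins its neighbor unless
it holds at least 25% of a block.

Beyond the first/last reference point the baseline continues linearly along
the spline's end tangent rather than holding a constant value: the first
reference point of a recording can fall up to one block (50 s) after its
start, and holding the end value across that gap leaves errors up to most
of the drift amplitude exactly where spike inference then misfires.

**Baseline refinement.** One reference point per 50 s block cannot track a
5%-amplitude, 300 s-period drift to much better than a few tenths of a
percent dF/F between points — the same order as the 1% transient
amplitude. The pipeline therefore alternates: peel, subtract the
reconstructed transients from the raw trace, re-fit F0 on the transient-
free remainder with one reference point per 10 s block, re-normalize, and
re-peel (two rounds by default). Robustness of the refit against
first-pass mistakes comes from (a) excluding frames within two decay
constants after each inferred onset, since a spuriously subtracted event
leaves a below-baseline dip that would otherwise reinforce itself, and
(b) summarizing each block by its 20th percentile plus the expected
Gaussian quantile offset (noise scale estimated robustly from first
differences), which ignores transients the first pass missed. Under the
default study conditions the refined baseline tracks the true drift with
RMSE ≈ 5% of the drift amplitude, and spike inference reaches F1 ≈ 0.93–0.95
at ±1-frame tolerance and A/σ = 5.

## Trace classification

The paper-level workflow selects "neuronal activity" traces by a
supervised classifier trained from manual labels. Features per normalized
trace (deliberately small and auditable, since no feature set is published
for this system): standard deviation, skewness, kurtosis, maximum
amplitude, count of upward excursions above 0.5% dF/F, lag-1 s
autocorrelation, and the ratio of spectral power below/above 0.5 Hz.
AdaBoost over depth-1 decision stumps (50 rounds, seeded, samples weighted
inversely to class frequency) is the learner; a file-driven refinement
loop applies manual corrections with an audit trail and retrains. A trace
is "neuronal" iff it carries neuronal activity — the generator labels a
silent neuron's trace non-neuronal, since it is indistinguishable in
principle from a flat artifact and would not be selected by eye either.

## Activity metrics

Per window (basal or 4-AP): individual firing rate = spikes/duration; a
neuron is **active** when at least one spike is inferred in the window;
the **global firing rate** is total spikes per unit time in the culture
(not divided by neuron count; a per-neuron flag exists because the phrase
is ambiguous in the source description). Summaries are computed per
culture, and cultures — not neurons — are the statistical units. Spikes
are inferred once over the whole recording and partitioned into windows by
onset time; the 5 min drug-stabilization gap belongs to no window.

## Group comparisons

Two-way ANOVA (genotype × treatment) with Type II sums of squares — the
designs are unbalanced (10/10/5/5 cultures per cell) — via statsmodels
OLS, with Bonferroni post hoc cell comparisons using the pooled error
term (raw p × number of comparisons, capped at 1). Residual normality
(Shapiro) is reported as a diagnostic only and never switches the analysis
to a non-parametric branch. Incidence counts are handled as printed
percentages (one decimal) and 2×2 Pearson chi-square with optional Yates
correction. Recomputing the chi-square from the published seizure-incidence
counts (8/18 vs 8/21) gives 0.161 (p = 0.688), not the printed 0.255
(p = 0.613); the variant behind the printed value is unstated, and this
package reports the formula-derived number.

## The synthetic generator

The generator emulates: homogeneous Poisson firing (basal 0.05 Hz among
active neurons; a silent fraction, default 0.5); a 4-AP condition that
multiplies rates by 3 and recruits each silent neuron independently with a
genotype-dependent probability (0.4 vs 0 in the default two-genotype
design); exponential transients rendered at exact (inter-frame) spike
times; sinusoidal baseline drift (5% of baseline, 300 s period — smooth
and spline-recoverable); additive Gaussian noise (0.2% dF/F, i.e.
A/σ = 5); three artifact classes for classifier training (flat noise,
astrocyte-like slow waves of 2–4% over 20–60 s, and 5–10% step
discontinuities; 10% of traces by default); movies as 2-D Gaussian soma
footprints on a background with pixel noise; and the between-group design
of 10 basal + 5 treated cultures per genotype, 200 neurons each, 10 min
windows at 20 frames/s. Culture-to-culture variability — unspecified in
the source system — is a log-normal multiplier on the basal rate with 20%
coefficient of variation. All randomness derives from named
`SeedSequence` children of one master seed; identical configuration and
seed give bit-identical outputs.

What the generator does **not** emulate: calcium buffering/saturation and
nonlinear indicator dynamics, photon shot noise, motion, neuropil
contamination, overlapping somata, bursting or network synchrony, and
astrocytic calcium signals. Passing tests therefore demonstrate the
pipeline's correctness under its own model assumptions — linear transient
superposition with a known kernel on a smooth baseline — not performance
on real recordings, where kernel mismatch and correlated noise would
dominate.

## Problem sizes

The replicate experiment that checks detection of the genotype × treatment
interaction runs the design at the generator's spike-train level (spike
trains → per-culture summaries → ANOVA) for 100 seeded replicates; the
trace-level stages (rendering, baseline correction, classification,
peeling) are validated end-to-end on smaller cultures, since their
fidelity, not their scale, is what the composition depends on. Benchmarks
use 10–20 rendered traces of 10 min; the end-to-end session test uses 12
neurons over a 2 × 150 s protocol with a 60 s gap.

## Known limitations

* Peeling fidelity degrades near recording edges (less template support,
  extrapolated baseline) and in dense-activity windows where transients
  overlap heavily; the end guard simply refuses onsets in the last decay
  constant.
* The exact "modified" peeling variant, detection threshold, spline
  penalty, classifier features, and ANOVA software of the original
  analysis are unpublished; equivalence with that software cannot be
  claimed, only adherence to the stated model.
* The fraction-active metric uses classifier-accepted traces as its
  denominator; with an activity-defined ground-truth labeling it is
  trivially 1, so the count of active neurons is the primary recruitment
  read-out, as in the source analysis.
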