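# Methods

`packetcode` analyses how sparsely-firing, phase-preferring units of the
electrosensory lobe (EL) of a pulse-type electric fish encode each electric
organ discharge (EOD) as a *packet* built from two channels: the number of
spikes evoked by the discharge and the distribution of their latencies after
it. Because the original recordings of this preparation are not publicly
available, the package pairs every analysis stage with a synthetic
point-process generator whose defaults define the study conditions; all
quantitative claims the test suite makes are claims about that generator.

## Point-process model

**EOD train.** A gamma-renewal process with mean interval 44.5 ms
(22.5 discharges/s, the resting rate of the preparation) and shape 50. Only
the mean is constrained by observation; the shape is a free parameter chosen
to reproduce the low interval jitter visible in EOD-aligned rasters
(CV ≈ 1/√50 ≈ 0.14) and is exposed in `EODTrainParams`.

**Conditional spike intensity.** For each complete inter-EOD interval the
number of primary spikes is Poisson with mean
(Σ mode weights + baseline_rate·interval)·gain, truncated at 4 spikes per
interval. Latencies are drawn from the weighted mixture of Gaussian modes
plus a uniform baseline, then thinned by rejection inside each inhibition
window (probability = window depth) and clipped to the blanking-safe range
(2.5, interval − 2.5) ms, so generation and analysis share the ±2.5 ms
blanking convention exactly. Burst structure is stereotyped: each primary
spike spawns, with a per-archetype probability, `size − 1` extra spikes at a
fixed 3–4.5 ms intra-burst ISI. The Poisson count assumption is a modelling
choice — the per-type count distributions of the real units are not
characterised — and is flagged as such.

**Stimulus modulation.** A two-level stimulus (3-fold amplitude ratio)
drives three archetype parameters: a sustained `level_gain` applied while
the stimulus is at the high level (the "center-on"/"center-off" steady-state
difference), a phasic `count_gain_up/down` applied at each level transition
and decaying toward 1 exponentially with e-fold constant
`adaptation_tau_eods` = 8 EODs (the adaptation time constant is not reported;
8 EODs reproduces a phasic response that is maximal at EOD_0 and gone well
before EOD_23), and an optional latency shift with the same decay. The EOD
rate itself stays stationary: the transient interval shortening after a
novel stimulus (the novelty response) is deliberately not modelled.

**Receptive fields.** A Mexican-hat gain profile along the rostro-caudal
axis (difference of two Gaussians around a center position), clipped at
zero, multiplies the per-interval intensity as an object sweeps at constant
speed. Direction asymmetry is modelled as a post-center suppression factor
active only for one movement direction; its magnitude is a free parameter.

## The six archetypes and their calibration

The six default archetypes reproduce the reported firing-pattern types:
sharp monomodal (single narrow mode at 11 ms, doublet bursts), broad
monomodal (broad mode at 23 ms with an occasional 5 ms spike), bimodal
(modes at 11 and 18–20 ms), trimodal (sharp 5 ms spike, 11 ms mode, broad
late shoulder at ~28 ms), mildly inhibited (early and end-of-interval peaks
over a floor with inhibition dips at 5–8 and 10–14 ms) and deeply inhibited
(a deep 4–28 ms silence with firing ramping toward the next discharge).
Units of a type are mild parameter variants of the archetype (mode centers
jittered by 0.15 ms SD, widths/weights/baselines by ~10%), enough to fill
the per-cluster 20/50/80 percentile bands without eroding separability.

Mode weights, baselines and burst probabilities were calibrated jointly,
once, so that the default population (17 units per type, 500 EODs per unit)
reproduces two grand means: ≈0.35 spikes/EOD and ≈84 ms mean inter-spike
interval. These two constants are **not jointly attainable under the naive
ISI definition**: the mean of all successive differences telescopes to
(recording span)/(N−1) ≈ 44.5/(spikes/EOD) ≥ 127 ms whenever spikes cover
the recording, for any burst structure. `mean_isi_ms` therefore summarizes
the *bounded* ISI distribution: successive differences longer than 300 ms
(the forward span of the cross-correlogram window) are treated as silent
gaps and excluded. Under that definition — the natural one for sparse
EOD-locked trains analysed over a ±(200, 300) ms span — burst doublets and
the geometric mixture of 1–6-cycle gaps make both grand means attainable,
and the defaults are frozen at that calibration.

## Histograms

All histograms use 1 ms bins *centered* on integer latencies (bin k covers
[k − 0.5, k + 0.5) ms, bin 0 centered at the reference discharge). The long
cross-correlogram spans −200…+300 ms in percent-per-EOD units, each spike
contributing to every reference window it falls in; blanking notches appear
at multiples of the EOD interval by construction. The post-EOD histogram
restricts to 2.5–40 ms (bins centered 3…40, 38 bins; the window is treated
as closed at 2.5 through the first bin edge and effectively half-open above
40.5) and is normalized to unit sum, making it invariant to spike and EOD
rate. Ordinal analyses assign each spike to its preceding EOD; the
cross-correlogram uses every EOD in the window. No smoothing anywhere.

## Classification

Units enter as unit-sum post-EOD histogram vectors after the minimum-data
filter (≥500 EODs and ≥100 spikes, inclusive, counted post-blanking).
Pairwise Euclidean distances feed Ward minimum-variance linkage. The cluster
count is read off the Davies-Bouldin curve for k = 2…12. Two index variants
are provided: the textbook definition (mean over clusters of the worst
(S_i + S_j)/M_ij ratio of centroid dispersions to centroid distance; lower
is better — the default) and the looser "minimum inter-cluster over maximum
intra-cluster distance" ratio sometimes quoted for it. The elbow rule: a
textbook DB curve over genuine cluster structure falls until the true k and
rises once clusters get split, so an interior global minimum is taken
directly; only when the curve is monotone to the upper end of the k range is
the kink located by the maximal discrete second difference, and a strictly
linear curve warns and falls back to the minimum. (A pure second-difference
rule was tried first and proved fragile: splitting sampling-noise clusters
at large k produces spurious curvature that can out-curve the true dip.)
A manual k override is supported throughout.

Group comparisons on unit properties (recording depth, mean latency,
spikes/EOD) use Kruskal-Wallis followed by pairwise Wilcoxon rank-sum tests
with Holm-Bonferroni control; all-pairs two-sample KS tests on raw
2.5–40 ms latencies are Holm-adjusted across all C(n,2) pairs. Mean spike
latency of a multimodal unit is the all-spike mean within the window (the
per-EOD first-spike alternative was considered and rejected as it discards
the late modes that distinguish several types).

## Step-response analysis

Each trial is aligned on its stimulus step: EOD_0 is the first discharge at
or after the step (a step exactly at a discharge makes that discharge
EOD_0), ordinals run −25…+25, and trials without full flanks are dropped
with a warning. Spike counts per ordinal EOD are summed over trials; triad
distributions pool latencies over the named ordinal ranges (long control
−25…−4, control3 −6…−4, pre −3…−1, post 0…2, late 23…25) into unit-sum
38-bin histograms.

**Friedman with repetitions.** The replicated-block Friedman test ranks all
t·r replicate values jointly within each block, averages ranks per
treatment, re-ranks those means 1…t within the block, and applies the
tie-corrected Friedman χ² with df = t − 1. The steady-state variant uses 25
replicates (the 25 pre-step EODs at each level, blocks = units); the step
and adaptation variants use 3 replicates (the 3-EOD triads). With two
treatments this statistic reduces to a sign test on within-block rank
direction, whose χ² approximation is accurate only from roughly 25 blocks
upward; the calibration suites therefore use 30 blocks. An exhaustive
within-block permutation p-value is available for small tables and is what
the oracle tests check against. Missing cells raise — no imputation.

**Jensen-Shannon divergence.** JSD(p, q) = H((p+q)/2) − (H(p)+H(q))/2 with
base-2 entropies and 0·log 0 ≡ 0; equal-weight mixture; no pseudocounts
(triads are already spike-count-normalized). The divergence battery reports,
per unit, seven comparisons: (a) long-control up vs down, (b, c) pre vs
long control per direction, (d, e) pre vs post per direction, (f, g) post
vs late per direction. The inferential contrast — "does the step add
spike-timing information?" — is a one-sided sign-rank of
JSD(pre, post) > JSD(control, pre) across units of a type, Holm-adjusted
over all (type × direction) tests. For that contrast the control divergence
is computed against the size-matched 3-EOD control triad (−6…−4) rather
than the pooled 22-EOD long control: the plug-in JSD estimator carries a
small-sample bias that grows as the spike count shrinks (a 3-EOD triad at
0.35 spikes/EOD holds ~17 spikes over 38 bins), so a 22-vs-3 reference
comparison is bias-mismatched and anticonservative under a stationary
process, while the 3-vs-3 reference keeps the paired difference centered at
zero under the null and errs conservative when only counts change. The
long-control divergences remain in the report for descriptive use.

**JSD-count correlation.** Per unit, the 15 unordered pairs among its six
direction-specific triads (pre/post/late × up/down) yield paired (JSD,
|Δ spikes/EOD|, count ratio) samples; Pearson r, R² and p are reported for
both count measures. Low R² supports the claim that timing and count carry
complementary information; a generator that couples the latency shift to
the count gain serves as the positive control for the statistic's
sensitivity.

## Receptive-field profiles

Each EOD is assigned to the 1 mm half-open position bin the object occupied
at its emission (ties to the bin whose left edge they hit); the per-bin rate
is spikes-following-those-EODs / EODs (preceding-EOD convention, consistent
with the ordinal analysis). The direction contrast reports per-bin rate
differences and a normalized L1 asymmetry index in [0, 1].

## Statistical conventions

Zero paired differences are dropped before sign-rank tests (standard
Wilcoxon convention). Exact null distributions are used for sign-rank and
rank-sum below n = 25 when tie-free, with normal approximation plus
continuity correction otherwise; KS uses scipy's automatic exact/asymptotic
switch, with optional seeded sub-microsecond jitter to break ties in the
exact path. Holm-Bonferroni adjusted p-values are the max-monotone
(m−i+1)·p(i), capped at 1.

## Problem sizes

Simulation sizes throughout the test and acceptance suites are the
package's own choices: classification cohorts of 102 units × 500 EODs
(matching the filter threshold), step experiments of 16–24 trials with a
(2 s, 2 s) duty cycle (≈45 EODs per phase, comfortably above the 25-EOD
flank requirement; the long 28 s/2 s cycle of the physical protocol is the
`StepProtocol` default), 1,000 replicates for type-I calibration with 30
blocks per replicate, and 8 runs per cell for the 2 × 2 channel-attribution
cross. The full default pipeline completes in seconds on one CPU.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses consume:
EOD-locked latency mixtures, sparse truncated-Poisson counts, doublet
bursts, phasic-adapting count gains, sustained level gains, latency shifts,
and Mexican-hat spatial gains with direction asymmetry. It does **not**
model biophysics (no membranes, no network dynamics), raw waveforms, spike
sorting errors, nonstationary drift, EOD-rate novelty responses, or
correlations between simultaneously recorded units. Passing tests therefore
demonstrate that the pipeline recovers known ground truth of this
generative family at realistic sample sizes — not that the biological
claims of the original experiments are reproduced. Known limitations: the
Friedman-with-repetitions definition is one of several consistent with the
phrase (its printed degrees of freedom are not reconstructible, so it is
validated by calibration, not by matching printed χ² values); plug-in JSD
values at triad sample sizes are bias-inflated and should be compared only
between size-matched distributions; and the enumeration of the "15 triad
pairs" for the count correlation takes all unordered pairs among the six
direction-specific triads of a unit.
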