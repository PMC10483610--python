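# Methods

This note documents the models behind `ctfusion`: what the calling rules
assume, how the synthetic-data generator is parametrised and what it does
and does not emulate, and the numerical and design choices made where the
underlying assay description leaves room.

## Count-profile calling

Each sample is a vector of non-negative integer counts over a 34-probe
panel: 23 fusion-junction probes (7 *ALK*, 10 *ROS1*, 6 *RET*), one probe
each for wild-type *MET* and the exon-14-skipped transcript, 3 housekeeping
probes (*GAPDH*, *MRPL19*, *PSMC4*) and 6 no-target negative controls. The
default panel's junction labels are a synthetic reconstruction of a
recurrent-fusion codeset, not a vendor file.

**QC gate.** A sample is evaluable iff the geometric mean of the three
housekeeping counts is strictly greater than 30. The gate is total: a
non-evaluable sample contributes to nothing downstream (neither thresholds
nor calls), and requesting calls on it raises rather than returning
empty calls.

**Thresholds.** For every fusion probe, positivity requires the count to
strictly exceed mean + 6·SD of that probe's counts in a tissue-negative
reference cohort. Choices made here:

* *SD flavour*: sample SD (n−1 denominator), the conservative default;
  configurable via `ddof`.
* *Negative reference set*: one shared control cohort for all probes (not
  per-gene complements); provenance (the control sample ids) is stored in
  the `CallThresholds` object.
* *Negative-control probes*: used as a background QC floor — any fusion
  threshold below the negative-control mean + 2SD is flagged, because calls
  from such a threshold would sit inside nonspecific background. A
  `background_mode="subtract"` variant subtracts the negative-control mean
  from all counts before thresholding instead. The floor is the default
  because subtraction interacts with the 6×SD rule in ways the assay
  description never specifies.
* *Strictness*: both cutoffs are strict (`count > T`, `ratio > 1.0`); a
  count exactly at threshold is negative.
* *Tie resolution*: fusion and *MET*Δex14 positivity is biologically
  mutually exclusive, so multi-gene positives indicate noise. The call with
  the largest margin (count/threshold, or ratio/cutoff for MET) is reported
  as the overall alteration; all positives remain listed.
* *MET with zero wild-type counts*: the ratio is undefined, and the MET
  call is "non-evaluable" — never positive.

**Levey-Jennings.** Replicate runs of a control sample are summarised as
mean, ±2SD warning and ±3SD control limits, with the 1₃ₛ rule
(|value − center| > 3SD) as the violation flag. Self-derived limits on a
small batch can never flag (with n values the largest studentised
deviation is (n−1)/√n, below 3 for n ≤ 10), so the function accepts the
laboratory's established mean/SD as reference limits — the standard way LJ
charts are run.

**Limit of detection.** From a dilution bank (replicates × strictly
decreasing tumor fractions), the LOD is the smallest fraction whose
replicate detection rate reaches `min_detection_rate` (default 1.0, i.e.
every replicate positive); levels below the LOD are not required to pass.
The full per-level rate table is returned so stricter monotone conventions
can be applied downstream.

## Digital PCR

Molecules load into ~20,000 partitions independently, so per-partition
counts are Poisson with occupancy λ = c·v. The estimator is the exact
binomial MLE λ̂ = −ln(1−f); the 95% CI is the delta-method normal
approximation λ̂ ± 1.96·√(f/(n(1−f))) scaled by 1/v and floored at 0, with
an exact Clopper-Pearson option. A fully positive chip has unbounded
likelihood in λ and raises a saturation error instead of returning a
number. λ̂ ≥ f always (co-occupancy), the estimator is unbiased to well
under 1% for λ ≤ 1, and bias grows near saturation (λ > 3) — re-dilution
territory.

Double-positive partitions count as positive in both channels, consistent
with the independent co-loading model. MAF is computed on estimated
concentrations (molecule counts), not raw partition tallies. Evaluability
requires the endogenous reference channel to reach 0.5 copies/µL; failure
is strictly below the floor, so exactly 0.5 is evaluable. The partition
volume defaults to the 20K chip's nominal 0.755 nL but is configurable,
since instrument-reported copies/µL depend on an effective volume that is
not published; all concentration comparisons in this package are internal.

Manual cluster reassignment in instrument software is reproduced by
`classify_partitions`' explicit per-channel thresholds plus an auditable
per-partition override map. Run controls (blank, wild-type negative,
optional positive) are checked at cohort level: any mutant-positive
partition in a blank or negative control flags the run.

## Concordance statistics

For gene g, every sample is one binary test of "is g altered" — samples
positive for *other* genes belong to g's negative margin (an *ALK* patient
is a true negative for *ROS1*). This convention reproduces the per-gene
concordant/discordant counts and κ values the pooled clinical table
implies. The "overall" table is the cell-wise sum of per-gene tables
(n = genes × samples).

Proportion CIs default to the Wilson score interval (robust at the extreme
proportions this panel produces, e.g. specificity 1.0); Wald and
Clopper-Pearson are available by flag. κ uses the asymptotic SE
√(p_o(1−p_o)/(n(1−p_e)²)); the resulting CI is reported as computed and may
exceed [−1, 1] (a `clipped()` accessor intersects it). Published κ CIs for
this assay family are not exactly reproducible by the standard formulas, so
no equality with any printed κ interval is asserted anywhere.

The Mann-Whitney U test (positive vs negative count distributions) uses an
exact enumeration over all group assignments of midrank sums for combined
n ≤ 20 — correct under ties, verified against scipy's exact recursion on
tie-free data — and scipy's tie-corrected normal approximation otherwise.
Two-technique comparisons report the joint 2×2, agreement, union detection
and a two-proportion two-tailed Z test; `reconcile_marginals` inverts the
published marginal form (n, positives by each technique, agreement count)
back to the joint table and rejects inconsistent inputs.

## Longitudinal monitoring

Serial dPCR concentrations are summarised per consecutive interval as
fold changes, bucketed as increase (fold ≥ 2), marked decrease
(fold ≤ 0.2) or stable. The anchors in the clinical narrative are
qualitative ("same range of magnitude", a "five-fold decrease" under
partial response), so the default folds are a documented choice that
separates those patterns cleanly, not validated cutoffs; every output
carries an `exploratory` flag. Zero handling: both timepoints undetected is
its own category; appearance from zero is an increase; clearance to zero is
a marked decrease (the strongest decrease signal). Categories are invariant
under rescaling all concentrations, and with reciprocal fold thresholds
swapping baseline and follow-up swaps increase and marked decrease.

## Synthetic-data generator

The generator is the package's stand-in for clinical material, and its
defaults are the study conditions the analysis assumes:

| parameter | default | meaning |
| --- | --- | --- |
| `background_mean` | 6 counts | NB background on non-target probes (per-probe overrides 8/6/3 for the three clinically characterised probes) |
| `background_dispersion` | 0.5 | excess Fano factor; var = (1+d)·mean |
| `hk_geomean`, `hk_cv` | 500, 0.5 | lognormal housekeeping counts (QC gate is 30); low values emulate EV-RNA-like low-input preparations |
| `signal_median` | 6756 counts | median target-probe counts at tumor fraction 1, clinical scale (per-probe overrides 6756/4063/6911) |
| `detection_noise_cv` | 0.6 | lognormal multiplicative signal noise |
| `met_ratio_positive/negative` | 1.7 / 0.1 | target skip/wt ratio in carriers (fraction 1) / non-carriers |
| `dilution_stock_scale` | 100 | bank-stock brightness relative to clinical scale |
| `partitions_per_chip`, `partition_volume_ul` | 20000, 7.55e-4 | chip geometry |

Counts on the target probe are background plus a lognormal signal whose
median scales linearly with tumor fraction; the MET skip count is the
wild-type count times a ratio that interpolates linearly in tumor fraction
between the non-carrier (0.1) and carrier (1.7) ratios, so the MET channel
obeys the same linearity the fusion probes do. Chips draw the four
partition quadrants from a multinomial with independent per-channel
occupancy probabilities 1 − e^(−λ); tallies always sum to the partition
count. A single `numpy` Generator drives everything, so a fixed seed
reproduces a cohort byte-for-byte.

Two parametrisation choices deserve explanation:

* **Background dispersion.** "Dispersion 0.5" is implemented as
  var = 1.5·mean. The quadratic alternative (var = mean + 0.5·mean²)
  produces tails heavy enough that mean+6SD thresholds estimated from 16
  negatives misfire on several percent of null samples — inconsistent with
  the calibration this assay demonstrates (zero positives across 16
  controls × 23 probes) and with the mild overdispersion implied by
  negative counts with mean ≈ 8 and SD ≈ 3.
* **Dilution-bank stock scale.** Dilution banks are built from cell-line
  RNA, in which the fusion transcript is expressed by every cell; clinical
  cfRNA positives carry only a minority of tumor-derived RNA. A single
  linear scale cannot simultaneously give clinical-scale medians (~6800
  counts) at fraction 1 *and* detection at fractions of 10⁻³–10⁻⁴, so the
  bank applies `dilution_stock_scale` (default 100) to the signal median:
  the undiluted stock is two orders of magnitude brighter than a
  clinical-scale sample. Under the defaults the recovered LOD falls at
  0.01–0.1% tumor fraction. Signal remains strictly linear in fraction
  within each generator.

What the generator does **not** emulate: sequence-level structure (no
reads, no breakpoints), fluid-specific count shifts (fluid is metadata
only), cartridge batch effects, cross-hybridisation between probes, and
EV-RNA biophysics beyond a lower housekeeping abundance. Passing tests
therefore demonstrate the correctness and calibration of the *rules and
estimators* under the assumed generative law — not the clinical
sensitivity of the assay on real fluids.

## Problem sizes and tolerances

Monte-Carlo checks use sizes at which their acceptance bands are stable:
1000 replicate profiles for distributional medians and null calibration
(probe-level false-call rate, expected ≈ 0.03%, band < 1%), 1000 chips for
estimator bias (< 1%) and CI coverage (93–97%), dilution banks of 40
replicates × 4 levels spanning 10⁻²–10⁻⁵, and a likelihood grid of 10⁶
points for the dPCR oracle (agreement to 3 significant figures). The full
suite runs in well under a minute on one CPU. With thresholds estimated
from only 16 negatives, the *per-probe maximum* false-call rate fluctuates
with the SD estimate (it exceeds 1% in roughly a tenth of reference-cohort
draws); the pooled probe-level rate is the stable calibration readout and
the one the tests assert.

## Known limitations

* Thresholds are derived cohort-wide, not per fluid; the assay description
  gives no per-fluid derivation and the generator does not model fluid
  effects.
* The κ confidence interval is the asymptotic one; small-n κ intervals are
  known to misbehave, and no bootstrap alternative is provided.
* The exact Mann-Whitney path enumerates all C(n, m) assignments and is
  capped at combined n ≤ 20.
* `reconcile_marginals` assumes the printed marginals come from one
  consistent joint table; it cannot repair rounding in published
  percentages, only reject impossible combinations.
* Monitoring fold thresholds are exploratory by construction and must not
  be read as clinically validated decision rules.
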