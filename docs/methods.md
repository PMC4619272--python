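# Methods

## The measurement model

Chip digital PCR partitions one reaction into ~20,000 fixed wells and reads
each well's end-point fluorescence on two channels: FAM for the target miRNA
assay and VIC for a synthetic *C. elegans* spike-in (cel-miR-39) added before
extraction as a whole-process control. Template molecules land in wells
approximately independently, so the per-well copy count is Poisson with mean

    lambda = C · v

where `C` is the concentration in the reaction mix (copies/µl) and `v` the
well volume. A well is called positive on a channel if at least one template
copy amplified, so the negative fraction estimates `exp(-lambda)`:

    p_hat      = n_positive / n_valid
    lambda_hat = -ln(1 - p_hat)
    C_hat      = lambda_hat / v

This is absolute quantification: no standard curve, only counting and the
chip geometry.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| quality threshold | 0.5 | score in [0,1] | instrument convention; wells below it are excluded from all counts |
| QC floor | 10,000 | valid wells | a chip with fewer valid partitions is flagged (estimates are still reported) |
| partition volume | 8.09×10⁻⁴ | µl | the vendor-documented 0.809 nl well of the 20,000-well chip; reproduces the order of published CI widths |
| confidence level | 0.95 | — | two-sided |
| fluorescence thresholds | automatic | a.u. | exact two-class variance-minimizing split per channel, computed on valid wells; numeric override available |
| spike assay | cel-mir-39 | — | VIC channel by convention; FAM is always the target |
| CI method | delta | — | `binomial` (Clopper–Pearson on p, mapped through −ln(1−p)) available for low counts |
| normalization scope | project | — | averaging set for the spike reference; `per-sample` groups by sample |

## Confidence intervals

The default interval is the delta-method normal interval on the lambda
scale, `se(lambda_hat) = sqrt(p_hat / ((1−p_hat)·n_valid))`, clipped at 0
and divided by the well volume. At the occupancies of a well-loaded chip
(hundreds to thousands of positives) it is symmetric, narrow (±1–3 %
relative), and its empirical coverage over simulated chips sits within
93–97 % for lambda from 0.01 to 3 (measured by the acceptance script). An
all-negative chip reports 0 copies/µl with the rule-of-three upper bound
`3 / n_valid` on lambda (the literal 3 at the default 95 % level;
`−ln(1−CL)/n` otherwise), so negative and non-template controls are
representable rather than errors. A fully positive chip raises a
"saturated" error advising dilution — lambda is undefined and no interval
is honest there.

## Spike-in normalization

Within an averaging set ("project" by default), the reference is the
arithmetic mean of the spike concentration over chips; each chip's target is
multiplied by `reference / spike_chip` and by its dilution factor. This
removes chip-to-chip whole-process efficiency differences and restores the
specimen scale. The choice of averaging set is deliberately a parameter: a
run, a sample, or a whole study are all defensible sets, and the package
does not guess. Normalization is scale-equivariant — rescaling every spike
value leaves normalized targets unchanged — which the suite asserts.

## Automatic fluorescence thresholding

`auto_threshold` minimizes the within-group sum of squares over all
midpoints between consecutive distinct sorted values — the exact 1-D
two-class split, deterministic, with no histogram binning. Its domain of
validity matters: when one class holds less than roughly half a percent of
wells (a trace-level target, an empty channel, or a saturated one), the
split lands inside the majority cloud's noise and the calls are wrong. This
is inherent to unsupervised two-class splitting, not an implementation
defect. Practice (and the tests) handles trace chips by fixing thresholds
from a well-loaded calibration chip or from known dye regimes; the CLI and
config expose numeric per-channel overrides for exactly this.

## Validation metrics

- **Detection efficiency** is `round(100 · expected / observed)` per
  dilution point. That direction — expected over observed — is the one that
  reproduces the published efficiency column on four of six rows exactly
  and within one point on a fifth; the conventional observed/expected does
  not reproduce it. The remaining one-point discrepancies are source
  rounding noise and are not asserted.
- **Dilution linearity** summarizes undiluted/diluted ratios by their mean
  and sample (n−1) SD. A singleton pair reports SD 0 with an explicit
  `sd_defined=False` flag.
- **Precision** is the per-sample CV (sample SD over mean of replicates),
  averaged arithmetically across samples, reported to 3 decimals and as an
  integer percent.
- **Ct-vs-copies correlation** is plain Pearson r on the linear scale,
  matching how the published correlations behave; the CLI reports it as a
  signed integer percent.

## What the simulator emulates — and what it does not

Each simulated well draws a Poisson copy count per channel, then an
intensity from a negative or positive Gaussian regime (means 500/4000 a.u.,
SD 300 — ~11 SDs of separation, so calls are limited by loading statistics,
not optics). Quality scores come from a "filled" regime above 0.5 (fill
rate 0.9, giving ~18,000 valid wells, inside the 10,000–19,800 range of
real chips) and an "unfilled" regime below it. Channels are independent
unless a cross-talk coefficient is set. Identical seeds give bit-identical
chips.

The simulator does not model amplification kinetics, partial ("rain")
amplitudes beyond an optional misclassification rate, spatial loading
artifacts, or the real instrument's quality-score distribution (which is
unpublished — the simulated score only needs to exercise the 0.5 cut).
Passing tests therefore demonstrate the correctness of the counting
statistics and the pipeline, not robustness to instrument-specific optical
pathologies.

## Statistical checks and their problem sizes

The acceptance script and suite verify, at the chip's study conditions
(20,000 wells × 0.809 nl, fill rate 0.9):

- **Estimator vs Monte-Carlo oracle.** The closed-form inversion is checked
  against an oracle that never takes a logarithm: a well at occupancy
  lambda is occupied iff an Exp(1) first-arrival falls below lambda, so the
  oracle lambda is the empirical p̂-quantile of 1.2×10⁸ exponential draws
  (accumulated chunk-wise into a 4,000-point geometric histogram; MC error
  ~0.3 % at p̂ = 0.001). Agreement is required to <1 % over p̂ from 0.001
  to 0.95. The unit suite cross-checks the same mapping by root-finding on
  scipy's Poisson survival function.
- **CI coverage**: 1,500 simulated chips at each lambda in
  {0.01, 0.1, 1, 3}; empirical coverage required in [93 %, 97 %].
- **Parameter recovery**: 100 seeded chips at each of 1, 10, 100, 1,000 and
  3,000 copies/µl through the full classify→quantify pipeline. The reported
  statistic is the median *signed* relative error — a bias measure —
  required under 5 %. The median absolute error is necessarily larger at
  the bottom of that range (1 copy/µl puts only ~15 copies on the whole
  chip, so single-chip scatter is ~25 %); the estimator is unbiased there,
  it is simply counting few molecules. In the sub-copy regime
  (0.16 copies/µl ≈ 2.6 copies per chip) the median signed error stays
  within 50 %, dominated by Poisson-median skew.
- **Dilution-series slope**: log(estimate) vs log(truth) on six-point
  five-fold series from 500 copies/µl, fitted over points with nonzero
  estimates. A single series has slope SD ≈ 0.045 because the two trace
  points carry ~12 and ~2.6 expected positive wells, so the reported slope
  is the median over 21 replicate series, required in [0.95, 1.05].

## Known limitations

- Copies/µl refer to the reaction mix; conversion to the specimen is pure
  dilution-factor bookkeeping, and RT/pre-amplification efficiency is
  assumed to be 100 % (no correction is applied).
- The published tables print neither positive counts nor the partition
  volume, so CI agreement with them is checked as order-of-magnitude
  relative half-width (~2 % at the highest-occupancy plasma chip), not
  digit-for-digit.
- The published fold-dilution summary statistics and the Ct-correlation
  table could not be reproduced from unambiguous printed inputs (the
  source is typographically ambiguous there); the corresponding operations
  are validated by their structural invariants (scale invariance, sign
  behavior) instead of by those printed values.
- Multi-chip merging of raw partitions into one estimate is out of scope;
  chips combine only through normalization and downstream statistics.
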