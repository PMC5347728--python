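# Methods

## The NAC dosage statistic

A targeted amplicon library yields read counts c_a over a fixed panel. The
normalized amplicon coverage of amplicon *a* is

    NAC_a = c_a / mean_b(c_b),

the count divided by the sample's mean count over **all** panel amplicons.
Normalizing within the sample removes library size, so NAC values average to
1 per sample by construction. The ERBB2 dosage ratio is

    r = mean(NAC_a : a ∈ ERBB2 amplicons) / mean(NAC_a : a ∈ TP53 amplicons),

with 3 ERBB2 and 8 TP53 amplicons in the default panel. TP53 serves as the
copy-neutral reference; a TP53 copy-number change in a tumor violates this
assumption and biases r — a documented failure mode, not a default of the
simulator. Because the per-sample mean cancels, r is algebraically the
ratio of the two genes' mean raw counts (a property test asserts this) and
is invariant to multiplying all counts by a constant; the choice of
normalization divisor (whole panel vs. targets only) therefore affects
per-amplicon NAC values but never the ratio or the call. The computation is
nevertheless ordered normalize → gene means → ratio, matching how the
statistic is defined.

Under the simulator's dosage model, a tumor with true ERBB2 copy number c,
copy-neutral reference and purity 1 has E[r] ≈ c/2.

### Threshold calibration

The gain cutoff is calibrated on a copy-neutral control cohort as

    threshold = mean(r_controls) + 2 · SD(r_controls),

using the sample standard deviation (n−1 denominator; the conventional
estimator for a small control cohort — a design choice, since the defining
description does not fix the convention). At least 2 controls are required;
the clinical design uses 12. A ratio **strictly greater** than the threshold
is called positive, otherwise negative; the NAC route has no equivocal
category. The boundary rule is fixed for determinism — no reference case
sits on the boundary, so either convention reproduces the published calls.

The published cutoff for this assay, 1.18, was calibrated on 12
formalin-fixed tonsil controls whose read counts are not public; it
therefore ships as a provenance-free constant (`PUBLISHED_NAC_THRESHOLD`)
used to classify the reference cohort, and is not re-derivable here.

## ASCO/CAP classification and FISH scoring

FISH and MIP copy numbers are classified by the ASCO/CAP 2013 single-probe
copy-number route: negative CN < 4, equivocal 4 ≤ CN < 6, positive CN ≥ 6.
The dual-probe ERBB2/CEP17 ratio route is out of scope. The FISH average CN
is (observer1 total + observer2 total) / (2 · 50 cells); signal clusters
enter as the observers' estimated per-cell totals — no cluster-detection
logic exists here. Classification always uses the unrounded value; FISH is
*reported* to one decimal and MIP to two (half-up rounding, so 22.95 reports
as 23.0). Rounding behaviour exactly on a reporting boundary is this
package's rule, not an external one.

## Concordance statistics

Paired classifications are cross-tabulated with the fixed category order
(negative, equivocal, positive); for a pair written `fish:mip` the rows are
the second-listed platform. Empty categories are retained — a 3×3 table is
kept even for the NAC platform, which never calls equivocal — because
collapsing rows changes the chance-agreement term p_e of Cohen's κ,
κ = (p_o − p_e)/(1 − p_e). When p_e = 1 (both raters constant on one
category) κ is undefined; the implementation returns the exact-agreement
indicator and flags the result degenerate. κ is reported to two decimals.
Spearman's r_s uses mid-ranks for ties (Pearson correlation of the rank
vectors, delegated to scipy) with the large-sample t approximation
t = r√((n−2)/(1−r²)) for the p-value; tests check it against an independent
first-principles mid-rank oracle.

## The synthetic cohort generator

The generator emulates the data-generating process the pipeline assumes, so
recovery can be tested without any external data:

- **Counts.** Amplicon *a* of gene *g* has expected count
  m = depth · e_a · c_eff(g)/2 with effective dosage
  c_eff = purity·CN + (1−purity)·2 (tumor DNA diluted by diploid stroma).
  Counts are negative-binomial with variance m + d·m², Poisson in the limit
  d → 0. Default dispersion d = 0.05 (count CV ≈ 22% at high depth), a
  realistic overdispersion for FFPE amplicon assays; the source assay states
  no noise model, so this is the package's own choice.
- **Efficiencies.** Per-amplicon capture efficiencies e_a are log-normal
  (σ = 0.5 by default), normalized to mean 1, and drawn **once per cohort**:
  primer performance is a property of the assay, not of a library. This
  reproduces the empirical regime in which even copy-neutral samples have
  dosage ratios far from 1 (the reference cohort's negatives span ≈
  0.33–0.97), because within-sample normalization cannot remove a
  systematic ERBB2-vs-TP53 efficiency imbalance. Calibration on controls
  sharing the same panel absorbs the shift.
- **Design defaults** mirror the clinical series: 29 tumors vs 12 diploid
  controls (purity 1), mean per-amplicon depths 3869 (tumor) and 2484
  (control), tumor purity uniform on [0.5, 0.9] (macrodissected FFPE;
  unstated in the source, chosen once as realistic), and tumor copy-number
  strata (CN 2, 5, 12) weighted 18/29, 3/29, 8/29 to match the reference
  cohort's negative/equivocal/positive composition. TP53 stays at CN 2 by
  default.
- **FISH.** Per-cell signal counts are Poisson(true CN) truncated at ≥ 1 (a
  scored nucleus section shows at least one signal), totalled over 50 cells
  for each of two observers; a deterministic mode emits exact per-cell
  counts for arithmetic checks.
- **MIP.** Estimates are c_eff plus Gaussian noise, floored at 0 and
  quantized to thirds, mimicking the array caller's output granularity.

What the generator does **not** emulate: GC/length-dependent coverage
trends, FFPE artefacts, intratumoral heterogeneity (spatial subclones are
precisely what extraction-based assays miss), TP53-altered tumors, or the
array platform's real error structure (a simple noise model stands in for
the upstream caller). Passing recovery tests therefore demonstrate internal
consistency of the pipeline under its stated assumptions, not clinical
performance.

## Numerical and testing choices

- Contingency tables, κ and r_s on the 29-case reference cohort are exact
  desk-scale computations; κ comparisons use |computed − printed| ≤ 0.005
  after two-decimal rounding, r_s ± 0.005 to absorb rank-tie conventions.
- Simulation test sizes (10⁴ single-sample replicates for the
  law-of-large-numbers dosage check; 150–200 cohorts for threshold
  recovery; 120–200 tumors for sensitivity strata) keep Monte-Carlo error
  well inside the asserted tolerances while the full suite runs in a few
  seconds.
- The diploid false-positive band uses the predictive tail
  P(t_{n−1} > 2/√(1 + 1/n)) for a future ratio exceeding a mean + 2·SD
  cutoff estimated from n controls (≈ 4% at n = 12, versus the naive 2.3%
  normal tail), with a margin for the mild right-skew of a ratio of count
  means.
- Degenerate inputs (all-zero libraries, zero TP53 coverage, constant
  vectors in correlation, < 2 controls) raise typed errors rather than
  propagating NaN.

## Limitations

The NAC route's binary call has limited sensitivity for borderline
amplification (CN 4–6, low purity): dosage ratios near the calibrated
threshold fall below it once purity dilutes the signal — the simulation
study reproduces this directionally. Threshold transfer between cohorts
assumes identical panel efficiency structure; recalibrate per assay
version. The reference cohort ships printed values only, so upstream
read-level processing is out of scope.
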