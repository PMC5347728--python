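# her2cn

ERBB2/HER2 copy-number assessment from targeted amplicon sequencing, with
cross-platform concordance analysis against FISH and MIP-array measurements.

HER2/*ERBB2* amplification determines breast-cancer eligibility for
HER2-targeted therapy. The clinical standard counts *ERBB2* FISH signals per
cell; DNA-extraction-based alternatives — molecular inversion probe (MIP,
OncoScan) arrays and amplicon sequencing — produce copy-number estimates that
must be shown to agree with FISH before they can support clinical decisions.
This package implements the amplicon-sequencing route and the agreement
analysis, for bioinformaticians evaluating extraction-based HER2 testing:

- **The NAC statistic.** For one library, the normalized amplicon coverage of
  amplicon *a* is NAC_a = c_a / mean(c), the read count divided by the
  sample's mean read count. The *ERBB2* dosage ratio is
  r = mean(NAC over 3 ERBB2 amplicons) / mean(NAC over 8 TP53 amplicons),
  with *TP53* as the copy-neutral reference. A gain threshold is calibrated
  on copy-neutral controls as mean + 2·SD of the control ratios; r above the
  threshold is called positive (never equivocal).
- **ASCO/CAP 2013 classification** shared by FISH and MIP: negative CN < 4,
  equivocal 4 ≤ CN < 6, positive CN ≥ 6; FISH averages two observers' signal
  totals over 50 cells each.
- **Concordance statistics**: 3×3 contingency tables (empty categories
  retained), percent agreement, Cohen's unweighted κ, and tie-corrected
  Spearman rank correlation.
- **A packaged 29-case reference cohort** (FISH CN, MIP CN, NAC ratio and the
  published classes per case) plus a **synthetic cohort generator**
  (negative-binomial counts, per-amplicon efficiencies, tumor purity,
  two-observer FISH counts, MIP-like quantized values) for recovery
  experiments.

## Worked example

```python
>>> import her2cn
>>> report = her2cn.reproduce_reference_analysis()
>>> print(report.concordance_frame())
           n  n_agree  percent_agreement  kappa  spearman_r_s    spearman_p
pair
fish:mip  29       27                 93   0.87         0.940  4.001654e-14
fish:nac  29       24                 83   0.62         0.895  5.823497e-11
mip:nac   29       23                 79   0.56         0.917  2.813031e-12
```

Each row compares two platforms over the 29 reference cases: FISH and MIP
agree on 27/29 HER2 classes (93%, near-perfect κ = 0.87), while the
sequencing-based NAC call agrees with FISH on 24/29 (83%, substantial
κ = 0.62) — the NAC route, lacking an equivocal category, misses
borderline-amplified cases. Copy-number values are tightly rank-correlated
across all pairs (r_s ≥ 0.895, p < 0.001).

Fitting the pipeline to coverage data looks like:

```python
model = her2cn.NacCopyNumberModel(samples, her2cn.default_panel())
res = model.fit()          # calibrates mean + 2*SD threshold from controls
print(res.summary())       # per-sample ERBB2/TP53 ratios and gain calls
```

The same pipeline is scriptable from the shell:

```sh
her2cn simulate --seed 3 --out-dir sim/
her2cn nac --coverage sim/coverage.tsv --panel sim/panel.tsv \
       --controls control_001,control_002,... --out nac.csv
her2cn reproduce            # exits nonzero if any published statistic deviates
```

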