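"""The normalized-amplicon-coverage (NAC) gene-dosage statistic.

For one sequencing library the NAC of amplicon *a* is its read count
divided by the mean read count over all panel amplicons in that library,

    NAC_a = c_a / mean(c),

so the NAC values of a sample average to 1 by construction and are
invariant to library size.  The ERBB2 dosage statistic is

    r = mean(NAC over the ERBB2 amplicons) / mean(NAC over the TP53 amplicons),

with TP53 acting as the copy-neutral reference gene.  A gain threshold is
calibrated on a copy-neutral control cohort as mean + 2*SD of the control
ratios; a sample with r strictly above the threshold is called positive,
otherwise negative (the NAC route has no equivocal category).

`NacCopyNumberModel` wraps the pipeline statsmodels-style: construct it
from coverage data and a panel, `fit()` calibrates the threshold (unless
one is supplied) and returns a `NacResults` carrying per-sample dosage
ratios, calls, and the calibration provenance.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import (
    AmpliconPanel,
    Cohort,
    DegenerateInputError,
    Her2Class,
    NacThreshold,
    SampleCoverage,
)

__all__ = [
    "normalized_amplicon_coverage",
    "gene_nac",
    "erbb2_tp53_ratio",
    "calibrate_threshold",
    "classify_nac",
    "NacCopyNumberModel",
    "NacResults",
]


def normalized_amplicon_coverage(sample: SampleCoverage) -> dict[str, float]:
    """Per-amplicon NAC values: each count divided by the sample mean count.

    The divisor is the mean over *all* amplicons present in the sample
    (background amplicons included when the panel has them).  The returned
    values average to 1 exactly up to floating-point rounding.
    """
    if not sample.counts:
        raise DegenerateInputError(f"sample {sample.sample_id!r} has no amplicons")
    mean = sum(sample.counts.values()) / len(sample.counts)
    if mean <= 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id!r}: mean read count is zero"
        )
    return {amp: c / mean for amp, c in sample.counts.items()}


def gene_nac(nac: Mapping[str, float], panel: AmpliconPanel, gene: str) -> float:
    """Unweighted mean NAC over the amplicons covering ``gene``."""
    amps = panel.amplicons_for(gene)  # raises KeyError for unknown genes
    try:
        values = [nac[a.amplicon_id] for a in amps]
    except KeyError as e:
        raise DegenerateInputError(f"no NAC value for panel amplicon {e}") from None
    return sum(values) / len(values)


def erbb2_tp53_ratio(sample: SampleCoverage, panel: AmpliconPanel) -> float:
    """The ERBB2/TP53 gene-dosage ratio of one sample.

    Mean ERBB2-amplicon NAC divided by mean TP53-amplicon NAC; because the
    per-sample normalization cancels, this equals the ratio of the two
    genes' mean raw counts.
    """
    nac = normalized_amplicon_coverage(sample)
    tp53 = gene_nac(nac, panel, "TP53")
    if tp53 <= 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id!r}: zero TP53 coverage, ratio undefined"
        )
    return gene_nac(nac, panel, "ERBB2") / tp53


def calibrate_threshold(
    controls: Sequence[SampleCoverage], panel: AmpliconPanel
) -> NacThreshold:
    """Gain threshold from a copy-neutral control cohort: mean + 2*SD.

    The spread is the sample standard deviation (n-1 denominator), the
    conventional estimator for a control cohort.  At least two controls
    are required.
    """
    if len(controls) < 2:
        raise ValueError(
            f"threshold calibration needs >= 2 controls, got {len(controls)}"
        )
    ratios = [erbb2_tp53_ratio(s, panel) for s in controls]
    mean = statistics.fmean(ratios)
    sd = statistics.stdev(ratios)
    return NacThreshold(
        value=mean + 2.0 * sd, control_n=len(ratios), control_mean=mean, control_sd=sd
    )


def classify_nac(ratio: float, threshold: NacThreshold | float) -> Her2Class:
    """Binary gain call: positive iff the ratio strictly exceeds the threshold.

    The NAC route never returns equivocal.
    """
    cutoff = threshold.value if isinstance(threshold, NacThreshold) else float(threshold)
    return Her2Class.positive if ratio > cutoff else Her2Class.negative


# ---------------------------------------------------------------------------
# Model/Results wrapper
# ---------------------------------------------------------------------------


class NacCopyNumberModel:
    """ERBB2 gain calling from amplicon coverage, as a fitted model.

    Parameters
    ----------
    samples
        Coverage of tumor samples and (optionally) copy-neutral controls.
        Samples flagged ``cohort=control`` calibrate the threshold.
    panel
        The amplicon panel; must cover ERBB2 and TP53.
    threshold
        Optional fixed gain cutoff (a float or :class:`NacThreshold`).
        When given, controls are not required and calibration is skipped —
        pass :data:`her2cn.PUBLISHED_NAC_THRESHOLD` to reproduce the
        published classification.

    Examples
    --------
    >>> model = NacCopyNumberModel(samples, panel)
    >>> res = model.fit()
    >>> res.threshold.value        # mean + 2*SD over the controls
    >>> print(res.summary())
    """

    def __init__(
        self,
        samples: Sequence[SampleCoverage],
        panel: AmpliconPanel,
        threshold: NacThreshold | float | None = None,
    ) -> None:
        if not samples:
            raise ValueError("no samples")
        for s in samples:
            s.validate_against(panel)
        self.samples = list(samples)
        self.panel = panel
        if isinstance(threshold, (int, float)):
            threshold = NacThreshold(value=float(threshold))
        self.threshold = threshold

    @classmethod
    def from_files(
        cls,
        coverage_path,
        panel_path,
        control_ids: Sequence[str] = (),
        threshold: float | None = None,
    ) -> "NacCopyNumberModel":
        """Construct from a coverage-matrix TSV and a panel TSV/BED."""
        from . import datamodel as dm

        panel = dm.read_panel(panel_path)
        samples = dm.read_coverage_matrix(coverage_path, control_ids=control_ids)
        return cls(samples, panel, threshold=threshold)

    @property
    def controls(self) -> list[SampleCoverage]:
        return [s for s in self.samples if s.cohort is Cohort.control]

    @property
    def tumors(self) -> list[SampleCoverage]:
        return [s for s in self.samples if s.cohort is Cohort.tumor]

    def fit(self) -> "NacResults":
        """Calibrate the threshold (if not fixed) and call every sample."""
        threshold = self.threshold
        if threshold is None:
            threshold = calibrate_threshold(self.controls, self.panel)
        rows = []
        for s in self.samples:
            nac = normalized_amplicon_coverage(s)
            erbb2 = gene_nac(nac, self.panel, "ERBB2")
            tp53 = gene_nac(nac, self.panel, "TP53")
            ratio = erbb2 / tp53
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "cohort": s.cohort.value,
                    "erbb2_nac": erbb2,
                    "tp53_nac": tp53,
                    "ratio": ratio,
                    "her2_class": str(classify_nac(ratio, threshold)),
                }
            )
        frame = pd.DataFrame(rows).set_index("sample_id")
        return NacResults(model=self, threshold=threshold, frame=frame)


@dataclass
class NacResults:
    """Fitted per-sample ERBB2 dosage ratios and gain calls.

    Attributes
    ----------
    threshold
        The gain cutoff used, with calibration provenance when it was
        derived from controls in this fit.
    frame
        Per-sample table (index ``sample_id``) with columns ``cohort``,
        ``erbb2_nac``, ``tp53_nac``, ``ratio``, ``her2_class``.
    """

    model: NacCopyNumberModel
    threshold: NacThreshold
    frame: pd.DataFrame

    @property
    def ratios(self) -> pd.Series:
        return self.frame["ratio"]

    @property
    def calls(self) -> dict[str, Her2Class]:
        return {
            sid: Her2Class.from_label(cls)
            for sid, cls in self.frame["her2_class"].items()
        }

    def summary(self) -> str:
        t = self.threshold
        lines = ["ERBB2 NAC copy-number model", "=" * 35]
        lines.append(f"samples:      {len(self.frame)} "
                     f"({(self.frame['cohort'] == 'tumor').sum()} tumor, "
                     f"{(self.frame['cohort'] == 'control').sum()} control)")
        lines.append(f"panel:        {len(self.model.panel)} amplicons "
                     f"({len(self.model.panel.amplicons_for('ERBB2'))} ERBB2, "
                     f"{len(self.model.panel.amplicons_for('TP53'))} TP53)")
        if t.control_n is not None:
            lines.append(
                f"threshold:    {t.value:.4f} = {t.control_mean:.4f} + 2*{t.control_sd:.4f} "
                f"(mean + 2*SD over {t.control_n} controls)"
            )
        else:
            lines.append(f"threshold:    {t.value:.4f} (fixed)")
        n_pos = (self.frame["her2_class"] == "positive").sum()
        lines.append(f"gain calls:   {n_pos} positive / {len(self.frame) - n_pos} negative")
        lines.append("")
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(self.frame.to_string())
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, float_format="%.6g")
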