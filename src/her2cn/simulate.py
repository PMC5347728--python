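"""Synthetic amplicon-sequencing cohorts with known ERBB2 copy number.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised against a known ground truth:

* per-amplicon read counts are negative-binomial with mean
  ``depth * efficiency_a * c_eff(gene) / 2`` where the effective dosage
  ``c_eff = purity * true_cn + (1 - purity) * 2`` mixes tumor and stromal
  cells, and variance ``m + dispersion * m**2`` (Poisson in the
  dispersion -> 0 limit);
* per-amplicon capture efficiencies are drawn log-normal once per cohort
  (not per sample), reproducing the systematic ERBB2-vs-TP53 efficiency
  imbalance that makes even diploid dosage ratios sit far from 1 in real
  panels;
* FISH per-cell signal counts are Poisson(true_cn) truncated at 1 (a
  scored nucleus shows at least one signal), totalled over 50 cells for
  each of two observers;
* MIP-like copy-number values are the purity-mixed dosage plus Gaussian
  noise, quantized to thirds to mimic the array caller's output
  granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    AmpliconPanel,
    Cohort,
    FishObservation,
    SampleCoverage,
    default_panel,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "GroundTruth",
    "effective_cn",
    "draw_efficiencies",
    "simulate_sample",
    "simulate_cohort",
    "simulate_fish_observation",
    "simulate_mip_cn",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the clinical series the analysis was built for: 29
    tumors against 12 copy-neutral controls, mean library depths of 3869
    (tumors) and 2484 (controls) reads per amplicon, and a tumor mix that
    is mostly copy-neutral with equivocal-range and amplified strata.
    """

    seed: int = 0
    n_tumors: int = 29
    n_controls: int = 12
    mean_depth_tumor: float = 3869.0
    mean_depth_control: float = 2484.0
    dispersion: float = 0.05
    purity_range: tuple[float, float] = (0.5, 0.9)
    efficiency_sd: float = 0.5
    tp53_cn: float = 2.0
    #: (true ERBB2 copy number, sampling weight) strata for tumor samples.
    cn_states: tuple[tuple[float, float], ...] = (
        (2.0, 18 / 29),
        (5.0, 3 / 29),
        (12.0, 8 / 29),
    )

    def __post_init__(self) -> None:
        if self.mean_depth_tumor <= 0 or self.mean_depth_control <= 0:
            raise ValueError("mean depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"purity_range must satisfy 0 < lo <= hi <= 1, got {self.purity_range}")
        if self.efficiency_sd < 0:
            raise ValueError("efficiency_sd must be non-negative")
        weights = [w for _, w in self.cn_states]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"cn_states weights must sum to 1, got {sum(weights)}")
        if any(w < 0 for w in weights) or any(c < 0 for c, _ in self.cn_states):
            raise ValueError("cn_states entries must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Latent state of one simulated sample."""

    sample_id: str
    cohort: Cohort
    erbb2_cn: float
    tp53_cn: float
    purity: float


@dataclass
class GroundTruth:
    """Latent states of a simulated cohort plus the shared amplicon efficiencies."""

    samples: dict[str, TruthRecord] = field(default_factory=dict)
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, sample_id: str) -> TruthRecord:
        return self.samples[sample_id]


def effective_cn(true_cn: float, purity: float) -> float:
    """Bulk-DNA effective dosage: tumor copies diluted by diploid stroma."""
    return purity * true_cn + (1.0 - purity) * 2.0


def draw_efficiencies(
    panel: AmpliconPanel, sd: float, rng: np.random.Generator
) -> dict[str, float]:
    """Log-normal per-amplicon capture efficiencies, normalized to mean 1.

    Drawn once per cohort: efficiency differences are a property of the
    assay (primer performance), not of individual libraries.
    """
    if sd < 0:
        raise ValueError("efficiency_sd must be non-negative")
    if sd == 0:
        return {a: 1.0 for a in panel.amplicon_ids}
    raw = rng.lognormal(mean=0.0, sigma=sd, size=len(panel))
    raw = raw / raw.mean()
    return dict(zip(panel.amplicon_ids, raw))


def _gene_cn(gene: str, truth: TruthRecord) -> float:
    if gene == "ERBB2":
        return truth.erbb2_cn
    if gene == "TP53":
        return truth.tp53_cn
    return 2.0  # background genes are copy-neutral


def simulate_sample(
    truth: TruthRecord,
    panel: AmpliconPanel,
    depth: float,
    dispersion: float,
    rng: np.random.Generator,
    efficiencies: dict[str, float] | None = None,
) -> SampleCoverage:
    """Draw one sample's read counts.

    Amplicon *a* of gene *g* has expected count
    ``depth * efficiency_a * c_eff(g) / 2``; counts are negative-binomial
    with variance ``m + dispersion * m**2``, degenerating to Poisson as
    dispersion -> 0.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if efficiencies is None:
        efficiencies = {a: 1.0 for a in panel.amplicon_ids}
    counts: dict[str, int] = {}
    for amp in panel:
        c_eff = effective_cn(_gene_cn(amp.gene, truth), truth.purity)
        m = depth * efficiencies[amp.amplicon_id] * c_eff / 2.0
        if m <= 0:
            counts[amp.amplicon_id] = 0
        elif dispersion < 1e-12:
            counts[amp.amplicon_id] = int(rng.poisson(m))
        else:
            size = 1.0 / dispersion  # NB: var = m + d*m^2
            p = size / (size + m)
            counts[amp.amplicon_id] = int(rng.negative_binomial(size, p))
    return SampleCoverage(sample_id=truth.sample_id, cohort=truth.cohort, counts=counts)


def simulate_cohort(
    config: SimulationConfig, panel: AmpliconPanel | None = None
) -> tuple[list[SampleCoverage], GroundTruth]:
    """Draw a full cohort: tumors with mixed copy-number states plus controls.

    Controls are pure diploid (erbb2_cn = tp53_cn = 2, purity 1) and are
    flagged ``cohort=control`` for downstream threshold calibration; at
    least two are required.  Returns the coverage list and the ground
    truth for recovery experiments.  Fully reproducible from the seed.
    """
    if config.n_controls < 2:
        raise ValueError("need >= 2 controls for threshold calibration")
    if config.n_tumors < 0:
        raise ValueError("n_tumors must be non-negative")
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(efficiencies=draw_efficiencies(panel, config.efficiency_sd, rng))

    cns = np.array([c for c, _ in config.cn_states])
    weights = np.array([w for _, w in config.cn_states])
    samples: list[SampleCoverage] = []
    for i in range(config.n_tumors):
        record = TruthRecord(
            sample_id=f"tumor_{i + 1:03d}",
            cohort=Cohort.tumor,
            erbb2_cn=float(rng.choice(cns, p=weights)),
            tp53_cn=config.tp53_cn,
            purity=float(rng.uniform(*config.purity_range)),
        )
        truth.samples[record.sample_id] = record
        samples.append(
            simulate_sample(
                record, panel, config.mean_depth_tumor, config.dispersion, rng,
                truth.efficiencies,
            )
        )
    for i in range(config.n_controls):
        record = TruthRecord(
            sample_id=f"control_{i + 1:03d}",
            cohort=Cohort.control,
            erbb2_cn=2.0,
            tp53_cn=2.0,
            purity=1.0,
        )
        truth.samples[record.sample_id] = record
        samples.append(
            simulate_sample(
                record, panel, config.mean_depth_control, config.dispersion, rng,
                truth.efficiencies,
            )
        )
    return samples, truth


def simulate_fish_observation(
    true_cn: float,
    cells: int = 50,
    observers: int = 2,
    rng: np.random.Generator | None = None,
    case_id: str = "sim",
    deterministic: bool = False,
) -> FishObservation:
    """Two-observer FISH signal totals over ``cells`` nuclei each.

    Per-cell counts are Poisson(true_cn) truncated to >= 1 — a sectioned
    nucleus that gets scored retains at least one visible signal.  With
    ``deterministic=True`` every cell reports ``max(1, round(true_cn))``,
    the zero-variance limit used for exact-arithmetic checks.
    """
    if cells <= 0:
        raise ValueError(f"cells must be positive, got {cells}")
    if observers != 2:
        raise ValueError("the two-observer protocol is the only one supported")
    if true_cn < 0:
        raise ValueError("true_cn must be non-negative")
    if deterministic:
        per_cell = max(1, round(true_cn))
        total = per_cell * cells
        return FishObservation(case_id, total, total, cells_per_observer=cells)
    if rng is None:
        raise ValueError("rng is required unless deterministic=True")
    totals = []
    for _ in range(observers):
        draws = rng.poisson(true_cn, size=cells)
        while True:  # truncate at 1 by redrawing zero-signal cells
            zeros = draws == 0
            if not zeros.any():
                break
            draws[zeros] = rng.poisson(true_cn, size=int(zeros.sum()))
        totals.append(int(draws.sum()))
    return FishObservation(case_id, totals[0], totals[1], cells_per_observer=cells)


def simulate_mip_cn(
    true_cn: float,
    purity: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """MIP-array-like copy-number estimate.

    Purity-mixed dosage plus Gaussian measurement noise, floored at 0 and
    quantized to multiples of 1/3 (the granularity the array caller
    emits).
    """
    value = effective_cn(true_cn, purity)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        value += rng.normal(0.0, noise_sd)
    value = max(0.0, value)
    return round(value * 3.0) / 3.0
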