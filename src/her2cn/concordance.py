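"""Cross-platform agreement statistics.

Paired HER2 classifications are compared with a k-by-k contingency table,
overall percent agreement, and Cohen's unweighted kappa; paired continuous
copy-number values are compared with the tie-corrected Spearman rank
correlation.  Category order is fixed everywhere as
(negative, equivocal, positive), and empty categories are retained in the
table: a platform that never calls equivocal still contributes a 3x3 table,
because collapsing rows changes the chance-agreement term of kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import Her2Class

__all__ = [
    "ConcordanceResult",
    "CorrelationResult",
    "contingency_table",
    "percent_agreement",
    "cohen_kappa",
    "spearman_correlation",
    "HER2_LABELS",
]

#: Fixed category order shared by every table and kappa computation.
HER2_LABELS: tuple[Her2Class, ...] = (
    Her2Class.negative,
    Her2Class.equivocal,
    Her2Class.positive,
)


@dataclass
class ConcordanceResult:
    """A k-by-k agreement table (rows = platform A, columns = platform B)."""

    labels: tuple
    table: np.ndarray
    degenerate_kappa: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        k = len(self.labels)
        if self.table.shape != (k, k):
            raise ValueError(f"table shape {self.table.shape} != ({k}, {k})")
        if (self.table < 0).any():
            raise ValueError("negative cell counts")

    @property
    def n(self) -> int:
        return int(self.table.sum())

    @property
    def n_agree(self) -> int:
        return int(np.trace(self.table))

    def __str__(self) -> str:
        names = [str(l) for l in self.labels]
        width = max(len(s) for s in names) + 2
        head = " " * width + "".join(f"{s:>{width}}" for s in names)
        rows = [
            f"{names[i]:>{width}}" + "".join(f"{c:>{width}}" for c in self.table[i])
            for i in range(len(names))
        ]
        return "\n".join([head, *rows])


@dataclass(frozen=True)
class CorrelationResult:
    """Tie-corrected Spearman rank correlation with its t-approximation p-value."""

    r_s: float
    n: int
    p_value: float


def contingency_table(
    a: Sequence[Her2Class],
    b: Sequence[Her2Class],
    labels: Sequence = HER2_LABELS,
) -> ConcordanceResult:
    """Cross-tabulate paired classifications (rows = ``a``, columns = ``b``)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=int)
    for x, y in zip(a, b):
        try:
            table[index[x], index[y]] += 1
        except KeyError as e:
            raise ValueError(f"value {e} not in labels {tuple(labels)}") from None
    return ConcordanceResult(labels=tuple(labels), table=table)


def percent_agreement(result: ConcordanceResult) -> float:
    """Overall agreement, 100 * trace / n, on the 0-100 scale."""
    if result.n == 0:
        raise ValueError("empty table")
    return 100.0 * result.n_agree / result.n


def cohen_kappa(result: ConcordanceResult) -> float:
    """Cohen's unweighted kappa of an agreement table.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o = trace/n
    and chance agreement p_e = sum_i row_i * col_i / n^2.  In the
    degenerate case p_e = 1 (both raters constant on the same category)
    kappa is undefined; the exact-agreement indicator (1.0 for perfect
    agreement, 0.0 otherwise) is returned and ``result.degenerate_kappa``
    is set.
    """
    n = result.n
    if n == 0:
        raise ValueError("empty table")
    p_o = result.n_agree / n
    rows = result.table.sum(axis=1)
    cols = result.table.sum(axis=0)
    p_e = float(rows @ cols) / (n * n)
    if p_e >= 1.0 - 1e-15:
        result.degenerate_kappa = True
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-rank tie handling.

    r_s is the Pearson correlation of the mid-rank vectors (exact tie
    correction); the p-value uses the large-sample t approximation
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  Requires n >= 3
    and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(r_s=float(r), n=len(x), p_value=float(p))
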