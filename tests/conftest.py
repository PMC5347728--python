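"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths (and the
library calls behind them): Spearman via explicit mid-ranks plus a raw
Pearson formula, kappa via the textbook probability bookkeeping on label
lists.  Tests compare package output against these.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from her2cn import default_panel, load_reference_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def reference():
    return load_reference_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20160929)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def midranks(values) -> list[float]:
    """Mid-ranks (average rank over ties), 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of the mid-rank vectors, from first principles."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def kappa_oracle(a, b) -> float | None:
    """Cohen's unweighted kappa from label lists; None when p_e = 1."""
    n = len(a)
    labels = sorted(set(a) | set(b))
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum(
        (sum(x == lab for x in a) / n) * (sum(y == lab for y in b) / n)
        for lab in labels
    )
    if p_e >= 1.0 - 1e-15:
        return None
    return (p_o - p_e) / (1.0 - p_e)
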