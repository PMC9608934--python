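"""Exact binomial probability calculus for two-stage pass events.

Every stopping rule in a Bryant & Day-type design is of the form
"continue/pass if the observed count reaches a boundary".  With a count
``X1 ~ Binomial(n1, p)`` at the interim and an independent second-stage
count ``X2 ~ Binomial(n2, p)``, the two events that matter are

* the stage-1 pass event ``{X1 >= k1}``, and
* the joint pass event ``{X1 >= k1 and X1 + X2 >= k}``,

whose probabilities are computed here by stable survival-function
evaluation and a convolution over the admissible stage-1 outcomes.

Conventions used throughout the package: "pass" is ``count >= boundary``,
"stop" is ``count < boundary``.  Boundaries above the sample size are
legal inputs and give probability 0 (the design searches iterate through
them); boundaries at or below 0 always pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "StageCounts",
    "stage1_pass_prob",
    "joint_pass_prob",
    "joint_pass_table",
]


def _check_prob(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p!r}")


def _check_size(n: int, name: str) -> None:
    if n < 0 or int(n) != n:
        raise ValueError(f"{name} must be a nonnegative integer, got {n!r}")


@dataclass(frozen=True)
class StageCounts:
    """Sample sizes and boundaries for one endpoint of one two-stage arm.

    Attributes
    ----------
    n1, n2
        Stage-1 and stage-2 sample sizes (patients).
    k1, k
        Stage-1 and final pass boundaries (minimum counts).  Boundaries
        exceeding the reachable counts are allowed; the pass event then
        has probability 0.
    """

    n1: int
    n2: int
    k1: int
    k: int

    def __post_init__(self) -> None:
        _check_size(self.n1, "n1")
        _check_size(self.n2, "n2")
        if self.k1 < 0 or self.k < 0:
            raise ValueError("boundaries must be >= 0")

    @property
    def n(self) -> int:
        return self.n1 + self.n2


def stage1_pass_prob(n1: int, k1: int, p: float) -> float:
    """P(X1 >= k1) for X1 ~ Binomial(n1, p)."""
    _check_size(n1, "n1")
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    _check_prob(p)
    if k1 == 0:
        return 1.0
    if k1 > n1:
        return 0.0
    return float(binom.sf(k1 - 1, n1, p))


def joint_pass_prob(n1: int, n2: int, k1: int, k: int, p: float) -> float:
    """P(X1 >= k1 and X1 + X2 >= k) for independent binomial stage counts.

    Computed by conditioning on the stage-1 count:

        sum_{x1 = k1}^{n1}  pmf(x1; n1, p) * P(X2 >= k - x1; n2, p)

    which is exact and never exceeds ``stage1_pass_prob(n1, k1, p)``.
    """
    _check_size(n1, "n1")
    _check_size(n2, "n2")
    if k1 < 0 or k < 0:
        raise ValueError("boundaries must be >= 0")
    _check_prob(p)
    if k1 > n1:
        return 0.0
    x1 = np.arange(k1, n1 + 1)
    pmf = binom.pmf(x1, n1, p)
    # sf(j) = P(X2 > j); j < 0 gives 1, j >= n2 gives 0 — no special-casing.
    tail = binom.sf(k - x1 - 1, n2, p)
    return float(min(1.0, pmf @ tail))


def joint_pass_table(n1: int, n2: int, p: float) -> np.ndarray:
    """Table J[k1, k] = P(X1 >= k1 and X1 + X2 >= k) for all boundary pairs.

    Shape ``(n1 + 2, n1 + n2 + 2)``: k1 ranges over 0..n1+1 and k over
    0..n1+n2+1, so the out-of-range rows/columns (probability of an
    unreachable boundary) are included for the benefit of design searches.
    Column 0 is the stage-1 pass probability P(X1 >= k1).
    """
    _check_size(n1, "n1")
    _check_size(n2, "n2")
    _check_prob(p)
    x1 = np.arange(0, n1 + 1)
    pmf = binom.pmf(x1, n1, p)
    k = np.arange(0, n1 + n2 + 2)
    # M[x1, k] = pmf(x1) * P(X2 >= k - x1)
    tail = binom.sf(k[None, :] - x1[:, None] - 1, n2, p)
    m = pmf[:, None] * tail
    j = np.zeros((n1 + 2, n1 + n2 + 2))
    # J[k1] = sum over x1 >= k1; reverse cumulative sum over stage-1 rows.
    j[:-1] = np.cumsum(m[::-1], axis=0)[::-1]
    return np.minimum(j, 1.0)
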