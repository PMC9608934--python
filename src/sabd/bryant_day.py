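"""Bryant & Day two-stage phase II design for co-primary endpoints.

The Bryant & Day (BD) design extends Simon's two-stage design to a pair
of binary co-primary endpoints, conventionally response and non-toxicity.
A single arm enrols ``N1`` patients; the trial stops for futility unless
both the response count and the non-toxicity count reach their stage-1
boundaries (``X_R1 >= k_R1 and X_T1 >= k_T1``).  Otherwise ``N - N1``
further patients are enrolled and the treatment is declared promising if
both final counts reach their final boundaries.

With the endpoints assumed independent, every rejection probability
factorises into a response term and a non-toxicity term, each a two-stage
joint pass probability.  Four error rates are attached to the four corner
hypotheses H00/H01/H10/H11 pairing unacceptable (0) and acceptable (1)
rates: alpha (H00), alpha_R (H01), alpha_T (H10) and beta (H11).

The optimal design minimises the maximum expected sample size under H01
or H10 subject to ``alpha_R``, ``alpha_T`` and ``beta``; the minimax
design minimises the total sample size first.  Overall alpha under H00 is
reported but not constrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom

from .core import joint_pass_prob, joint_pass_table, stage1_pass_prob

__all__ = [
    "BDHypotheses",
    "BDDesign",
    "BDOperatingCharacteristics",
    "BDSearchResult",
    "InfeasibleDesignError",
    "bd_reject_prob",
    "bd_pet",
    "bd_ess",
    "bd_operating_characteristics",
    "single_stage_min_n",
    "bd_optimal_search",
]

_STATES = ("H00", "H01", "H10", "H11")


class InfeasibleDesignError(Exception):
    """No design within the search bounds satisfies the error constraints."""


@dataclass(frozen=True)
class BDHypotheses:
    """Rate hypotheses and error-rate constraints for one BD design.

    ``p_r0 < p_r1`` are the unacceptable/acceptable response rates and
    ``p_t0 < p_t1`` the unacceptable/acceptable non-toxicity rates.
    ``alpha_r`` bounds the type I error under H01 (response null true,
    toxicity acceptable), ``alpha_t`` under H10, and ``beta`` the type II
    error under H11.
    """

    p_r0: float
    p_r1: float
    p_t0: float
    p_t1: float
    alpha_r: float
    alpha_t: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_r0 < self.p_r1 < 1.0:
            raise ValueError("need 0 < p_r0 < p_r1 < 1")
        if not 0.0 < self.p_t0 < self.p_t1 < 1.0:
            raise ValueError("need 0 < p_t0 < p_t1 < 1")
        for name in ("alpha_r", "alpha_t", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")

    def rate_state(self, state: str) -> tuple[float, float]:
        """(p_R, p_T) at one of the corner states H00/H01/H10/H11."""
        i, j = int(state[1]), int(state[2])
        return (
            self.p_r1 if i else self.p_r0,
            self.p_t1 if j else self.p_t0,
        )


@dataclass(frozen=True)
class BDDesign:
    """One-arm two-stage design: sizes (N1, N) and boundaries.

    ``k_r1``/``k_t1`` are the stage-1 pass boundaries for response and
    non-toxicity, ``k_r``/``k_t`` the final ones.
    """

    n1: int
    n: int
    k_r1: int
    k_t1: int
    k_r: int
    k_t: int

    def __post_init__(self) -> None:
        if not 1 <= self.n1 < self.n:
            raise ValueError("need 1 <= n1 < n")
        if min(self.k_r1, self.k_t1, self.k_r, self.k_t) < 0:
            raise ValueError("boundaries must be >= 0")
        if self.k_r1 > self.k_r or self.k_t1 > self.k_t:
            raise ValueError("stage-1 boundary cannot exceed final boundary")

    @property
    def n2(self) -> int:
        return self.n - self.n1


@dataclass(frozen=True)
class BDOperatingCharacteristics:
    """Exact attained error rates, power, ESS and PET of a BD design."""

    alpha: float
    alpha_r: float
    alpha_t: float
    power: float
    ess_by_state: dict[str, float]
    pet_by_state: dict[str, float]
    max_ess: float

    def satisfies(self, h: BDHypotheses) -> bool:
        return (
            self.alpha_r <= h.alpha_r
            and self.alpha_t <= h.alpha_t
            and self.power >= 1.0 - h.beta
        )


@dataclass(frozen=True)
class BDSearchResult:
    design: BDDesign
    oc: BDOperatingCharacteristics
    criterion: str
    n_max: int
    n_candidates: int


def bd_reject_prob(d: BDDesign, p_r: float, p_t: float) -> float:
    """Probability of a go-decision: both endpoints pass both analyses."""
    return joint_pass_prob(d.n1, d.n2, d.k_r1, d.k_r, p_r) * joint_pass_prob(
        d.n1, d.n2, d.k_t1, d.k_t, p_t
    )


def bd_pet(d: BDDesign, p_r: float, p_t: float) -> float:
    """Probability of stopping at the interim (either endpoint below bar)."""
    return 1.0 - stage1_pass_prob(d.n1, d.k_r1, p_r) * stage1_pass_prob(
        d.n1, d.k_t1, p_t
    )


def bd_ess(d: BDDesign, p_r: float, p_t: float) -> float:
    """Expected sample size: N1 plus the second stage when continuing."""
    return d.n1 + d.n2 * (1.0 - bd_pet(d, p_r, p_t))


def bd_operating_characteristics(
    d: BDDesign, h: BDHypotheses
) -> BDOperatingCharacteristics:
    reject = {s: bd_reject_prob(d, *h.rate_state(s)) for s in _STATES}
    ess = {s: bd_ess(d, *h.rate_state(s)) for s in _STATES}
    pet = {s: bd_pet(d, *h.rate_state(s)) for s in _STATES}
    return BDOperatingCharacteristics(
        alpha=reject["H00"],
        alpha_r=reject["H01"],
        alpha_t=reject["H10"],
        power=reject["H11"],
        ess_by_state=ess,
        pet_by_state=pet,
        max_ess=max(ess["H01"], ess["H10"]),
    )


def single_stage_min_n(h: BDHypotheses, n_limit: int = 500) -> int:
    """Smallest single-stage bivariate sample size meeting the constraints.

    A single-stage design declares success when both final counts reach
    their boundaries; this is the natural lower anchor for the two-stage
    search range.
    """
    for n in range(1, n_limit + 1):
        k = np.arange(0, n + 2)
        fr0 = binom.sf(k - 1, n, h.p_r0)
        fr1 = binom.sf(k - 1, n, h.p_r1)
        ft0 = binom.sf(k - 1, n, h.p_t0)
        ft1 = binom.sf(k - 1, n, h.p_t1)
        ok = (
            (np.outer(fr0, ft1) <= h.alpha_r)
            & (np.outer(fr1, ft0) <= h.alpha_t)
            & (np.outer(fr1, ft1) >= 1.0 - h.beta)
        )
        if ok.any():
            return n
    raise InfeasibleDesignError(
        f"no single-stage design with n <= {n_limit} satisfies the constraints"
    )


def _feasible_finals(
    a0: np.ndarray,
    a1: np.ndarray,
    b0: np.ndarray,
    b1: np.ndarray,
    h: BDHypotheses,
) -> tuple[int, int] | None:
    """First (lexicographic) feasible final-boundary offsets, or None.

    ``a0/a1`` are joint pass probabilities for response at p_r0/p_r1 over
    candidate k_r values (ascending), ``b0/b1`` likewise for toxicity.
    """
    ok = (
        (np.outer(a0, b1) <= h.alpha_r)
        & (np.outer(a1, b0) <= h.alpha_t)
        & (np.outer(a1, b1) >= 1.0 - h.beta)
    )
    if not ok.any():
        return None
    i, j = np.argwhere(ok)[0]
    return int(i), int(j)


def bd_optimal_search(
    h: BDHypotheses,
    n_max: int | None = None,
    criterion: str = "optimal",
) -> BDSearchResult:
    """Search for the optimal (min max-ESS) or minimax (min N) BD design.

    For each (N1, N) the four joint-pass tables are pre-tabulated, the
    stage-1 boundary pairs are ordered by their max-ESS and scanned until
    the first pair admitting feasible final boundaries — valid because
    the objective depends on the design only through (N1, N, k_r1, k_t1).
    Pairs whose stage-1 pass probabilities already cap power below
    ``1 - beta`` are pruned (raising a boundary never raises power).

    Ties in max-ESS (within 1e-9) break to smaller N, then smaller N1,
    then the lexicographically smallest (k_r1, k_t1, k_r, k_t).
    """
    if criterion not in ("optimal", "minimax"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if n_max is None:
        n_max = 2 * single_stage_min_n(h)
    best_key: tuple | None = None
    best: tuple[BDDesign, float] | None = None
    n_candidates = 0
    any_power_ok = False
    for n in range(2, n_max + 1):
        if criterion == "minimax" and best is not None:
            break
        for n1 in range(1, n):
            if (
                criterion == "optimal"
                and best is not None
                and n1 >= best[1] - 1e-9
            ):
                continue  # ESS >= N1 can never beat the incumbent
            n2 = n - n1
            jr0 = joint_pass_table(n1, n2, h.p_r0)
            jr1 = joint_pass_table(n1, n2, h.p_r1)
            jt0 = joint_pass_table(n1, n2, h.p_t0)
            jt1 = joint_pass_table(n1, n2, h.p_t1)
            # Stage-1 pass probabilities are column 0 of the tables.
            s1r0, s1r1 = jr0[: n1 + 1, 0], jr1[: n1 + 1, 0]
            s1t0, s1t1 = jt0[: n1 + 1, 0], jt1[: n1 + 1, 0]
            # Power cap: no final boundary can beat the stage-1 gate.
            cap = np.outer(s1r1, s1t1) >= 1.0 - h.beta
            if not cap.any():
                continue
            any_power_ok = True
            cont01 = np.outer(s1r0, s1t1)
            cont10 = np.outer(s1r1, s1t0)
            max_ess = n1 + n2 * np.maximum(cont01, cont10)
            pairs = np.argwhere(cap)
            n_candidates += len(pairs)
            order = np.argsort(max_ess[cap], kind="stable")
            for kr1, kt1 in pairs[order]:
                kr1, kt1 = int(kr1), int(kt1)
                ess_here = float(max_ess[kr1, kt1])
                if best is not None and ess_here > best[1] + 1e-9:
                    break
                hit = _feasible_finals(
                    jr0[kr1, kr1 : n + 1],
                    jr1[kr1, kr1 : n + 1],
                    jt0[kt1, kt1 : n + 1],
                    jt1[kt1, kt1 : n + 1],
                    h,
                )
                if hit is None:
                    continue
                kr = kr1 + hit[0]
                kt = kt1 + hit[1]
                key = (n, n1, kr1, kt1, kr, kt)
                if (
                    best is None
                    or ess_here < best[1] - 1e-9
                    or (abs(ess_here - best[1]) <= 1e-9 and key < best_key)
                ):
                    best = (BDDesign(n1, n, kr1, kt1, kr, kt), ess_here)
                    best_key = key
                break  # first feasible pair is optimal for this (N1, N)
    if best is None:
        binding = (
            "power >= 1 - beta (stage-1 pass probabilities too low at the "
            "acceptable rates)"
            if not any_power_ok
            else "alpha_R / alpha_T at the null rates"
        )
        raise InfeasibleDesignError(
            f"no feasible BD design with N <= {n_max}; binding constraint: "
            f"{binding}; consider raising n_max"
        )
    d = best[0]
    oc = bd_operating_characteristics(d, h)
    assert oc.satisfies(h)
    return BDSearchResult(
        design=d,
        oc=oc,
        criterion=criterion,
        n_max=n_max,
        n_candidates=n_candidates,
    )


@lru_cache(maxsize=64)
def bd_optimal_search_cached(
    h: BDHypotheses, n_max: int | None = None, criterion: str = "optimal"
) -> BDSearchResult:
    """Memoised front-end to :func:`bd_optimal_search` (hypotheses are frozen)."""
    return bd_optimal_search(h, n_max=n_max, criterion=criterion)
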