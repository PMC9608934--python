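"""Exact operating characteristics of the stratified adaptive BD design.

The stratified adaptive Bryant & Day (SABD) design runs the two-stage
co-primary-endpoint decision rule in two pre-defined strata — a
"negative" subgroup (e.g. frail patients) and a "positive" subgroup
(e.g. fit patients) — under the hierarchy assumption that true response
and non-toxicity rates in the positive subgroup are at least those in
the negative one.  Stage 1 enrols ``N1-`` and ``N1+`` patients; then

* if the negative subgroup passes its stage-1 boundaries, accrual
  continues in the unselected population (both subgroups) and a
  go-decision in the unselected population (pathway S1) requires the
  negative subgroup's final counts to pass; failing that, a go-decision
  restricted to the positive subgroup (pathway S2) requires the positive
  totals over ``N+`` patients to pass their final boundaries;
* if only the positive subgroup passes stage 1, accrual continues in
  that subgroup alone (enrichment) up to ``Ne+`` patients, and a
  positive-subgroup-only go-decision (pathway S3) requires the
  enrichment totals to pass;
* if neither subgroup passes stage 1, the trial stops for futility.

With independent endpoints all pathway probabilities factorise into
products of binomial tail and two-stage joint pass probabilities, so the
operating characteristics below are exact, not simulated.  Three type I
error rates (alpha, alpha_R, alpha_T) are evaluated at the corner null
states, and the overall power is the minimum of the unselected-population
power P(S1 | H11-) and the positive-subgroup-only power
P(S2) + P(S3) evaluated with the negative subgroup at its null.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

from .core import joint_pass_prob, stage1_pass_prob

__all__ = [
    "SABDHypotheses",
    "SABDDesign",
    "RateState",
    "OperatingCharacteristics",
    "p_s1",
    "p_s2",
    "p_s3",
    "sabd_error_rates",
    "sabd_power",
    "sabd_ess",
    "sabd_pet",
    "sabd_operating_characteristics",
]

_STATES = ("H00", "H01", "H10", "H11")


@dataclass(frozen=True)
class SABDHypotheses:
    """Per-subgroup rate hypotheses and error-rate constraints.

    The null rates ``p_r0``/``p_t0`` are common to both subgroups; the
    acceptable rates may differ, with the positive subgroup at least as
    good (hierarchy assumption).  ``alpha_r``/``alpha_t`` bound the type I
    error rates under H01/H10 applied in both subgroups, ``beta`` the
    type II error under H11.
    """

    p_r0: float
    p_t0: float
    p_r1_neg: float
    p_r1_pos: float
    p_t1_neg: float
    p_t1_pos: float
    alpha_r: float
    alpha_t: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_r0 < self.p_r1_neg <= self.p_r1_pos < 1.0:
            raise ValueError("need 0 < p_r0 < p_r1_neg <= p_r1_pos < 1")
        if not 0.0 < self.p_t0 < self.p_t1_neg <= self.p_t1_pos < 1.0:
            raise ValueError("need 0 < p_t0 < p_t1_neg <= p_t1_pos < 1")
        for name in ("alpha_r", "alpha_t", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")

    def rate_state(self, state: str) -> "RateState":
        """RateState at a corner hypothesis applied in both subgroups.

        Uses the subgroup-specific acceptable rates, e.g. H01 is
        ``(p_r0, p_t1_neg)`` in the negative and ``(p_r0, p_t1_pos)`` in
        the positive subgroup.
        """
        i, j = int(state[1]), int(state[2])
        return RateState(
            p_r_neg=self.p_r1_neg if i else self.p_r0,
            p_t_neg=self.p_t1_neg if j else self.p_t0,
            p_r_pos=self.p_r1_pos if i else self.p_r0,
            p_t_pos=self.p_t1_pos if j else self.p_t0,
        )

    @property
    def negative(self):
        from .bryant_day import BDHypotheses

        return BDHypotheses(
            self.p_r0, self.p_r1_neg, self.p_t0, self.p_t1_neg,
            self.alpha_r, self.alpha_t, self.beta,
        )

    @property
    def positive(self):
        from .bryant_day import BDHypotheses

        return BDHypotheses(
            self.p_r0, self.p_r1_pos, self.p_t0, self.p_t1_pos,
            self.alpha_r, self.alpha_t, self.beta,
        )


@dataclass(frozen=True)
class RateState:
    """True response/non-toxicity rates per subgroup."""

    p_r_neg: float
    p_t_neg: float
    p_r_pos: float
    p_t_pos: float

    def __post_init__(self) -> None:
        for name in ("p_r_neg", "p_t_neg", "p_r_pos", "p_t_pos"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class SABDDesign:
    """The 15-parameter stratified design.

    Negative subgroup: ``n1_neg`` then up to ``n_neg`` with boundaries
    ``k_r1_neg/k_t1_neg`` (stage 1) and ``k_r_neg/k_t_neg`` (final).
    Positive subgroup, unselected path: ``n1_pos`` then ``n_pos`` with
    stage-1 boundaries ``k_r1_pos/k_t1_pos`` and final boundaries
    ``k_r_pos/k_t_pos`` applied to the totals over ``n_pos``.
    Enrichment path: total ``ne_pos`` with final boundaries
    ``k_re_pos/k_te_pos``.
    """

    n1_neg: int
    n_neg: int
    k_r1_neg: int
    k_t1_neg: int
    k_r_neg: int
    k_t_neg: int
    n1_pos: int
    n_pos: int
    ne_pos: int
    k_r1_pos: int
    k_t1_pos: int
    k_r_pos: int
    k_t_pos: int
    k_re_pos: int
    k_te_pos: int

    def __post_init__(self) -> None:
        if not 1 <= self.n1_neg < self.n_neg:
            raise ValueError("need 1 <= n1_neg < n_neg")
        if not 1 <= self.n1_pos <= self.n_pos:
            raise ValueError("need 1 <= n1_pos <= n_pos")
        if not self.n1_pos < self.ne_pos:
            raise ValueError("need n1_pos < ne_pos")
        bounds = (
            self.k_r1_neg, self.k_t1_neg, self.k_r_neg, self.k_t_neg,
            self.k_r1_pos, self.k_t1_pos, self.k_r_pos, self.k_t_pos,
            self.k_re_pos, self.k_te_pos,
        )
        if min(bounds) < 0:
            raise ValueError("boundaries must be >= 0")
        if self.k_r1_neg > self.k_r_neg or self.k_t1_neg > self.k_t_neg:
            raise ValueError("negative stage-1 boundary exceeds final boundary")
        if self.k_r1_pos > self.k_r_pos or self.k_t1_pos > self.k_t_pos:
            raise ValueError("positive stage-1 boundary exceeds final boundary")
        if self.k_r1_pos > self.k_re_pos or self.k_t1_pos > self.k_te_pos:
            raise ValueError("enrichment boundary below stage-1 boundary")

    @property
    def n2_neg(self) -> int:
        return self.n_neg - self.n1_neg

    @property
    def n2_pos(self) -> int:
        return self.n_pos - self.n1_pos

    @property
    def n2e_pos(self) -> int:
        return self.ne_pos - self.n1_pos

    @property
    def max_sample_size(self) -> int:
        return self.n_neg + self.n_pos


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Exact operating characteristics of an SABD design."""

    alpha: float
    alpha_r: float
    alpha_t: float
    power: float
    ess_by_state: dict[str, float]
    pet_by_state: dict[str, float]
    max_ess: float
    min_pet: float
    max_sample_size: int

    def satisfies(self, h: SABDHypotheses) -> bool:
        return (
            self.alpha_r <= h.alpha_r
            and self.alpha_t <= h.alpha_t
            and self.power >= 1.0 - h.beta
        )


def _stage1_pass_neg(d: SABDDesign, p_r_neg: float, p_t_neg: float) -> float:
    """P(negative subgroup passes both stage-1 boundaries)."""
    return stage1_pass_prob(d.n1_neg, d.k_r1_neg, p_r_neg) * stage1_pass_prob(
        d.n1_neg, d.k_t1_neg, p_t_neg
    )


def _stage1_pass_pos(d: SABDDesign, p_r_pos: float, p_t_pos: float) -> float:
    """P(positive subgroup passes both stage-1 boundaries)."""
    return stage1_pass_prob(d.n1_pos, d.k_r1_pos, p_r_pos) * stage1_pass_prob(
        d.n1_pos, d.k_t1_pos, p_t_pos
    )


def p_s1(d: SABDDesign, p_r_neg: float, p_t_neg: float) -> float:
    """Go-decision in the unselected population (pathway S1).

    Requires the negative subgroup to pass stage 1 and its final
    boundaries on both endpoints; by the hierarchy assumption it depends
    on the negative-subgroup rates only.
    """
    return joint_pass_prob(
        d.n1_neg, d.n2_neg, d.k_r1_neg, d.k_r_neg, p_r_neg
    ) * joint_pass_prob(d.n1_neg, d.n2_neg, d.k_t1_neg, d.k_t_neg, p_t_neg)


def p_s2(d: SABDDesign, rs: RateState) -> float:
    """Positive-subgroup-only go after continuing unselected (pathway S2).

    The negative subgroup passes stage 1 but misses a final boundary,
    while the positive totals over ``n_pos`` patients pass theirs.  The
    negative-subgroup bracket is P(pass stage 1) - P(S1), exact under
    endpoint independence.
    """
    pos = binom.sf(d.k_r_pos - 1, d.n_pos, rs.p_r_pos) * binom.sf(
        d.k_t_pos - 1, d.n_pos, rs.p_t_pos
    )
    bracket = _stage1_pass_neg(d, rs.p_r_neg, rs.p_t_neg) - p_s1(
        d, rs.p_r_neg, rs.p_t_neg
    )
    return float(pos) * max(0.0, bracket)


def p_s3(d: SABDDesign, rs: RateState) -> float:
    """Positive-subgroup-only go via enrichment (pathway S3).

    The negative subgroup fails stage 1; the positive subgroup passes
    stage 1 and its enrichment totals over ``ne_pos`` patients pass the
    enrichment boundaries.
    """
    enrich = joint_pass_prob(
        d.n1_pos, d.n2e_pos, d.k_r1_pos, d.k_re_pos, rs.p_r_pos
    ) * joint_pass_prob(d.n1_pos, d.n2e_pos, d.k_t1_pos, d.k_te_pos, rs.p_t_pos)
    return enrich * (1.0 - _stage1_pass_neg(d, rs.p_r_neg, rs.p_t_neg))


def _p_any_go(d: SABDDesign, rs: RateState) -> float:
    return p_s1(d, rs.p_r_neg, rs.p_t_neg) + p_s2(d, rs) + p_s3(d, rs)


def sabd_error_rates(
    d: SABDDesign, h: SABDHypotheses
) -> tuple[float, float, float]:
    """Attained (alpha, alpha_R, alpha_T): any-go probability at the nulls."""
    return (
        _p_any_go(d, h.rate_state("H00")),
        _p_any_go(d, h.rate_state("H01")),
        _p_any_go(d, h.rate_state("H10")),
    )


def sabd_power(d: SABDDesign, h: SABDHypotheses) -> float:
    """min of unselected-population power and positive-subgroup-only power."""
    unselected = p_s1(d, h.p_r1_neg, h.p_t1_neg)
    mixed = RateState(h.p_r0, h.p_t0, h.p_r1_pos, h.p_t1_pos)
    subgroup_only = p_s2(d, mixed) + p_s3(d, mixed)
    return min(unselected, subgroup_only)


def sabd_ess(d: SABDDesign, rs: RateState) -> float:
    """Expected sample size under a rate state.

    ``N1- + N1+`` always accrue; ``N2- + N2+`` more when the negative
    subgroup passes stage 1; ``N2e+`` more when it fails but the positive
    subgroup passes (enrichment).
    """
    s1_neg = _stage1_pass_neg(d, rs.p_r_neg, rs.p_t_neg)
    s1_pos = _stage1_pass_pos(d, rs.p_r_pos, rs.p_t_pos)
    return (
        d.n1_neg
        + d.n1_pos
        + (d.n2_neg + d.n2_pos) * s1_neg
        + d.n2e_pos * s1_pos * (1.0 - s1_neg)
    )


def sabd_pet(d: SABDDesign, rs: RateState) -> float:
    """Probability of early termination: both subgroups fail stage 1."""
    fail_neg = 1.0 - _stage1_pass_neg(d, rs.p_r_neg, rs.p_t_neg)
    fail_pos = 1.0 - _stage1_pass_pos(d, rs.p_r_pos, rs.p_t_pos)
    return fail_neg * fail_pos


def sabd_operating_characteristics(
    d: SABDDesign, h: SABDHypotheses
) -> OperatingCharacteristics:
    """Assemble the full exact operating characteristics of a design.

    ESS and PET are evaluated at the four corner states with the
    subgroup-specific acceptable rates; max-ESS and min-PET are taken
    over the mixed states H01/H10, the convention used to rank designs.
    """
    alpha, alpha_r, alpha_t = sabd_error_rates(d, h)
    ess = {s: sabd_ess(d, h.rate_state(s)) for s in _STATES}
    pet = {s: sabd_pet(d, h.rate_state(s)) for s in _STATES}
    return OperatingCharacteristics(
        alpha=alpha,
        alpha_r=alpha_r,
        alpha_t=alpha_t,
        power=sabd_power(d, h),
        ess_by_state=ess,
        pet_by_state=pet,
        max_ess=max(ess["H01"], ess["H10"]),
        min_pet=min(pet["H01"], pet["H10"]),
        max_sample_size=d.max_sample_size,
    )
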