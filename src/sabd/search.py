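"""Optimal SABD design construction via dimension reduction.

A full SABD design has 15 parameters and a naive joint enumeration is
intractable.  The search implemented here fixes 9 of them from two inner
Bryant & Day searches run at halved type I error rates (a multiplicity
adjustment, since the stratified trial can reject in either the
unselected population or the positive subgroup alone):

* the whole negative-subgroup design
  ``(N1-, N-, k_R1-, k_T1-, k_R-, k_T-)`` from the BD design for the
  negative-subgroup hypotheses at ``(alpha_R/2, alpha_T/2, beta)``, and
* the positive-subgroup stage-1 triple ``(N1+, k_R1+, k_T1+)`` from the
  BD design for the positive-subgroup hypotheses at the same rates.

The remaining 6 free parameters — the unselected-path positive total and
final boundaries ``(N+, k_R+, k_T+)`` and the enrichment total and
boundaries ``(Ne+, k_Re+, k_Te+)`` — are enumerated, with both totals
bounded by ``cap_multiplier * N-`` (default 2).  The objective,
``max{ESS(H01), ESS(H10)}``, depends on the free parameters only through
``N+`` and ``Ne+``, so candidate size pairs are visited in increasing
objective order and the first pair admitting constraint-satisfying
boundaries wins; the attained error rates of every candidate boundary
set are evaluated through the exact formulas of :mod:`sabd.design`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .bryant_day import (
    BDDesign,
    BDHypotheses,
    InfeasibleDesignError,
    bd_optimal_search,
)
from .core import joint_pass_table, stage1_pass_prob
from .design import (
    OperatingCharacteristics,
    RateState,
    SABDDesign,
    SABDHypotheses,
    sabd_operating_characteristics,
)

__all__ = [
    "SearchConfig",
    "SABDSearchResult",
    "derive_fixed_parameters",
    "sabd_optimal_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Options for the reduced SABD search.

    ``cap_multiplier`` bounds each positive-subgroup total (``N+`` and
    ``Ne+``) at ``cap_multiplier * N-``; ``bd_n_max`` is forwarded to the
    inner BD searches; ``allow_no_second_stage_pos`` admits ``N+ = N1+``
    (no second-stage positive accrual on the unselected path), which is
    excluded by default.
    """

    hypotheses: SABDHypotheses
    cap_multiplier: float = 2.0
    bd_n_max: int | None = None
    allow_no_second_stage_pos: bool = False

    def __post_init__(self) -> None:
        if self.cap_multiplier < 1.0:
            raise ValueError("cap_multiplier must be >= 1")


@dataclass(frozen=True)
class SABDSearchResult:
    design: SABDDesign
    oc: OperatingCharacteristics
    fixed_negative: BDDesign
    n_pairs_scanned: int


def derive_fixed_parameters(
    h: SABDHypotheses, bd_n_max: int | None = None
) -> tuple[BDDesign, tuple[int, int, int]]:
    """Fix 9 of the 15 parameters from two BD searches at halved alphas.

    Returns the full negative-subgroup BD design and the positive
    stage-1 triple ``(N1+, k_R1+, k_T1+)``.
    """
    half = {"alpha_r": h.alpha_r / 2.0, "alpha_t": h.alpha_t / 2.0}
    try:
        neg = bd_optimal_search(
            BDHypotheses(
                h.p_r0, h.p_r1_neg, h.p_t0, h.p_t1_neg, beta=h.beta, **half
            ),
            n_max=bd_n_max,
        ).design
    except InfeasibleDesignError as e:
        raise InfeasibleDesignError(
            f"negative-subgroup BD search infeasible: {e}"
        ) from e
    try:
        pos = bd_optimal_search(
            BDHypotheses(
                h.p_r0, h.p_r1_pos, h.p_t0, h.p_t1_pos, beta=h.beta, **half
            ),
            n_max=bd_n_max,
        ).design
    except InfeasibleDesignError as e:
        raise InfeasibleDesignError(
            f"positive-subgroup BD search infeasible: {e}"
        ) from e
    return neg, (pos.n1, pos.k_r1, pos.k_t1)


def _lex_first_true(mask: np.ndarray) -> tuple[int, int] | None:
    if not mask.any():
        return None
    i, j = np.argwhere(mask)[0]
    return int(i), int(j)


def sabd_optimal_search(cfg: SearchConfig) -> SABDSearchResult:
    """Minimise max-ESS over the 6 free parameters under the constraints.

    The three constraints are ``alpha_R <= alpha_r``, ``alpha_T <=
    alpha_t`` and ``power >= 1 - beta``, each assembled from the exact
    pathway probabilities.  Because P(S1) and all stage-1 probabilities
    are fixed by the 9 derived parameters, each constraint splits into a
    fixed offset plus a term linear in the positive-subgroup pass
    probabilities, which are pre-tabulated per candidate ``(N+, Ne+)``.

    Ties in max-ESS break to smaller ``N+``, then smaller ``Ne+``, then
    the lexicographically smallest ``(k_R+, k_T+, k_Re+, k_Te+)``.
    """
    h = cfg.hypotheses
    neg, (n1p, kr1p, kt1p) = derive_fixed_parameters(h, cfg.bd_n_max)
    cap = int(np.floor(cfg.cap_multiplier * neg.n))
    n_pos_min = n1p if cfg.allow_no_second_stage_pos else n1p + 1
    if cap < max(n_pos_min, n1p + 1):
        raise InfeasibleDesignError(
            f"cap {cap} leaves no room for positive-subgroup totals above "
            f"N1+ = {n1p}; increase cap_multiplier"
        )

    # Per-state constants of the search (negative subgroup + stage 1).
    def neg_constants(rs: RateState) -> tuple[float, float, float]:
        s1n = stage1_pass_prob(neg.n1, neg.k_r1, rs.p_r_neg) * stage1_pass_prob(
            neg.n1, neg.k_t1, rs.p_t_neg
        )
        ps1 = _p_s1_neg(neg, rs.p_r_neg, rs.p_t_neg)
        return ps1, s1n - ps1, 1.0 - s1n  # P(S1), bracket B, enrich gate C

    def pos_stage1(rs: RateState) -> float:
        return stage1_pass_prob(n1p, kr1p, rs.p_r_pos) * stage1_pass_prob(
            n1p, kt1p, rs.p_t_pos
        )

    st01 = h.rate_state("H01")
    st10 = h.rate_state("H10")
    mixed = RateState(h.p_r0, h.p_t0, h.p_r1_pos, h.p_t1_pos)
    ps1_01, b01, c01 = neg_constants(st01)
    ps1_10, b10, c10 = neg_constants(st10)
    _, bm, cm = neg_constants(mixed)
    ar_slack = h.alpha_r - ps1_01
    at_slack = h.alpha_t - ps1_10
    pow_target = 1.0 - h.beta
    if ar_slack < 0 or at_slack < 0:
        raise InfeasibleDesignError(
            "the fixed negative-subgroup design already exhausts the type I "
            "error budget through pathway S1; increase alpha_r/alpha_t"
        )
    # Power through the unselected pathway is fixed by the negative design.
    p_s1_fixed = _p_s1_neg(neg, h.p_r1_neg, h.p_t1_neg)
    if p_s1_fixed < pow_target:
        raise InfeasibleDesignError(
            "fixed negative-subgroup design has unselected-population "
            f"power {p_s1_fixed:.3f} < {pow_target}; raise bd_n_max"
        )

    # ESS(state) = A + c1 * (N+ - N1+) + c2 * (Ne+ - N1+).
    def ess_coeffs(rs, s1n_b):
        a = neg.n1 + n1p + neg.n2 * s1n_b
        return a, s1n_b, pos_stage1(rs) * (1.0 - s1n_b)

    s1n01 = ps1_01 + b01 + 0.0  # = stage-1 pass prob at state 01
    s1n10 = ps1_10 + b10
    a01, c1_01, c2_01 = ess_coeffs(st01, s1n01)
    a10, c1_10, c2_10 = ess_coeffs(st10, s1n10)

    n_pos_vals = np.arange(n_pos_min, cap + 1)
    ne_pos_vals = np.arange(n1p + 1, cap + 1)
    pairs = [
        (
            max(
                a01 + c1_01 * (np_ - n1p) + c2_01 * (ne - n1p),
                a10 + c1_10 * (np_ - n1p) + c2_10 * (ne - n1p),
            ),
            int(np_),
            int(ne),
        )
        for np_ in n_pos_vals
        for ne in ne_pos_vals
    ]
    pairs.sort(key=lambda t: (round(t[0], 9), t[1], t[2]))

    # Single-stage tails for the unselected path, cached per N+.
    tails: dict[int, tuple[np.ndarray, ...]] = {}

    def pos_tails(n_pos: int):
        if n_pos not in tails:
            kr = np.arange(kr1p, n_pos + 1)
            kt = np.arange(kt1p, n_pos + 1)
            tails[n_pos] = (
                binom.sf(kr - 1, n_pos, h.p_r0),
                binom.sf(kr - 1, n_pos, h.p_r1_pos),
                binom.sf(kt - 1, n_pos, h.p_t0),
                binom.sf(kt - 1, n_pos, h.p_t1_pos),
            )
        return tails[n_pos]

    enrich: dict[int, tuple[np.ndarray, ...]] = {}

    def enrich_tails(ne_pos: int):
        if ne_pos not in enrich:
            sl_r = slice(kr1p, ne_pos + 1)
            sl_t = slice(kt1p, ne_pos + 1)
            enrich[ne_pos] = (
                joint_pass_table(n1p, ne_pos - n1p, h.p_r0)[kr1p][sl_r],
                joint_pass_table(n1p, ne_pos - n1p, h.p_r1_pos)[kr1p][sl_r],
                joint_pass_table(n1p, ne_pos - n1p, h.p_t0)[kt1p][sl_t],
                joint_pass_table(n1p, ne_pos - n1p, h.p_t1_pos)[kt1p][sl_t],
            )
        return enrich[ne_pos]

    n_scanned = 0
    for max_ess, n_pos, ne_pos in pairs:
        n_scanned += 1
        fr0, fr1, ft0, ft1 = pos_tails(n_pos)
        gr0, gr1, gt0, gt1 = enrich_tails(ne_pos)
        y1 = np.outer(gr0, gt1)  # enrichment pass at H01 rates
        y2 = np.outer(gr1, gt0)
        y3 = np.outer(gr1, gt1)
        # Quick necessary conditions before boundary enumeration.
        best_pow = bm * fr1[0] * ft1[0] + cm * y3[0, 0]
        if best_pow < pow_target - 1e-12:
            continue
        # Enumerate unselected-path boundary pairs in lexicographic order,
        # prefiltered by the three per-term bounds.
        x1 = np.outer(fr0, ft1)
        x2 = np.outer(fr1, ft0)
        x3 = np.outer(fr1, ft1)
        u_ok = (
            (b01 * x1 <= ar_slack + 1e-15)
            & (b10 * x2 <= at_slack + 1e-15)
            & (bm * x3 + cm * y3[0, 0] >= pow_target - 1e-15)
        )
        if not u_ok.any():
            continue
        found = None
        for ui, uj in np.argwhere(u_ok):
            v_ok = (
                (b01 * x1[ui, uj] + c01 * y1 <= ar_slack + 1e-15)
                & (b10 * x2[ui, uj] + c10 * y2 <= at_slack + 1e-15)
                & (bm * x3[ui, uj] + cm * y3 >= pow_target - 1e-15)
            )
            hit = _lex_first_true(v_ok)
            if hit is not None:
                found = (int(ui), int(uj), *hit)
                break
        if found is None:
            continue
        ui, uj, vi, vj = found
        d = SABDDesign(
            n1_neg=neg.n1,
            n_neg=neg.n,
            k_r1_neg=neg.k_r1,
            k_t1_neg=neg.k_t1,
            k_r_neg=neg.k_r,
            k_t_neg=neg.k_t,
            n1_pos=n1p,
            n_pos=n_pos,
            ne_pos=ne_pos,
            k_r1_pos=kr1p,
            k_t1_pos=kt1p,
            k_r_pos=kr1p + ui,
            k_t_pos=kt1p + uj,
            k_re_pos=kr1p + vi,
            k_te_pos=kt1p + vj,
        )
        oc = sabd_operating_characteristics(d, h)
        # Exact re-validation; the linear decomposition must agree.
        if not oc.satisfies(h):
            continue
        assert abs(oc.max_ess - max_ess) < 1e-6
        return SABDSearchResult(
            design=d, oc=oc, fixed_negative=neg, n_pairs_scanned=n_scanned
        )
    raise InfeasibleDesignError(
        f"no feasible SABD design with positive-subgroup totals <= {cap}; "
        "the binding constraint is the positive-subgroup power "
        "P(S2) + P(S3) >= 1 - beta; consider increasing cap_multiplier"
    )


def _p_s1_neg(neg: BDDesign, p_r: float, p_t: float) -> float:
    """P(S1) computed directly from the fixed negative BD design."""
    from .core import joint_pass_prob

    return joint_pass_prob(
        neg.n1, neg.n2, neg.k_r1, neg.k_r, p_r
    ) * joint_pass_prob(neg.n1, neg.n2, neg.k_t1, neg.k_t, p_t)
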