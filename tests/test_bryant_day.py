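"""Bryant & Day design: operating characteristics and optimal search."""

import numpy as np
import pytest

from sabd import (
    BDDesign,
    BDHypotheses,
    InfeasibleDesignError,
    bd_ess,
    bd_operating_characteristics,
    bd_optimal_search,
    bd_pet,
    bd_reject_prob,
    joint_pass_prob,
    single_stage_min_n,
)

CASE1_NEG = BDDesign(n1=10, n=35, k_r1=8, k_t1=8, k_r=29, k_t=29)
CASE1_H = BDHypotheses(0.70, 0.90, 0.70, 0.90, alpha_r=0.05, alpha_t=0.05, beta=0.20)


def test_reject_prob_trivial_and_monotone():
    d0 = BDDesign(n1=2, n=5, k_r1=0, k_t1=0, k_r=0, k_t=0)
    assert bd_reject_prob(d0, 0.1, 0.9) == pytest.approx(1.0)
    d = BDDesign(n1=3, n=7, k_r1=1, k_t1=2, k_r=4, k_t=5)
    ps = np.linspace(0.05, 0.95, 10)
    r_in_pr = [bd_reject_prob(d, p, 0.6) for p in ps]
    r_in_pt = [bd_reject_prob(d, 0.6, p) for p in ps]
    assert np.all(np.diff(r_in_pr) >= -1e-12)
    assert np.all(np.diff(r_in_pt) >= -1e-12)


def test_pet_and_ess_hand_values():
    d = BDDesign(n1=10, n=35, k_r1=8, k_t1=8, k_r=29, k_t=29)
    # 1 - P(X_R1 >= 8 | 0.7) * P(X_T1 >= 8 | 0.9) = 1 - 0.38278 * 0.92981
    assert bd_pet(d, 0.7, 0.9) == pytest.approx(0.64409, abs=1e-4)
    assert bd_ess(d, 0.7, 0.9) == pytest.approx(18.898, abs=0.01)
    assert bd_ess(d, 0.0, 0.0) == pytest.approx(d.n1)  # always stops
    d_open = BDDesign(n1=10, n=35, k_r1=0, k_t1=0, k_r=29, k_t=29)
    assert bd_pet(d_open, 0.3, 0.3) == 0.0
    assert bd_ess(d_open, 0.3, 0.3) == pytest.approx(d_open.n)


def test_case1_negative_design_meets_constraints():
    oc = bd_operating_characteristics(CASE1_NEG, CASE1_H)
    assert oc.alpha_r <= 0.05
    assert oc.alpha_t <= 0.05
    assert oc.power >= 0.80
    assert oc.alpha <= min(oc.alpha_r, oc.alpha_t)
    # symmetric hypotheses and boundaries: the two error rates coincide
    assert oc.alpha_r == pytest.approx(oc.alpha_t, abs=1e-14)
    assert oc.max_ess == pytest.approx(18.898, abs=0.01)


def test_simon_reduction_single_endpoint():
    """With the toxicity endpoint disabled the design is a response-only
    two-stage design: the rejection probability reduces to the response
    factor alone."""
    d = BDDesign(n1=7, n=16, k_r1=3, k_t1=0, k_r=9, k_t=0)
    for p in (0.2, 0.5, 0.8):
        expected = joint_pass_prob(7, 9, 3, 9, p)
        assert bd_reject_prob(d, p, 1.0) == pytest.approx(expected, abs=1e-12)


def test_search_matches_exhaustive_small_grid():
    """Brute force over every design with N <= 6 (wide rate separation so
    the space contains feasible designs) must agree with the pruned search."""
    h = BDHypotheses(0.05, 0.80, 0.05, 0.80, alpha_r=0.10, alpha_t=0.10, beta=0.20)
    best = None
    for n in range(2, 7):
        for n1 in range(1, n):
            for k_r1 in range(0, n1 + 1):
                for k_r in range(k_r1, n + 1):
                    for k_t1 in range(0, n1 + 1):
                        for k_t in range(k_t1, n + 1):
                            d = BDDesign(n1, n, k_r1, k_t1, k_r, k_t)
                            oc = bd_operating_characteristics(d, h)
                            if not oc.satisfies(h):
                                continue
                            if best is None or oc.max_ess < best[0] - 1e-9:
                                best = (oc.max_ess, d)
    res = bd_optimal_search(h, n_max=6)
    assert best is not None
    assert res.oc.max_ess == pytest.approx(best[0], abs=1e-9)


def test_search_reproduces_reference_design():
    res = bd_optimal_search(CASE1_H)
    d = res.design
    assert (d.n1, d.n, d.k_r1, d.k_t1, d.k_r, d.k_t) == (10, 35, 8, 8, 29, 29)
    assert res.oc.satisfies(CASE1_H)


def test_minimax_criterion_minimises_n():
    h = BDHypotheses(0.05, 0.80, 0.05, 0.80, alpha_r=0.10, alpha_t=0.10, beta=0.20)
    opt = bd_optimal_search(h, n_max=10, criterion="optimal")
    mm = bd_optimal_search(h, n_max=10, criterion="minimax")
    assert mm.design.n <= opt.design.n
    assert mm.oc.satisfies(h)


def test_infeasible_search_raises_with_context():
    h = BDHypotheses(0.45, 0.55, 0.45, 0.55, alpha_r=0.05, alpha_t=0.05, beta=0.10)
    with pytest.raises(InfeasibleDesignError, match="n_max"):
        bd_optimal_search(h, n_max=8)


def test_single_stage_min_n_is_minimal():
    h = BDHypotheses(0.05, 0.80, 0.05, 0.80, alpha_r=0.10, alpha_t=0.10, beta=0.20)
    n = single_stage_min_n(h)
    assert n >= 1
    # one patient fewer must not admit a single-stage design
    if n > 1:
        from scipy.stats import binom

        m = n - 1
        ks = np.arange(0, m + 2)
        fr0 = binom.sf(ks - 1, m, h.p_r0)
        fr1 = binom.sf(ks - 1, m, h.p_r1)
        ok = (
            (np.outer(fr0, fr1) <= h.alpha_r)
            & (np.outer(fr1, fr0) <= h.alpha_t)
            & (np.outer(fr1, fr1) >= 1 - h.beta)
        )
        assert not ok.any()


def test_hypotheses_validation():
    with pytest.raises(ValueError):
        BDHypotheses(0.9, 0.7, 0.7, 0.9, 0.05, 0.05, 0.2)
    with pytest.raises(ValueError):
        BDHypotheses(0.7, 0.9, 0.7, 0.9, 1.5, 0.05, 0.2)
    with pytest.raises(ValueError):
        BDDesign(n1=5, n=5, k_r1=1, k_t1=1, k_r=2, k_t=2)
    with pytest.raises(ValueError):
        BDDesign(n1=2, n=5, k_r1=3, k_t1=1, k_r=2, k_t=2)
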