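"""Exact SABD operating characteristics against hand values and invariants."""

import numpy as np
import pytest

from sabd import (
    RateState,
    SABDDesign,
    SABDHypotheses,
    p_s1,
    p_s2,
    p_s3,
    sabd_error_rates,
    sabd_ess,
    sabd_operating_characteristics,
    sabd_pet,
    sabd_power,
)

from conftest import TINY_RATES, TINY_SABD


def test_pathway_trivial_cases(cases):
    d = cases[1].design
    # negative boundaries 0: S1 certain, S2 and S3 impossible
    open_neg = SABDDesign(
        n1_neg=2, n_neg=4, k_r1_neg=0, k_t1_neg=0, k_r_neg=0, k_t_neg=0,
        n1_pos=2, n_pos=3, ne_pos=4, k_r1_pos=1, k_t1_pos=1,
        k_r_pos=2, k_t_pos=2, k_re_pos=2, k_te_pos=2,
    )
    rs = RateState(0.4, 0.6, 0.5, 0.7)
    assert p_s1(open_neg, rs.p_r_neg, rs.p_t_neg) == pytest.approx(1.0)
    assert p_s2(open_neg, rs) == pytest.approx(0.0)
    assert p_s3(open_neg, rs) == pytest.approx(0.0)
    # stage-1 boundary above N1-: S1 impossible
    closed = SABDDesign(
        n1_neg=2, n_neg=4, k_r1_neg=3, k_t1_neg=0, k_r_neg=3, k_t_neg=0,
        n1_pos=2, n_pos=3, ne_pos=4, k_r1_pos=1, k_t1_pos=1,
        k_r_pos=2, k_t_pos=2, k_re_pos=2, k_te_pos=2,
    )
    assert p_s1(closed, 0.9, 0.9) == 0.0
    # real design sanity: all pathways in (0, 1) at mixed rates
    rs_mix = RateState(0.7, 0.7, 0.9, 0.9)
    for v in (p_s2(d, rs_mix), p_s3(d, rs_mix)):
        assert 0.0 < v < 1.0


def test_case1_hand_verified_identities(cases):
    d, h = cases[1].design, cases[1].hypotheses
    rs01 = h.rate_state("H01")
    assert sabd_ess(d, rs01) == pytest.approx(42.459, abs=5e-3)
    assert sabd_pet(d, rs01) == pytest.approx(0.41485, abs=5e-5)
    # unselected-population go under acceptable rates: squared joint pass
    assert p_s1(d, 0.9, 0.9) == pytest.approx(0.8945827797410881**2, abs=1e-10)


def test_error_rates_and_power_printed_values(cases):
    expected = {
        1: (0.094, 0.094, 0.800),
        2: (0.094, 0.093, 0.800),
        3: (0.087, 0.096, 0.800),
    }
    for c, (ar, at, pw) in expected.items():
        d, h = cases[c].design, cases[c].hypotheses
        alpha, alpha_r, alpha_t = sabd_error_rates(d, h)
        assert round(alpha_r, 3) == ar
        assert round(alpha_t, 3) == at
        assert round(sabd_power(d, h), 3) == pw
        assert alpha <= min(alpha_r, alpha_t)


def test_pathways_sum_below_one(cases):
    d = cases[2].design
    for pr_n in (0.2, 0.5, 0.8):
        for pt_n in (0.3, 0.9):
            rs = RateState(pr_n, pt_n, max(pr_n, 0.6), max(pt_n, 0.6))
            total = p_s1(d, rs.p_r_neg, rs.p_t_neg) + p_s2(d, rs) + p_s3(d, rs)
            assert 0.0 <= total <= 1.0 + 1e-12


def test_pathway_monotonicity(cases):
    d = cases[1].design
    grid = np.linspace(0.1, 0.95, 12)
    s1_vals = [p_s1(d, p, 0.8) for p in grid]
    assert np.all(np.diff(s1_vals) >= -1e-12)
    # S3 falls as the negative subgroup improves (fixed positive rates)
    s3_vals = [p_s3(d, RateState(p, 0.8, 0.9, 0.9)) for p in grid]
    assert np.all(np.diff(s3_vals) <= 1e-12)


def test_degenerate_always_go_design_has_zero_subgroup_power():
    h = SABDHypotheses(0.3, 0.3, 0.6, 0.6, 0.6, 0.6, 0.1, 0.1, 0.2)
    d = TINY_SABD[4]  # all boundaries 0
    # S2 and S3 are impossible, so the min{} power definition collapses to 0
    assert sabd_power(d, h) == pytest.approx(0.0)


def test_operating_characteristics_assembly(cases):
    expected = {
        1: (42.5, 0.415, 67),
        2: (25.7, 0.554, 39),
        3: (32.1, 0.580, 45),
    }
    for c, (max_ess, min_pet, n_max) in expected.items():
        oc = sabd_operating_characteristics(cases[c].design, cases[c].hypotheses)
        assert round(oc.max_ess, 1) == max_ess
        assert round(oc.min_pet, 3) == min_pet
        assert oc.max_sample_size == n_max
        assert oc.satisfies(cases[c].hypotheses)
        lo = cases[c].design.n1_neg + cases[c].design.n1_pos
        hi = max(
            oc.max_sample_size,
            cases[c].design.n1_neg + cases[c].design.ne_pos,
        )
        assert all(lo <= e <= hi for e in oc.ess_by_state.values())


def test_symmetric_case_gives_equal_error_rates(cases):
    _, alpha_r, alpha_t = sabd_error_rates(cases[1].design, cases[1].hypotheses)
    assert alpha_r == pytest.approx(alpha_t, abs=1e-14)


def test_case3_subgroup_specific_acceptable_rates(cases):
    """H01 must use the per-subgroup acceptable non-toxicity rates."""
    h = cases[3].hypotheses
    rs = h.rate_state("H01")
    assert (rs.p_t_neg, rs.p_t_pos) == (0.80, 0.90)
    assert rs.p_r_neg == rs.p_r_pos == h.p_r0


def test_hypotheses_validation():
    with pytest.raises(ValueError):
        SABDHypotheses(0.5, 0.5, 0.4, 0.6, 0.6, 0.6, 0.1, 0.1, 0.2)
    with pytest.raises(ValueError):  # hierarchy violated: neg > pos
        SABDHypotheses(0.3, 0.5, 0.7, 0.6, 0.8, 0.7, 0.1, 0.1, 0.2)
    with pytest.raises(ValueError):
        SABDDesign(
            n1_neg=5, n_neg=5, k_r1_neg=1, k_t1_neg=1, k_r_neg=2, k_t_neg=2,
            n1_pos=2, n_pos=3, ne_pos=4, k_r1_pos=1, k_t1_pos=1,
            k_r_pos=2, k_t_pos=2, k_re_pos=2, k_te_pos=2,
        )


def test_bracket_identity_against_union_expansion(cases):
    """P(S2)'s bracket equals P(stage-1 pass) - P(S1) for every tiny design;
    the enumeration oracle already checks this, here we check it on the
    real case-study scale via the probability bounds."""
    for c in (1, 2, 3):
        d, h = cases[c].design, cases[c].hypotheses
        for rs in TINY_RATES:
            s2 = p_s2(d, rs)
            assert 0.0 <= s2 <= 1.0
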