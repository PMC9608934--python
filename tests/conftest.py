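import pytest

from sabd import BDDesign, RateState, SABDDesign, load_case


@pytest.fixture(scope="session")
def cases():
    """The three shipped case studies, loaded once."""
    return {c: load_case(c) for c in (1, 2, 3)}


# Tiny designs for which the enumeration oracle is exact and fast.
TINY_BD = [
    BDDesign(n1=2, n=3, k_r1=1, k_t1=1, k_r=1, k_t=1),
    BDDesign(n1=1, n=3, k_r1=1, k_t1=0, k_r=2, k_t=1),
    BDDesign(n1=2, n=5, k_r1=1, k_t1=2, k_r=3, k_t=3),
    BDDesign(n1=3, n=5, k_r1=0, k_t1=2, k_r=2, k_t=4),
    BDDesign(n1=2, n=4, k_r1=3, k_t1=1, k_r=4, k_t=2),  # k_r1 > n1: stops always
]

TINY_SABD = [
    SABDDesign(
        n1_neg=2, n_neg=3, k_r1_neg=1, k_t1_neg=1, k_r_neg=1, k_t_neg=1,
        n1_pos=2, n_pos=3, ne_pos=3, k_r1_pos=1, k_t1_pos=1,
        k_r_pos=1, k_t_pos=1, k_re_pos=1, k_te_pos=1,
    ),
    SABDDesign(
        n1_neg=2, n_neg=4, k_r1_neg=1, k_t1_neg=2, k_r_neg=3, k_t_neg=3,
        n1_pos=2, n_pos=3, ne_pos=4, k_r1_pos=1, k_t1_pos=1,
        k_r_pos=2, k_t_pos=2, k_re_pos=2, k_te_pos=3,
    ),
    SABDDesign(
        n1_neg=3, n_neg=5, k_r1_neg=2, k_t1_neg=1, k_r_neg=4, k_t_neg=2,
        n1_pos=2, n_pos=4, ne_pos=5, k_r1_pos=2, k_t1_pos=1,
        k_r_pos=3, k_t_pos=2, k_re_pos=4, k_te_pos=2,
    ),
    SABDDesign(  # degenerate: negative never passes stage 1, enrichment only
        n1_neg=2, n_neg=3, k_r1_neg=3, k_t1_neg=1, k_r_neg=3, k_t_neg=2,
        n1_pos=2, n_pos=3, ne_pos=4, k_r1_pos=1, k_t1_pos=1,
        k_r_pos=2, k_t_pos=2, k_re_pos=3, k_te_pos=2,
    ),
    SABDDesign(  # all boundaries 0: always continues unselected, S1 certain
        n1_neg=1, n_neg=2, k_r1_neg=0, k_t1_neg=0, k_r_neg=0, k_t_neg=0,
        n1_pos=1, n_pos=2, ne_pos=2, k_r1_pos=0, k_t1_pos=0,
        k_r_pos=0, k_t_pos=0, k_re_pos=0, k_te_pos=0,
    ),
]

TINY_RATES = [
    RateState(0.5, 0.5, 0.5, 0.5),
    RateState(0.3, 0.8, 0.6, 0.9),
    RateState(0.7, 0.2, 0.9, 0.4),
]
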