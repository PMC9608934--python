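"""Brute-force enumeration oracle for tiny designs.

Enumerates every possible outcome vector (all stage-1 and stage-2
response/non-toxicity counts), applies the trial decision algorithm
literally to each, and accumulates exact event probabilities.  This is
the reference the closed-form modules are tested against; it shares no
code path with them beyond the binomial pmf.

Restricted to small sample sizes (every stage size <= 12) — the state
space grows as the product of all stage sizes.
"""

from __future__ import annotations

from itertools import product

from scipy.stats import binom

from .bryant_day import BDDesign
from .design import RateState, SABDDesign

__all__ = ["enumerate_bd_oracle", "enumerate_sabd_oracle", "ORACLE_MAX_N"]

ORACLE_MAX_N = 12


def _guard(sizes: dict[str, int]) -> None:
    for name, n in sizes.items():
        if n > ORACLE_MAX_N:
            raise ValueError(
                f"enumeration oracle refuses {name}={n} > {ORACLE_MAX_N}: "
                "the outcome space is enumerated exhaustively and is only "
                "tractable for tiny designs"
            )


def _pmf(n: int, p: float) -> list[float]:
    return [float(binom.pmf(x, n, p)) for x in range(n + 1)]


def enumerate_bd_oracle(d: BDDesign, p_r: float, p_t: float) -> dict[str, float]:
    """Exact BD event probabilities by full outcome enumeration.

    Returns ``early_stop`` (interim futility stop), ``reject`` (go) and
    ``no_go_final`` (continued but failed the final bar), plus the
    expected sample size ``ess``.  The three terminal probabilities sum
    to 1.
    """
    _guard({"n1": d.n1, "n2": d.n2})
    pr1, pt1 = _pmf(d.n1, p_r), _pmf(d.n1, p_t)
    pr2, pt2 = _pmf(d.n2, p_r), _pmf(d.n2, p_t)
    out = {"early_stop": 0.0, "reject": 0.0, "no_go_final": 0.0, "ess": 0.0}
    for xr1, xt1 in product(range(d.n1 + 1), repeat=2):
        w1 = pr1[xr1] * pt1[xt1]
        if xr1 < d.k_r1 or xt1 < d.k_t1:
            out["early_stop"] += w1
            out["ess"] += w1 * d.n1
            continue
        out["ess"] += w1 * d.n
        for xr2, xt2 in product(range(d.n2 + 1), repeat=2):
            w = w1 * pr2[xr2] * pt2[xt2]
            if xr1 + xr2 >= d.k_r and xt1 + xt2 >= d.k_t:
                out["reject"] += w
            else:
                out["no_go_final"] += w
    return out


def enumerate_sabd_oracle(d: SABDDesign, rs: RateState) -> dict[str, float]:
    """Exact SABD event probabilities by full outcome enumeration.

    Walks the decision algorithm outcome by outcome: stage-1 counts in
    both subgroups decide between futility stop, unselected continuation
    and enrichment; the corresponding second-stage counts then decide
    between the go-pathways S1 (unselected population), S2 (positive
    subgroup after unselected accrual), S3 (positive subgroup after
    enrichment) and a no-go.  Returns the pathway probabilities, the
    branch probabilities and the expected sample size.
    """
    _guard(
        {
            "n1_neg": d.n1_neg,
            "n2_neg": d.n2_neg,
            "n1_pos": d.n1_pos,
            "n2_pos": d.n2_pos,
            "n2e_pos": d.n2e_pos,
        }
    )
    pr1n, pt1n = _pmf(d.n1_neg, rs.p_r_neg), _pmf(d.n1_neg, rs.p_t_neg)
    pr2n, pt2n = _pmf(d.n2_neg, rs.p_r_neg), _pmf(d.n2_neg, rs.p_t_neg)
    pr1p, pt1p = _pmf(d.n1_pos, rs.p_r_pos), _pmf(d.n1_pos, rs.p_t_pos)
    pr2p, pt2p = _pmf(d.n2_pos, rs.p_r_pos), _pmf(d.n2_pos, rs.p_t_pos)
    pr2e, pt2e = _pmf(d.n2e_pos, rs.p_r_pos), _pmf(d.n2e_pos, rs.p_t_pos)
    out = {
        "early_stop": 0.0,
        "continue_unselected": 0.0,
        "enrich": 0.0,
        "s1": 0.0,
        "s2": 0.0,
        "s3": 0.0,
        "no_go_final": 0.0,
        "ess": 0.0,
    }
    base_n = d.n1_neg + d.n1_pos
    for xr1n, xt1n in product(range(d.n1_neg + 1), repeat=2):
        w_neg = pr1n[xr1n] * pt1n[xt1n]
        neg_pass = xr1n >= d.k_r1_neg and xt1n >= d.k_t1_neg
        for xr1p, xt1p in product(range(d.n1_pos + 1), repeat=2):
            w1 = w_neg * pr1p[xr1p] * pt1p[xt1p]
            pos_pass = xr1p >= d.k_r1_pos and xt1p >= d.k_t1_pos
            if neg_pass:
                out["continue_unselected"] += w1
                out["ess"] += w1 * (base_n + d.n2_neg + d.n2_pos)
                for xr2n, xt2n in product(range(d.n2_neg + 1), repeat=2):
                    w2 = w1 * pr2n[xr2n] * pt2n[xt2n]
                    s1 = (
                        xr1n + xr2n >= d.k_r_neg
                        and xt1n + xt2n >= d.k_t_neg
                    )
                    for xr2p, xt2p in product(range(d.n2_pos + 1), repeat=2):
                        w = w2 * pr2p[xr2p] * pt2p[xt2p]
                        if s1:
                            out["s1"] += w
                        elif (
                            xr1p + xr2p >= d.k_r_pos
                            and xt1p + xt2p >= d.k_t_pos
                        ):
                            out["s2"] += w
                        else:
                            out["no_go_final"] += w
            elif pos_pass:
                out["enrich"] += w1
                out["ess"] += w1 * (base_n + d.n2e_pos)
                for xr2e, xt2e in product(range(d.n2e_pos + 1), repeat=2):
                    w = w1 * pr2e[xr2e] * pt2e[xt2e]
                    if (
                        xr1p + xr2e >= d.k_re_pos
                        and xt1p + xt2e >= d.k_te_pos
                    ):
                        out["s3"] += w
                    else:
                        out["no_go_final"] += w
            else:
                out["early_stop"] += w1
                out["ess"] += w1 * base_n
    return out
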