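"""Packaged case-study fixtures: hypotheses and published design parameters.

Three worked case studies ship with the package as YAML files.  Each
bundles an :class:`~sabd.design.SABDHypotheses` block and the full
15-parameter :class:`~sabd.design.SABDDesign` for that set of hypotheses
(type I error rates 10%, power 80%).  They are the standard inputs for
the examples, the simulation scenarios and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from ..design import SABDDesign, SABDHypotheses

__all__ = ["CaseStudy", "CASE_IDS", "load_case"]

CASE_IDS = (1, 2, 3)


@dataclass(frozen=True)
class CaseStudy:
    label: str
    hypotheses: SABDHypotheses
    design: SABDDesign


def load_case(case: int) -> CaseStudy:
    """Load one of the shipped case studies (1, 2 or 3)."""
    if case not in CASE_IDS:
        raise ValueError(f"unknown case {case!r}; choose one of {CASE_IDS}")
    ref = resources.files("sabd.fixtures").joinpath(f"case{case}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return CaseStudy(
        label=raw["label"],
        hypotheses=SABDHypotheses(**raw["hypotheses"]),
        design=SABDDesign(**raw["design"]),
    )
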