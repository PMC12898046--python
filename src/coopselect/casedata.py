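"""Objective vectors reported for the Wuhou District case study.

The underlying community-level instance (29 RMCs with subordinate PHCs, 28
communities, 726 discharged cardiovascular patients per year) is not public,
but the case study prints, for each of its 10 optimized solutions and for
three manually designed 10-hospital schemes (A: two distal regions, B: the
densest region, C: the central region), the number of selected hospitals and
the objective pair (cost for patients, cost for the hospital).  Those printed
vectors are usable as inputs: they provide a worked example for
non-dominated sorting — the 10 optimized rows are mutually non-dominated and
each manual scheme is dominated by at least one of them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CASE_SOLUTIONS",
    "MANUAL_SCHEMES",
    "case_objectives",
    "manual_objectives",
    "all_case_vectors",
]

# solution label -> (selected hospital count, cost for patients, cost for the hospital)
CASE_SOLUTIONS: dict[str, tuple[int, float, float]] = {
    "1": (7, 257_313.27, 1_194_297.59),
    "2": (9, 255_472.26, 1_194_765.01),
    "3": (11, 253_492.38, 1_195_964.90),
    "4": (13, 250_206.89, 1_198_833.75),
    "5": (13, 248_451.44, 1_204_843.01),
    "6": (14, 247_975.42, 1_212_564.85),
    "7": (15, 246_969.38, 1_220_250.66),
    "8": (15, 246_906.36, 1_228_940.93),
    "9": (18, 246_631.62, 1_247_665.54),
    "10": (16, 246_498.87, 1_248_898.04),
}

MANUAL_SCHEMES: dict[str, tuple[int, float, float]] = {
    "A": (10, 289_989.81, 1_358_774.19),
    "B": (10, 292_200.42, 1_370_623.31),
    "C": (10, 333_162.04, 1_627_151.88),
}


def case_objectives() -> np.ndarray:
    """(10, 2) objective vectors of the optimized solutions, in label order."""
    return np.array([[f1, f2] for _, f1, f2 in CASE_SOLUTIONS.values()])


def manual_objectives() -> np.ndarray:
    """(3, 2) objective vectors of manual schemes A, B, C."""
    return np.array([[f1, f2] for _, f1, f2 in MANUAL_SCHEMES.values()])


def all_case_vectors() -> tuple[list[str], np.ndarray]:
    """All 13 printed vectors with their labels, optimized rows first."""
    labels = list(CASE_SOLUTIONS) + list(MANUAL_SCHEMES)
    return labels, np.vstack([case_objectives(), manual_objectives()])
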