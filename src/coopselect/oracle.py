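"""Exact ground truth on small instances by exhaustive enumeration.

Every non-empty facility selection in {0, 1}^n is pushed through the same
plan construction the heuristic uses (proximity allocation, repair of
selected-but-unused facilities, minimal contracts, capacity fixed to induced
workload), and the mutually non-dominated set over distinct repaired
selections is returned.  A guard refuses instances whose 2^n enumeration
would be accidental (default 16 facilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import AllocationError, SelectionPlan, plan_from_selection
from .instance import ProblemInstance
from .nsga2 import nondominated_sort

__all__ = ["ExactFront", "enumerate_front"]


class EnumerationGuardError(ValueError):
    """The instance exceeds the exhaustive-enumeration guard."""


@dataclass(frozen=True)
class ExactFront:
    """The true Pareto front of a small instance.

    ``plans`` are mutually non-dominated and complete: no feasible selection
    maps to an objective vector dominating a member.  ``n_enumerated`` records
    the number of facilities whose 2^n selections were enumerated.
    """

    plans: tuple[SelectionPlan, ...]
    n_enumerated: int

    @property
    def objectives(self) -> np.ndarray:
        return np.array([p.objectives for p in self.plans], dtype=float)

    def __len__(self) -> int:
        return len(self.plans)

    def to_csv(self) -> str:
        lines = ["selection,f1,f2"]
        for p in self.plans:
            bits = "".join(str(int(v)) for v in p.x)
            lines.append(f"{bits},{p.f1!r},{p.f2!r}")
        return "\n".join(lines) + "\n"


def enumerate_front(instance: ProblemInstance, max_facilities: int = 16) -> ExactFront:
    """Exhaustively enumerate all selections and return the exact front.

    Selections are deduplicated by their repaired form (cosmetically distinct
    selections that repair to the same operating plan are counted once);
    capacity-infeasible selections are skipped.  Deterministic.
    """
    n = instance.n_facilities
    if n > max_facilities:
        raise EnumerationGuardError(
            f"instance has {n} facilities; enumeration guard is {max_facilities} "
            f"(2^{n} selections)"
        )
    plans: dict[tuple, SelectionPlan] = {}
    for code in range(1, 1 << n):
        selected = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        try:
            plan = plan_from_selection(instance, selected, repair_unused=True)
        except AllocationError:
            continue
        key = tuple(int(v) for v in plan.x)
        if key not in plans:
            plans[key] = plan
    if not plans:
        raise AllocationError("no feasible selection exists under the capacity caps")
    all_plans = list(plans.values())
    objs = np.array([p.objectives for p in all_plans])
    front_idx = nondominated_sort(objs)[0]
    front = tuple(all_plans[i] for i in sorted(front_idx))
    return ExactFront(plans=front, n_enumerated=n)
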