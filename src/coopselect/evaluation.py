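"""Plan construction and evaluation for the bi-objective selection model.

Given a binary facility selection, this module induces the demand-point
allocation by the proximity principle (each community goes to the nearest
selected facility, overflowing to the next-nearest only when an explicit
capacity cap saturates), derives the minimal RMC contract vector from the
hierarchy, evaluates both objectives and checks every model constraint.

Objectives (both minimized, in currency):

* patient cost  f1 = sum_k sum_{i,j} (F_k1 h_ijk1 + F_k2 h_ijk2) n_j p_jk z_ij
* hospital cost f2 = C1 sum_i y_i
                     + sum_k sum_{i,j} (F_k1 c_ijk1 + F_k2 c_ijk2) n_j p_jk z_ij
                     + sum_k sum_{i,j} C2 (F_k1 e_k1 + F_k2 e_k2) n_j p_jk z_ij

with the affine defaults h_ijk1 = h1_per_dist * d_ij, h_ijk2 = h2_base,
c_ijk1 = c1_base, c_ijk2 = c2_per_dist * d_ij (overridable per (i, j, k)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .instance import ProblemInstance

__all__ = [
    "AllocationError",
    "ConstraintViolationError",
    "Violation",
    "SelectionPlan",
    "ParetoSet",
    "cost_coefficients",
    "induce_allocation",
    "contracts_from_selection",
    "workload",
    "plan_from_selection",
    "evaluate_objectives",
    "check_constraints",
]

# constraint identifiers used in violation reports
UNIQUE_ASSIGNMENT = "unique_assignment"
ASSIGNMENT_REQUIRES_SELECTION = "assignment_requires_selection"
HIERARCHY_CONTRACT = "hierarchy_contract"
CAPACITY = "capacity"


class AllocationError(ValueError):
    """No feasible allocation exists (no facility selected, or caps too tight)."""


class ConstraintViolationError(ValueError):
    """A plan violates the structural constraints required for evaluation."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations))


@dataclass(frozen=True)
class Violation:
    """One itemized constraint violation: which constraint, at which indices."""

    constraint: str
    indices: tuple

    def __str__(self) -> str:
        return f"{self.constraint} at {self.indices}"


@dataclass(frozen=True)
class SelectionPlan:
    """A complete solution.

    x: binary selection over all facilities; y: binary contract vector over
    RMCs (in RMC file order); z: demand-point -> facility-index assignment;
    w: per-facility annual capacity units; objectives: (f1, f2).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    w: np.ndarray
    objectives: tuple[float, float]

    @property
    def f1(self) -> float:
        return self.objectives[0]

    @property
    def f2(self) -> float:
        return self.objectives[1]

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.x))

    def to_dict(self, instance: ProblemInstance) -> dict:
        fac_ids = instance.facility_ids
        rmc_ids = [fac_ids[i] for i in instance.rmc_indices]
        return {
            "x": {fac_ids[i]: int(v) for i, v in enumerate(self.x)},
            "y": {rmc_ids[p]: int(v) for p, v in enumerate(self.y)},
            "z": {instance.demand_ids[j]: fac_ids[int(i)] for j, i in enumerate(self.z)},
            "w": {fac_ids[i]: float(v) for i, v in enumerate(self.w)},
            "f1": float(self.f1),
            "f2": float(self.f2),
        }


@dataclass(frozen=True)
class ParetoSet:
    """A mutually non-dominated collection of plans with their objectives."""

    plans: tuple[SelectionPlan, ...]

    @property
    def objectives(self) -> np.ndarray:
        return np.array([p.objectives for p in self.plans], dtype=float)

    def __len__(self) -> int:
        return len(self.plans)

    def __iter__(self):
        return iter(self.plans)

    def to_json(self, instance: ProblemInstance, *, indent: int | None = 2) -> str:
        return json.dumps([p.to_dict(instance) for p in self.plans], indent=indent)


def cost_coefficients(instance: ProblemInstance) -> dict[str, np.ndarray]:
    """Per-assignment cost/load coefficients, cached on the instance.

    Returns arrays keyed:

    * ``patient`` (n_fac, n_dem): f1 contribution of assigning demand j to i;
    * ``hospital`` (n_fac, n_dem): variable f2 contribution (service +
      capacity-provision terms, excluding contracting);
    * ``load`` (n_dem,): annual capacity units demand point j consumes.
    """
    cached = instance.__dict__.get("_cost_coefficients")
    if cached is not None:
        return cached

    d = instance.distances  # (I, J)
    n = instance.patient_counts  # (J,)
    p = instance.type_mix_matrix  # (J, K)
    F1 = np.array([t.F1 for t in instance.patient_types])
    F2 = np.array([t.F2 for t in instance.patient_types])
    e1 = np.array([t.e1 for t in instance.patient_types])
    e2 = np.array([t.e2 for t in instance.patient_types])
    costs = instance.costs
    ov = costs.overrides or {}

    np_jk = n[:, None] * p  # (J, K) patients of type k at j

    def per_visit(key: str, affine: np.ndarray) -> np.ndarray:
        """(I, J, K) per-visit cost array; override table wins if supplied."""
        return ov[key] if key in ov else affine

    shape = (instance.n_facilities, instance.n_demand, instance.n_types)
    h1 = per_visit("h1", np.broadcast_to((costs.h1_per_dist * d)[:, :, None], shape))
    h2 = per_visit("h2", np.broadcast_to(np.full((), costs.h2_base), shape))
    c1 = per_visit("c1", np.broadcast_to(np.full((), costs.c1_base), shape))
    c2 = per_visit("c2", np.broadcast_to((costs.c2_per_dist * d)[:, :, None], shape))

    patient = np.einsum("ijk,jk->ij", F1 * h1 + F2 * h2, np_jk)
    service = np.einsum("ijk,jk->ij", F1 * c1 + F2 * c2, np_jk)
    load_per_patient = e1 * F1 + e2 * F2  # (K,)
    load = np_jk @ load_per_patient  # (J,)
    hospital = service + costs.C2 * load[None, :]

    coeffs = {"patient": patient, "hospital": hospital, "load": load}
    for arr in coeffs.values():
        arr.setflags(write=False)
    object.__setattr__(instance, "_cost_coefficients", coeffs)
    return coeffs


def _as_selection(instance: ProblemInstance, selected: np.ndarray | Sequence[int]) -> np.ndarray:
    sel = np.asarray(selected, dtype=bool)
    if sel.shape != (instance.n_facilities,):
        raise ValueError(
            f"selection vector has shape {sel.shape}, expected ({instance.n_facilities},)"
        )
    return sel


def induce_allocation(
    instance: ProblemInstance, selected: np.ndarray | Sequence[int]
) -> np.ndarray:
    """Assign each demand point to a selected facility by proximity.

    Uncapped: the nearest selected facility, ties broken toward the lower
    facility index in file order.  With ``capacity_cap`` set, demand points
    are processed in descending annual workload (ties toward the lower demand
    index); each takes its nearest selected facility whose remaining capacity
    absorbs its full workload, never splitting a demand point.

    Returns an int array mapping demand index -> facility index.
    """
    sel = _as_selection(instance, selected)
    if not sel.any():
        raise AllocationError("no facility selected")

    d = instance.distances
    if instance.capacity_cap is None:
        masked = np.where(sel[:, None], d, np.inf)
        return np.argmin(masked, axis=0)  # argmin takes the lowest index on ties

    load = cost_coefficients(instance)["load"]
    residual = instance.capacity_cap.astype(float).copy()
    sel_idx = np.flatnonzero(sel)
    total_cap = residual[sel_idx].sum()
    if load.sum() > total_cap + 1e-9:
        raise AllocationError(
            f"total workload {load.sum():.3f} exceeds selected capacity {total_cap:.3f} "
            f"(shortfall {load.sum() - total_cap:.3f})"
        )
    assign = np.full(instance.n_demand, -1, dtype=int)
    order = np.lexsort((np.arange(instance.n_demand), -load))
    for j in order:
        # selected facilities by (distance, index); first with room wins
        cand = sel_idx[np.lexsort((sel_idx, d[sel_idx, j]))]
        placed = False
        for i in cand:
            if residual[i] + 1e-12 >= load[j]:
                assign[j] = i
                residual[i] -= load[j]
                placed = True
                break
        if not placed:
            raise AllocationError(
                f"demand point {instance.demand_ids[j]!r} (workload {load[j]:.3f}) "
                "cannot be absorbed by any selected facility's remaining capacity"
            )
    return assign


def contracts_from_selection(
    instance: ProblemInstance, selected: np.ndarray | Sequence[int]
) -> np.ndarray:
    """Minimal feasible contract vector: an RMC is contracted iff it is
    selected itself or supervises a selected PHC."""
    sel = _as_selection(instance, selected)
    y = np.zeros(len(instance.rmc_indices), dtype=np.int8)
    y[instance.parent_rmc_pos[sel]] = 1
    return y


def workload(
    instance: ProblemInstance, assignment: np.ndarray, facility: str | int
) -> float:
    """Annual capacity units facility ``facility`` must provide under
    ``assignment`` (sum of the served demand points' loads)."""
    if isinstance(facility, str):
        try:
            fi = instance.facility_ids.index(facility)
        except ValueError:
            raise KeyError(f"unknown facility id {facility!r}") from None
    else:
        fi = int(facility)
        if not 0 <= fi < instance.n_facilities:
            raise KeyError(f"facility index {fi} out of range")
    load = cost_coefficients(instance)["load"]
    return float(load[np.asarray(assignment) == fi].sum())


def _workload_vector(instance: ProblemInstance, assignment: np.ndarray) -> np.ndarray:
    load = cost_coefficients(instance)["load"]
    w = np.zeros(instance.n_facilities)
    np.add.at(w, assignment, load)
    return w


def _objectives_from_assignment(
    instance: ProblemInstance, assignment: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    coeffs = cost_coefficients(instance)
    j = np.arange(instance.n_demand)
    f1 = float(coeffs["patient"][assignment, j].sum())
    f2 = float(instance.costs.C1 * y.sum() + coeffs["hospital"][assignment, j].sum())
    return f1, f2


def plan_from_selection(
    instance: ProblemInstance,
    selected: np.ndarray | Sequence[int],
    *,
    repair_unused: bool = True,
) -> SelectionPlan:
    """Build the canonical plan induced by a facility selection.

    Allocation follows the proximity rule; with ``repair_unused`` (default),
    selected facilities that serve no demand point are deselected — the
    allocation is unchanged since they served nothing.  Contracts are the
    minimal feasible vector for the (possibly repaired) selection, and w is
    fixed to each facility's induced workload (the cheapest feasible choice,
    since capacity provision is costed per unit).
    """
    sel = _as_selection(instance, selected).copy()
    assign = induce_allocation(instance, sel)
    if repair_unused:
        used = np.zeros(instance.n_facilities, dtype=bool)
        used[assign] = True
        sel &= used
    y = contracts_from_selection(instance, sel)
    w = _workload_vector(instance, assign)
    objectives = _objectives_from_assignment(instance, assign, y)
    return SelectionPlan(
        x=sel.astype(np.int8), y=y, z=assign.copy(), w=w, objectives=objectives
    )


def check_constraints(instance: ProblemInstance, plan: SelectionPlan) -> list[Violation]:
    """Itemized constraint report; empty iff the plan is feasible.

    Checks: unique assignment of every demand point; assignment only to
    selected facilities; selected facilities imply a contract with their
    supervising RMC; induced workload within w (and within capacity_cap when
    present).
    """
    violations: list[Violation] = []
    z = np.asarray(plan.z)
    if z.shape != (instance.n_demand,) or np.any(z < 0) or np.any(z >= instance.n_facilities):
        bad = tuple(int(j) for j in np.flatnonzero((z < 0) | (z >= instance.n_facilities)))
        violations.append(Violation(UNIQUE_ASSIGNMENT, bad or ("shape",)))
        return violations

    x = np.asarray(plan.x).astype(bool)
    for j in np.flatnonzero(~x[z]):
        violations.append(Violation(ASSIGNMENT_REQUIRES_SELECTION, (int(z[j]), int(j))))

    y = np.asarray(plan.y).astype(bool)
    for i in np.flatnonzero(x):
        if not y[instance.parent_rmc_pos[i]]:
            violations.append(
                Violation(HIERARCHY_CONTRACT, (int(instance.rmc_indices[instance.parent_rmc_pos[i]]), int(i)))
            )

    w_induced = _workload_vector(instance, z)
    w = np.asarray(plan.w, dtype=float)
    for i in np.flatnonzero(w_induced > w + 1e-9):
        violations.append(Violation(CAPACITY, (int(i),)))
    if instance.capacity_cap is not None:
        for i in np.flatnonzero(w_induced > instance.capacity_cap + 1e-9):
            violations.append(Violation(CAPACITY, (int(i), "cap")))
    return violations


def evaluate_objectives(
    instance: ProblemInstance, plan: SelectionPlan
) -> tuple[float, float]:
    """Evaluate (f1, f2) for a structurally feasible plan.

    Raises :class:`ConstraintViolationError` when the plan violates unique
    assignment, selection linkage or hierarchical contracting.
    """
    structural = [
        v
        for v in check_constraints(instance, plan)
        if v.constraint in (UNIQUE_ASSIGNMENT, ASSIGNMENT_REQUIRES_SELECTION, HIERARCHY_CONTRACT)
    ]
    if structural:
        raise ConstraintViolationError(structural)
    return _objectives_from_assignment(
        instance, np.asarray(plan.z), np.asarray(plan.y)
    )
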