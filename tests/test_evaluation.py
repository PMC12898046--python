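import dataclasses
import itertools

import numpy as np
import pytest

from coopselect import (
    CostParams,
    DemandPoint,
    Facility,
    ProblemInstance,
    check_constraints,
    contracts_from_selection,
    default_parameters,
    evaluate_objectives,
    generate_instance,
    induce_allocation,
    plan_from_selection,
    workload,
)
from coopselect.evaluation import (
    ASSIGNMENT_REQUIRES_SELECTION,
    CAPACITY,
    HIERARCHY_CONTRACT,
    AllocationError,
    ConstraintViolationError,
    SelectionPlan,
)
from tests.conftest import small_generator_config


class TestInduceAllocation:
    def test_single_selected_facility_takes_everything(self, hierarchy_instance):
        assign = induce_allocation(hierarchy_instance, [1, 0, 0, 0])
        assert (assign == 0).all()

    def test_unused_selected_facility_gets_zero(self, hierarchy_instance):
        # R2 is farther from both demand points than every other facility
        assign = induce_allocation(hierarchy_instance, [0, 1, 1, 1])
        counts = np.bincount(assign, minlength=4)
        assert counts[3] == 0

    def test_matches_bruteforce_nearest_neighbor(self):
        for seed in range(5):
            inst = generate_instance(small_generator_config(seed), 200 + seed)
            rng = np.random.default_rng(seed)
            sel = rng.uniform(size=inst.n_facilities) < 0.5
            if not sel.any():
                sel[0] = True
            assign = induce_allocation(inst, sel)
            for j in range(inst.n_demand):
                best = min(
                    (inst.distances[i, j], i) for i in range(inst.n_facilities) if sel[i]
                )
                assert assign[j] == best[1]

    def test_tie_breaks_to_lower_index(self, baseline_params):
        pt, costs = baseline_params
        inst = ProblemInstance(
            facilities=(Facility("R1", "RMC", "R1"), Facility("R2", "RMC", "R2")),
            demand_points=(DemandPoint("J1", 1, (1.0,)),),
            patient_types=(pt,),
            costs=costs,
            distances=np.array([[3.0], [3.0]]),
        )
        assert induce_allocation(inst, [1, 1])[0] == 0

    def test_no_selection_raises(self, unit_instance):
        with pytest.raises(AllocationError):
            induce_allocation(unit_instance, [0])

    def test_capacity_overflow_shifts_to_next_nearest(self, baseline_params):
        pt, costs = baseline_params
        # each demand point needs 42 units; R1 can hold only one of them
        inst = ProblemInstance(
            facilities=(Facility("R1", "RMC", "R1"), Facility("R2", "RMC", "R2")),
            demand_points=(DemandPoint("J1", 1, (1.0,)), DemandPoint("J2", 1, (1.0,))),
            patient_types=(pt,),
            costs=costs,
            distances=np.array([[1.0, 2.0], [5.0, 5.0]]),
            capacity_cap=np.array([42.0, 100.0]),
        )
        assign = induce_allocation(inst, [1, 1])
        # both are nearest to R1; the overflow point moves to R2
        assert sorted(assign.tolist()) == [0, 1]

    def test_capacity_infeasible_names_shortfall(self, baseline_params):
        pt, costs = baseline_params
        inst = ProblemInstance(
            facilities=(Facility("R1", "RMC", "R1"),),
            demand_points=(DemandPoint("J1", 2, (1.0,)),),
            patient_types=(pt,),
            costs=costs,
            distances=np.array([[1.0]]),
            capacity_cap=np.array([42.0]),
        )
        with pytest.raises(AllocationError, match="shortfall"):
            induce_allocation(inst, [1])


class TestContracts:
    def test_empty_selection_no_contracts(self, hierarchy_instance):
        assert contracts_from_selection(hierarchy_instance, [0, 0, 0, 0]).sum() == 0

    def test_rmc_contracts_itself(self, hierarchy_instance):
        y = contracts_from_selection(hierarchy_instance, [1, 0, 0, 0])
        assert y.tolist() == [1, 0]

    def test_sibling_phcs_share_one_contract(self, hierarchy_instance):
        y = contracts_from_selection(hierarchy_instance, [0, 1, 1, 0])
        assert y.sum() == 1
        assert y.tolist() == [1, 0]

    def test_minimality_against_exhaustive_01_check(self, hierarchy_instance):
        """The returned y is the cheapest vector satisfying the hierarchical
        contracting constraint, for every possible selection."""
        inst = hierarchy_instance
        parent = inst.parent_rmc_pos
        for bits in itertools.product([0, 1], repeat=inst.n_facilities):
            x = np.array(bits)
            y = contracts_from_selection(inst, x)
            feasible = [
                np.array(yb)
                for yb in itertools.product([0, 1], repeat=len(inst.rmc_indices))
                if all(yb[parent[i]] >= x[i] for i in range(inst.n_facilities))
            ]
            best = min(yv.sum() for yv in feasible)
            assert y.sum() == best
            assert all(y[parent[i]] >= x[i] for i in range(inst.n_facilities))


class TestWorkload:
    def test_single_patient_year_is_42_units(self, unit_instance):
        assign = induce_allocation(unit_instance, [1])
        assert workload(unit_instance, assign, "R1") == pytest.approx(42.0)

    def test_facility_serving_nothing_is_zero(self, hierarchy_instance):
        assign = induce_allocation(hierarchy_instance, [0, 1, 1, 1])
        assert workload(hierarchy_instance, assign, "R2") == 0.0

    def test_linearity_in_patient_counts(self, hierarchy_instance):
        inst = hierarchy_instance
        doubled = dataclasses.replace(
            inst,
            demand_points=tuple(
                dataclasses.replace(d, n=2 * d.n) for d in inst.demand_points
            ),
        )
        assign = induce_allocation(inst, [1, 1, 1, 0])
        for fid in inst.facility_ids:
            assert workload(doubled, assign, fid) == pytest.approx(
                2 * workload(inst, assign, fid)
            )

    def test_unknown_facility_raises(self, unit_instance):
        with pytest.raises(KeyError):
            workload(unit_instance, np.array([0]), "NOPE")


class TestObjectives:
    def test_worked_single_point_example(self, unit_instance):
        """One patient at distance 2 under baseline parameters costs the
        patient 860 and the hospital 13,780 per year."""
        plan = plan_from_selection(unit_instance, [1])
        assert plan.f1 == pytest.approx(860.0)
        assert plan.f2 == pytest.approx(13_780.0)

    def test_zero_demand_leaves_only_contracting_cost(self, baseline_params):
        pt, costs = baseline_params
        inst = ProblemInstance(
            facilities=(Facility("R1", "RMC", "R1"),),
            demand_points=(DemandPoint("J1", 0, (1.0,)),),
            patient_types=(pt,),
            costs=costs,
            distances=np.array([[2.0]]),
        )
        plan = plan_from_selection(inst, [1], repair_unused=False)
        assert plan.f1 == 0.0
        assert plan.f2 == pytest.approx(costs.C1 * plan.y.sum())

    def test_independent_scalar_recomputation(self, hierarchy_instance):
        """Objective evaluation agrees with a plain-Python sum over the
        model's cost terms."""
        inst = hierarchy_instance
        plan = plan_from_selection(inst, [1, 1, 0, 0])
        pt = inst.patient_types[0]
        c = inst.costs
        f1 = f2v = load = 0.0
        for j, dpt in enumerate(inst.demand_points):
            i = plan.z[j]
            d = inst.distances[i, j]
            f1 += (pt.F1 * c.h1_per_dist * d + pt.F2 * c.h2_base) * dpt.n
            f2v += (pt.F1 * c.c1_base + pt.F2 * c.c2_per_dist * d) * dpt.n
            load += (pt.e1 * pt.F1 + pt.e2 * pt.F2) * dpt.n
        f2 = c.C1 * plan.y.sum() + f2v + c.C2 * load
        assert plan.f1 == pytest.approx(f1)
        assert plan.f2 == pytest.approx(f2)

    def test_cost_override_tables_replace_affine_defaults(self, baseline_params):
        pt, costs = baseline_params
        shape = (1, 1, 1)
        overridden = dataclasses.replace(
            costs,
            overrides={
                "h1": np.full(shape, 7.0),
                "h2": np.full(shape, 11.0),
                "c1": np.full(shape, 13.0),
                "c2": np.full(shape, 17.0),
            },
        )
        inst = ProblemInstance(
            facilities=(Facility("R1", "RMC", "R1"),),
            demand_points=(DemandPoint("J1", 1, (1.0,)),),
            patient_types=(pt,),
            costs=overridden,
            distances=np.array([[2.0]]),
        )
        plan = plan_from_selection(inst, [1])
        assert plan.f1 == pytest.approx(6 * 7.0 + 10 * 11.0)
        assert plan.f2 == pytest.approx(10_000 + (6 * 13.0 + 10 * 17.0) + 50 * 42)

    def test_violated_precondition_raises(self, unit_instance):
        bad = SelectionPlan(
            x=np.array([0], dtype=np.int8),
            y=np.array([0], dtype=np.int8),
            z=np.array([0]),
            w=np.array([42.0]),
            objectives=(0.0, 0.0),
        )
        with pytest.raises(ConstraintViolationError):
            evaluate_objectives(unit_instance, bad)


class TestCheckConstraints:
    def test_constructed_plan_is_feasible(self, hierarchy_instance):
        plan = plan_from_selection(hierarchy_instance, [1, 1, 1, 1])
        assert check_constraints(hierarchy_instance, plan) == []

    def test_assignment_to_unselected_facility_cited(self, hierarchy_instance):
        plan = plan_from_selection(hierarchy_instance, [1, 1, 1, 0])
        # deselect the PHC that serves the first demand point
        bad = dataclasses.replace(plan, x=np.array([0, 0, 1, 0], dtype=np.int8))
        report = check_constraints(hierarchy_instance, bad)
        kinds = {v.constraint for v in report}
        assert ASSIGNMENT_REQUIRES_SELECTION in kinds

    def test_uncontracted_parent_cited(self, hierarchy_instance):
        plan = plan_from_selection(hierarchy_instance, [0, 1, 1, 0])
        bad = dataclasses.replace(plan, y=np.zeros_like(plan.y))
        report = check_constraints(hierarchy_instance, bad)
        assert {v.constraint for v in report} == {HIERARCHY_CONTRACT}

    def test_insufficient_w_cited(self, unit_instance):
        plan = plan_from_selection(unit_instance, [1])
        bad = dataclasses.replace(plan, w=np.array([10.0]))
        report = check_constraints(unit_instance, bad)
        assert {v.constraint for v in report} == {CAPACITY}


class TestLinearity:
    def test_f2_shift_equals_delta_c1_times_contracts(self, hierarchy_instance):
        inst = hierarchy_instance
        plan = plan_from_selection(inst, [1, 0, 1, 1])
        delta = 1234.5
        shifted = inst.with_costs(inst.costs.replace(C1=inst.costs.C1 + delta))
        f1b, f2b = evaluate_objectives(shifted, plan)
        assert f1b == plan.f1
        assert f2b - plan.f2 == pytest.approx(delta * plan.y.sum())

    def test_scaling_demand_scales_noncontract_terms_exactly(self, hierarchy_instance):
        inst = hierarchy_instance
        alpha = 3
        scaled = dataclasses.replace(
            inst,
            demand_points=tuple(
                dataclasses.replace(d, n=alpha * d.n) for d in inst.demand_points
            ),
        )
        plan = plan_from_selection(inst, [1, 1, 1, 0])
        plan_s = plan_from_selection(scaled, [1, 1, 1, 0])
        contracts = inst.costs.C1 * plan.y.sum()
        assert plan_s.f1 == pytest.approx(alpha * plan.f1)
        assert plan_s.f2 - contracts == pytest.approx(alpha * (plan.f2 - contracts))


class TestPlanSerialization:
    def test_plan_round_trips_as_json_mapping(self, hierarchy_instance):
        import json

        plan = plan_from_selection(hierarchy_instance, [1, 1, 0, 0])
        doc = json.loads(json.dumps(plan.to_dict(hierarchy_instance)))
        assert set(doc) == {"x", "y", "z", "w", "f1", "f2"}
        assert doc["z"]["J1"] in doc["x"]
        assert doc["f1"] == plan.f1
        assert all(v in (0, 1) for v in doc["x"].values())
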