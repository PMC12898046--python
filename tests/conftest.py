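import numpy as np
import pytest

from coopselect import (
    CostParams,
    DemandPoint,
    Facility,
    GeneratorConfig,
    PatientTypeParams,
    ProblemInstance,
    default_parameters,
    generate_instance,
)


@pytest.fixture(scope="session")
def baseline_params():
    return default_parameters()


@pytest.fixture
def unit_instance(baseline_params):
    """One RMC at distance 2 from one demand point with one patient/year."""
    pt, costs = baseline_params
    return ProblemInstance(
        facilities=(Facility("R1", "RMC", "R1"),),
        demand_points=(DemandPoint("J1", 1, (1.0,)),),
        patient_types=(pt,),
        costs=costs,
        distances=np.array([[2.0]]),
    )


@pytest.fixture
def two_rmc_instance(baseline_params):
    """Two RMCs, two demand points of 10 patients each; near/far distances
    chosen so contracting both trades hospital cost against patient cost."""
    pt, costs = baseline_params
    return ProblemInstance(
        facilities=(Facility("R1", "RMC", "R1"), Facility("R2", "RMC", "R2")),
        demand_points=(DemandPoint("J1", 10, (1.0,)), DemandPoint("J2", 10, (1.0,))),
        patient_types=(pt,),
        costs=costs,
        distances=np.array([[1.0, 2.0], [2.0, 1.0]]),
    )


@pytest.fixture
def hierarchy_instance(baseline_params):
    """Two RMCs; the first supervises two PHCs. Demand sits near the PHCs."""
    pt, costs = baseline_params
    return ProblemInstance(
        facilities=(
            Facility("R1", "RMC", "R1"),
            Facility("R1P1", "PHC", "R1"),
            Facility("R1P2", "PHC", "R1"),
            Facility("R2", "RMC", "R2"),
        ),
        demand_points=(
            DemandPoint("J1", 5, (1.0,)),
            DemandPoint("J2", 5, (1.0,)),
        ),
        patient_types=(pt,),
        costs=costs,
        distances=np.array(
            [
                [3.0, 3.0],
                [0.5, 2.0],
                [2.0, 0.5],
                [4.0, 4.0],
            ]
        ),
    )


def small_generator_config(index: int) -> GeneratorConfig:
    """Two alternating small-instance shapes (<= 10 facilities / demand points)
    used for oracle-equivalence checks."""
    if index % 2 == 0:
        return GeneratorConfig(
            n_rmc=3, phc_per_rmc=(1, 2), n_demand=8, total_patients=60,
            extent=(6.0, 6.0), cluster_fraction=0.5, n_cluster_communities=2,
        )
    return GeneratorConfig(
        n_rmc=4, phc_per_rmc=(0, 1), n_demand=10, total_patients=100,
        extent=(8.0, 8.0), cluster_fraction=0.6, n_cluster_communities=3,
    )


@pytest.fixture
def small_instance():
    return generate_instance(small_generator_config(0), 1000)
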