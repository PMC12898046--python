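"""Problem-instance data model, validation, I/O and synthetic generation.

The planning problem couples a two-tier hierarchy of candidate community
facilities -- regional medical centers (RMCs) and their subordinate primary
health centers (PHCs) -- with community demand points that aggregate
discharged patients needing post-discharge follow-up.  An instance is the
complete immutable description of that setting: facilities, hierarchy,
demand, patient-type parameters, cost coefficients and the facility-by-demand
travel-distance matrix.

Instances are read and written as a single JSON document or an equivalent
CSV bundle; seeded synthetic instances emulating the Wuhou District study
region (29 RMCs, 28 communities, 726 patients/year, spatially clustered
demand) are produced by :func:`generate_instance`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "InstanceValidationError",
    "Facility",
    "DemandPoint",
    "PatientTypeParams",
    "CostParams",
    "ProblemInstance",
    "GeneratorConfig",
    "default_parameters",
    "load_instance",
    "save_instance",
    "generate_instance",
    "wuhou_like",
]

_PROPORTION_TOL = 1e-9


class InstanceValidationError(ValueError):
    """Raised when an instance document violates the data-model invariants.

    The message always names the offending record (facility id, demand-point
    id, or parameter) so that malformed documents are diagnosable.
    """


@dataclass(frozen=True)
class Facility:
    """A candidate follow-up provider.

    ``tier`` is ``"RMC"`` (upper tier, holds contracting authority) or
    ``"PHC"`` (lower tier).  ``parent_id`` is the supervising RMC; an RMC is
    its own parent, which encodes that an RMC is subordinate to itself in the
    hierarchy relation.
    """

    id: str
    tier: str
    parent_id: str
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.tier not in ("RMC", "PHC"):
            raise InstanceValidationError(
                f"facility {self.id!r}: tier must be 'RMC' or 'PHC', got {self.tier!r}"
            )
        if self.tier == "RMC" and self.parent_id != self.id:
            raise InstanceValidationError(
                f"facility {self.id!r}: an RMC must be its own parent "
                f"(got parent_id={self.parent_id!r})"
            )
        if self.location is not None:
            object.__setattr__(self, "location", (float(self.location[0]), float(self.location[1])))


@dataclass(frozen=True)
class DemandPoint:
    """A community aggregating ``n`` discharged patients per year.

    ``type_mix`` gives the proportion of each patient type at this community;
    entries lie in [0, 1] and sum to 1.
    """

    id: str
    n: int
    type_mix: tuple[float, ...]
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InstanceValidationError(f"demand point {self.id!r}: n must be >= 0, got {self.n}")
        mix = tuple(float(v) for v in self.type_mix)
        object.__setattr__(self, "type_mix", mix)
        if any(v < -_PROPORTION_TOL or v > 1 + _PROPORTION_TOL for v in mix):
            raise InstanceValidationError(
                f"demand point {self.id!r}: type_mix entries must lie in [0, 1], got {mix}"
            )
        if abs(sum(mix) - 1.0) > _PROPORTION_TOL:
            raise InstanceValidationError(
                f"demand point {self.id!r}: type_mix must sum to 1, got sum={sum(mix)!r}"
            )
        if self.location is not None:
            object.__setattr__(self, "location", (float(self.location[0]), float(self.location[1])))


@dataclass(frozen=True)
class PatientTypeParams:
    """Follow-up intensity of one patient type.

    F1 / F2: facility-based / home visits per patient-year; e1 / e2: service
    capacity units consumed per facility / home visit.
    """

    F1: float
    F2: float
    e1: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("F1", "F2", "e1", "e2"):
            if getattr(self, name) < 0:
                raise InstanceValidationError(f"patient type parameter {name} must be >= 0")

    @property
    def load_per_patient_year(self) -> float:
        """Capacity units one patient of this type consumes per year."""
        return self.e1 * self.F1 + self.e2 * self.F2


@dataclass(frozen=True)
class CostParams:
    """Scalar cost coefficients (all in abstract currency units).

    C1 is the fixed annual contracting fee per contracted RMC; C2 the cost per
    capacity unit the general hospital provisions.  The remaining four define
    affine per-visit costs: facility visits cost the provider ``c1_base`` per
    visit and the patient ``h1_per_dist * d_ij``; home visits cost the
    provider ``c2_per_dist * d_ij`` and the patient ``h2_base``.  Fully
    general per-(facility, demand, type) override tables may replace any of
    the four affine forms.
    """

    C1: float
    C2: float
    c1_base: float
    c2_per_dist: float
    h1_per_dist: float
    h2_base: float
    overrides: Mapping[str, np.ndarray] | None = None

    _OVERRIDE_KEYS = ("c1", "c2", "h1", "h2")

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "c1_base", "c2_per_dist", "h1_per_dist", "h2_base"):
            if getattr(self, name) < 0:
                raise InstanceValidationError(f"cost parameter {name} must be >= 0")
        if self.overrides is not None:
            bad = set(self.overrides) - set(self._OVERRIDE_KEYS)
            if bad:
                raise InstanceValidationError(
                    f"unknown cost override keys {sorted(bad)}; allowed: {self._OVERRIDE_KEYS}"
                )
            frozen = {k: np.asarray(v, dtype=float) for k, v in self.overrides.items()}
            for k, arr in frozen.items():
                arr.setflags(write=False)
                if np.any(arr < 0):
                    raise InstanceValidationError(f"cost override {k!r} has negative entries")
            object.__setattr__(self, "overrides", frozen)

    def replace(self, **changes: float) -> "CostParams":
        return dataclasses.replace(self, **changes)


def default_parameters() -> tuple[PatientTypeParams, CostParams]:
    """Baseline single-type parameterization of the study setting.

    One facility visit every other month (F1=6/yr), monthly home visits
    (F2=10/yr), 2 and 3 capacity units per visit respectively, a 10,000
    currency/year contracting fee, 50 currency per capacity unit, 80 currency
    per facility visit provider-side, and distance-proportional travel costs
    of 60 (provider home-visit) and 30 (patient facility-visit) currency per
    distance unit, plus 50 currency per home visit patient-side.
    """
    return (
        PatientTypeParams(F1=6, F2=10, e1=2, e2=3),
        CostParams(C1=10_000, C2=50, c1_base=80, c2_per_dist=60, h1_per_dist=30, h2_base=50),
    )


@dataclass(frozen=True)
class ProblemInstance:
    """Immutable, validated description of one planning problem.

    ``distances`` is facility-major: ``distances[i, j]`` is the travel
    distance between facility ``i`` and demand point ``j`` (file order).
    ``capacity_cap`` is an optional per-facility upper bound on annual
    capacity units; absent means unbounded.
    """

    facilities: tuple[Facility, ...]
    demand_points: tuple[DemandPoint, ...]
    patient_types: tuple[PatientTypeParams, ...]
    costs: CostParams
    distances: np.ndarray
    capacity_cap: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "facilities", tuple(self.facilities))
        object.__setattr__(self, "demand_points", tuple(self.demand_points))
        object.__setattr__(self, "patient_types", tuple(self.patient_types))
        if not self.facilities:
            raise InstanceValidationError("instance must contain at least one facility")
        if not self.demand_points:
            raise InstanceValidationError("instance must contain at least one demand point")
        if not self.patient_types:
            raise InstanceValidationError("instance must define at least one patient type")

        ids = [f.id for f in self.facilities]
        if len(set(ids)) != len(ids):
            raise InstanceValidationError("duplicate facility ids")
        did = [d.id for d in self.demand_points]
        if len(set(did)) != len(did):
            raise InstanceValidationError("duplicate demand point ids")

        by_id = {f.id: f for f in self.facilities}
        for f in self.facilities:
            parent = by_id.get(f.parent_id)
            if parent is None:
                raise InstanceValidationError(
                    f"facility {f.id!r}: parent_id {f.parent_id!r} does not exist"
                )
            if parent.tier != "RMC":
                raise InstanceValidationError(
                    f"facility {f.id!r}: parent {f.parent_id!r} is a PHC; "
                    "the hierarchy must be RMC-rooted"
                )

        k = len(self.patient_types)
        for d in self.demand_points:
            if len(d.type_mix) != k:
                raise InstanceValidationError(
                    f"demand point {d.id!r}: type_mix has length {len(d.type_mix)}, "
                    f"expected {k} (number of patient types)"
                )

        dist = np.asarray(self.distances, dtype=float)
        if dist.shape != (len(self.facilities), len(self.demand_points)):
            raise InstanceValidationError(
                f"distance matrix shape {dist.shape} does not match "
                f"({len(self.facilities)} facilities, {len(self.demand_points)} demand points)"
            )
        if np.any(~np.isfinite(dist)):
            raise InstanceValidationError("distance matrix contains non-finite entries")
        if np.any(dist < 0):
            i, j = np.argwhere(dist < 0)[0]
            raise InstanceValidationError(
                f"negative distance between facility {ids[i]!r} and demand point {did[j]!r}"
            )
        dist = dist.copy()
        dist.setflags(write=False)
        object.__setattr__(self, "distances", dist)

        if self.capacity_cap is not None:
            cap = np.broadcast_to(
                np.asarray(self.capacity_cap, dtype=float), (len(self.facilities),)
            ).copy()
            if np.any(cap < 0):
                raise InstanceValidationError("capacity_cap entries must be >= 0")
            cap.setflags(write=False)
            object.__setattr__(self, "capacity_cap", cap)

        if self.costs.overrides:
            want = (len(self.facilities), len(self.demand_points), k)
            for key, arr in self.costs.overrides.items():
                if arr.shape != want:
                    raise InstanceValidationError(
                        f"cost override {key!r} has shape {arr.shape}, expected {want}"
                    )

    # -- derived views ----------------------------------------------------

    @property
    def n_facilities(self) -> int:
        return len(self.facilities)

    @property
    def n_demand(self) -> int:
        return len(self.demand_points)

    @property
    def n_types(self) -> int:
        return len(self.patient_types)

    @property
    def facility_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.facilities)

    @property
    def demand_ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.demand_points)

    @property
    def rmc_indices(self) -> np.ndarray:
        """Facility indices of the RMCs, in file order."""
        return self._cached("_rmc_indices", lambda: np.array(
            [i for i, f in enumerate(self.facilities) if f.tier == "RMC"], dtype=int
        ))

    @property
    def parent_rmc_pos(self) -> np.ndarray:
        """For each facility, the position of its supervising RMC within ``rmc_indices``."""
        def build() -> np.ndarray:
            rmc_pos = {self.facilities[i].id: p for p, i in enumerate(self.rmc_indices)}
            return np.array([rmc_pos[f.parent_id] for f in self.facilities], dtype=int)
        return self._cached("_parent_rmc_pos", build)

    @property
    def patient_counts(self) -> np.ndarray:
        return self._cached("_patient_counts", lambda: np.array(
            [d.n for d in self.demand_points], dtype=float
        ))

    @property
    def type_mix_matrix(self) -> np.ndarray:
        """(n_demand, n_types) matrix of patient-type proportions."""
        return self._cached("_type_mix", lambda: np.array(
            [d.type_mix for d in self.demand_points], dtype=float
        ))

    def _cached(self, slot: str, build) -> Any:
        value = self.__dict__.get(slot)
        if value is None:
            value = build()
            if isinstance(value, np.ndarray):
                value.setflags(write=False)
            object.__setattr__(self, slot, value)
        return value

    def with_costs(self, costs: CostParams) -> "ProblemInstance":
        return dataclasses.replace(self, costs=costs)

    def with_patient_types(self, types: Sequence[PatientTypeParams]) -> "ProblemInstance":
        return dataclasses.replace(self, patient_types=tuple(types))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "facilities": [
                {
                    "id": f.id,
                    "tier": f.tier,
                    "parent_id": f.parent_id,
                    **({"location": list(f.location)} if f.location is not None else {}),
                }
                for f in self.facilities
            ],
            "demand_points": [
                {
                    "id": d.id,
                    "n": d.n,
                    "type_mix": list(d.type_mix),
                    **({"location": list(d.location)} if d.location is not None else {}),
                }
                for d in self.demand_points
            ],
            "patient_types": [
                {"F1": t.F1, "F2": t.F2, "e1": t.e1, "e2": t.e2} for t in self.patient_types
            ],
            "costs": {
                "C1": self.costs.C1,
                "C2": self.costs.C2,
                "c1_base": self.costs.c1_base,
                "c2_per_dist": self.costs.c2_per_dist,
                "h1_per_dist": self.costs.h1_per_dist,
                "h2_base": self.costs.h2_base,
            },
            "distances": self.distances.tolist(),
        }
        if self.costs.overrides:
            doc["costs"]["overrides"] = {
                k: v.tolist() for k, v in sorted(self.costs.overrides.items())
            }
        if self.capacity_cap is not None:
            doc["capacity_cap"] = self.capacity_cap.tolist()
        return doc

    def to_json(self, *, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _euclidean_distances(
    facilities: Sequence[Facility], demand_points: Sequence[DemandPoint]
) -> np.ndarray:
    missing = [f.id for f in facilities if f.location is None]
    missing += [d.id for d in demand_points if d.location is None]
    if missing:
        raise InstanceValidationError(
            "no distance matrix supplied and these records lack locations: "
            + ", ".join(repr(m) for m in missing)
        )
    fxy = np.array([f.location for f in facilities], dtype=float)
    dxy = np.array([d.location for d in demand_points], dtype=float)
    diff = fxy[:, None, :] - dxy[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _instance_from_dict(doc: Mapping[str, Any]) -> ProblemInstance:
    for key in ("facilities", "demand_points", "patient_types", "costs"):
        if key not in doc:
            raise InstanceValidationError(f"instance document missing required key {key!r}")
    facilities = tuple(
        Facility(
            id=str(rec["id"]),
            tier=str(rec["tier"]),
            parent_id=str(rec["parent_id"]),
            location=tuple(rec["location"]) if rec.get("location") is not None else None,
        )
        for rec in doc["facilities"]
    )
    demand_points = tuple(
        DemandPoint(
            id=str(rec["id"]),
            n=int(rec["n"]),
            type_mix=tuple(rec["type_mix"]),
            location=tuple(rec["location"]) if rec.get("location") is not None else None,
        )
        for rec in doc["demand_points"]
    )
    patient_types = tuple(
        PatientTypeParams(F1=rec["F1"], F2=rec["F2"], e1=rec["e1"], e2=rec["e2"])
        for rec in doc["patient_types"]
    )
    cdoc = dict(doc["costs"])
    overrides = cdoc.pop("overrides", None)
    costs = CostParams(
        C1=cdoc["C1"],
        C2=cdoc["C2"],
        c1_base=cdoc["c1_base"],
        c2_per_dist=cdoc["c2_per_dist"],
        h1_per_dist=cdoc["h1_per_dist"],
        h2_base=cdoc["h2_base"],
        overrides={k: np.asarray(v, dtype=float) for k, v in overrides.items()}
        if overrides
        else None,
    )
    if doc.get("distances") is not None:
        distances = np.asarray(doc["distances"], dtype=float)
    else:
        distances = _euclidean_distances(facilities, demand_points)
    return ProblemInstance(
        facilities=facilities,
        demand_points=demand_points,
        patient_types=patient_types,
        costs=costs,
        distances=distances,
        capacity_cap=np.asarray(doc["capacity_cap"], dtype=float)
        if doc.get("capacity_cap") is not None
        else None,
    )


def _instance_from_csv_bundle(directory: Path) -> ProblemInstance:
    import pandas as pd

    fac_df = pd.read_csv(directory / "facilities.csv", dtype={"id": str, "parent_id": str})
    dem_df = pd.read_csv(directory / "demand.csv", dtype={"id": str})
    par_df = pd.read_csv(directory / "params.csv")

    has_xy = {"x", "y"}.issubset(fac_df.columns)
    facilities = tuple(
        Facility(
            id=row["id"],
            tier=row["tier"],
            parent_id=row["parent_id"],
            location=(row["x"], row["y"]) if has_xy and not math.isnan(row["x"]) else None,
        )
        for _, row in fac_df.iterrows()
    )
    mix_cols = sorted(
        (c for c in dem_df.columns if c.startswith("p_type")),
        key=lambda c: int(c.removeprefix("p_type")),
    )
    dem_has_xy = {"x", "y"}.issubset(dem_df.columns)
    demand_points = tuple(
        DemandPoint(
            id=row["id"],
            n=int(row["n"]),
            type_mix=tuple(row[c] for c in mix_cols) if mix_cols else (1.0,),
            location=(row["x"], row["y"]) if dem_has_xy and not math.isnan(row["x"]) else None,
        )
        for _, row in dem_df.iterrows()
    )

    scalars = {
        row["param"]: row["value"]
        for _, row in par_df.iterrows()
        if pd.isna(row.get("type_index"))
    }
    typed: dict[int, dict[str, float]] = {}
    for _, row in par_df.iterrows():
        if not pd.isna(row.get("type_index")):
            typed.setdefault(int(row["type_index"]), {})[row["param"]] = row["value"]
    if typed:
        patient_types = tuple(
            PatientTypeParams(**typed[i]) for i in sorted(typed)
        )
    else:
        patient_types = (default_parameters()[0],)
    costs = CostParams(
        C1=scalars["C1"],
        C2=scalars["C2"],
        c1_base=scalars["c1_base"],
        c2_per_dist=scalars["c2_per_dist"],
        h1_per_dist=scalars["h1_per_dist"],
        h2_base=scalars["h2_base"],
    )

    dist_path = directory / "distances.csv"
    if dist_path.exists():
        dist_df = pd.read_csv(dist_path, index_col=0)
        dist_df = dist_df.loc[[f.id for f in facilities], [d.id for d in demand_points]]
        distances = dist_df.to_numpy(dtype=float)
    else:
        distances = _euclidean_distances(facilities, demand_points)
    return ProblemInstance(
        facilities=facilities,
        demand_points=demand_points,
        patient_types=patient_types,
        costs=costs,
        distances=distances,
    )


def load_instance(source: str | Path | Mapping[str, Any]) -> ProblemInstance:
    """Load and validate a problem instance.

    ``source`` may be a mapping (already-parsed JSON document), a path to a
    ``.json`` file, or a directory holding the CSV bundle
    (``facilities.csv``, ``demand.csv``, ``params.csv`` and optionally
    ``distances.csv``).  When locations are given but distances are not,
    Euclidean distances are computed; an explicit distance matrix always wins.
    """
    if isinstance(source, Mapping):
        return _instance_from_dict(source)
    path = Path(source)
    if path.is_dir():
        return _instance_from_csv_bundle(path)
    with open(path) as fh:
        return _instance_from_dict(json.load(fh))


def save_instance(instance: ProblemInstance, path: str | Path) -> None:
    """Write the instance as its canonical JSON document."""
    Path(path).write_text(instance.to_json() + "\n")


# -- synthetic generation --------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the seeded synthetic-instance generator.

    The generator emulates an urban district with a two-tier facility
    hierarchy and spatially clustered demand: ``cluster_fraction`` of all
    patients live in ``n_cluster_communities`` dense communities confined to
    an eastern sub-region, the rest are spread uniformly.
    """

    n_rmc: int = 29
    phc_per_rmc: tuple[int, int] = (1, 3)
    n_demand: int = 28
    total_patients: int = 726
    extent: tuple[float, float] = (9.0, 9.0)
    cluster_fraction: float = 0.65
    n_cluster_communities: int = 4
    n_types: int = 1

    def __post_init__(self) -> None:
        if self.n_rmc <= 0 or self.n_demand <= 0 or self.total_patients <= 0:
            raise InstanceValidationError("generator counts must be positive")
        if self.phc_per_rmc[0] < 0 or self.phc_per_rmc[1] < self.phc_per_rmc[0]:
            raise InstanceValidationError("phc_per_rmc must be a nondecreasing nonnegative range")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise InstanceValidationError("cluster_fraction must lie in [0, 1]")
        if self.n_cluster_communities < 0:
            raise InstanceValidationError("n_cluster_communities must be >= 0")
        if self.n_types <= 0:
            raise InstanceValidationError("n_types must be positive")


def wuhou_like() -> GeneratorConfig:
    """Preset mirroring the study region's published structure.

    29 RMCs with subordinate PHCs, 28 communities, 726 discharged patients
    per year, a single patient type, and the baseline cost parameters.
    """
    return GeneratorConfig()


def generate_instance(config: GeneratorConfig, seed: int) -> ProblemInstance:
    """Generate a seeded synthetic instance; deterministic per (config, seed).

    Demand counts are drawn by a Dirichlet-multinomial split: the dense
    cluster receives ``round(cluster_fraction * total)`` patients shared over
    the cluster communities, the sparse background the remainder; every
    community keeps at least one patient when counts permit.  PHCs scatter
    around their parent RMC.
    """
    rng = np.random.default_rng(seed)
    width, height = config.extent

    facilities: list[Facility] = []
    rmc_xy = rng.uniform((0.0, 0.0), (width, height), size=(config.n_rmc, 2))
    for r in range(config.n_rmc):
        rid = f"R{r + 1:02d}"
        facilities.append(Facility(id=rid, tier="RMC", parent_id=rid,
                                   location=(rmc_xy[r, 0], rmc_xy[r, 1])))
        n_phc = int(rng.integers(config.phc_per_rmc[0], config.phc_per_rmc[1] + 1))
        for p in range(n_phc):
            offset = rng.normal(0.0, min(width, height) / 20.0, size=2)
            xy = np.clip(rmc_xy[r] + offset, [0.0, 0.0], [width, height])
            facilities.append(
                Facility(id=f"{rid}P{p + 1}", tier="PHC", parent_id=rid,
                         location=(xy[0], xy[1]))
            )

    n_dense = min(config.n_cluster_communities, config.n_demand)
    n_sparse = config.n_demand - n_dense
    # dense communities sit in the eastern third of the extent
    dense_xy = rng.uniform((2 * width / 3, 0.0), (width, height), size=(n_dense, 2))
    sparse_xy = rng.uniform((0.0, 0.0), (2 * width / 3, height), size=(n_sparse, 2))
    xy = np.vstack([sparse_xy, dense_xy]) if n_dense else sparse_xy

    dense_total = round(config.cluster_fraction * config.total_patients) if n_dense else 0
    if n_sparse == 0:
        dense_total = config.total_patients
    sparse_total = config.total_patients - dense_total
    counts = np.zeros(config.n_demand, dtype=int)

    def split(total: int, m: int) -> np.ndarray:
        if m == 0 or total == 0:
            return np.zeros(m, dtype=int)
        base = 1 if total >= m else 0
        remainder = total - base * m
        weights = rng.dirichlet(np.full(m, 2.0))
        extra = rng.multinomial(remainder, weights)
        return base + extra

    counts[:n_sparse] = split(sparse_total, n_sparse)
    counts[n_sparse:] = split(dense_total, n_dense)

    if config.n_types == 1:
        mixes = np.ones((config.n_demand, 1))
    else:
        mixes = rng.dirichlet(np.full(config.n_types, 5.0), size=config.n_demand)
        mixes = mixes / mixes.sum(axis=1, keepdims=True)

    demand_points = tuple(
        DemandPoint(
            id=f"J{j + 1:02d}",
            n=int(counts[j]),
            type_mix=tuple(mixes[j]),
            location=(xy[j, 0], xy[j, 1]),
        )
        for j in range(config.n_demand)
    )

    base_type, base_costs = default_parameters()
    if config.n_types == 1:
        patient_types: tuple[PatientTypeParams, ...] = (base_type,)
    else:
        # spread follow-up intensity across types around the baseline
        scales = np.linspace(0.5, 1.5, config.n_types)
        patient_types = tuple(
            PatientTypeParams(
                F1=base_type.F1 * s, F2=base_type.F2 * s, e1=base_type.e1, e2=base_type.e2
            )
            for s in scales
        )

    return ProblemInstance(
        facilities=tuple(facilities),
        demand_points=demand_points,
        patient_types=patient_types,
        costs=base_costs,
        distances=_euclidean_distances(facilities, demand_points),
    )
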