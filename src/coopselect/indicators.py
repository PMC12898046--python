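"""Pareto-front quality indicators and the two evaluation protocols.

Two distinct protocols are exposed, matching the two ways hypervolume is
used when assessing solution sets for this problem:

* **Benchmarking** (:func:`benchmark_report`): fronts from several runs (or
  algorithms) are pooled into a union reference front, min-max normalized by
  the pooled bounds, and scored with hypervolume against the reference point
  (1.2, 1.2), inverted generational distance against the pooled front, and
  Schott spacing; results aggregate as mean +/- std over runs.
* **Sensitivity scoring** (:func:`sensitivity_hv`): scenario fronts stay in
  raw objective units and share a single global reference point (the
  component-wise maximum over all pooled points, optionally inflated), so
  hypervolumes are comparable across parameter levels.

All indicators assume bi-objective minimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NormalizationBounds",
    "IndicatorReport",
    "normalize",
    "hypervolume_2d",
    "igd",
    "spacing",
    "union_reference_front",
    "sensitivity_hv",
    "benchmark_report",
]


def _points(points) -> np.ndarray:
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P.reshape(1, -1)
    if np.any(np.isnan(P)):
        raise ValueError("points contain NaN")
    return P


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-objective min and max used for min-max scaling."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mins) != len(self.maxs):
            raise ValueError("mins and maxs must have equal length")
        for m, lo, hi in zip(range(len(self.mins)), self.mins, self.maxs):
            if hi < lo:
                raise ValueError(f"objective {m}: max {hi} < min {lo}")

    @classmethod
    def from_points(cls, points) -> "NormalizationBounds":
        P = _points(points)
        return cls(mins=tuple(P.min(axis=0)), maxs=tuple(P.max(axis=0)))

    @property
    def degenerate_objectives(self) -> tuple[int, ...]:
        return tuple(m for m, (lo, hi) in enumerate(zip(self.mins, self.maxs)) if hi == lo)


def normalize(points, bounds: NormalizationBounds) -> np.ndarray:
    """Min-max scale each coordinate by ``(v - min) / (max - min)``.

    Values outside [0, 1] are permitted (points beyond the bounds source).
    Degenerate bounds raise, naming the objective.
    """
    P = _points(points)
    if bounds.degenerate_objectives:
        raise ValueError(
            f"degenerate normalization bounds for objective(s) {bounds.degenerate_objectives}"
        )
    mins = np.asarray(bounds.mins)
    maxs = np.asarray(bounds.maxs)
    return (P - mins) / (maxs - mins)


def _nondominated_mask(P: np.ndarray) -> np.ndarray:
    le = np.all(P[:, None, :] <= P[None, :, :], axis=2)
    lt = np.any(P[:, None, :] < P[None, :, :], axis=2)
    dominated = (le & lt).any(axis=0)
    return ~dominated


def hypervolume_2d(points, reference: Sequence[float]) -> float:
    """Exact 2-D hypervolume of ``points`` w.r.t. ``reference`` (minimization).

    The Lebesgue measure of the union of axis-aligned rectangles [z, r] over
    the points z, computed by a sort-and-sweep over the non-dominated subset.
    Points with any coordinate >= the reference contribute only their clipped
    (possibly empty) rectangle.
    """
    P = _points(points)
    r = np.asarray(reference, dtype=float)
    if P.shape[1] != 2 or r.shape != (2,):
        raise ValueError("hypervolume_2d handles exactly two objectives")
    P = P[np.all(P < r, axis=1)]
    if len(P) == 0:
        return 0.0
    P = P[_nondominated_mask(P)]
    order = np.lexsort((P[:, 1], P[:, 0]))  # f1 ascending; f2 then descends
    hv = 0.0
    y_prev = r[1]
    for x, y in P[order]:
        if y < y_prev:
            hv += (r[0] - x) * (y_prev - y)
            y_prev = y
    return float(hv)


def igd(candidate_points, reference_front) -> float:
    """Inverted generational distance: mean over reference points of the
    Euclidean distance to the nearest candidate point (smaller is better)."""
    C = _points(candidate_points)
    R = _points(reference_front)
    if len(C) == 0:
        raise ValueError("candidate set is empty")
    if len(R) == 0:
        raise ValueError("reference front is empty")
    d = np.sqrt(((R[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def spacing(points, *, metric: str = "euclidean") -> float:
    """Schott spacing: sample standard deviation of each point's
    nearest-neighbour distance (0 means perfectly even)."""
    P = _points(points)
    if len(P) < 2:
        raise ValueError("spacing requires at least 2 points")
    diff = P[:, None, :] - P[None, :, :]
    if metric == "euclidean":
        d = np.sqrt((diff**2).sum(axis=2))
    elif metric == "manhattan":
        d = np.abs(diff).sum(axis=2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    return float(np.std(nn, ddof=1))


def union_reference_front(run_fronts: Sequence) -> np.ndarray:
    """Pool fronts from multiple runs/algorithms, deduplicate, and keep only
    the mutually non-dominated points."""
    arrays = [_points(f) for f in run_fronts if len(np.atleast_2d(f)) > 0]
    if not arrays:
        raise ValueError("all run fronts are empty")
    pooled = np.unique(np.vstack(arrays), axis=0)
    return pooled[_nondominated_mask(pooled)]


def sensitivity_hv(
    scenario_fronts: Mapping[object, np.ndarray] | Sequence[np.ndarray],
    *,
    margin: float = 0.0,
) -> tuple[dict | list, tuple[float, float]]:
    """Raw-scale hypervolumes of scenario fronts against one shared point.

    The global reference point is the component-wise maximum over all pooled
    points, inflated by ``1 + margin`` (default 0), so the per-scenario
    hypervolumes are comparable across scenarios by construction.  Returns
    the per-scenario values (same container kind as the input) and the
    reference point used.
    """
    if isinstance(scenario_fronts, Mapping):
        keys = list(scenario_fronts)
        fronts = [_points(scenario_fronts[k]) for k in keys]
    else:
        keys = None
        fronts = [_points(f) for f in scenario_fronts]
    if not fronts:
        raise ValueError("no scenario fronts supplied")
    pooled = np.vstack(fronts)
    ref = pooled.max(axis=0) * (1.0 + margin)
    values = [hypervolume_2d(f, ref) for f in fronts]
    reference = (float(ref[0]), float(ref[1]))
    if keys is not None:
        return dict(zip(keys, values)), reference
    return values, reference


@dataclass(frozen=True)
class IndicatorReport:
    """Aggregated benchmarking indicators over several seeded runs."""

    hv: float
    igd: float
    spacing: float
    hv_std: float
    igd_std: float
    spacing_std: float
    per_run: tuple[dict, ...]
    reference_point: tuple[float, float]
    reference_front: np.ndarray
    bounds: NormalizationBounds
    runs: int

    def to_dict(self) -> dict:
        return {
            "hv": {"mean": self.hv, "std": self.hv_std},
            "igd": {"mean": self.igd, "std": self.igd_std},
            "spacing": {"mean": self.spacing, "std": self.spacing_std},
            "per_run": list(self.per_run),
            "reference_point": list(self.reference_point),
            "reference_front": self.reference_front.tolist(),
            "bounds": {"mins": list(self.bounds.mins), "maxs": list(self.bounds.maxs)},
            "runs": self.runs,
        }


def benchmark_report(
    run_fronts: Sequence,
    *,
    reference_point: tuple[float, float] = (1.2, 1.2),
    spacing_metric: str = "euclidean",
) -> IndicatorReport:
    """Score each run front in normalized space against the pooled union
    reference front.

    Normalization bounds are the min/max of the pooled union reference set,
    so the reference front spans [0, 1] per objective; individual run points
    may fall outside that box.  Spacing of single-point fronts is reported
    as 0 (a lone solution has no unevenness to measure).
    """
    ref_front = union_reference_front(run_fronts)
    bounds = NormalizationBounds.from_points(ref_front)
    if bounds.degenerate_objectives:
        raise ValueError(
            "pooled reference front is degenerate in objective(s) "
            f"{bounds.degenerate_objectives}; indicators are not comparable"
        )
    ref_norm = normalize(ref_front, bounds)

    per_run = []
    for front in run_fronts:
        F = normalize(front, bounds)
        per_run.append(
            {
                "hv": hypervolume_2d(F, reference_point),
                "igd": igd(F, ref_norm),
                "spacing": spacing(F, metric=spacing_metric) if len(F) >= 2 else 0.0,
            }
        )
    def agg(key: str) -> tuple[float, float]:
        vals = np.array([r[key] for r in per_run])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    hv_m, hv_s = agg("hv")
    igd_m, igd_s = agg("igd")
    sp_m, sp_s = agg("spacing")
    return IndicatorReport(
        hv=hv_m,
        igd=igd_m,
        spacing=sp_m,
        hv_std=hv_s,
        igd_std=igd_s,
        spacing_std=sp_s,
        per_run=tuple(per_run),
        reference_point=reference_point,
        reference_front=ref_front,
        bounds=bounds,
        runs=len(per_run),
    )
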