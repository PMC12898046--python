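# Methods

## The planning model

The package plans one year of post-discharge follow-up. A general hospital
contracts regional medical centers (RMCs); each RMC supervises primary
health centers (PHCs) that can deliver follow-up only under their RMC's
contract (an RMC counts as its own supervisor, so selecting an RMC or any of
its PHCs triggers exactly one contract). Community demand points aggregate
discharged patients: `n_j` patients per year at point `j`, split over
patient types `k` with proportions `p_jk`. A type-`k` patient receives
`F_k1` facility visits and `F_k2` home visits per year, consuming `e_k1` and
`e_k2` capacity units per visit respectively.

Two objectives are minimized jointly: the patients' own cost of obtaining
care (travel to facility visits at `h1_per_dist` currency per distance unit,
plus a flat per-home-visit charge) and the hospital's total cost
(contracting fees `C1`, per-visit service costs — flat for facility visits,
distance-proportional for home-visit provision — and capacity-building at
`C2` per unit). Because both a patient-side and a provider-side cost grow
with the facility–community distance `d_ij`, proximity is economically
endogenous; the solver additionally *enforces* it through the allocation
rule below.

Model assumptions worth stating explicitly:

- demand is deterministic (annual averages); no patient choice behaviour —
  assignment is planner-driven and never splits a community;
- costs are linear in visits, patients and distance; no congestion,
  overtime or batching effects;
- the planning horizon is a single year; contracts are annual and atomic.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| `C1` | contracting fee per RMC | 10,000 | currency/year |
| `C2` | capacity-building cost | 50 | currency/capacity unit |
| `F1`, `F2` | facility / home visits | 6, 10 | visits/(patient·year) |
| `e1`, `e2` | capacity per facility / home visit | 2, 3 | units/visit |
| `c1_base` | provider cost per facility visit | 80 | currency/visit |
| `c2_per_dist` | provider cost per home visit | 60·d | currency/visit |
| `h1_per_dist` | patient travel cost per facility visit | 30·d | currency/visit |
| `h2_base` | patient cost per home visit | 50 | currency/visit |

Currency and distance units are abstract; no conversion layer is offered.
One patient-year under the defaults consumes `2·6 + 3·10 = 42` capacity
units — the anchor for all capacity arithmetic. Per-(facility, demand, type)
cost tables may override any of the four affine forms when calibrated data
exist.

## Allocation, contracts, capacity

Given a selection, each demand point is assigned to the nearest selected
facility; ties break toward the lower facility index in file order
(determinism — the tie rule is otherwise arbitrary). When an explicit
per-facility capacity cap is supplied, demand points are processed in
descending annual workload and each takes its nearest selected facility with
sufficient *remaining* capacity — the overflow-to-next-nearest rule — and an
infeasibility error names the shortfall when the caps cannot absorb total
workload. The processing order is a design choice (largest-first packs
tight caps more reliably and is deterministic); no cap is the default, since
the capacity variable `w_i` is itself costed through `C2` and its minimal
feasible value — the induced workload — is therefore the canonical choice
the evaluator fixes.

Contracts are derived, not searched: the minimal feasible contract vector
sets `y_i = 1` exactly for RMCs that are selected or supervise a selected
PHC. Any larger vector only adds `C1` multiples.

## The evolutionary engine

The genome is one real key in [0, 1] per candidate facility, decoded at
threshold 0.5. This random-key encoding keeps the search space binary while
letting the variation hyperparameters — SBX crossover with distribution
index 2, polynomial mutation with index 5 — act on a real vector, which is
the setting in which those indices are defined. A configuration switch
(`operators="binary"`) provides uniform crossover and per-gene bit-flip on
0/1 keys for comparison.

Chromosome construction is three-staged: stochastic selection, proximity
allocation, and a consistency repair that deselects every selected facility
with zero allocated demand (its key is mapped back below threshold by
`(key − 0.5)·0.999`, preserving genetic variation). Repair only removes
facilities; an all-zero decode is rescued deterministically by
force-selecting the largest key. Re-running allocation after repair is
unnecessary: removed facilities served nothing, so the assignment is
unchanged.

Selection pressure: 100 *independent probabilistic binary* tournaments per
generation on (rank, crowding distance), the better individual winning with
probability 0.9. (A single deterministic tournament among 100 individuals
would collapse diversity to the current best; the repeated-binary reading is
the one implemented, and this interpretation is a documented choice, not an
attribution.) Survivors of the combined parent+offspring population are
taken front by front, the last partial front truncated by crowding distance
— standard elitist NSGA-II. Crossover probability defaults to 0.9 and
mutation to 1/n per gene, standard practice where no value is prescribed;
population 100 and 500 generations are the study defaults, scaled down in
tests (60 generations suffice for exact-front agreement on ≤10-facility
instances, as the oracle comparison verifies).

The reported front is the final population's rank-0 set, deduplicated by
selection vector (first occurrence kept); duplicates are retained *during*
search to avoid biasing crowding.

## Exact oracle

`enumerate_front` enumerates all `2^n − 1` non-empty selections (guard:
n ≤ 16), pushes each through the identical plan construction, deduplicates
by repaired selection — cosmetically distinct selections that repair to the
same operating plan are one solution — and filters to the non-dominated set.
It is the ground truth the engine is tested against: no returned vector may
be dominated by an enumerated one, and the union of seeded runs must cover
the exact front.

## Indicators

- `hypervolume_2d`: exact sort-and-sweep union-of-rectangles measure for
  bi-objective minimization; validated against a 10^6-sample Monte-Carlo
  estimate in the test suite.
- `igd`: mean distance from each reference-front point to its nearest
  obtained point.
- `spacing`: sample standard deviation (ddof = 1) of each point's
  nearest-neighbour distance, Euclidean by default with a Manhattan option —
  the literature carries both variants and no single formula is canonical;
  the choice is configurable and recorded here rather than attributed.

Two protocols wrap these. **Benchmarking** pools all runs' fronts into a
union reference front, min–max normalizes by that front's bounds (so the
reference spans [0,1] per objective — the bound source is a documented
choice), scores HV at (1.2, 1.2) plus IGD and spacing, and aggregates
mean ± std over seeds (20 by default). **Sensitivity scoring** stays in raw
currency units: all scenario fronts share one global reference point, the
component-wise maximum of the pooled points (margin configurable, default
0), making hypervolumes comparable across parameter levels; the resulting
magnitudes are currency² and reach 10^9–10^11 at district scale. Sweeps
reuse identical seed lists across levels so differences reflect parameters,
not sampling noise.

## Synthetic instances

The real district data behind the case study are not public, so a seeded
generator emulates their structure: 29 RMCs uniform over a 9×9 (km-like)
extent — the study area is ~75 km² — each with 1–3 PHCs scattered normally
(σ = extent/20) around it; 28 communities, 726 patients/year; 65% of
patients concentrated in 4 dense communities confined to the eastern third
of the extent, the remainder spread uniformly (the case study describes a
few dense communities on one side and many sparse ones). Patient totals
split by Dirichlet(2)-multinomial within each stratum, every community
keeping at least one patient when totals permit. PHC counts per RMC, the
extent, and the 65% cluster share are the package's own modelling choices
where the source setting is qualitative.

What the generator does *not* emulate: road-network distances (Euclidean by
default, with an explicit matrix override for road data), demand
uncertainty, patient no-shows, and heterogeneous per-facility cost
structures. Passing tests therefore demonstrate correctness of the
optimization machinery under the stated cost model, not predictive validity
for any real district.

Small test instances scale patient totals down with facility counts
(60–100 patients on 6–10 facilities): at full district demand the
distance-proportional terms dwarf the contracting fee and the Pareto front
degenerates to a single point, whereas the scaled instances preserve the
contract-count-versus-distance trade-off that makes oracle comparisons
informative.

## Numerical choices and degenerate inputs

- Distance ties and workload-order ties break by file-order index.
- Proportion vectors must sum to 1 within 1e-9; distances are validated
  non-negative and finite.
- Capacity feasibility uses a 1e-12 slack on residuals and 1e-9 on
  totals to absorb float accumulation.
- Objective comparisons in tests round to 6 decimals before set membership;
  all objective arithmetic is double precision, exact for the integer-valued
  defaults.
- Crowding distance on fronts of ≤ 2 points is +inf (boundary rule); a
  zero-range objective contributes no gap.
- Empty candidate sets, empty reference fronts, degenerate normalization
  bounds and sub-2-point spacing all raise named errors rather than
  returning sentinel values.

## Known limitations

- The exhaustive oracle is exponential; beyond 16 facilities only heuristic
  self-consistency (single-front, feasibility, repair invariants) is
  checkable.
- Uncapped allocation makes constraint (capacity) non-binding by
  construction; capped behaviour depends on the documented largest-first
  overflow order, one of several defensible rules.
- The engine is single-threaded and evaluates ~10^4 plans/second at
  district scale; many-objective (>2) fronts are out of scope.
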