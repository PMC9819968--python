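# Methods

## Accounting model

The pipeline implements consumption-based ecological footprint accounting
in "provincial hectares": standardized hectares referenced to provincial
(not global) average yields. The reference frame is carried entirely by the
packaged constant tables — per-item average yields `Y_i` (kg/hm²), energy
conversion coefficients, and per-land-type equivalence (`r_j`) and yield
(`y_j`) factors — so no code path distinguishes provincial from global
hectares.

Per-capita footprint of the biological account, by land type *j*:

    ef_j = Σ_{i on j} r_j · C_i / Y_i

with `C_i` per-capita consumption. Energy items are converted through
low calorific value: `area_i = C_i · q_i / D_i · r_j`, where `q_i` is GJ
per declared consumption unit and `D_i` the energy-footprint density
(GJ/hm²). Fossil fuels accumulate on carbon-capture land, electricity on
built-up land (which carries cropland-row factors 3.39/1.74 in the default
table).

Per-capita carrying capacity: `ec_j = a_j · r_j · y_j · 0.88`, the 0.12
deduction being the biodiversity set-aside. Carbon-capture land has yield
factor 0, hence zero capacity always. The aggregate balance
`ED = (Σ ef_j − Σ ec_j) · N` is positive in deficit. The capacity sum
includes all six land types; land types without a supplied area default to
zero capacity (logged, since area tables rarely cover all types).

### Three-dimensional indicators

    EF_size  = Σ_j min(EF_j, EC_j)
    EF_depth = 1 + Σ_j max(EF_j − EC_j, 0) / Σ_j EC_j
    EF3D     = EF_size × EF_depth

Two candidate formulations of depth circulate: netting the regional
aggregate (`1 + max(ΣEF − ΣEC, 0)/ΣEC`) and the per-land-type form above.
The per-land-type form is implemented as canonical: aggregate netting lets
a forest surplus cancel a grazing deficit and understates stock depletion
(on any account with one surplus and one deficit type the revised depth is
strictly larger — a tested invariant). When every land type is in surplus,
depth is exactly 1 ("original length"). Depth is undefined when ΣEC = 0
(raised as an error); the per-land-type depth `max(1, EF_j/EC_j)` is
undefined (NaN) when `EC_j = 0 < EF_j`, which is always the case for
carbon-capture land with any fossil consumption.

Indicators are computed on totals; per-capita reporting divides size (and
EF3D) by population — depth is scale-free. Both variants are exposed and
flagged on the result object.

### Numerical choices

- **Balance-point guard.** Per-type deficits below `1e-12 · max(EF_j, EC_j)`
  are treated as zero in the depth numerator, and per-type depth ratios
  within `1e-12` of 1 snap to 1. Inputs that round-trip through CSV land a
  few ulp away from exact balance; without the guard a balanced land type
  would report depth `1 + O(1e-16)` instead of 1.
- Coefficients of variation use the sample (n−1) standard deviation,
  reported in percent. Change statistics report absolute change, percent
  change, and the geometric annualized rate
  `100·((end/start)^{1/years} − 1)`; ratio outputs are NaN for a
  non-positive start. The geometric convention for "average annual growth"
  is an assumption — published annual-change figures cannot be reconciled
  without the underlying yearly values.
- Negative inputs (consumptions, areas, factors) are rejected at load time,
  not clamped.

## Sustainability typology

City-years are standardized jointly across the whole panel ((x − mean)/sd,
sample sd) — one shared plane, not per-year — and clustered by
agglomerative hierarchical clustering with Ward linkage on Euclidean
distance, cut at k = 4 ("systematic clustering" in the regional-footprint
literature denotes exactly this hierarchical procedure; the linkage is
configurable). The four types are ordered by increasing sustainability:

1. high size, high depth (least sustainable),
2. low size, moderate depth,
3. moderate size, moderate depth,
4. moderate size, low depth (most sustainable).

The literature defines the types verbally but not the cluster→type mapping.
The implemented rule is centroid-based: among clusters whose mean z_size
lies at or above the panel median z_size, the one with the highest mean
z_depth becomes Type 1; the remaining three are ranked by decreasing mean
z_depth into Types 2–4, ties broken by descending mean z_size. On archetype
panels built from the verbal quadrant definitions this rule recovers the
planted labels; it is a design choice, documented as such. Joint clustering
of all city-years (rather than one clustering per year) is the default for
the same shared-plane reason.

## Random-forest OOB permutation importance

Responses are `ln EF_size` (per capita) and `ln EF_depth` — both indicators
are exponential-type quantities, so logs linearize the scale — regressed on
X1–X9 for each panel year separately and for all years pooled.

The forest is built in-package so that in-bag/out-of-bag index sets are
explicit: each of n_trees (default 500) CART regression trees (scikit-learn
`DecisionTreeRegressor`) is fitted on a size-n bootstrap sample with
`mtry = max(1, p//3)` features tried per split (3 for p = 9) and minimum
leaf size 5. Per tree t, the OOB error is
`MSE_t = mean_{i∈OOB_t}(y_i − ŷ_{i,t})²`. For variable ν, its values are
permuted *within each tree's OOB rows* (a fresh draw per tree from a
seeded, per-variable stream) and the error recomputed as `MSE_t(ν)`. Then

    VI(ν) = (1/n) Σ_t (MSE_t(ν) − MSE_t),     R(ν) = VI(ν) / Σ_ν VI(ν).

The sign convention is the standard "error increase"; negative VI (a
shuffle that happened to improve OOB error — noise) is truncated to zero
before normalization so ratios stay in [0, 1] (an absolute-value policy is
selectable). Category ratios sum R(ν) over economic {X1, X2}, social
{X3–X5} and environment {X6–X9}. Goodness of fit is OOB R²:
`1 − mean((y_i − ŷ_i^OOB)²)/var(y)`, each observation predicted by
averaging the trees for which it is out of bag; never-OOB observations are
excluded with a warning. Permuting the full column once per variable
(instead of per tree) is a known alternative; the per-tree OOB permutation
is the standard OOB algorithm and is the default here.

Small-sample behavior: on an 8-city single-year slice a fixed leaf of 5
forbids any split, so the effective minimum leaf is capped at n//4 (never
above the configured value) and a loud warning is emitted below n = 15 —
OOB statistics on such slices rest on ~3 observations per tree. If, after
truncation, every VI is zero on a slice (typical when the response carries
no signal at n = 8), that slice's ratios are reported as NaN with a warning
rather than failing the run. Trees with an empty OOB set (vanishingly rare
for n ≥ 8) are excluded from OOB statistics.

## Synthetic panel generator

Real yearbook inputs are not redistributable, so the generator emulates the
study conditions: an 8-city × 4-year panel whose per-capita EF_size spans
0.2–0.6 hm²/cap and whose EF_depth spans 1–61 — the magnitude range
observed for a mid-sized, cropland-dependent Chinese urban agglomeration.

- Indicators X1–X9 are drawn from fixed log-normal/uniform marginals with
  plausible magnitudes in yearbook units (e.g. GDP ~ lognormal(ln 1.5e7,
  0.8) RMB 10⁴; greenery coverage ~ U(25, 45)%). These are documented
  constants, not fits to any observed city.
- The planted signal sets `ln EF_depth = β₀ + β₁·z(ln X8) + β₂·z(ln X9) + ε`
  with defaults β = (2.0, 0.9, −0.5) and ε ~ N(0, 0.25); depth is clipped
  into the configured range. EF_size is drawn uniformly on its range,
  independent of the indicators.
- Consumptions and land areas are **back-solved** through the accounting
  equations rather than drawn directly: flow-side land types get balanced
  `EF_j = EC_j` in fixed shares (croplands 80%, forests 7%, grazing 5%,
  fishing 3%, built-up 5%), and the stock deficit `(depth − 1)·size` is
  placed 60% on carbon-capture land (raw coal), 30% on grazing and 10% on
  fishing grounds, so per-land-type depths vary realistically. One
  representative item per land type is inverted (`C = ef_j·Y/r`, etc.).
  Every synthetic run therefore exercises the full accounting arithmetic,
  and with zero noise the pipeline reproduces the planted size/depth to
  float precision (tested at 1e-9 relative).
- The archetype generator samples (size, depth) around four centroids
  matching the verbal type definitions — (0.55, 50), (0.22, 28),
  (0.40, 12), (0.45, 2.5) with sd (0.015, 0.8) — and returns ground-truth
  labels for recovery tests.

What passing synthetic tests do **not** show: the marginals are neither
correlated across indicators nor autocorrelated in time the way real city
panels are, consumptions are concentrated on one item per land type, and
the size signal is deliberately absent. Recovery rates measured here bound
the method's behavior under its own assumptions, not its accuracy on any
particular real agglomeration.

## Problem sizes and defaults

Recovery experiments use 50-seed batches of 200-observation panels
(50 cities × 4 years, 500 trees) for importance and 100-seed batches of
4 × 8 archetype points for typology; both choices keep a full run of the
experiments around a minute while leaving the per-run sample sizes at the
scale the estimators need. Published-table statistics (coefficients of
variation, category averages, change statistics) are recomputed from the
packaged reference CSVs for the Chengdu urban agglomeration.

## Known limitations

- No trade-corrected (apparent-consumption) accounting; direct consumption
  only.
- No uncertainty propagation through the factor tables.
- The cluster→type mapping rule and the electricity consumption unit
  (10⁴ kWh per declared unit, configurable) are documented conventions
  where the published material is silent or ambiguous.
- Ward clustering can, rarely, absorb a single boundary point of one
  archetype into a neighboring cluster; typology recovery is reported per
  seed rather than assumed perfect.
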