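# Methods

## Model

An assemblage is a multinomial sample: `n[i]` artifacts classified into
`T ≥ 3` historical types, with plug-in proportions `f[i,t]`. The
deterministic frequency-seriation (DFS) model holds that, within a single
interacting tradition observed through comparable-duration deposits,
every type's expected proportion is unimodal along the true (temporal or
interaction-gradient) order, and change between neighbors is continuous.
An ordering is *valid* when every type's comparison-sign sequence matches
`[+0]*[-0]*` (rises, possibly with plateaus, then falls; flat and
monotone sequences are special cases) and every adjacent pair lies within
the continuity threshold. Validity is invariant under reversal —
seriation yields an order, not a direction — so orders are canonicalized
to the lexicographically smaller of (sequence, reversed sequence).

Two properties carry the algorithm:

* **Hereditarity.** Any contiguous sub-window of a valid order is valid:
  its sign sequences are substrings (no new `+` can appear after a `-`)
  and its adjacent pairs are a subset. Agglomeration from valid triples
  therefore reaches every valid order, and an order with no valid
  extension is exactly an order that is not a proper sub-window of a
  larger valid order. The brute-force enumerator in `idss.search` is kept
  as an independent oracle for this equivalence on small instances.
* **Monotonicity.** Raising the continuity threshold, or widening the
  confidence bands (smaller α), can only grow the set of valid orders.
  Both are asserted as property tests.

## Statistical comparisons

Confidence bands are percentile bootstrap intervals: each assemblage row
is resampled as a multinomial at its own row total `B` times (default
`B = 1000`), and the band is the `[α/2, 1−α/2]` percentile interval of
the resampled proportions, clamped to contain the plug-in point. A type
with zero count has band exactly `[0, 0]` (resampling cannot invent an
absent type); a type comprising the whole assemblage has `[1, 1]`. Bands
are computed once per assemblage and reused for all pairs; under the
interval-overlap match rule this is identical to recomputing per pair.
Per-assemblage RNG substreams are keyed by a SHA-256 hash of the
assemblage id combined with the run seed, so band values do not depend on
row order in the input file.

Two MATCH rules are provided: `overlap` (default — closed intervals
overlap; symmetric and the most conservative) and `point_in` (either
point falls inside the other assemblage's band; nested strictly between
overlap and raw comparison). Raw mode compares point proportions, with
exact ties scoring MATCH. All three are antisymmetric by construction.

Percentile rather than BCa intervals: the simplest method consistent with
multinomial resampling, and deterministic under a seed. Coverage of the
95% band is verified empirically (within 3 points of nominal at n = 100).

## Search

Seed triples enumerate the three canonical arrangements of every
3-subset. Extension tries each unused assemblage at both ends of each
frontier order; the continuity check applies to the new terminal pair
(the interior pairs were checked when they became terminal). Frontiers
and outputs are iterated in lexicographic order, so all output files are
byte-stable given the input and seed. A configurable frontier budget
(default 2 × 10⁶) makes the search refuse, rather than silently
subsample, when a permissive configuration explodes.

Continuity defaults to adjacent pairs and the per-type-max gap. The
all-pairs variant (threshold between *every* pair in an order) and the
summed-across-types gap are switches; all four combinations are valid
readings of the informal method description, and the worked-example runs
record which was used.

**Which combination reproduces the published ceramic atlas.** On the
packaged 20-assemblage dataset at threshold 0.30, raw point comparisons
with per-type-max adjacent-pair continuity give 97 maximal solutions with
the largest of size 4 (and 123 valid orders before maximality filtering),
deterministically. Bootstrap-band comparisons at α = 0.05 give larger
atlases (from 21 to ~10⁴ solutions depending on match rule and
continuity variant) and longer chains — overlap matching is conservative
enough that many statistically-equivalent assemblages interleave. The
acceptance script therefore runs and records the raw-comparison
combination.

## Solution graphs

Aggregate graph: union of solution path graphs; edge weight is the
frequency distance between endpoints (Euclidean by default, summed-L1 as
option), edge provenance lists contributing solutions. The minmax
reduction scans edges in ascending (weight, endpoints) order, accepting
component-joining edges (Kruskal) and, within a tied-weight group
(tolerance 1e-12), also edges touching a vertex first connected at that
weight — so equally good alternatives stay visible. `--keep-all-ties`
retains every tied edge. The non-tie skeleton's total weight equals the
minimum spanning forest weight, verified against exhaustive spanning-tree
enumeration on small graphs. Disconnected aggregates yield one tree per
component. Hubs (degree ≥ 3) and the connected groups left after removing
them are reported descriptively as branch hypotheses, not tested claims.

## Spatial test

Default statistic (`geo_edge_sum`): the sum of planar Euclidean
geographic distances along minmax edges; the null permutes the
coordinate-to-assemblage assignment, holding graph topology fixed. The
alternative (`freq_pair_sum`) sums frequency distances over the edges
against same-cardinality random edge sets. Both use a one-sided
lower-tail p (clustering = small sums) with the add-one correction
`p = (1 + #{null ≤ obs}) / (1 + R)`, so `p > 0` always. Coordinates are
treated as planar; study areas at the scale this method serves do not
warrant geodesic handling. Under a null of coordinates independent of
frequencies, the p distribution is uniform to KS < 0.15 over 200 seeds
(tested). The spatial p for the packaged ceramic data is *not*
reproducible here: the site coordinates are not distributed with the
counts, and the test refuses to run without real coordinates.

## Synthetic generators

The generators produce count matrices with known ground truth, as
fixtures for the oracle tests and as planted-recovery benchmarks.

* **Lineage** — triangular partition-of-unity curves: peaks spaced `d`
  apart with half-width `overlap · d`, padded beyond the axis so every
  row sums to 1 exactly and every step changes each active type by the
  same amount. The overlap is the smallest whose uniform step fits under
  `max_adjacent_gap` (sharpest identifiable signal); for 15 assemblages
  and 6 types under a 0.10 cap this gives a 0.0536 step. In
  exact-frequency mode (`sample_size=None`) counts are scaled integers at
  denominator 10⁵ via largest-remainder rounding (perturbation ≤ 10⁻⁵
  per cell), and the planted order is provably the unique maximal
  solution at threshold = gap cap, because any skip doubles the step.
* **Branching** — a stem splitting into two arms, built from a closed
  per-step budget: declining and rising stem ramps, a balance type that
  funds the arm novelties, a divergent type pushed up by one arm and down
  by the other (cross-arm pairs exceed the continuity threshold), and
  two arm-rate types rising fast in their own arm and slowly in the other
  (junction-crossing orders trough). Verified against brute-force
  enumeration: exactly the two planted lineages are maximal.
* **CI fork** — a well-sampled stem with two smaller candidate
  continuations. Each fork *loses* one persistent low-frequency type the
  other keeps (zero counts give exact `[0,0]` bands, so fork-vs-fork
  comparisons are significant at any α), both share a novelty absent from
  the stem (which kills the fork–stem–fork arrangement), and one fork
  carries a half-percent non-monotonicity that raw comparisons reject but
  confidence bands absorb. Bootstrap comparisons therefore yield exactly
  two maximal solutions sharing the stem; raw comparisons keep one.

What the generators do **not** emulate: closed-array compositional
artifacts of real typologies, sample-size heterogeneity beyond the fork
fixture, type extinction/re-introduction, spatially structured sampling
error, or drift simulated from an explicit transmission process. Passing
the planted-recovery tests shows the search recovers structure the DFS
model can express, not that real assemblages satisfy the model.

## Recovery under sampling noise: a sharp limit

With multinomial sampling at `n = 1000` per assemblage, proportion
differences carry noise of roughly 0.012–0.021 sd. Unique recovery of a
planted order at threshold τ requires every legitimate adjacent step to
stay below τ *and* every two-step gap to exceed τ (skip-orders are always
jointly unimodal, so only continuity can exclude them, and for unimodal
curves a two-step gap is at most twice a one-step gap). The feasible
per-step signal therefore sits in `(τ/2, τ]`, leaving a margin of `τ/4`
on each side — about 1.2–2 noise sd at τ = 0.10 — multiplied over 14
adjacent pairs and 13 skip positions. Measured consequence (100 seeds,
15 × 6 lineage, τ = 0.10, α = 0.05 bands): the planted order is the
unique maximal solution in 17% of seeds and among the maximal solutions
in 62%. At τ = 0.15 — 1.5× the construction gap, giving the truth order
sampling headroom while still excluding most rivals — the planted order
is valid in 99/100 seeds and among the maximal solutions in 99/100; the
reproducibility suite tests recovery at that threshold and documents this
choice. Tight-threshold unique recovery at n = 1000 is a statistical
impossibility for any curve family, not an implementation artifact.

## Numerical and interface choices

* Zero row totals, duplicate labels, fewer than 3 types, and malformed
  cells are hard input errors; all-zero type columns are retained but
  flagged (they contribute nothing to comparisons but keep column
  indexing stable). Sample-size screening (traditional floor: 50) is
  advisory by default, a hard gate under `--strict-n`.
* Frequencies are written at 6 decimals; integer count matrices
  round-trip bit-identically.
* Weight-tie tolerance in the minmax scan: 1e-12 (weights are sums of
  few-term float expressions; real ties arise from identical rows or
  symmetric constructions and survive this tolerance).
* Battleship SVGs are emitted as hand-built SVG text so identical inputs
  produce byte-identical files; whiskers show the upper band as a thin
  line and the lower band as a thick overlay, and `[0,0]` bands draw
  nothing.
* Problem sizes in the test suite: oracle equivalence on 50 random
  instances of 4–7 assemblages; coverage on 500 simulated assemblages of
  size 100; recovery benchmarks on 100 seeds of the 15 × 6 lineage;
  spatial calibration on 200 seeds at 199 resamples. The full suite and
  the acceptance script each run in well under typical CI budgets.

## Known limitations

* Continuity distances are always measured on raw frequencies, under
  either comparison mode: a band-adjusted distance would make the
  continuity criterion α-dependent and conflate the two model
  requirements. The all-pairs continuity reading is implemented but
  lightly exercised; the worked example uses adjacent-pair continuity.
* No occurrence (presence/absence) seriation, no typology construction,
  no closed-array correction, and no heuristic fallback for very large
  collections — the search refuses beyond its frontier budget rather
  than approximate.
* Which end of a seriation is "early" is not identified; orientation
  requires external evidence (stratigraphy, dates).
* The minmax tie-retention rule keeps ties competitive at the weight
  where a vertex first joins; whether cycle-closing ties among
  already-connected vertices should also be kept is genuinely
  underdetermined — `--keep-all-ties` implements the liberal reading.
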