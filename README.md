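# idss — iterative deterministic frequency seriation

Frequency seriation orders archaeological assemblages so that the relative
abundance of every historical (stylistic) artifact type rises to a single
peak and falls again along the order — the lens-shaped "battleship curves"
that underwrote relative chronology for much of the twentieth century, and
that neutral cultural-transmission theory now explains: under drift within
an interacting population, type frequencies change unimodally through time
and continuously across neighbors. Deterministic frequency seriation (DFS)
demands an exact fit to that model rather than a probabilistic best fit,
which makes violations informative — they mark boundaries in space, time,
or interaction — but brute-force search over orderings is hopeless beyond
a dozen assemblages.

This package implements the iterative deterministic seriation search
(IDSS): an agglomerative, exhaustively pruned search that returns **all**
maximal valid orderings, plus the statistical and graph machinery around
it. It is written for archaeologists and students of cultural transmission
working with count matrices of assemblages by types.

## The method

Given a count matrix `n[i,t]` (assemblage `i`, type `t`) with proportions
`f[i,t] = n[i,t] / n[i]`, an ordering `a_1 … a_k` is **valid** when

* **joint unimodality** — for every type `t`, the sign sequence of
  successive comparisons `f[a_(j+1), t]` vs `f[a_j, t]` never rises again
  after falling (it matches `[+0]*[-0]*`), and
* **continuity** — adjacent assemblages differ by at most a threshold
  `τ`, measured either as `max_t |Δf_t|` (default) or `Σ_t |Δf_t|`.

Comparisons are trichotomous: *greater*, *less*, or *matching* when the
difference is not statistically resolvable. Matching is assessed against
percentile bootstrap confidence bands — each assemblage is resampled
multinomially at its own sample size, and two cells match when their
`(1−α)` bands overlap. A matching comparison is compatible with either
direction of change, so statistically equivalent assemblages can
participate in several orderings. Direct (raw) point comparisons are
available as `--comparison raw`.

The search seeds itself with every valid triple, then repeatedly extends
each frontier order by one unused assemblage at either end, keeping valid
extensions. Because every contiguous sub-window of a valid order is valid,
this agglomeration reaches every maximal solution while pruning the
factorial remainder of permutation space. The atlas of maximal solutions
is then aggregated into a single weighted graph (edges = adjacencies in
any solution, weights = frequency distance) and reduced to the **minmax
graph**: the fewest, smallest-weight edges connecting every participating
assemblage, with equal-weight ties retained. Branches of the minmax graph
are hypotheses about lineages and the structure of transmission, and a
coordinate-permutation test quantifies whether its edges are spatially
clustered.

## Worked example

The package ships the classic worked dataset: 20 late prehistoric
decorated ceramic assemblages from the Memphis and St. Francis areas of
the Mississippi River Valley (Phillips–Ford–Griffin survey collections),
counted over 10 decorated types.

```sh
idss seriate src/idss/data/pfg_ceramics.tsv \
    --comparison raw --threshold 0.30 --seed 1 --out pfg
```

prints

```
97 maximal solutions (largest: 4 assemblages, 123 valid orders examined)
outputs in pfg/
```

No single chronological order exists for these 20 assemblages: the search
finds 97 distinct maximal orderings, none longer than 4 assemblages,
because local interaction structures the data more strongly than time.
The first lines of `pfg/solutions.txt`:

```
10-P-1 -- 12-O-5 -- 11-N-1
10-P-1 -- 12-O-5 -- 11-N-9
10-P-1 -- 12-O-5 -- 11-O-10
```

`pfg/minmax.graphml` (also exported as graphviz `.dot`) holds the reduced
graph, in which the Parkin site (11-N-1) appears as a degree-3 hub with
branches toward 11-N-9, 13-P-1 and 11-O-10 — the signature of a central
node interacting with several otherwise-separate communities.
Per-solution battleship plots with bootstrap whiskers are written under
`pfg/battleship/`, and `pfg/report.json` records the full configuration
and outputs. Supply site coordinates (`--xy coords.csv`, rows `id,x,y`)
to run the spatial clustering test on the minmax edges.

From Python:

```python
import idss

counts = idss.pfg_ceramics()
cfg = idss.SearchConfig(comparison_mode="raw", continuity_threshold=0.30, seed=1)
atlas = idss.idss_search(counts, cfg)
len(atlas)            # 97
atlas.max_size        # 4
```

Synthetic instances with planted ground truth (single lineages, branching
lineages, confidence-interval forks) are available via `idss.synthetic`
or `idss synth` on the command line.

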