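"""The iterative deterministic seriation search.

A valid order of assemblages is one in which every type's frequency
sequence is jointly unimodal (rises, possibly plateaus, then falls — never
trough-then-rise) and every adjacently placed pair of assemblages differs
by no more than a continuity threshold. The search seeds itself with all
valid triples and grows them one assemblage at a time at either end,
keeping every extension that still satisfies both criteria. Because any
contiguous sub-window of a valid order is itself valid, growing from valid
building blocks is guaranteed to reach every maximal valid order while
pruning the combinatorially vast remainder of permutation space.

A brute-force enumerator over all permutations of all subsets is provided
as an independent oracle for small instances.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bootstrap import ConfidenceBands, bootstrap_bands, comparison_matrix
from .types import AssemblageCounts, FrequencyMatrix, SearchConfig, compute_frequencies

Sign = str  # one of "+", "0", "-"


class SearchError(RuntimeError):
    pass


class FrontierBudgetExceeded(SearchError):
    """The extension frontier outgrew ``max_frontier``; the search refuses
    to continue rather than silently subsample the solution space."""


def canonical(order: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical form of an order: an order and its reversal are the same
    seriation solution (seriation directionality is fixed externally), so
    the lexicographically smaller of the two represents both."""
    rev = order[::-1]
    return order if order <= rev else rev


@dataclass(frozen=True)
class SeriationOrder:
    """An ordered sequence of >= 3 distinct assemblage ids."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("repeated assemblage id in order")
        object.__setattr__(self, "ids", tuple(self.ids))

    def canonicalized(self) -> "SeriationOrder":
        return SeriationOrder(canonical(self.ids))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Certificate:
    """Why an order is valid: per-type sign sequences and per-adjacent-pair
    continuity distances under the config that produced it."""

    sign_sequences: dict[str, str]
    pair_distances: list[float]

    def to_dict(self) -> dict:
        return {
            "sign_sequences": self.sign_sequences,
            "pair_distances": [round(d, 10) for d in self.pair_distances],
        }


@dataclass
class SolutionSet:
    """The atlas: all maximal valid orders, canonicalized and deduplicated.

    ``orders`` is sorted lexicographically so output files are byte-stable.
    ``certificates`` is parallel to ``orders``. ``n_valid_orders`` counts
    every distinct valid order of length >= 3 encountered (maximal or not);
    the atlas itself retains only orders that admit no valid extension and
    are not contiguous sub-sequences of another member.
    """

    orders: list[tuple[str, ...]]
    certificates: list[Certificate]
    config: SearchConfig
    n_valid_orders: int = 0
    frontier_sizes: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.orders)

    @property
    def max_size(self) -> int:
        return max((len(o) for o in self.orders), default=0)

    def member_ids(self) -> list[str]:
        out: set[str] = set()
        for o in self.orders:
            out.update(o)
        return sorted(out)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_solutions": len(self.orders),
            "n_valid_orders": self.n_valid_orders,
            "max_size": self.max_size,
            "frontier_sizes": {str(k): v for k, v in self.frontier_sizes.items()},
            "solutions": [
                {"ids": list(o), "certificate": c.to_dict()}
                for o, c in zip(self.orders, self.certificates)
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def write_text(self, path: str | Path) -> None:
        """One solution per line, ids separated by ' -- '."""
        lines = [" -- ".join(o) for o in self.orders]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Order evaluation


def type_sign_sequence(
    order: tuple[str, ...] | SeriationOrder,
    type_name: str,
    bands: ConfidenceBands,
    *,
    comparison_mode: str = "bootstrap_ci",
    match_rule: str = "overlap",
) -> str:
    """Signs of successive comparisons along an order for one type.

    Position ``i`` encodes how ``order[i+1]`` compares with ``order[i]``:
    ``+`` if the later is GREATER, ``-`` if LESS, ``0`` on MATCH.
    """
    from .bootstrap import compare_pair, Comparison

    ids = order.ids if isinstance(order, SeriationOrder) else tuple(order)
    out = []
    for a, b in zip(ids, ids[1:]):
        c = compare_pair(
            bands, b, a, type_name,
            comparison_mode=comparison_mode, match_rule=match_rule,
        )
        out.append({Comparison.GREATER: "+", Comparison.LESS: "-",
                    Comparison.MATCH: "0"}[c])
    return "".join(out)


def is_unimodal(signs: str) -> bool:
    """True iff the sign string never rises again after having fallen.

    Accepts flat, monotone, and single-peak sequences; rejects any
    trough (a ``+`` occurring after a ``-``), i.e. the string must match
    ``0*(+|0)*(-|0)*``.
    """
    seen_minus = False
    for s in signs:
        if s == "-":
            seen_minus = True
        elif s == "+" and seen_minus:
            return False
    return True


def continuity_distance(
    a: str,
    b: str,
    freqs: FrequencyMatrix,
    mode: str = "per_type_max",
) -> float:
    """Frequency gap between two assemblages under the continuity criterion.

    ``per_type_max``: largest absolute difference in any single type.
    ``summed_across_types``: L1 distance across all types. Symmetric.
    """
    if a == b:
        raise ValueError("continuity distance requires two distinct assemblages")
    da = np.abs(freqs.row(a) - freqs.row(b))
    return float(da.max()) if mode == "per_type_max" else float(da.sum())


class _Evaluator:
    """Precomputed lookup tables so that order evaluation is O(len x types)."""

    def __init__(
        self,
        freqs: FrequencyMatrix,
        bands: ConfidenceBands,
        config: SearchConfig,
    ) -> None:
        self.freqs = freqs
        self.config = config
        self.ids = freqs.assemblage_ids
        self.index = {a: i for i, a in enumerate(self.ids)}
        self.codes = comparison_matrix(bands, config)  # (t, n, n)
        diff = np.abs(freqs.freqs[:, None, :] - freqs.freqs[None, :, :])
        if config.continuity_mode == "per_type_max":
            self.dist = diff.max(axis=2)
        else:
            self.dist = diff.sum(axis=2)

    def valid(self, order: tuple[str, ...]) -> bool:
        idx = [self.index[a] for a in order]
        thr = self.config.continuity_threshold
        if self.config.all_pairs_continuity:
            for i, j in itertools.combinations(idx, 2):
                if self.dist[i, j] > thr:
                    return False
        else:
            for i, j in zip(idx, idx[1:]):
                if self.dist[i, j] > thr:
                    return False
        codes = self.codes
        for t in range(codes.shape[0]):
            seen_minus = False
            row = codes[t]
            for i, j in zip(idx, idx[1:]):
                c = row[j, i]  # later vs earlier
                if c < 0:
                    seen_minus = True
                elif c > 0 and seen_minus:
                    return False
        return True

    def certificate(self, order: tuple[str, ...]) -> Certificate:
        idx = [self.index[a] for a in order]
        sign_map = {1: "+", 0: "0", -1: "-"}
        seqs = {
            t: "".join(
                sign_map[int(self.codes[k, j, i])]
                for i, j in zip(idx, idx[1:])
            )
            for k, t in enumerate(self.freqs.type_names)
        }
        dists = [float(self.dist[i, j]) for i, j in zip(idx, idx[1:])]
        return Certificate(sign_sequences=seqs, pair_distances=dists)


def evaluate_order(
    order: tuple[str, ...] | SeriationOrder,
    freqs: FrequencyMatrix,
    bands: ConfidenceBands,
    config: SearchConfig,
) -> tuple[bool, Certificate]:
    """Check joint unimodality of every type and continuity of every
    adjacent pair; return the verdict and the supporting certificate.

    The verdict is invariant under reversal of the order.
    """
    ids = order.ids if isinstance(order, SeriationOrder) else tuple(order)
    ev = _Evaluator(freqs, bands, config)
    return ev.valid(ids), ev.certificate(ids)


# ---------------------------------------------------------------------------
# Search


def _prepare(counts: AssemblageCounts, config: SearchConfig, bands=None):
    freqs = compute_frequencies(counts)
    if bands is None:
        bands = bootstrap_bands(counts, config)
    return freqs, bands, _Evaluator(freqs, bands, config)


def seed_triples(
    freqs: FrequencyMatrix,
    bands: ConfidenceBands,
    config: SearchConfig,
) -> set[tuple[str, ...]]:
    """All valid canonical orders of three assemblages.

    Three is the smallest number of assemblages for which the unimodality
    criterion has content. Each unordered triple {a, b, c} yields three
    distinct canonical arrangements (by choice of middle element).
    """
    if freqs.n_assemblages < 3:
        raise SearchError("seriation requires at least 3 assemblages")
    ev = _Evaluator(freqs, bands, config)
    out: set[tuple[str, ...]] = set()
    for a, b, c in itertools.combinations(freqs.assemblage_ids, 3):
        for arrangement in ((a, b, c), (a, c, b), (b, a, c)):
            if ev.valid(arrangement):
                out.add(canonical(arrangement))
    return out


def _is_contiguous_subseq(small: tuple[str, ...], big: tuple[str, ...]) -> bool:
    if len(small) >= len(big):
        return False
    n = len(small)
    for variant in (small, small[::-1]):
        for i in range(len(big) - n + 1):
            if big[i:i + n] == variant:
                return True
    return False


def _maximality_filter(orders: set[tuple[str, ...]]) -> list[tuple[str, ...]]:
    by_size = sorted(orders, key=len, reverse=True)
    kept: list[tuple[str, ...]] = []
    for o in by_size:
        if not any(_is_contiguous_subseq(o, k) for k in kept):
            kept.append(o)
    return sorted(kept)


def idss_search(
    counts: AssemblageCounts,
    config: SearchConfig,
    *,
    bands: ConfidenceBands | None = None,
) -> SolutionSet:
    """Find every maximal valid seriation order by iterative agglomeration.

    Seeds with all valid triples, then repeatedly tries to prepend or
    append each unused assemblage to each frontier order, keeping
    extensions that remain valid. An order that admits no valid extension
    is emitted as a solution; the final atlas is canonicalized,
    deduplicated, and filtered so no member is a contiguous sub-sequence
    (in either orientation) of another. Deterministic given
    ``config.seed``: the bootstrap bands are computed once up front and the
    search itself involves no randomness.
    """
    if counts.n_assemblages < 3:
        raise SearchError("seriation requires at least 3 assemblages")
    freqs, bands, ev = _prepare(counts, config, bands)
    frontier = seed_triples(freqs, bands, config)
    all_ids = set(counts.assemblage_ids)
    solutions: set[tuple[str, ...]] = set()
    n_valid = len(frontier)
    frontier_sizes = {3: len(frontier)}
    while frontier:
        next_frontier: set[tuple[str, ...]] = set()
        for order in sorted(frontier):
            extended = False
            members = set(order)
            for x in all_ids - members:
                for cand in ((*order, x), (x, *order)):
                    if ev.valid(cand):
                        extended = True
                        next_frontier.add(canonical(cand))
            if not extended:
                solutions.add(order)
        if len(next_frontier) > config.max_frontier:
            raise FrontierBudgetExceeded(
                f"frontier of {len(next_frontier)} orders exceeds budget "
                f"{config.max_frontier}; raise max_frontier or tighten the "
                f"continuity threshold"
            )
        n_valid += len(next_frontier)
        if next_frontier:
            frontier_sizes[len(next(iter(next_frontier)))] = len(next_frontier)
        frontier = next_frontier
    kept = _maximality_filter(solutions)
    return SolutionSet(
        orders=kept,
        certificates=[ev.certificate(o) for o in kept],
        config=config,
        n_valid_orders=n_valid,
        frontier_sizes=frontier_sizes,
    )


def brute_force_enumerate(
    counts: AssemblageCounts,
    config: SearchConfig,
    *,
    bands: ConfidenceBands | None = None,
    guard: int = 8,
) -> SolutionSet:
    """Testing oracle: evaluate every permutation of every subset of size
    >= 3, keep the valid ones, canonicalize, and filter to maximal members.

    Identical contract to :func:`idss_search`; refuses instances above
    ``guard`` assemblages (the point of the iterative search is precisely
    that this enumeration is infeasible at scale).
    """
    n = counts.n_assemblages
    if n > guard:
        raise SearchError(
            f"brute force enumeration refused for {n} > {guard} assemblages"
        )
    if n < 3:
        raise SearchError("seriation requires at least 3 assemblages")
    freqs, bands, ev = _prepare(counts, config, bands)
    valid: set[tuple[str, ...]] = set()
    ids = counts.assemblage_ids
    for k in range(3, n + 1):
        for subset in itertools.combinations(ids, k):
            for perm in itertools.permutations(subset):
                if perm > perm[::-1]:
                    continue  # evaluate one orientation only
                if ev.valid(perm):
                    valid.add(perm)
    kept = _maximality_filter(valid)
    return SolutionSet(
        orders=kept,
        certificates=[ev.certificate(o) for o in kept],
        config=config,
        n_valid_orders=len(valid),
        frontier_sizes={},
    )
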