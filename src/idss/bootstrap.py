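"""Bootstrap confidence bands for type proportions and pairwise comparison.

Each assemblage is a multinomial sample of its own size. Confidence bands
are percentile intervals over ``reps`` multinomial resamples of the row at
its observed total. Comparisons between two assemblages for one type are
trichotomous: GREATER, LESS, or MATCH when the difference cannot be
distinguished at the configured level — a MATCH is compatible with any
direction of change, which is what lets statistically equivalent
assemblages participate in multiple orderings.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .types import AssemblageCounts, SearchConfig, compute_frequencies


class Comparison(Enum):
    GREATER = "greater"
    LESS = "less"
    MATCH = "match"


def _substream(seed: int, assemblage_id: str) -> np.random.Generator:
    # Stable per-assemblage substream: band values must not depend on the
    # position of the assemblage in the input file.
    digest = hashlib.sha256(assemblage_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


@dataclass(frozen=True)
class ConfidenceBands:
    """Per-(assemblage, type) percentile bootstrap interval at level alpha.

    ``lower``/``upper`` have the same shape as the frequency matrix; the
    point proportion always lies inside its own band. A type absent from an
    assemblage has band exactly [0, 0] (resampling with replacement cannot
    produce an absent type); a type comprising the whole assemblage has
    band exactly [1, 1].
    """

    assemblage_ids: tuple[str, ...]
    type_names: tuple[str, ...]
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    reps: int
    seed: int

    def index_of(self, assemblage_id: str) -> int:
        try:
            return self.assemblage_ids.index(assemblage_id)
        except ValueError:
            raise KeyError(f"unknown assemblage id {assemblage_id!r}") from None

    def type_index(self, type_name: str) -> int:
        try:
            return self.type_names.index(type_name)
        except ValueError:
            raise KeyError(f"unknown type {type_name!r}") from None

    def band(self, assemblage_id: str, type_name: str) -> tuple[float, float]:
        i, j = self.index_of(assemblage_id), self.type_index(type_name)
        return float(self.lower[i, j]), float(self.upper[i, j])

    def write_tsv(self, path: str | Path) -> None:
        """Audit export: one line per (assemblage, type) cell."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["assemblage", "type", "point", "lower", "upper"])
            for i, aid in enumerate(self.assemblage_ids):
                for j, t in enumerate(self.type_names):
                    writer.writerow(
                        [aid, t, f"{self.point[i, j]:.6f}",
                         f"{self.lower[i, j]:.6f}", f"{self.upper[i, j]:.6f}"]
                    )


def bootstrap_bands(counts: AssemblageCounts, config: SearchConfig) -> ConfidenceBands:
    """Compute percentile bootstrap bands for every (assemblage, type) cell.

    For each assemblage the observed row is resampled ``bootstrap_reps``
    times as a multinomial at its own row total; the band is the
    [alpha/2, 1 - alpha/2] percentile interval of the resampled
    proportions. Bands are computed once per assemblage and reused for all
    pairwise comparisons: under the interval-overlap MATCH rule this is
    identical to recomputing them per pair. Deterministic given
    ``config.seed``; per-assemblage substreams are keyed by a stable hash
    of the assemblage id, so values do not depend on row order.
    """
    freqs = compute_frequencies(counts)
    n, t = counts.n_assemblages, counts.n_types
    lower = np.empty((n, t))
    upper = np.empty((n, t))
    q = [100 * config.alpha / 2, 100 * (1 - config.alpha / 2)]
    for i, aid in enumerate(counts.assemblage_ids):
        rng = _substream(config.seed, aid)
        total = int(counts.row_totals[i])
        p = freqs.freqs[i]
        reps = rng.multinomial(total, p, size=config.bootstrap_reps) / total
        lo, hi = np.percentile(reps, q, axis=0)
        # The point estimate is the plug-in proportion of the observed row;
        # clamp so it always lies inside its own band (percentiles of a
        # finite replicate pool can otherwise exclude it marginally).
        lower[i] = np.minimum(lo, p)
        upper[i] = np.maximum(hi, p)
    return ConfidenceBands(
        assemblage_ids=counts.assemblage_ids,
        type_names=counts.type_names,
        point=freqs.freqs,
        lower=lower,
        upper=upper,
        alpha=config.alpha,
        reps=config.bootstrap_reps,
        seed=config.seed,
    )


def _compare_cells(
    pa: float, la: float, ua: float, pb: float, lb: float, ub: float,
    match_rule: str,
) -> Comparison:
    if match_rule == "overlap":
        # Closed intervals; overlap => statistically indistinguishable.
        if la <= ub and lb <= ua:
            return Comparison.MATCH
    else:  # point_in
        if (lb <= pa <= ub) or (la <= pb <= ua):
            return Comparison.MATCH
    return Comparison.GREATER if pa > pb else Comparison.LESS


def compare_pair(
    bands: ConfidenceBands,
    a: str,
    b: str,
    type_name: str,
    *,
    comparison_mode: str = "bootstrap_ci",
    match_rule: str = "overlap",
) -> Comparison:
    """Trichotomous comparison of one type's proportion in two assemblages.

    Bootstrap mode scores MATCH when the difference does not exceed the
    confidence limits (by default: the two closed intervals overlap);
    otherwise GREATER/LESS by which band is strictly higher. Raw mode
    compares point proportions, with an exact tie scoring MATCH. The
    operator is antisymmetric: ``compare(a, b) == GREATER`` iff
    ``compare(b, a) == LESS``, and MATCH is symmetric.
    """
    if a == b:
        raise ValueError("cannot compare an assemblage with itself")
    i, j = bands.index_of(a), bands.index_of(b)
    k = bands.type_index(type_name)
    pa, pb = bands.point[i, k], bands.point[j, k]
    if comparison_mode == "raw":
        if pa == pb:
            return Comparison.MATCH
        return Comparison.GREATER if pa > pb else Comparison.LESS
    return _compare_cells(
        pa, bands.lower[i, k], bands.upper[i, k],
        pb, bands.lower[j, k], bands.upper[j, k],
        match_rule,
    )


def comparison_matrix(bands: ConfidenceBands, config: SearchConfig) -> np.ndarray:
    """Vectorized all-pairs comparison codes, shape (types, n, n).

    Entry ``[t, i, j]`` is +1 if assemblage ``i``'s proportion of type
    ``t`` is GREATER than ``j``'s, -1 if LESS, 0 if MATCH. The search core
    consumes this table so that evaluating an order is pure lookup.
    """
    p = bands.point.T[:, :, None]  # (t, n, 1)
    pT = bands.point.T[:, None, :]
    if config.comparison_mode == "raw":
        codes = np.sign(p - pT).astype(np.int8)
        return codes
    lo = bands.lower.T[:, :, None]
    hi = bands.upper.T[:, :, None]
    loT = bands.lower.T[:, None, :]
    hiT = bands.upper.T[:, None, :]
    if config.match_rule == "overlap":
        match = (lo <= hiT) & (loT <= hi)
    else:
        match = ((loT <= p) & (p <= hiT)) | ((lo <= pT) & (pT <= hi))
    codes = np.where(match, 0, np.where(p > pT, 1, -1)).astype(np.int8)
    np.einsum("tii->ti", codes)[:] = 0
    return codes
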