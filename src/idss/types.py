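"""Core domain types: count matrices, frequency matrices, and run configuration.

An *assemblage* is one row of the input matrix: a collection of artifacts
from a single deposit, described as counts per historical (stylistic) type.
Frequency seriation works on the row-normalized proportions of those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input matrix violates the seriation preconditions."""


@dataclass(frozen=True)
class AssemblageCounts:
    """Integer count matrix with assemblage ids (rows) and type names (columns).

    Invariants enforced at construction:

    * all counts are non-negative integers,
    * every row total is positive (an empty assemblage carries no frequency
      information and would silently distort the solution space),
    * at least three type columns are present — with fewer than three
      classes the closed-array constraint makes every proportion a function
      of the others and the unimodality criterion degenerates,
    * assemblage ids and type names are unique.
    """

    assemblage_ids: tuple[str, ...]
    type_names: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.assemblage_ids), len(self.type_names)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.assemblage_ids)} assemblages x {len(self.type_names)} types"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at assemblage {self.assemblage_ids[i]!r}, "
                f"type {self.type_names[j]!r}"
            )
        if len(self.type_names) < 3:
            raise ValidationError(
                f"need at least 3 type columns, got {len(self.type_names)}"
            )
        if len(set(self.assemblage_ids)) != len(self.assemblage_ids):
            raise ValidationError("duplicate assemblage ids")
        if len(set(self.type_names)) != len(self.type_names):
            raise ValidationError("duplicate type names")
        totals = counts.sum(axis=1)
        if np.any(totals == 0):
            bad = [self.assemblage_ids[i] for i in np.flatnonzero(totals == 0)]
            raise ValidationError(f"zero row total for assemblage(s): {bad}")
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "assemblage_ids", tuple(self.assemblage_ids))
        object.__setattr__(self, "type_names", tuple(self.type_names))

    @property
    def n_assemblages(self) -> int:
        return len(self.assemblage_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def empty_type_columns(self) -> list[str]:
        """Type columns whose counts are zero across all assemblages.

        Such columns are retained (they preserve column indexing for
        reports) but contribute nothing to any comparison.
        """
        col = self.counts.sum(axis=0)
        return [self.type_names[j] for j in np.flatnonzero(col == 0)]

    def index_of(self, assemblage_id: str) -> int:
        try:
            return self.assemblage_ids.index(assemblage_id)
        except ValueError:
            raise KeyError(f"unknown assemblage id {assemblage_id!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list(self.assemblage_ids),
            columns=list(self.type_names),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AssemblageCounts":
        return cls(
            assemblage_ids=tuple(str(i) for i in df.index),
            type_names=tuple(str(c) for c in df.columns),
            counts=df.to_numpy(),
        )


@dataclass(frozen=True)
class FrequencyMatrix:
    """Row-stochastic proportions derived from an :class:`AssemblageCounts`."""

    assemblage_ids: tuple[str, ...]
    type_names: tuple[str, ...]
    freqs: np.ndarray
    row_totals: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("frequency rows must sum to 1")
        freqs.setflags(write=False)
        totals = np.asarray(self.row_totals, dtype=np.int64)
        totals.setflags(write=False)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "row_totals", totals)
        object.__setattr__(self, "assemblage_ids", tuple(self.assemblage_ids))
        object.__setattr__(self, "type_names", tuple(self.type_names))

    @property
    def n_assemblages(self) -> int:
        return len(self.assemblage_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def index_of(self, assemblage_id: str) -> int:
        try:
            return self.assemblage_ids.index(assemblage_id)
        except ValueError:
            raise KeyError(f"unknown assemblage id {assemblage_id!r}") from None

    def row(self, assemblage_id: str) -> np.ndarray:
        return self.freqs[self.index_of(assemblage_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs,
            index=list(self.assemblage_ids),
            columns=list(self.type_names),
        )


def compute_frequencies(counts: AssemblageCounts) -> FrequencyMatrix:
    """Row-normalize a count matrix to proportions.

    ``freqs[i, t] = counts[i, t] / row_total[i]``; the row totals (the
    per-assemblage sample sizes) are carried along because every statistical
    statement downstream is conditional on them.
    """
    totals = counts.row_totals
    return FrequencyMatrix(
        assemblage_ids=counts.assemblage_ids,
        type_names=counts.type_names,
        freqs=counts.counts / totals[:, None],
        row_totals=totals,
    )


#: Continuity distance between adjacent assemblages: largest single-type gap
#: or the sum of gaps across all types.
CONTINUITY_MODES = ("per_type_max", "summed_across_types")

#: How adjacent assemblages are compared: via bootstrap confidence bands or
#: raw point proportions.
COMPARISON_MODES = ("bootstrap_ci", "raw")

#: How two confidence bands yield a MATCH: closed-interval overlap (the more
#: conservative, symmetric reading) or either point falling inside the other
#: assemblage's band.
MATCH_RULES = ("overlap", "point_in")


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of a seriation run.

    alpha
        Significance level of the bootstrap confidence bands; the bands are
        percentile intervals at ``alpha/2`` and ``1 - alpha/2``.
    continuity_threshold
        Maximum frequency difference allowed between adjacently placed
        assemblages. Interpreted per ``continuity_mode``.
    bootstrap_reps
        Number of multinomial resamples per assemblage.
    seed
        RNG seed; every stochastic step derives from it.
    continuity_mode
        ``per_type_max`` (default) or ``summed_across_types``.
    comparison_mode
        ``bootstrap_ci`` (default) or ``raw``.
    match_rule
        ``overlap`` (default) or ``point_in``; ignored in raw mode.
    all_pairs_continuity
        Enforce the continuity threshold between *every* pair in an order,
        not just adjacent pairs.
    max_frontier
        Upper bound on the number of partial orders carried between
        agglomeration rounds; exceeding it aborts the search rather than
        silently subsampling.
    """

    alpha: float = 0.05
    continuity_threshold: float = 0.30
    bootstrap_reps: int = 1000
    seed: int = 0
    continuity_mode: str = "per_type_max"
    comparison_mode: str = "bootstrap_ci"
    match_rule: str = "overlap"
    all_pairs_continuity: bool = False
    max_frontier: int = 2_000_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.continuity_threshold < 0:
            raise ValidationError("continuity_threshold must be >= 0")
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")
        if self.continuity_mode not in CONTINUITY_MODES:
            raise ValidationError(f"unknown continuity_mode {self.continuity_mode!r}")
        if self.comparison_mode not in COMPARISON_MODES:
            raise ValidationError(f"unknown comparison_mode {self.comparison_mode!r}")
        if self.match_rule not in MATCH_RULES:
            raise ValidationError(f"unknown match_rule {self.match_rule!r}")

    def with_(self, **kwargs) -> "SearchConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "continuity_threshold": self.continuity_threshold,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "continuity_mode": self.continuity_mode,
            "comparison_mode": self.comparison_mode,
            "match_rule": self.match_rule,
            "all_pairs_continuity": self.all_pairs_continuity,
            "max_frontier": self.max_frontier,
        }


@dataclass(frozen=True)
class CoordinateTable:
    """Planar (x, y) coordinates per assemblage id, in user units."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "coords",
            {str(k): (float(v[0]), float(v[1])) for k, v in self.coords.items()},
        )

    def __contains__(self, assemblage_id: str) -> bool:
        return assemblage_id in self.coords

    def __getitem__(self, assemblage_id: str) -> tuple[float, float]:
        return self.coords[assemblage_id]

    def missing(self, ids: Sequence[str]) -> list[str]:
        return [i for i in ids if i not in self.coords]
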