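"""Synthetic count-matrix generators with known ground truth.

Three families of instances, each emulating a transmission scenario the
search must handle:

* a single *lineage*: one interacting population drifting through time, so
  every type's expected frequency is unimodal along the (known) true order
  and adjacent assemblages differ by a controlled amount;
* a *branching lineage*: a shared stem that splits into two arms which
  drift apart, so the atlas should contain exactly the two arm orders and
  the aggregate graph a degree-3 hub at the branch point;
* a *confidence-interval fork*: a stem with two statistically
  interchangeable continuations, so bootstrap comparisons admit both forks
  while raw comparisons admit at most one.

Expected frequencies use triangular (piecewise-linear) unimodal curves:
unlike Gaussian bumps, the per-type gap between adjacent assemblages is
then analytically controllable, which the recovery guarantees need.
Counts are either drawn multinomially at a per-assemblage sample size or,
in exact-frequency mode, written as scaled integers at a large common
denominator using largest-remainder rounding (rounding can perturb a
frequency by at most one part in the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AssemblageCounts, CoordinateTable

#: Denominator used for exact-frequency-mode counts.
EXACT_DENOMINATOR = 100_000


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedInstance:
    """A generated count matrix together with its ground truth.

    ``truth_order`` is the planted order (for branching instances, the
    first arm's full order); ``branch_orders`` carries both arm orders
    when the instance branches. ``expected_freqs`` are the noise-free
    frequencies in truth order, for oracle tests.
    """

    counts: AssemblageCounts
    truth_order: tuple[str, ...]
    branch_orders: tuple[tuple[str, ...], ...]
    curve_params: dict
    sample_size: int | None
    seed: int
    expected_freqs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def exact(self) -> bool:
        return self.sample_size is None


def _largest_remainder(freq_row: np.ndarray, denom: int) -> np.ndarray:
    scaled = freq_row * denom
    base = np.floor(scaled).astype(np.int64)
    short = denom - int(base.sum())
    if short:
        order = np.argsort(-(scaled - base), kind="stable")
        base[order[:short]] += 1
    return base


def _draw_counts(
    freqs: np.ndarray, sample_size: int | None, rng: np.random.Generator
) -> np.ndarray:
    if sample_size is None:
        return np.vstack([_largest_remainder(row, EXACT_DENOMINATOR) for row in freqs])
    return np.vstack(
        [rng.multinomial(sample_size, row / row.sum()) for row in freqs]
    )


def _shuffle_rows(
    ids: list[str], counts: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    perm = rng.permutation(len(ids))
    return [ids[i] for i in perm], counts[perm]


def _triangular_profile(n: int, n_types: int, width: float) -> np.ndarray:
    """Rows: positions 0..n-1; columns: types with evenly spaced peaks."""
    positions = np.arange(n)[:, None]
    peaks = np.linspace(0, n - 1, n_types)[None, :]
    raw = np.maximum(0.0, 1.0 - np.abs(positions - peaks) / width)
    sums = raw.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise GeneratorError("triangular profile leaves uncovered positions")
    return raw / sums


def _partition_profile(n: int, n_types: int, overlap: int) -> np.ndarray:
    """Triangular partition-of-unity curves with uniform per-step gaps.

    Peaks are spaced ``d`` apart with half-width ``overlap * d`` and padded
    ``overlap - 1`` peaks beyond each end of the axis, so the unnormalized
    columns sum to exactly ``overlap`` at every position. After dividing by
    that constant, every row sums to 1 exactly and every type's flank has
    the same slope ``1 / (overlap**2 * d)`` — the largest per-type gap
    between adjacent assemblages is therefore identical at every step,
    which is what makes skip-orders controllably discontinuous.
    """
    span = n_types + 1 - 2 * overlap
    if span < 1:
        raise GeneratorError("too few types for the requested overlap")
    d = (n - 1) / span
    positions = np.arange(n)[:, None]
    peaks = (np.arange(n_types) - (overlap - 1))[None, :] * d
    raw = np.maximum(0.0, 1.0 - np.abs(positions - peaks) / (overlap * d))
    sums = raw.sum(axis=1)
    if not np.allclose(sums, overlap, atol=1e-9):
        raise GeneratorError("internal: partition profile is not constant-sum")
    return raw / overlap


def _adjacent_gaps(freqs: np.ndarray) -> np.ndarray:
    return np.abs(np.diff(freqs, axis=0)).max(axis=1)


def _is_unimodal_numeric(col: np.ndarray, tol: float = 1e-12) -> bool:
    signs = np.sign(np.round(np.diff(col), 12))
    seen_minus = False
    for s in signs:
        if s < 0:
            seen_minus = True
        elif s > 0 and seen_minus:
            return False
    return True


def generate_lineage(
    n_assemblages: int = 15,
    n_types: int = 6,
    sample_size: int | None = 1000,
    seed: int = 0,
    max_adjacent_gap: float = 0.10,
) -> PlantedInstance:
    """A single drifting lineage with a planted unimodal order.

    Type ``t`` peaks at an evenly spaced position along the order; the
    triangular half-width is chosen as the smallest value for which
    adjacent expected rows differ by at most ``max_adjacent_gap`` in every
    type (smaller widths give sharper, more identifiable curves). Counts
    are drawn multinomially at ``sample_size`` per assemblage
    (``sample_size=None`` for exact-frequency mode) and the returned row
    order is shuffled; the truth order is carried alongside.
    """
    if n_assemblages < 3 or n_types < 3:
        raise GeneratorError("need >= 3 assemblages and >= 3 types")
    if sample_size is not None and sample_size < 1:
        raise GeneratorError("sample_size must be >= 1")
    # Smallest overlap whose uniform per-step gap fits under the cap gives
    # the sharpest admissible curves (strongest planted signal).
    chosen = None
    for overlap in range(1, (n_types + 1) // 2 + 1):
        span = n_types + 1 - 2 * overlap
        if span < 1:
            break
        d = (n_assemblages - 1) / span
        slope = 1.0 / (overlap**2 * d)
        if slope <= max_adjacent_gap:
            chosen = overlap
            break
    if chosen is not None:
        freqs = _partition_profile(n_assemblages, n_types, chosen)
        params = {"profile": "partition", "overlap": int(chosen)}
    else:
        # Too few types for a constant-sum partition under the gap cap
        # (tiny instances): widen plain triangular curves until the gap
        # and unimodality constraints hold after normalization.
        freqs = None
        for width in np.arange(1.0, 8.0 * n_assemblages, 0.25):
            try:
                cand = _triangular_profile(n_assemblages, n_types, width)
            except GeneratorError:
                continue
            if _adjacent_gaps(cand).max() <= max_adjacent_gap and all(
                _is_unimodal_numeric(cand[:, t]) for t in range(n_types)
            ):
                freqs = cand
                params = {"profile": "triangular", "width": float(width)}
                break
        if freqs is None:
            raise GeneratorError(
                f"cannot satisfy max_adjacent_gap={max_adjacent_gap} with "
                f"{n_assemblages} assemblages and {n_types} types"
            )
    assert _adjacent_gaps(freqs).max() <= max_adjacent_gap + 1e-12
    rng = np.random.default_rng(seed)
    truth = [f"A{i+1:02d}" for i in range(n_assemblages)]
    counts = _draw_counts(freqs, sample_size, rng)
    ids, counts = _shuffle_rows(list(truth), counts, rng)
    type_names = tuple(f"T{t+1}" for t in range(n_types))
    return PlantedInstance(
        counts=AssemblageCounts(tuple(ids), type_names, counts),
        truth_order=tuple(truth),
        branch_orders=(tuple(truth),),
        curve_params={
            **params,
            "per_step_gap": float(_adjacent_gaps(freqs).max()),
            "max_adjacent_gap": max_adjacent_gap,
        },
        sample_size=sample_size,
        seed=seed,
        expected_freqs={aid: freqs[i] for i, aid in enumerate(truth)},
    )


def _branching_freqs(
    stem_length: int, branch_length: int, n_types: int
) -> tuple[np.ndarray, np.ndarray]:
    """Expected frequencies for the two full lineages (stem + one arm each).

    Three mechanisms keep the two complete lineages as the only maximal
    valid orders:

    * shared types follow unimodal curves along the depth axis, with step
      sizes large enough that skipping a stem assemblage breaks continuity;
    * two *arm-rate* types rise in both arms but fast in their own arm and
      slowly in the other, so any path crossing the branch point drops an
      arm-rate type to zero at the junction and then rises again — a trough;
    * a *divergent* type sits at a constant level through the stem and is
      pushed up by one arm and down by the other, so any pair of
      assemblages drawn from different arms is farther apart than the
      continuity threshold and cannot be placed adjacently.
    """
    if n_types < 6:
        raise GeneratorError("branching instances need >= 6 types")
    s, b = stem_length, branch_length
    L = s + b
    # Per-step frequency moves, scaled by 1/b so arm totals are
    # length-independent. The largest single-step move (the balance type's
    # decline within arm A, 0.225/b) sets the continuity threshold tau;
    # every legitimate adjacent step is <= tau while every two-step gap
    # exceeds tau by >= 1.2x, so skipping any assemblage breaks continuity.
    xs = 0.15 / b   # divergent move per arm step: +xs in arm A, -xs in arm B
    fs = 0.06 / b   # fast arm-rate step (own arm)
    ss = 0.015 / b  # slow arm-rate step (other arm)
    g = 0.16 / b    # stem ramp step
    bg = 0.06 / b   # balance decline per stem step (absorbed by r_up)
    x0 = 0.15                      # divergent level through the stem
    bal0 = 0.225 + bg * (s - 1)    # balance start level
    r_dn0 = 1.0 - bal0 - x0 - 0.05   # declining ramp start
    r_up0 = 0.05                     # rising ramp start
    if r_dn0 < g * (s - 1):
        raise GeneratorError(
            f"stem of {s} is too long for a branching instance: the "
            f"declining ramp cannot fund {s - 1} stem steps"
        )
    # arm B: divergent releases xs and balance releases bg per step while
    # the arm-rate types gain fs + ss; the rising ramp absorbs the surplus
    sigma_b = xs + bg - (fs + ss)

    def lineage(own_arm: str) -> np.ndarray:
        rows = []
        for depth in range(L):
            k = max(0, depth - (s - 1))          # arm step count
            stem_d = min(depth, s - 1)           # stem step count
            r_dn = r_dn0 - g * stem_d
            r_up = r_up0 + (g + bg) * stem_d
            bal = bal0 - bg * stem_d
            x = x0
            ra = rb = 0.0
            if k:
                if own_arm == "A":
                    x += xs * k
                    bal -= (xs + fs + ss) * k  # balance funds arm A novelty
                    ra, rb = fs * k, ss * k
                else:
                    x -= xs * k
                    bal -= bg * k
                    r_up += sigma_b * k
                    ra, rb = ss * k, fs * k
            rows.append([r_dn, r_up, bal, x, ra, rb])
        out = np.array(rows)
        if np.any(out < -1e-12):
            raise GeneratorError("branching construction left a negative cell")
        # pad with small constant types when more than 6 are requested
        extra = n_types - 6
        if extra:
            c = min(0.02, float(out[:, 0].min()) / (2 * extra))
            pad = np.full((L, extra), c)
            out = np.hstack(
                [out[:, :1] - c * extra, out[:, 1:3], pad, out[:, 3:]]
            )
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        return out

    fa, fb = lineage("A"), lineage("B")
    return fa, fb


def generate_branching(
    stem_length: int = 5,
    branch_length: int = 5,
    n_types: int = 6,
    sample_size: int | None = None,
    seed: int = 0,
) -> PlantedInstance:
    """A lineage that splits into two arms after a shared stem.

    Returns two truth orders sharing the stem (stem ids ``S1..``, arm ids
    ``A1../B1..``). In exact-frequency mode both arm orders are valid and
    any order mixing the two arms' tails contains a trough in one of the
    arm-rate types.
    """
    if stem_length < 2 or branch_length < 2:
        raise GeneratorError("stem and branches need length >= 2")
    fa, fb = _branching_freqs(stem_length, branch_length, n_types)
    for col in range(fa.shape[1]):
        if not (_is_unimodal_numeric(fa[:, col]) and _is_unimodal_numeric(fb[:, col])):
            raise GeneratorError("internal: constructed arm curves not unimodal")
    stem_ids = [f"S{i+1}" for i in range(stem_length)]
    a_ids = [f"A{i+1}" for i in range(branch_length)]
    b_ids = [f"B{i+1}" for i in range(branch_length)]
    order_a = tuple(stem_ids + a_ids)
    order_b = tuple(stem_ids + b_ids)
    all_ids = stem_ids + a_ids + b_ids
    freqs = np.vstack([fa[:stem_length], fa[stem_length:], fb[stem_length:]])
    rng = np.random.default_rng(seed)
    counts = _draw_counts(freqs, sample_size, rng)
    ids, counts = _shuffle_rows(all_ids, counts, rng)
    n_shared = n_types - 3
    type_names = tuple(
        [f"T{t+1}" for t in range(n_shared)]
        + ["Divergent", "ArmRateA", "ArmRateB"]
    )
    return PlantedInstance(
        counts=AssemblageCounts(tuple(ids), type_names, counts),
        truth_order=order_a,
        branch_orders=(order_a, order_b),
        curve_params={
            "stem_length": stem_length,
            "branch_length": branch_length,
            "recommended_threshold": float(
                max(
                    np.abs(np.diff(arm, axis=0)).max()
                    for arm in (fa, fb)
                )
            ),
        },
        sample_size=sample_size,
        seed=seed,
        expected_freqs={
            aid: freqs[all_ids.index(aid)] for aid in all_ids
        },
    )


def generate_ci_fork(seed: int = 0) -> PlantedInstance:
    """Seven assemblages, five types, with a statistically enabled fork.

    Assemblages 1-5 form a well-sampled stem (n = 400 each); assemblages 6
    and 7 are smaller (n = 150) candidate continuations. Each fork retains
    one of two low-frequency persistent types (``KeepA``/``KeepB``) that
    the other fork entirely lacks; a type with zero count has a bootstrap
    band of exactly [0, 0], so any order containing both forks places a
    point-zero band between two bands that exclude zero — a trough at any
    alpha. A novelty shared by both forks (``Fork``) likewise troughs on
    the fork-stem-fork arrangement, and the steep decline of ``Legacy``
    into the forks keeps either fork from skipping past the last stem
    assemblage. The result under bootstrap comparisons is exactly two
    maximal solutions sharing the stem. ``KeepA`` additionally drifts down
    by half a percent per stem step and back up in fork 6 — differences
    far inside any confidence band, so bootstrap comparisons score them
    MATCH, but raw comparisons see a trough and reject fork 6: on raw
    frequencies at most one fork survives.
    """
    # columns: Legacy, Late, Fork, KeepA, KeepB
    freq_rows = {
        "Stem1": [0.720, 0.140, 0.00, 0.080, 0.06],
        "Stem2": [0.585, 0.280, 0.00, 0.075, 0.06],
        "Stem3": [0.460, 0.410, 0.00, 0.070, 0.06],
        "Stem4": [0.345, 0.530, 0.00, 0.065, 0.06],
        "Stem5": [0.240, 0.640, 0.00, 0.060, 0.06],
        "Fork6": [0.100, 0.640, 0.14, 0.120, 0.00],
        "Fork7": [0.100, 0.620, 0.14, 0.000, 0.14],
    }
    sizes = {
        "Stem1": 400, "Stem2": 400, "Stem3": 400, "Stem4": 400, "Stem5": 400,
        "Fork6": 150, "Fork7": 150,
    }
    ids = list(freq_rows)
    counts = np.vstack(
        [_largest_remainder(np.array(freq_rows[a]), sizes[a]) for a in ids]
    )
    rng = np.random.default_rng(seed)
    ids, counts = _shuffle_rows(ids, counts, rng)
    type_names = ("Legacy", "Late", "Fork", "KeepA", "KeepB")
    stem = ("Stem1", "Stem2", "Stem3", "Stem4", "Stem5")
    return PlantedInstance(
        counts=AssemblageCounts(tuple(ids), type_names, counts),
        truth_order=stem + ("Fork6",),
        branch_orders=(stem + ("Fork6",), stem + ("Fork7",)),
        curve_params={"sizes": sizes, "recommended_threshold": 0.155},
        sample_size=None,
        seed=seed,
        expected_freqs={a: np.array(freq_rows[a]) for a in freq_rows},
    )


def clustered_coordinates(
    instance: PlantedInstance,
    step: float = 10.0,
    jitter: float = 1.0,
    seed: int = 0,
) -> CoordinateTable:
    """Coordinates correlated with the planted structure.

    Assemblages are placed along their lineage at ``step`` spacing (the
    two arms of a branching instance head in opposite y directions) with
    isotropic Gaussian jitter, so order-adjacency implies spatial
    proximity and the minmax graph should test as spatially clustered.
    """
    rng = np.random.default_rng(seed)
    coords: dict[str, tuple[float, float]] = {}
    for arm_index, order in enumerate(instance.branch_orders):
        direction = 1.0 if arm_index % 2 == 0 else -1.0
        for pos, aid in enumerate(order):
            if aid in coords:
                continue
            x = pos * step
            y = direction * (arm_index > 0) * pos * step * 0.5
            dx, dy = rng.normal(0, jitter, 2)
            coords[aid] = (x + dx, y + dy)
    return CoordinateTable(coords=coords)


def null_instance(
    n_assemblages: int = 10,
    n_types: int = 5,
    sample_size: int = 200,
    seed: int = 0,
) -> tuple[AssemblageCounts, CoordinateTable]:
    """Counts from i.i.d. Dirichlet rows and coordinates independent of
    them — the null scenario for calibrating the spatial test."""
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.ones(n_types), size=n_assemblages)
    counts = np.vstack([rng.multinomial(sample_size, row) for row in freqs])
    ids = tuple(f"N{i+1:02d}" for i in range(n_assemblages))
    coords = CoordinateTable(
        {aid: tuple(rng.uniform(0, 100, 2)) for aid in ids}
    )
    types = tuple(f"T{t+1}" for t in range(n_types))
    return AssemblageCounts(ids, types, counts), coords
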