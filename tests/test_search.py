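"""Unimodality, continuity, order evaluation, and the iterative search."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from idss import (
    AssemblageCounts,
    SearchConfig,
    SearchError,
    bootstrap_bands,
    brute_force_enumerate,
    compute_frequencies,
    continuity_distance,
    evaluate_order,
    idss_search,
    is_unimodal,
    seed_triples,
    type_sign_sequence,
)
from idss.search import canonical, _is_contiguous_subseq

from conftest import random_counts


def _instance(rows, ids=None, types=None):
    rows = np.asarray(rows)
    ids = ids or tuple(f"A{i}" for i in range(rows.shape[0]))
    types = types or tuple(f"T{j}" for j in range(rows.shape[1]))
    return AssemblageCounts(tuple(ids), tuple(types), rows)


def _freq_instance(freq_rows, denom=1000):
    """Counts realizing the given frequency rows exactly."""
    rows = (np.asarray(freq_rows) * denom).round().astype(int)
    return _instance(rows)


class TestSignsAndUnimodality:
    def test_sign_sequences_raw(self):
        c = _freq_instance(
            [[0.1, 0.3, 0.6], [0.2, 0.3, 0.5], [0.3, 0.3, 0.4]]
        )
        b = bootstrap_bands(c, SearchConfig(seed=0))
        order = ("A0", "A1", "A2")
        assert type_sign_sequence(order, "T0", b, comparison_mode="raw") == "++"
        assert type_sign_sequence(order, "T1", b, comparison_mode="raw") == "00"
        assert type_sign_sequence(order, "T2", b, comparison_mode="raw") == "--"
        peaked = _freq_instance(
            [[0.1, 0.5, 0.4], [0.3, 0.5, 0.2], [0.2, 0.5, 0.3]]
        )
        b2 = bootstrap_bands(peaked, SearchConfig(seed=0))
        assert type_sign_sequence(order, "T0", b2, comparison_mode="raw") == "+-"

    @pytest.mark.parametrize("signs,expected", [
        ("+-", True),          # single peak
        ("-+", False),         # trough
        ("+0-0-", True),
        ("+-+", False),        # second peak
        ("", True),
        ("0000", True),
        ("++++", True),
        ("----", True),
        ("0+0-0", True),
        ("-0+", False),
    ])
    def test_is_unimodal_cases(self, signs, expected):
        assert is_unimodal(signs) is expected

    @given(st.text(alphabet="+-0", max_size=12))
    def test_is_unimodal_matches_regex_oracle(self, signs):
        oracle = re.fullmatch(r"[+0]*[-0]*", signs) is not None
        assert is_unimodal(signs) is oracle


class TestContinuityDistance:
    def test_identical_rows_zero(self):
        c = _instance([[10, 10, 10], [10, 10, 10], [5, 5, 5]])
        f = compute_frequencies(c)
        for mode in ("per_type_max", "summed_across_types"):
            assert continuity_distance("A0", "A1", f, mode) == 0.0

    def test_disjoint_unit_rows(self):
        c = _instance([[100, 0, 0], [0, 100, 0], [0, 0, 100]])
        f = compute_frequencies(c)
        assert continuity_distance("A0", "A1", f, "per_type_max") == 1.0
        assert continuity_distance("A0", "A1", f, "summed_across_types") == 2.0

    def test_pfg_neighbors_hand_value(self, pfg_freqs):
        # 11-N-9 vs 11-N-1: Parkin Punctate 528/758 vs 865/1303
        expected = abs(528 / 758 - 865 / 1303)
        got = continuity_distance("11-N-9", "11-N-1", pfg_freqs)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.033, abs=1e-3)

    def test_symmetry(self, pfg_freqs):
        for mode in ("per_type_max", "summed_across_types"):
            assert continuity_distance(
                "13-N-5", "13-N-4", pfg_freqs, mode
            ) == continuity_distance("13-N-4", "13-N-5", pfg_freqs, mode)


class TestEvaluateOrder:
    def test_trough_is_invalid(self):
        c = _freq_instance(
            [[0.3, 0.4, 0.3], [0.1, 0.5, 0.4], [0.3, 0.4, 0.3]],
        )
        f = compute_frequencies(c)
        b = bootstrap_bands(c, SearchConfig(seed=0))
        cfg = SearchConfig(
            comparison_mode="raw", continuity_threshold=1.0, seed=0
        )
        ok, cert = evaluate_order(("A0", "A1", "A2"), f, b, cfg)
        assert not ok
        assert cert.sign_sequences["T0"] == "-+"

    def test_reversal_same_verdict(self, pfg, raw_config):
        f = compute_frequencies(pfg)
        b = bootstrap_bands(pfg, raw_config)
        sols = idss_search(pfg, raw_config, bands=b)
        for order in sols.orders[:10]:
            ok_f, _ = evaluate_order(order, f, b, raw_config)
            ok_r, _ = evaluate_order(order[::-1], f, b, raw_config)
            assert ok_f and ok_r

    def test_continuity_threshold_enforced(self):
        c = _freq_instance([[1, 0, 0], [0.5, 0.5, 0], [0, 0.5, 0.5]])
        f = compute_frequencies(c)
        b = bootstrap_bands(c, SearchConfig(seed=0))
        loose = SearchConfig(comparison_mode="raw", continuity_threshold=0.6)
        tight = SearchConfig(comparison_mode="raw", continuity_threshold=0.3)
        assert evaluate_order(("A0", "A1", "A2"), f, b, loose)[0]
        assert not evaluate_order(("A0", "A1", "A2"), f, b, tight)[0]


class TestSeedTriples:
    def test_identical_assemblages_all_three_arrangements(self):
        c = _instance([[20, 30, 50]] * 3)
        f = compute_frequencies(c)
        cfg = SearchConfig(comparison_mode="bootstrap_ci", seed=0,
                           continuity_threshold=0.5)
        b = bootstrap_bands(c, cfg)
        triples = seed_triples(f, b, cfg)
        assert len(triples) == 3  # one per choice of middle element

    def test_forced_trough_yields_empty_set(self):
        # each assemblage is the unique minimum of one type with both
        # others higher, so whichever assemblage sits in the middle, some
        # type falls and rises again: every arrangement troughs
        c = _freq_instance(
            [[0.10, 0.45, 0.45], [0.45, 0.10, 0.45], [0.45, 0.45, 0.10]]
        )
        f = compute_frequencies(c)
        cfg = SearchConfig(comparison_mode="raw", continuity_threshold=2.0)
        b = bootstrap_bands(c, cfg)
        assert seed_triples(f, b, cfg) == set()
        # and the full search consequently returns an empty solution set
        sols = idss_search(c, cfg)
        assert len(sols) == 0

    def test_planted_triple_recovered(self):
        from idss.synthetic import generate_lineage

        inst = generate_lineage(3, 3, sample_size=None, seed=2,
                                max_adjacent_gap=0.4)
        f = compute_frequencies(inst.counts)
        cfg = SearchConfig(comparison_mode="raw", continuity_threshold=0.4)
        b = bootstrap_bands(inst.counts, cfg)
        assert seed_triples(f, b, cfg) == {canonical(inst.truth_order)}

    def test_too_few_assemblages(self):
        c = _instance([[10, 10, 10], [10, 20, 30]])
        f = compute_frequencies(c)
        cfg = SearchConfig(seed=0)
        b = bootstrap_bands(c, cfg)
        with pytest.raises(SearchError):
            seed_triples(f, b, cfg)


class TestSearch:
    def test_two_assemblages_error(self):
        c = _instance([[10, 10, 10], [10, 20, 30]])
        with pytest.raises(SearchError):
            idss_search(c, SearchConfig(seed=0))

    def test_brute_force_guard(self):
        rng = np.random.default_rng(0)
        c = random_counts(rng, n=9, t=4)
        with pytest.raises(SearchError, match="refused"):
            brute_force_enumerate(c, SearchConfig(seed=0))

    @pytest.mark.parametrize("mode", ["raw", "bootstrap_ci"])
    def test_oracle_equivalence_sample(self, mode):
        rng = np.random.default_rng(99)
        for trial in range(8):
            c = random_counts(rng)
            cfg = SearchConfig(
                comparison_mode=mode, continuity_threshold=0.5,
                bootstrap_reps=200, seed=trial,
            )
            a = idss_search(c, cfg)
            b = brute_force_enumerate(c, cfg)
            assert sorted(a.orders) == sorted(b.orders)
            assert a.n_valid_orders == b.n_valid_orders

    def test_reversal_closure(self, pfg, raw_config):
        sols = idss_search(pfg, raw_config)
        for o in sols.orders:
            assert canonical(o[::-1]) in sols.orders

    def test_hereditarity_of_solutions(self, pfg, raw_config):
        # every contiguous sub-window of a solution is itself valid
        f = compute_frequencies(pfg)
        b = bootstrap_bands(pfg, raw_config)
        sols = idss_search(pfg, raw_config, bands=b)
        for o in sols.orders[:25]:
            for w in range(3, len(o)):
                for start in range(len(o) - w + 1):
                    ok, _ = evaluate_order(o[start:start + w], f, b, raw_config)
                    assert ok

    def test_no_solution_contains_another(self, pfg, raw_config):
        sols = idss_search(pfg, raw_config)
        for i, a in enumerate(sols.orders):
            for j, b in enumerate(sols.orders):
                if i != j:
                    assert not _is_contiguous_subseq(a, b)

    def test_threshold_monotonicity(self, pfg):
        # valid-order count is monotone in the continuity threshold
        counts = []
        for tau in (0.15, 0.30, 0.45):
            cfg = SearchConfig(comparison_mode="raw",
                               continuity_threshold=tau, seed=1)
            counts.append(idss_search(pfg, cfg).n_valid_orders)
        assert counts[0] <= counts[1] <= counts[2]

    def test_ci_monotonicity(self, pfg):
        # wider bands (smaller alpha) never remove a valid order; run on a
        # 10-assemblage subset to keep the widest-band atlas small
        sub = AssemblageCounts(
            pfg.assemblage_ids[:10], pfg.type_names,
            pfg.counts[:10].copy(),
        )
        n = {}
        for alpha in (0.2, 0.05, 0.01):
            cfg = SearchConfig(alpha=alpha, continuity_threshold=0.30,
                               bootstrap_reps=400, seed=6)
            n[alpha] = idss_search(sub, cfg).n_valid_orders
        assert n[0.2] <= n[0.05] <= n[0.01]

    def test_deterministic_output_order(self, pfg, raw_config):
        a = idss_search(pfg, raw_config)
        b = idss_search(pfg, raw_config)
        assert a.orders == b.orders
        assert a.orders == sorted(a.orders)

    def test_atlas_serialization(self, pfg, raw_config, tmp_path):
        sols = idss_search(pfg, raw_config)
        sols.write_json(tmp_path / "atlas.json")
        sols.write_text(tmp_path / "solutions.txt")
        import json

        atlas = json.loads((tmp_path / "atlas.json").read_text())
        assert atlas["n_solutions"] == len(sols.orders)
        lines = (tmp_path / "solutions.txt").read_text().splitlines()
        assert len(lines) == len(sols.orders)
        assert lines[0].split(" -- ") == list(sols.orders[0])


class TestCanonical:
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=8, unique=True))
    def test_canonical_idempotent_and_reversal_invariant(self, ids):
        order = tuple(f"a{i}" for i in ids)
        c = canonical(order)
        assert canonical(c) == c
        assert canonical(order[::-1]) == c
        assert c in (order, order[::-1])
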