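import math

import pytest
from hypothesis import given, strategies as st

from csccp.model import CsccpInstance, PositionSlot, SideChainOption, integerize
from csccp.solvers import (
    _build_table,
    backtrack,
    brute_force_topR,
    dp_decimals_threshold,
    dp_solve,
    idp_solve,
    merge_topR,
    real_weight_matches,
    weight_window,
)
from csccp.fixtures import GeneratorSpec, planted_instance, random_instance

from conftest import planted_corpus


def tiny_instance(weights, probs, target, R=10, D=2):
    slots = tuple(
        PositionSlot(
            index=i + 1,
            options=tuple(
                SideChainOption(id=f"c{i}{j}", mw=w, prob=p)
                for j, (w, p) in enumerate(zip(ws, ps))
            ),
        )
        for i, (ws, ps) in enumerate(zip(weights, probs))
    )
    return CsccpInstance(slots=slots, target_mw=target, R=R, D=D)


class TestBruteForce:
    def test_worked_example_products(self, example_instance):
        r = brute_force_topR(example_instance)
        assert r.top.products() == pytest.approx([0.512, 0.032])
        assert r.top.assignments() == [(2, 1, 2), (2, 2, 1)]

    def test_single_option(self):
        r = brute_force_topR(tiny_instance([[10.0]], [[0.7]], 10.0))
        assert r.top.products() == [0.7]
        assert r.top.assignments() == [(1,)]

    def test_two_by_two(self):
        r = brute_force_topR(
            tiny_instance([[10, 20], [10, 20]], [[0.5, 0.5], [0.6, 0.4]], 30.0, R=2)
        )
        assert r.top.products() == pytest.approx([0.3, 0.2])

    def test_guard_refuses_large_spaces(self, example_instance):
        with pytest.raises(ValueError, match="8"):
            brute_force_topR(example_instance, guard=5)


class TestMergeTopR:
    @pytest.mark.parametrize(
        "values,R,expected",
        [
            ([0.9, 0.5, 0.5, 0.1], 3, [0.9, 0.5, 0.5]),
            ([], 5, []),
            ([0.2, 0.8], 1, [0.8]),
        ],
    )
    def test_examples(self, values, R, expected):
        out = merge_topR([(v, i) for i, v in enumerate(values)], R)
        assert [v for v, _ in out] == expected

    def test_tied_values_keep_distinct_provenance(self):
        out = merge_topR([(0.5, "a"), (0.5, "b")], 2)
        assert {p for _, p in out} == {"a", "b"}

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), max_size=30),
        st.integers(min_value=0, max_value=10),
    )
    def test_non_increasing_and_maximal(self, values, R):
        out = merge_topR([(v, i) for i, v in enumerate(values)], R)
        got = [v for v, _ in out]
        assert got == sorted(values, reverse=True)[:R]


class TestCostTable:
    def test_initial_layer_is_single_unit_cell(self, example_instance):
        ints = integerize(example_instance, "scaled", 2)
        table = _build_table(example_instance, ints.int_weights, 2, ints.int_target)
        assert set(table.layers[0]) == {0}
        (entry,) = table.layers[0][0]
        assert entry.value == 1.0 and entry.prefix == () and entry.back is None

    def test_no_cell_holds_zero(self, example_instance):
        ints = integerize(example_instance, "scaled", 2)
        table = _build_table(example_instance, ints.int_weights, 2, ints.int_target)
        for layer in table.layers:
            for cell in layer.values():
                assert all(e.value > 0 for e in cell)


class TestDpSolve:
    def test_worked_example(self, example_instance):
        r = dp_solve(example_instance, D=2, R=2)
        assert r.top.products() == pytest.approx([0.512, 0.032])
        assert r.top.assignments() == [(2, 1, 2), (2, 2, 1)]
        assert r.algorithm == "dp" and r.d_used == 2

    def test_empty_result_when_infeasible(self, example_instance):
        inst = CsccpInstance(
            slots=example_instance.slots, target_mw=95.0, R=2, D=2
        )
        assert len(dp_solve(inst).top) == 0

    def test_backtracked_product_matches_stored_value(self, example_instance):
        ints = integerize(example_instance, "scaled", 2)
        table = _build_table(example_instance, ints.int_weights, 2, ints.int_target)
        cell = table.cell(3, ints.int_target)
        for rank, entry in enumerate(cell, start=1):
            assignment = backtrack(table, 3, ints.int_target, rank)
            product = 1.0
            for slot, x in zip(example_instance.slots, assignment):
                product *= slot.options[x - 1].prob
            assert math.isclose(product, entry.value, rel_tol=1e-12)

    def test_backtrack_rank_one_and_two(self, example_instance):
        ints = integerize(example_instance, "scaled", 2)
        table = _build_table(example_instance, ints.int_weights, 2, ints.int_target)
        assert backtrack(table, 3, ints.int_target, 1) == (2, 1, 2)
        assert backtrack(table, 3, ints.int_target, 2) == (2, 2, 1)

    def test_backtrack_single_option(self):
        inst = tiny_instance([[10.0]], [[0.7]], 10.0, D=0)
        ints = integerize(inst, "scaled", 0)
        table = _build_table(inst, ints.int_weights, 1, ints.int_target)
        assert backtrack(table, 1, ints.int_target, 1) == (1,)

    def test_backtrack_missing_rank_errors(self, example_instance):
        ints = integerize(example_instance, "scaled", 2)
        table = _build_table(example_instance, ints.int_weights, 2, ints.int_target)
        with pytest.raises(KeyError):
            backtrack(table, 3, ints.int_target, 7)
        with pytest.raises(KeyError):
            backtrack(table, 3, ints.int_target + 1, 1)


class TestWeightWindow:
    @pytest.mark.parametrize(
        "n,target,expected",
        [(3, 96, (94, 98)), (1, 10, (9, 11)), (4, 2, (0, 5))],
    )
    def test_examples(self, n, target, expected):
        assert weight_window(n, target) == expected

    def test_rejects_zero_positions(self):
        with pytest.raises(ValueError):
            weight_window(0, 10)


class TestRealWeightMatches:
    def test_examples(self):
        e = lambda m: type("E", (), {"exact_mass": m})()
        assert real_weight_matches(e(286.240000), 286.24, tol=5e-7)
        assert not real_weight_matches(e(286.2401), 286.24, tol=5e-7)
        assert real_weight_matches(e(96.0), 96.0, tol=0.0)


class TestDecimalsThreshold:
    def test_examples(self, example_instance):
        assert dp_decimals_threshold(example_instance) == pytest.approx(
            math.log10(8) / 96.0
        )
        inst = tiny_instance([[10.0] * 10] * 6, [[0.1] * 10] * 6, 300.0)
        assert dp_decimals_threshold(inst) == pytest.approx(0.02)
        single = tiny_instance([[10.0]], [[1.0]], 10.0)
        assert dp_decimals_threshold(single) == 0.0


class TestIdpSolve:
    def test_worked_example_single_pass(self, example_instance):
        r = idp_solve(example_instance, R=2)
        assert r.top.products() == pytest.approx([0.512, 0.032])
        assert r.top.assignments() == [(2, 1, 2), (2, 2, 1)]
        assert r.loop_count == 1

    def test_fewer_feasible_than_R_returns_them_all(self):
        # three feasible assignments, R=10: one pass, three entries
        spec = GeneratorSpec(seed=7, n=4, K=3, decimals=2)
        inst, planted = planted_instance(spec, n_feasible=3)
        bf = brute_force_topR(inst, R=10**6)
        assert len(bf.top) == 3  # instance really has exactly three
        r = idp_solve(inst, R=10)
        assert len(r.top) == 3
        assert r.loop_count == 1

    def test_empty_when_nothing_matches(self, example_instance):
        inst = CsccpInstance(slots=example_instance.slots, target_mw=95.0, R=2, D=2)
        r = idp_solve(inst)
        assert len(r.top) == 0 and r.loop_count == 1

    def test_every_entry_matches_target_mass(self):
        for seed, spec, inst, _ in planted_corpus(20):
            for entry in idp_solve(inst).top:
                assert abs(entry.exact_mass - inst.target_mw) <= 5e-7
                assert entry.product <= 1.0


class TestOracleEquivalence:
    def test_dp_and_idp_match_brute_force_on_planted_corpus(self):
        R_cycle = (1, 2, 10)
        for seed, spec, inst, planted in planted_corpus(50):
            R = R_cycle[seed % 3]
            bf = brute_force_topR(inst, R=R).ranked()
            dp = dp_solve(inst, D=spec.decimals, R=R).ranked()
            idp = idp_solve(inst, R=R).ranked()
            assert dp == bf, f"dp != bf at seed {seed}"
            assert idp == bf, f"idp != bf at seed {seed}"

    def test_random_targets_agree_even_when_infeasible(self):
        for seed in range(20):
            spec = GeneratorSpec(seed=seed, n=2 + seed % 4, K=2 + seed % 3, decimals=seed % 3)
            inst = random_instance(spec)
            bf = brute_force_topR(inst).ranked()
            assert dp_solve(inst, D=spec.decimals).ranked() == bf
            assert idp_solve(inst).ranked() == bf


class TestStructuralInvariants:
    def test_slot_permutation_leaves_solution_set_unchanged(self):
        for seed, spec, inst, _ in planted_corpus(15):
            base = {
                frozenset(e.mapping(inst).items()): e.product
                for e in brute_force_topR(inst, R=10**6).top
            }
            order = list(range(inst.n))[::-1]
            perm = inst.permuted(order)
            for solver in (
                lambda i: brute_force_topR(i, R=10**6),
                lambda i: dp_solve(i, D=spec.decimals, R=10**6),
                lambda i: idp_solve(i, R=10**6),
            ):
                got = {
                    frozenset(e.mapping(perm).items()): e.product
                    for e in solver(perm).top
                }
                assert got.keys() == base.keys()
                for key in base:
                    assert math.isclose(got[key], base[key], rel_tol=1e-12)

    def test_first_R_entries_stable_when_R_grows(self):
        for seed, spec, inst, _ in planted_corpus(15):
            for solve in (
                lambda i, R: brute_force_topR(i, R=R),
                lambda i, R: dp_solve(i, D=spec.decimals, R=R),
                lambda i, R: idp_solve(i, R=R),
            ):
                small = solve(inst, 2).ranked()
                large = solve(inst, 7).ranked()
                assert large[: len(small)] == small

    def test_products_non_increasing(self):
        for seed, spec, inst, _ in planted_corpus(15):
            for result in (brute_force_topR(inst), dp_solve(inst, D=spec.decimals), idp_solve(inst)):
                products = result.top.products()
                assert all(a >= b for a, b in zip(products, products[1:]))

    def test_idp_rank_budget_bounded(self):
        from csccp.model import candidate_space_size

        for seed, spec, inst, _ in planted_corpus(15):
            r = idp_solve(inst)
            assert r.final_Rprime <= max(10 * inst.R, 10 * candidate_space_size(inst))
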