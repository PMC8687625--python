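"""ICP greedy cover: traces, tie-breaks, guarantees, and planted recovery."""

import numpy as np
import pytest

from cfig.errors import ValidationError
from cfig.selection import coverage_curve, icp_select, recovery_score

from oracles import best_k_coverage, greedy_trace


class TestGreedyTraces:
    def test_single_ingredient_covering_everything(self):
        sel = icp_select({"A": {"1", "2"}}, {"1", "2"}, 0.9)
        assert sel.ingredient_ids == ["A"]
        assert sel.achieved_coverage == 1.0

    def test_three_pick_trace(self):
        targets = {"A": {"1", "2", "3"}, "B": {"3", "4"}, "C": {"5"}}
        sel = icp_select(targets, {"1", "2", "3", "4", "5"}, 0.9)
        assert [(p.ingredient_id, p.cumulative_coverage) for p in sel.picks] == [
            ("A", 0.6), ("B", 0.8), ("C", 1.0)]
        assert coverage_curve(sel) == [(1, 0.6), (2, 0.8), (3, 1.0)]

    def test_redundant_ingredient_never_picked(self):
        # B duplicates A's coverage: zero marginal gain, skipped forever
        targets = {"A": {"1", "2", "3"}, "B": {"1", "2", "3"}, "C": {"4"}}
        sel = icp_select(targets, {"1", "2", "3", "4"}, 1.0)
        assert sel.ingredient_ids == ["A", "C"]

    def test_tie_broken_by_raw_target_count_then_id(self):
        # equal gains on key proteins; B has more raw targets than A
        targets = {"A": {"1"}, "B": {"2", "x", "y"}}
        sel = icp_select(targets, {"1", "2"}, 1.0)
        assert sel.ingredient_ids[0] == "B"
        targets = {"A": {"1"}, "B": {"2"}}
        sel = icp_select(targets, {"1", "2"}, 1.0)
        assert sel.ingredient_ids[0] == "A"

    def test_unreachable_target_flagged(self):
        sel = icp_select({"A": {"1"}}, {"1", "2", "3"}, 0.9)
        assert sel.unreachable
        assert sel.achieved_coverage == pytest.approx(1 / 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            icp_select({"A": {"1"}}, {"1"}, 0.0)
        with pytest.raises(ValidationError):
            icp_select({"A": {"1"}}, set(), 0.9)


class TestAgainstExhaustiveOracle:
    def _random_instance(self, rng):
        n_ing = int(rng.integers(2, 13))
        n_prot = int(rng.integers(3, 21))
        proteins = [f"P{j}" for j in range(n_prot)]
        targets = {
            f"I{i:02d}": set(rng.choice(proteins,
                                        size=int(rng.integers(1, n_prot + 1)),
                                        replace=False))
            for i in range(n_ing)
        }
        key = set(rng.choice(proteins, size=int(rng.integers(2, n_prot + 1)),
                             replace=False))
        return targets, key

    def test_traces_match_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            targets, key = self._random_instance(rng)
            tgt = float(rng.choice([0.5, 0.8, 0.9, 1.0]))
            sel = icp_select(targets, key, tgt)
            expected = greedy_trace(targets, key, tgt)
            got = [(p.ingredient_id, p.marginal_gain, p.cumulative_coverage)
                   for p in sel.picks]
            assert got == expected

    def test_greedy_beats_1_minus_1_over_e_of_optimum(self):
        rng = np.random.default_rng(321)
        bound = 1 - 1 / np.e
        for _ in range(25):
            targets, key = self._random_instance(rng)
            sel = icp_select(targets, key, 1.0)
            k = len(sel.picks)
            if k == 0:
                continue
            opt = best_k_coverage(targets, key, k)
            assert sel.achieved_coverage >= bound * opt - 1e-12


class TestProperties:
    def test_curve_monotone_and_gains_positive(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            targets, key = TestAgainstExhaustiveOracle()._random_instance(rng)
            sel = icp_select(targets, key, 1.0)
            curve = [c for _, c in coverage_curve(sel)] if sel.picks else []
            assert all(a <= b for a, b in zip(curve, curve[1:]))
            assert all(p.marginal_gain > 0 for p in sel.picks)
            assert len(set(sel.ingredient_ids)) == len(sel.ingredient_ids)

    def test_deterministic(self):
        targets = {f"I{i}": {f"P{j}" for j in range(i % 5 + 1)} for i in range(10)}
        key = {f"P{j}" for j in range(5)}
        a = icp_select(targets, key, 0.9)
        b = icp_select(targets, key, 0.9)
        assert a.ingredient_ids == b.ingredient_ids


class TestRecovery:
    def test_prefix_and_disjoint_cases(self):
        targets = {"A": {"1"}, "B": {"2"}, "C": {"3"}}
        sel = icp_select(targets, {"1", "2", "3"}, 1.0)
        assert recovery_score(sel, set(sel.ingredient_ids)) == 1.0
        assert recovery_score(sel, {"Z1", "Z2", "Z3"}) == 0.0
        with pytest.raises(ValidationError):
            recovery_score(sel, set())

    def test_seed7_study_recovers_planted(self, study7):
        from cfig.filtering import filter_ingredients, retained_ids
        from cfig.importance import assign_communities, compute_nim, select_frs
        from cfig.networks import (
            build_disease_network, build_it_network, merge_networks, ROLE_GENE)

        retained = retained_ids(filter_ingredients(study7.ingredients))
        assoc = [(i, g) for i, g in study7.associations if i in set(retained)]
        disease = build_disease_network(study7.base_ppi, study7.evidence).network
        it = build_it_network(retained, assoc)
        merged = merge_networks(disease, it, study7.base_ppi)
        nim = compute_nim(merged, assign_communities(merged))
        frs = select_frs(nim, "median", merged,
                         {e.gene for e in study7.evidence}, it.targets)
        key = {n for n in frs.kept if merged.role(n) == ROLE_GENE}
        sel = icp_select(it, key, 0.90)
        assert recovery_score(sel, study7.planted_critical_ids) >= 0.6
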