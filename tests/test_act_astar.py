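import numpy as np
import pytest

from helpers import TOL, best_completion, brute_force_optimum, random_instance
from iscore import (
    DataError,
    Edge,
    ExpressionProfile,
    Mode,
    RegulatoryNetwork,
    ScoringInstance,
    Sign,
    TFState,
    compute_iscore,
    constrained_search,
    encode,
    heuristic,
    improvement,
    search,
    solution_pool_report,
    solve_exact,
)


def _disjoint_pairs():
    """Two TFs each owning one UP gene: improvements are exactly additive."""
    net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T2", "G2", Sign.ACT)])
    prof = ExpressionProfile(fc={"G1": 2.5, "G2": 2.0})  # weights 1.5, 1.0
    return net, prof


class TestImprovement:
    def test_explaining_an_up_gene(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})
        assert improvement({}, "T1", TFState.A_PLUS, net, prof) == pytest.approx(1.5)

    def test_wrong_direction_gives_zero(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})
        assert improvement({}, "T1", TFState.A_MINUS, net, prof) == 0.0

    def test_harmful_extension_floored_at_zero(self):
        # T1's only target is unchanged: activating T1 worsens the score
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 0.0})
        assert improvement({}, "T1", TFState.A_PLUS, net, prof) == 0.0

    def test_tf_without_scored_targets(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T2", "G2", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})  # G2 unmeasured
        for state in (TFState.A_PLUS, TFState.A_MINUS):
            assert improvement({}, "T2", state, net, prof) == 0.0


class TestHeuristic:
    def test_no_slots_left_returns_g(self):
        net, prof = _disjoint_pairs()
        inst = ScoringInstance(net, prof)
        active = {"T1": TFState.A_PLUS}
        g = inst.score_active(active)
        assert heuristic(active, N=1, instance=inst) == pytest.approx(g)

    def test_disjoint_targets_heuristic_is_exact(self):
        net, prof = _disjoint_pairs()
        # g(empty) = 2.5; both improvements subtract fully
        assert heuristic({}, net, prof, N=2) == pytest.approx(0.0)
        assert heuristic({}, net, prof, N=1) == pytest.approx(1.0)  # 2.5 - 1.5

    def test_admissible_on_random_instances(self):
        """h never exceeds the true best completion at any expanded node."""
        rng = np.random.default_rng(17)
        for _ in range(60):
            net, prof = random_instance(rng, max_tfs=5, max_genes=15)
            N = int(rng.integers(1, 4))
            audited = []
            search(net, prof, N, mode=Mode.ALL_OPTIMAL, node_hook=audited.append)
            for node in audited:
                true_best = best_completion(net, prof, node.active_map, N)
                assert node.h <= true_best + TOL


class TestSearch:
    def test_n_zero_returns_null_assignment(self, example):
        net, prof = example
        pool = search(net, prof, 0)
        assert len(pool.solutions) == 1
        rec = pool.solutions[0]
        assert rec.assignment.active == {}
        assert rec.iscore == pytest.approx(
            compute_iscore(net, prof, rec.assignment).iscore
        )

    def test_negative_n_rejected(self, example):
        net, prof = example
        with pytest.raises(DataError):
            search(net, prof, -1)

    def test_symmetric_instance_yields_both_optima(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T2", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})
        pool = search(net, prof, 1, mode=Mode.ALL_OPTIMAL)
        optima = {frozenset(s.assignment.active.items()) for s in pool.optima()}
        assert optima == {
            frozenset({("T1", TFState.A_PLUS)}),
            frozenset({("T2", TFState.A_PLUS)}),
        }
        assert pool.best == pytest.approx(0.0)

    def test_all_optimal_equals_brute_force_co_optima(self):
        """ALL_OPTIMAL enumerates exactly the brute-force co-optimal set."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            net, prof = random_instance(rng, max_tfs=6, max_genes=20)
            n_tfs = len(net.tfs)
            best, co = brute_force_optimum(net, prof)
            pool = search(net, prof, n_tfs, mode=Mode.ALL_OPTIMAL)
            assert pool.best == pytest.approx(best, abs=TOL)
            found = {frozenset(s.assignment.active.items()) for s in pool.optima()}
            assert found == co

    def test_optimum_monotone_in_n(self):
        rng = np.random.default_rng(31)
        net, prof = random_instance(rng, n_tfs=5, n_genes=25)
        scores = [search(net, prof, N).best for N in range(6)]
        assert all(a >= b - TOL for a, b in zip(scores, scores[1:]))
        _, sat_opt = solve_exact(encode(net, prof))
        assert scores[5] == pytest.approx(sat_opt, abs=TOL)

    def test_deterministic_solution_ordering(self):
        rng = np.random.default_rng(2)
        net, prof = random_instance(rng, n_tfs=5, n_genes=20)
        a = search(net, prof, 3, mode=Mode.ALL_OPTIMAL)
        b = search(net, prof, 3, mode=Mode.ALL_OPTIMAL)
        assert [(s.assignment, s.iscore) for s in a.solutions] == [
            (s.assignment, s.iscore) for s in b.solutions
        ]


class TestConstrainedSearch:
    def test_fixing_the_optimal_tfs_reproduces_optimum(self, example):
        net, prof = example
        free = search(net, prof, 2)
        fixed = constrained_search(
            net, prof, 2, fixed={"T1": TFState.A_PLUS, "T3": TFState.A_PLUS}
        )
        assert fixed.best == pytest.approx(free.best, abs=TOL)

    def test_wrong_prior_never_beats_unconstrained(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            net, prof = random_instance(rng, max_tfs=5, max_genes=15)
            tfs = sorted(net.tfs)
            free = search(net, prof, 2).best
            wrong_tf = tfs[rng.integers(len(tfs))]
            con = constrained_search(net, prof, 2, fixed={wrong_tf: TFState.A_MINUS})
            assert con.best >= free - TOL
            assert all(
                s.assignment[wrong_tf] is TFState.A_MINUS for s in con.solutions
            )

    def test_empty_prior_identical_to_search(self, example):
        net, prof = example
        assert constrained_search(net, prof, 2, fixed={}).best == pytest.approx(
            search(net, prof, 2).best
        )

    def test_too_many_fixed_tfs_rejected(self, example):
        net, prof = example
        with pytest.raises(DataError):
            constrained_search(
                net, prof, 1, fixed={"T1": TFState.A_PLUS, "T2": TFState.A_MINUS}
            )


class TestPoolReport:
    def test_fraction_selects_best_solutions(self):
        rng = np.random.default_rng(8)
        net, prof = random_instance(rng, n_tfs=5, n_genes=20)
        pool = search(net, prof, 3, mode=Mode.ALL_OPTIMAL)
        n = len(pool.solutions)
        report = solution_pool_report(pool, fraction=1.0)
        assert report.n_retained == n
        if n >= 10:
            small = solution_pool_report(pool, fraction=0.1)
            assert small.n_retained == n // 10

    def test_disjoint_fixture_position_one_improvement(self):
        net, prof = _disjoint_pairs()
        pool = search(net, prof, 2, mode=Mode.ALL_OPTIMAL)
        report = solution_pool_report(pool, fraction=1.0)
        # best first addition explains G1: relative improvement 1.5/2.5
        assert max(report.positional_improvements[1]) == pytest.approx(1.5 / 2.5)
        assert report.first_position["T1"] == 1

    def test_empty_pool_rejected(self):
        from iscore.act_astar import SolutionPool

        with pytest.raises(DataError):
            solution_pool_report(SolutionPool(solutions=[], best=0.0, n_expanded=0))

    def test_dot_output_mentions_first_positions(self):
        net, prof = _disjoint_pairs()
        pool = search(net, prof, 2, mode=Mode.ALL_OPTIMAL)
        dot = solution_pool_report(pool, fraction=1.0).to_dot()
        assert dot.startswith("digraph") and '"T1"' in dot
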