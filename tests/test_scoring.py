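import numpy as np
import pytest

from helpers import TOL, brute_force_optimum, random_instance
from iscore import (
    ActivityAssignment,
    DataError,
    Edge,
    Effect,
    ExpressionProfile,
    GeneCall,
    ParseError,
    RegulatoryNetwork,
    ScoringInstance,
    Sign,
    Status,
    TFState,
    compute_iscore,
    is_explained,
    regulatory_effect,
    score_prediction_file,
)

A = ActivityAssignment


@pytest.mark.parametrize(
    "sign,state,effect",
    [
        (Sign.ACT, TFState.A_PLUS, Effect.PLUS),
        (Sign.ACT, TFState.A_MINUS, Effect.MINUS),
        (Sign.INH, TFState.A_PLUS, Effect.MINUS),
        (Sign.INH, TFState.A_MINUS, Effect.PLUS),
        (Sign.UNKNOWN, TFState.A_PLUS, Effect.EITHER),
        (Sign.UNKNOWN, TFState.A_MINUS, Effect.EITHER),
        (Sign.ACT, TFState.A_ZERO, Effect.ZERO),
        (Sign.INH, TFState.A_ZERO, Effect.ZERO),
        (Sign.UNKNOWN, TFState.A_ZERO, Effect.ZERO),
    ],
)
def test_regulatory_effect_table(sign, state, effect):
    """Full sign x state effect table, including the optimistic unknown sign."""
    assert regulatory_effect(sign, state) is effect


UP = GeneCall(Status.UP, 1.0)
DOWN = GeneCall(Status.DOWN, 1.0)
UNCH = GeneCall(Status.UNCHANGED, 1.0)


@pytest.mark.parametrize(
    "call,regs,assignment,expected",
    [
        (UP, [("T1", Sign.ACT)], A({"T1": TFState.A_PLUS}), True),
        (UP, [("T1", Sign.ACT)], A({"T1": TFState.A_MINUS}), False),
        (UP, [("T1", Sign.ACT)], A(), False),
        (DOWN, [("T1", Sign.UNKNOWN)], A({"T1": TFState.A_PLUS}), True),
        (DOWN, [("T1", Sign.INH)], A({"T1": TFState.A_PLUS}), True),
        # unchanged gene: needs at least one A0 regulator
        (UNCH, [("T1", Sign.ACT), ("T2", Sign.INH)],
         A({"T1": TFState.A_PLUS, "T2": TFState.A_MINUS}), False),
        (UNCH, [("T1", Sign.ACT), ("T2", Sign.INH)],
         A({"T1": TFState.A_PLUS}), True),
        # unknown-sign edge from an active TF cannot explain an unchanged gene
        (UNCH, [("T1", Sign.UNKNOWN)], A({"T1": TFState.A_PLUS}), False),
    ],
)
def test_is_explained(call, regs, assignment, expected):
    assert is_explained("G", call, regs, assignment) is expected


def test_is_explained_requires_regulators():
    with pytest.raises(DataError):
        is_explained("G", UP, [], A())


class TestComputeIscore:
    def test_single_explained_gene(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})
        r = compute_iscore(net, prof, A({"T1": TFState.A_PLUS}))
        assert r.iscore == pytest.approx(0.0) and r.utg == set()

    def test_single_unexplained_gene_weight(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5})
        r = compute_iscore(net, prof, A())
        assert r.iscore == pytest.approx(1.5) and r.utg == {"G1"}

    def test_active_tf_breaks_unchanged_target(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T1", "G2", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5, "G2": 0.0})
        r = compute_iscore(net, prof, A({"T1": TFState.A_PLUS}))
        assert r.iscore == pytest.approx(1.0) and r.utg == {"G2"}

    def test_null_assignment_explains_null_data(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T2", "G2", Sign.INH)])
        prof = ExpressionProfile(fc={"G1": 0.1, "G2": -0.9})
        r = compute_iscore(net, prof, A())
        assert r.iscore == pytest.approx(0.0) and r.n_utg == 0

    def test_genes_without_regulators_or_fc_are_unscored(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T1", "G2", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.0, "ORPHAN": 3.0})  # G2 unmeasured
        r = compute_iscore(net, prof, A({"T1": TFState.A_PLUS}))
        assert set(r.per_gene) == {"G1"}
        assert r.n_unscored == 1

    def test_gene_allowlist_restricts_scoring(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T1", "G2", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5, "G2": 2.5})
        r = compute_iscore(net, prof, A(), genes={"G1"})
        assert set(r.per_gene) == {"G1"} and r.iscore == pytest.approx(1.5)

    def test_invariant_under_input_order(self):
        rng = np.random.default_rng(0)
        net, prof = random_instance(rng, n_tfs=5, n_genes=20)
        shuffled_edges = list(net.edges)
        rng.shuffle(shuffled_edges)
        net2 = RegulatoryNetwork(shuffled_edges)
        items = list(prof.fc.items())
        rng.shuffle(items)
        prof2 = ExpressionProfile(fc=dict(items))
        assign = A({"T0": TFState.A_PLUS, "T2": TFState.A_MINUS})
        assert compute_iscore(net, prof, assign).iscore == pytest.approx(
            compute_iscore(net2, prof2, assign).iscore, abs=TOL
        )


def test_unknown_sign_dominance():
    """Replacing any edge sign by UNKNOWN never increases a fixed assignment's score."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        net, prof = random_instance(rng, max_tfs=5, max_genes=20)
        tfs = sorted(net.tfs)
        assign = A({
            tf: (TFState.A_PLUS, TFState.A_MINUS, TFState.A_ZERO)[rng.integers(3)]
            for tf in tfs
        })
        base = compute_iscore(net, prof, assign).iscore
        edges = list(net.edges)
        e = edges[rng.integers(len(edges))]
        relaxed = [Edge(x.tf, x.target, Sign.UNKNOWN if x is e else x.sign) for x in edges]
        relaxed_score = compute_iscore(RegulatoryNetwork(relaxed), prof, assign).iscore
        assert relaxed_score <= base + TOL


def test_scoring_instance_matches_direct_predicate():
    """The incremental score path agrees with the per-gene predicate path."""
    rng = np.random.default_rng(21)
    for _ in range(25):
        net, prof = random_instance(rng, max_tfs=6, max_genes=25)
        inst = ScoringInstance(net, prof)
        tfs = sorted(net.tfs)
        for _ in range(10):
            active = {
                tf: (TFState.A_PLUS, TFState.A_MINUS)[rng.integers(2)]
                for tf in tfs
                if rng.random() < 0.4
            }
            direct = compute_iscore(net, prof, A(active))
            assert inst.score_active(active) == pytest.approx(direct.iscore, abs=TOL)
            assert inst.unexplained(active) == direct.utg


class TestScorePredictionFile:
    @pytest.fixture
    def simple(self):
        net = RegulatoryNetwork([Edge("T1", "G1", Sign.ACT), Edge("T2", "G2", Sign.ACT)])
        prof = ExpressionProfile(fc={"G1": 2.5, "G2": 2.5})
        return net, prof

    def test_plain_prediction(self, simple, tmp_path):
        net, prof = simple
        p = tmp_path / "act.tsv"
        p.write_text("T1\t+\n")
        r = score_prediction_file(net, prof, p)
        assert r.iscore == pytest.approx(1.5) and r.utg == {"G2"}

    def test_top_k_forces_rest_to_a0(self, simple, tmp_path):
        net, prof = simple
        p = tmp_path / "act.tsv"
        p.write_text("T1\t+\t0.9\nT2\t+\t0.1\n")
        r = score_prediction_file(net, prof, p, top_k=1)
        assert r.utg == {"G2"}  # T2 forced inactive

    def test_top_k_without_magnitude_errors(self, simple, tmp_path):
        net, prof = simple
        p = tmp_path / "act.tsv"
        p.write_text("T1\t+\n")
        with pytest.raises(DataError, match="magnitude"):
            score_prediction_file(net, prof, p, top_k=1)

    def test_bad_state_token(self, simple, tmp_path):
        net, prof = simple
        p = tmp_path / "act.tsv"
        p.write_text("T1\tup!\n")
        with pytest.raises(ParseError, match="state token"):
            score_prediction_file(net, prof, p)


def test_any_assignment_scores_at_least_the_optimum():
    """compute_iscore of arbitrary assignments is bounded below by the optimum."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        net, prof = random_instance(rng, max_tfs=5, max_genes=15)
        best, _ = brute_force_optimum(net, prof)
        tfs = sorted(net.tfs)
        for _ in range(5):
            assign = A({
                tf: (TFState.A_PLUS, TFState.A_MINUS, TFState.A_ZERO)[rng.integers(3)]
                for tf in tfs
            })
            assert compute_iscore(net, prof, assign).iscore >= best - TOL
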