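"""Act-SAT: i-score minimization as weighted partial max-SAT, solved exactly.

Encoding. Each TF contributes three boolean variables — more active (A+),
less active (A-), unchanged (A0) — and four hard clauses enforcing that
exactly one of them is true:

    (A+ v A- v A0) ^ (~A+ v ~A-) ^ (~A+ v ~A0) ^ (~A- v ~A0)

Each scored target gene contributes one soft clause whose weight is the
gene's UTG weight (its i-score contribution if left unexplained):

    unchanged gene:     OR of A0 over its regulators
    upregulated gene:   OR of A+ over activators  v  OR of A- over inhibitors
    downregulated gene: OR of A- over activators  v  OR of A+ over inhibitors

Unsigned edges put their TF in both the activator and the inhibitor group.
Minimizing the total weight of unsatisfied soft clauses under the hard
clauses is exactly minimizing the i-score.

Solving. :func:`solve_exact` runs a depth-first branch-and-bound directly
over TF states (the exactly-one constraint is built into the branching), with
a lower bound that sums the weights of clauses no unassigned TF can still
satisfy. For interoperability with external weighted max-SAT solvers,
:func:`export_wcnf` writes the DIMACS-style WCNF dialect with scaled integer
weights; hard clauses get weight ``(sum of scaled soft weights) + 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError
from .expression import ExpressionProfile
from .network import RegulatoryNetwork
from .scoring import ActivityAssignment, ScoringInstance, TFState

logger = logging.getLogger(__name__)

__all__ = ["WeightedCNF", "encode", "solve_exact", "export_wcnf"]

_STATES = (TFState.A_PLUS, TFState.A_MINUS, TFState.A_ZERO)
#: canonical state order for tie-breaking and variable numbering
_STATE_RANK = {TFState.A_ZERO: 0, TFState.A_PLUS: 1, TFState.A_MINUS: 2}
_TOL = 1e-12


@dataclass
class WeightedCNF:
    """Soft/hard clause container for the Act-SAT encoding.

    Variables are numbered per TF in lexicographic order: TF ``i`` (0-based)
    owns ``3i+1`` (A+), ``3i+2`` (A-), ``3i+3`` (A0). Soft clauses contain
    only positive literals by construction; ``soft_genes`` records which gene
    produced each soft clause (parallel to ``soft``).
    """

    n_vars: int
    soft: list[tuple[list[int], float]]
    hard: list[list[int]]
    var_map: dict[tuple[str, TFState], int]
    soft_genes: list[str] = field(default_factory=list)

    @property
    def tfs(self) -> list[str]:
        return sorted({tf for tf, _ in self.var_map})

    def var_of(self, tf: str, state: TFState) -> int:
        return self.var_map[(tf, state)]

    def state_of(self, var: int) -> tuple[str, TFState]:
        if not hasattr(self, "_inv"):
            self._inv = {v: k for k, v in self.var_map.items()}
        return self._inv[var]


def encode(net: RegulatoryNetwork, profile: ExpressionProfile) -> WeightedCNF:
    """Build the weighted CNF for (``net``, ``profile``).

    Genes with weight 0 are dropped at encoding time (they cannot move the
    optimum); genes without a measured fold change are not encoded.
    """
    tfs = sorted(net.tfs)
    var_map: dict[tuple[str, TFState], int] = {}
    for i, tf in enumerate(tfs):
        var_map[(tf, TFState.A_PLUS)] = 3 * i + 1
        var_map[(tf, TFState.A_MINUS)] = 3 * i + 2
        var_map[(tf, TFState.A_ZERO)] = 3 * i + 3

    inst = ScoringInstance(net, profile)
    soft: list[tuple[list[int], float]] = []
    soft_genes: list[str] = []
    for gene in sorted(inst.genes):
        w = inst.weights[gene]
        if w <= 0.0:
            continue
        if gene in inst.unchanged_regs:
            lits = sorted(var_map[(tf, TFState.A_ZERO)] for tf in inst.unchanged_regs[gene])
        else:
            lits = sorted(
                var_map[(tf, st)]
                for tf, states in inst.explainers[gene].items()
                for st in states
            )
        soft.append((lits, w))
        soft_genes.append(gene)

    hard: list[list[int]] = []
    for tf in tfs:
        p = var_map[(tf, TFState.A_PLUS)]
        m = var_map[(tf, TFState.A_MINUS)]
        z = var_map[(tf, TFState.A_ZERO)]
        hard.extend([[p, m, z], [-p, -m], [-p, -z], [-m, -z]])

    return WeightedCNF(
        n_vars=3 * len(tfs), soft=soft, hard=hard, var_map=var_map, soft_genes=soft_genes
    )


def _assignment_key(states: dict[str, TFState], tfs: list[str]) -> tuple[int, ...]:
    return tuple(_STATE_RANK[states.get(tf, TFState.A_ZERO)] for tf in tfs)


def solve_exact(cnf: WeightedCNF) -> tuple[ActivityAssignment, float]:
    """Minimize the weight of unsatisfied soft clauses; exact.

    Branch-and-bound over TF states. Among co-optimal assignments the one
    with the fewest active TFs is returned, ties broken by the lexicographic
    state tuple over TFs in sorted order (A0 < A+ < A-).
    """
    tfs = cnf.tfs
    # per soft clause: tf -> set of satisfying states, via the variable map
    clause_states: list[dict[str, set[TFState]]] = []
    for lits, _w in cnf.soft:
        by_tf: dict[str, set[TFState]] = {}
        for lit in lits:
            if lit <= 0:
                raise DataError("soft clauses of the Act-SAT encoding are positive")
            tf, st = cnf.state_of(lit)
            by_tf.setdefault(tf, set()).add(st)
        clause_states.append(by_tf)
    weights = [w for _lits, w in cnf.soft]

    # clauses touching each TF; branch on high-impact TFs first
    touching: dict[str, list[int]] = {tf: [] for tf in tfs}
    impact = {tf: 0.0 for tf in tfs}
    for ci, by_tf in enumerate(clause_states):
        for tf in by_tf:
            touching[tf].append(ci)
            impact[tf] += weights[ci]
    order = sorted(tfs, key=lambda tf: (-impact[tf], tf))

    n_clauses = len(weights)
    satisfied = [False] * n_clauses
    remaining = [len(by_tf) for by_tf in clause_states]  # unassigned TFs in clause
    assigned: dict[str, TFState] = {}

    best: dict = {"score": float("inf"), "n_active": 0, "key": None, "states": None}

    def leaf() -> None:
        score = sum(w for ci, w in enumerate(weights) if not satisfied[ci])
        n_active = sum(1 for s in assigned.values() if s is not TFState.A_ZERO)
        key = _assignment_key(assigned, tfs)
        cand = (score, n_active, key)
        cur = (best["score"], best["n_active"], best["key"])
        if best["key"] is None or (
            score < cur[0] - _TOL
            or (abs(score - cur[0]) <= _TOL and (n_active, key) < (cur[1], cur[2]))
        ):
            best.update(score=score, n_active=n_active, key=key, states=dict(assigned))

    def dfs(depth: int, lb: float) -> None:
        if depth == len(order):
            leaf()
            return
        tf = order[depth]
        n_active = sum(1 for s in assigned.values() if s is not TFState.A_ZERO)
        for state in (TFState.A_ZERO, TFState.A_PLUS, TFState.A_MINUS):
            delta = 0.0
            touched: list[int] = []
            for ci in touching[tf]:
                if satisfied[ci]:
                    continue
                touched.append(ci)
                if state in clause_states[ci].get(tf, ()):
                    satisfied[ci] = True
                else:
                    remaining[ci] -= 1
                    if remaining[ci] == 0:
                        delta += weights[ci]
            assigned[tf] = state
            new_lb = lb + delta
            new_active = n_active + (1 if state is not TFState.A_ZERO else 0)
            prune = new_lb > best["score"] + _TOL or (
                best["key"] is not None
                and new_lb > best["score"] - _TOL
                and new_active > best["n_active"]
            )
            if not prune:
                dfs(depth + 1, new_lb)
            del assigned[tf]
            for ci in touched:
                if state in clause_states[ci].get(tf, ()):
                    satisfied[ci] = False
                else:
                    remaining[ci] += 1

    dfs(0, 0.0)
    states = best["states"] or {}
    return ActivityAssignment(states), float(best["score"])


def export_wcnf(cnf: WeightedCNF, path: str | Path, scale: int = 10**6) -> None:
    """Write ``cnf`` in the DIMACS-style WCNF dialect with integer weights.

    Real soft weights are multiplied by ``scale`` and rounded; clauses whose
    weight rounds to 0 are dropped with a warning (they could otherwise be
    misread as hard by some solvers). Hard clauses get weight
    ``sum(scaled soft weights) + 1``, strictly larger than any soft subset.
    A sidecar JSON file ``<path>.vars.json`` records the variable map and
    scale for decoding solver models.
    """
    if scale < 1:
        raise DataError("scale must be >= 1")
    path = Path(path)
    scaled: list[tuple[list[int], int]] = []
    dropped = 0
    for lits, w in cnf.soft:
        iw = round(w * scale)
        if iw <= 0:
            dropped += 1
            continue
        scaled.append((lits, iw))
    if dropped:
        logger.warning(
            "%d soft clause(s) with weight rounding to 0 at scale %d were dropped",
            dropped,
            scale,
        )
    top = sum(iw for _l, iw in scaled) + 1
    with open(path, "w") as fh:
        fh.write(f"p wcnf {cnf.n_vars} {len(scaled) + len(cnf.hard)} {top}\n")
        for lits, iw in scaled:
            fh.write(f"{iw} " + " ".join(map(str, lits)) + " 0\n")
        for lits in cnf.hard:
            fh.write(f"{top} " + " ".join(map(str, lits)) + " 0\n")
    sidecar = {
        "scale": scale,
        "top": top,
        "variables": {
            str(v): [tf, st.value] for (tf, st), v in sorted(cnf.var_map.items(), key=lambda kv: kv[1])
        },
    }
    with open(str(path) + ".vars.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
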