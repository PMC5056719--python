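"""Act-A*: exact i-score minimization with at most N active TFs.

Best-first search over partial solutions. A partial solution is a set of at
most N TFs fixed to an active state (A+ or A-); all unset TFs are implicitly
unchanged (A0), so every partial solution is also a complete, scoreable
assignment. The search starts from the empty assignment and extends one TF
per step.

Each partial solution with x active TFs and i-score g is valued by an
admissible (optimistic) heuristic: for every unset TF the best single-TF
score improvement (max over setting it A+ or A-) is computed, the
improvements are sorted, and the N - x largest are subtracted from g.
Improvements can only shrink as more TFs are set — a gene explained by one
TF no longer needs another — so the heuristic never overestimates the score
any completion can reach, and A* returns the true optimum. With
``Mode.ALL_OPTIMAL`` pruning is strict, so every co-optimal assignment is
enumerated.

Setting a TF active can also *worsen* the score (an unchanged gene may lose
its last A0 regulator); the per-TF improvement is floored at 0 inside the
heuristic, while the true (possibly negative) score delta is used when a
partial solution is actually extended.

The pool of all complete solutions scored during a run supports the
solution-variability report: per-position relative score improvements and
the first position at which each TF enters a solution.
"""

from __future__ import annotations

import enum
import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import DataError
from .expression import ExpressionProfile
from .network import RegulatoryNetwork
from .scoring import ActivityAssignment, ScoringInstance, TFState

__all__ = [
    "Mode",
    "PartialSolution",
    "SolutionPool",
    "PoolReport",
    "improvement",
    "heuristic",
    "search",
    "constrained_search",
    "solution_pool_report",
]

_TOL = 1e-9
_ACTIVE_STATES = (TFState.A_PLUS, TFState.A_MINUS)


class Mode(enum.Enum):
    BEST_ONE = "best_one"
    ALL_OPTIMAL = "all_optimal"


@dataclass(frozen=True)
class PartialSolution:
    """A set of active TFs with its score g and heuristic value h.

    ``g`` is the i-score of the assignment with all unset TFs at A0; ``h``
    is the optimistic estimate of the best completion with at most N active
    TFs; ``order`` records the sequence in which TFs were added along the
    path that first created this solution.
    """

    active: tuple[tuple[str, TFState], ...]  # sorted items
    g: float
    h: float
    order: tuple[tuple[str, TFState], ...]

    @property
    def active_map(self) -> dict[str, TFState]:
        return dict(self.active)

    @property
    def n_active(self) -> int:
        return len(self.active)

    def assignment(self) -> ActivityAssignment:
        return ActivityAssignment(self.active_map)


@dataclass
class SolutionRecord:
    assignment: ActivityAssignment
    iscore: float
    order: tuple[tuple[str, TFState], ...]


@dataclass
class SolutionPool:
    """All complete solutions scored during one Act-A* run, best first."""

    solutions: list[SolutionRecord]
    best: float
    n_expanded: int
    instance: ScoringInstance | None = None

    def optima(self, tol: float = _TOL) -> list[SolutionRecord]:
        return [s for s in self.solutions if s.iscore <= self.best + tol]


def improvement(
    partial: Mapping[str, TFState] | PartialSolution,
    tf: str,
    state: TFState,
    net: RegulatoryNetwork | None = None,
    profile: ExpressionProfile | None = None,
    instance: ScoringInstance | None = None,
) -> float:
    """Score improvement from setting ``tf`` to ``state`` on top of ``partial``.

    Returns ``max(0, g(partial) - g(partial + {tf: state}))`` — the decrease
    in i-score, floored at 0 (extensions that worsen the score count as no
    improvement for heuristic purposes).
    """
    if instance is None:
        if net is None or profile is None:
            raise DataError("pass either a ScoringInstance or (net, profile)")
        instance = ScoringInstance(net, profile)
    active = partial.active_map if isinstance(partial, PartialSolution) else dict(partial)
    if tf in active:
        raise DataError(f"TF {tf!r} is already set in the partial solution")
    if state not in _ACTIVE_STATES:
        raise DataError("improvements are defined for the active states A+/A-")
    g0 = instance.score_active(active)
    g1 = instance.score_active({**active, tf: state})
    return max(0.0, g0 - g1)


def _best_improvements(
    instance: ScoringInstance,
    active: dict[str, TFState],
    g: float,
    barred: frozenset[str],
) -> list[float]:
    """Floored best single-TF improvement for every unset, unbarred TF."""
    imps = []
    for tf in instance.tfs:
        if tf in active or tf in barred:
            continue
        best = 0.0
        # only TFs that touch some scored gene can improve anything
        if instance.touches.get(tf):
            for state in _ACTIVE_STATES:
                d = g - instance.score_active({**active, tf: state})
                if d > best:
                    best = d
        imps.append(best)
    return imps


def heuristic(
    partial: Mapping[str, TFState] | PartialSolution,
    net: RegulatoryNetwork | None = None,
    profile: ExpressionProfile | None = None,
    N: int = 10,
    instance: ScoringInstance | None = None,
    barred: frozenset[str] = frozenset(),
) -> float:
    """Admissible estimate of the best i-score reachable from ``partial``.

    h = g minus the sum of the N - x largest per-TF improvements (x = number
    of already active TFs), clamped at 0.
    """
    if instance is None:
        if net is None or profile is None:
            raise DataError("pass either a ScoringInstance or (net, profile)")
        instance = ScoringInstance(net, profile)
    active = partial.active_map if isinstance(partial, PartialSolution) else dict(partial)
    g = partial.g if isinstance(partial, PartialSolution) else instance.score_active(active)
    slots = N - len(active)
    if slots <= 0:
        return g
    imps = sorted(_best_improvements(instance, active, g, barred), reverse=True)
    return max(0.0, g - sum(imps[:slots]))


def search(
    net: RegulatoryNetwork | None,
    profile: ExpressionProfile | None,
    N: int,
    mode: Mode = Mode.BEST_ONE,
    instance: ScoringInstance | None = None,
    fixed: Mapping[str, TFState] | None = None,
    node_hook: Callable[[PartialSolution], None] | None = None,
) -> SolutionPool:
    """Best-first enumeration of activity assignments with <= N active TFs.

    Every expanded partial solution is itself a complete assignment and is
    recorded in the returned pool with its exact i-score. In BEST_ONE mode a
    node is pruned as soon as its heuristic cannot strictly beat the best
    score found; in ALL_OPTIMAL mode pruning is strict, so the pool's
    :meth:`SolutionPool.optima` equals the full co-optimal set.

    ``fixed`` seeds the root: TFs set to A+/A- are active from the start and
    never revised; TFs fixed to A0 are barred from ever becoming active.
    ``node_hook`` is called with every expanded node (used for heuristic
    audits).
    """
    if N < 0:
        raise DataError("N must be non-negative")
    if instance is None:
        if net is None or profile is None:
            raise DataError("pass either a ScoringInstance or (net, profile)")
        instance = ScoringInstance(net, profile)

    fixed = dict(fixed or {})
    barred = frozenset(tf for tf, s in fixed.items() if s is TFState.A_ZERO)
    root_active = {tf: s for tf, s in fixed.items() if s in _ACTIVE_STATES}
    for tf in fixed:
        if tf not in instance.touches and tf not in instance.net.tfs:
            raise DataError(f"fixed TF {tf!r} is not a TF of the network")
    if len(root_active) > N:
        raise DataError(f"{len(root_active)} fixed active TFs exceed N={N}")

    def make_node(active: dict[str, TFState], order: tuple) -> PartialSolution:
        g = instance.score_active(active)
        slots = N - len(active)
        if slots <= 0:
            h = g
        else:
            imps = sorted(_best_improvements(instance, active, g, barred), reverse=True)
            h = max(0.0, g - sum(imps[:slots]))
        return PartialSolution(tuple(sorted(active.items(), key=lambda kv: (kv[0], kv[1].value))), g, h, order)

    def heap_key(node: PartialSolution):
        return (node.h, node.n_active, tuple((tf, s.value) for tf, s in node.active))

    root = make_node(root_active, tuple(sorted(root_active.items())))
    heap: list[tuple] = [(*heap_key(root), root)]
    visited: set[frozenset] = {frozenset(root.active)}
    solutions: list[SolutionRecord] = []
    best = math.inf
    n_expanded = 0
    strict = mode is Mode.ALL_OPTIMAL

    while heap:
        *_, node = heapq.heappop(heap)
        if strict:
            if solutions and node.h > best + _TOL:
                break
        else:
            if solutions and node.h >= best - _TOL:
                break
        n_expanded += 1
        if node_hook is not None:
            node_hook(node)
        solutions.append(SolutionRecord(node.assignment(), node.g, node.order))
        if node.g < best:
            best = node.g
        if node.n_active >= N:
            continue
        active = node.active_map
        for tf in instance.tfs:
            if tf in active or tf in barred:
                continue
            for state in _ACTIVE_STATES:
                child_active = {**active, tf: state}
                key = frozenset(child_active.items())
                if key in visited:
                    continue
                visited.add(key)
                child = make_node(child_active, node.order + ((tf, state),))
                if strict:
                    if child.h > best + _TOL:
                        continue
                elif child.h >= best - _TOL and not math.isinf(best):
                    continue
                heapq.heappush(heap, (*heap_key(child), child))

    solutions.sort(
        key=lambda s: (
            s.iscore,
            len(s.assignment),
            tuple((tf, st.value) for tf, st in sorted(s.assignment.active.items())),
        )
    )
    return SolutionPool(solutions=solutions, best=best, n_expanded=n_expanded, instance=instance)


def constrained_search(
    net: RegulatoryNetwork | None,
    profile: ExpressionProfile | None,
    N: int,
    fixed: Mapping[str, TFState],
    mode: Mode = Mode.BEST_ONE,
    instance: ScoringInstance | None = None,
) -> SolutionPool:
    """Act-A* started from a prior partial assignment (prior knowledge).

    TFs in ``fixed`` keep their states in every solution; the optimum is
    therefore an upper bound constrained by the prior (never better than the
    unconstrained optimum).
    """
    return search(net, profile, N, mode=mode, instance=instance, fixed=fixed)


@dataclass
class PoolReport:
    """Variability summary of the best fraction of scored solutions."""

    n_retained: int
    best: float
    #: position (1-based) -> relative score improvements, one per retained
    #: solution that has a TF at that position
    positional_improvements: dict[int, list[float]]
    #: TF -> first (earliest) position at which it occurs in any retained solution
    first_position: dict[str, int]

    def to_tsv(self) -> str:
        lines = ["#position\ttf\trelative_improvement"]
        for rec in self._rows:
            lines.append(f"{rec[0]}\t{rec[1]}\t{rec[2]:.6g}")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        """Plain DOT text: solution paths with repeat TFs collapsed to meta nodes."""
        lines = ["digraph solutions {", "  rankdir=LR;"]
        for tf, pos in sorted(self.first_position.items(), key=lambda kv: (kv[1], kv[0])):
            lines.append(f'  "{tf}" [label="{tf} (p{pos})"];')
        for a, b in sorted(self._dot_edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def solution_pool_report(pool: SolutionPool, fraction: float = 0.1) -> PoolReport:
    """Summarize the best ``fraction`` of all solutions scored in a run.

    For each retained solution the relative improvement of the i-score at
    every position of its TF-addition path is computed:
    (g before - g after) / g of the empty assignment. For each TF only its
    first (earliest) position across retained solutions is tabulated; later
    occurrences collapse into meta positions in the DOT rendering.
    """
    if not pool.solutions:
        raise DataError("empty solution pool")
    if not (0 < fraction <= 1):
        raise DataError("fraction must be in (0, 1]")
    if pool.instance is None:
        raise DataError("pool carries no scoring instance; rerun search")
    inst = pool.instance
    n_keep = max(1, int(math.floor(fraction * len(pool.solutions))))
    kept = pool.solutions[:n_keep]
    g0 = inst.score_active({})
    positional: dict[int, list[float]] = {}
    first_pos: dict[str, int] = {}
    rows: list[tuple[int, str, float]] = []
    dot_edges: set[tuple[str, str]] = set()
    for rec in kept:
        active: dict[str, TFState] = {}
        g_prev = g0
        prev_label = "start"
        for pos, (tf, state) in enumerate(rec.order, start=1):
            active[tf] = state
            g_now = inst.score_active(active)
            rel = (g_prev - g_now) / g0 if g0 > 0 else 0.0
            positional.setdefault(pos, []).append(rel)
            if tf not in first_pos or pos < first_pos[tf]:
                first_pos[tf] = pos
            rows.append((pos, tf, rel))
            label = tf if first_pos.get(tf) == pos else f"meta_p{pos}"
            dot_edges.add((prev_label, label))
            prev_label = label
            g_prev = g_now
    report = PoolReport(
        n_retained=n_keep,
        best=pool.best,
        positional_improvements=positional,
        first_position=first_pos,
    )
    report._rows = rows
    report._dot_edges = dot_edges
    return report
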