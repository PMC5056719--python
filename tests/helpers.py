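"""Shared test utilities: random instances and the brute-force oracle.

The brute-force oracle enumerates all 3^|TF| activity assignments and
scores each with :func:`iscore.compute_iscore` (the direct per-gene
predicate path); it is independent of both optimizers and of the
incremental ``ScoringInstance.score_active`` path they use.
"""

from __future__ import annotations

import itertools

import numpy as np

from iscore import (
    ActivityAssignment,
    Edge,
    ExpressionProfile,
    RegulatoryNetwork,
    Sign,
    TFState,
    compute_iscore,
)

STATES = (TFState.A_ZERO, TFState.A_PLUS, TFState.A_MINUS)
SIGNS = (Sign.ACT, Sign.INH, Sign.UNKNOWN)

TOL = 1e-9


def random_instance(
    rng: np.random.Generator,
    n_tfs: int | None = None,
    n_genes: int | None = None,
    max_tfs: int = 8,
    max_genes: int = 60,
) -> tuple[RegulatoryNetwork, ExpressionProfile]:
    """A random signed network plus a random fold-change profile."""
    if n_tfs is None:
        n_tfs = int(rng.integers(2, max_tfs + 1))
    if n_genes is None:
        n_genes = int(rng.integers(4, max_genes + 1))
    tfs = [f"T{i}" for i in range(n_tfs)]
    edges = []
    for j in range(n_genes):
        k = int(rng.integers(1, min(3, n_tfs) + 1))
        for i in rng.choice(n_tfs, size=k, replace=False):
            edges.append(Edge(tfs[i], f"G{j}", SIGNS[rng.integers(3)]))
    fc = {f"G{j}": float(rng.normal(0.0, 1.8)) for j in range(n_genes)}
    return RegulatoryNetwork(edges), ExpressionProfile(fc=fc)


def brute_force_optimum(
    net: RegulatoryNetwork,
    profile: ExpressionProfile,
    max_active: int | None = None,
) -> tuple[float, set[frozenset]]:
    """Exact minimum i-score by exhaustive enumeration, plus all co-optima.

    Co-optima are returned as frozensets of the active (TF, state) pairs.
    ``max_active`` restricts enumeration to assignments with at most that
    many non-A0 TFs.
    """
    tfs = sorted(net.tfs)
    best = float("inf")
    co: set[frozenset] = set()
    for combo in itertools.product(STATES, repeat=len(tfs)):
        active = {tf: s for tf, s in zip(tfs, combo) if s is not TFState.A_ZERO}
        if max_active is not None and len(active) > max_active:
            continue
        s = compute_iscore(net, profile, ActivityAssignment(active)).iscore
        if s < best - TOL:
            best = s
            co = {frozenset(active.items())}
        elif s <= best + TOL:
            co.add(frozenset(active.items()))
    return best, co


def best_completion(
    net: RegulatoryNetwork,
    profile: ExpressionProfile,
    fixed_active: dict[str, TFState],
    N: int,
) -> float:
    """Exact best score among completions of a partial solution (<= N active)."""
    tfs = [tf for tf in sorted(net.tfs) if tf not in fixed_active]
    slots = N - len(fixed_active)
    best = float("inf")
    for combo in itertools.product(STATES, repeat=len(tfs)):
        extra = {tf: s for tf, s in zip(tfs, combo) if s is not TFState.A_ZERO}
        if len(extra) > slots:
            continue
        s = compute_iscore(
            net, profile, ActivityAssignment({**fixed_active, **extra})
        ).iscore
        best = min(best, s)
    return best
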