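"""Null models for network assessment: how much better does the real data
score than randomized data on the same network (or the same data on a
randomized network)?

Three null kinds are supported:

- ``LABEL_SHUFFLE``: permute the gene labels of the expression profile,
  keeping the network fixed. Destroys the gene-to-regulator correspondence
  while conserving the fold-change distribution.
- ``RANDOM_EDGES``: replace the network by one with the same TFs, targets
  and edge count but uniformly random edges.
- ``DEGREE_PRESERVING``: rewire the network by double-edge swaps, conserving
  every node's in/out degree.

For each null the optimal i-score (Act-A*, same N as the real run) is
computed on ``n_shuffles`` independent randomizations, and the real optimal
score is expressed as a z-score against that null distribution. A negative
z means the real data is explained better than random — the signature of a
network that actually carries regulatory signal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .act_astar import Mode, search
from .errors import DataError
from .expression import ExpressionProfile
from .network import RegulatoryNetwork, randomize_edges, shuffle_degree_preserving

__all__ = ["NullKind", "ZScoreResult", "shuffle_gene_labels", "zscore_evaluation"]


class NullKind(enum.Enum):
    LABEL_SHUFFLE = "labels"
    RANDOM_EDGES = "edges"
    DEGREE_PRESERVING = "degree"


@dataclass
class ZScoreResult:
    real_score: float
    null_scores: list[float]
    z: float  # NaN when the null distribution has zero spread
    n_shuffles: int
    null_kind: NullKind

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_scores))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_scores, ddof=1))


def shuffle_gene_labels(profile: ExpressionProfile, rng_seed: int) -> ExpressionProfile:
    """Permute gene labels uniformly at random; fold-change multiset conserved."""
    if not profile.fc:
        raise DataError("empty profile")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(profile.fc)
    perm = rng.permutation(len(genes))
    values = [profile.fc[g] for g in genes]
    fc = {genes[i]: values[perm[i]] for i in range(len(genes))}
    pv = None
    if profile.pvalue is not None:
        # p-values travel with their fold change
        pvals = [profile.pvalue.get(g) for g in genes]
        pv = {
            genes[i]: pvals[perm[i]]
            for i in range(len(genes))
            if pvals[perm[i]] is not None
        }
    return ExpressionProfile(fc=fc, c=profile.c, m_fc=profile.m_fc, pvalue=pv, alpha=profile.alpha)


def _derive_seed(master: int, counter: int) -> int:
    """Stable per-shuffle seed from a master seed (fixed counter scheme)."""
    return int(np.random.SeedSequence([master, counter]).generate_state(1)[0] % (2**31))


def zscore_evaluation(
    net: RegulatoryNetwork,
    profile: ExpressionProfile,
    N: int,
    null_kind: NullKind,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    n_swaps: int | None = None,
) -> ZScoreResult:
    """Optimal-i-score z-score of the real inputs against a chosen null.

    The optimizer is Act-A* (BEST_ONE) with the same ``N`` for the real run
    and every null run. ``n_swaps`` applies to the degree-preserving null
    (default: 10x the edge count).
    """
    if n_shuffles < 2:
        raise DataError("need at least 2 shuffles for a z-score")
    real = search(net, profile, N, mode=Mode.BEST_ONE).best
    null_scores: list[float] = []
    for i in range(n_shuffles):
        seed_i = _derive_seed(rng_seed, i)
        if null_kind is NullKind.LABEL_SHUFFLE:
            score = search(net, shuffle_gene_labels(profile, seed_i), N, mode=Mode.BEST_ONE).best
        elif null_kind is NullKind.RANDOM_EDGES:
            score = search(randomize_edges(net, seed_i), profile, N, mode=Mode.BEST_ONE).best
        else:
            swaps = n_swaps if n_swaps is not None else 10 * len(net)
            score = search(
                shuffle_degree_preserving(net, swaps, seed_i), profile, N, mode=Mode.BEST_ONE
            ).best
        null_scores.append(score)
    sd = float(np.std(null_scores, ddof=1))
    if sd > 0:
        z = (real - float(np.mean(null_scores))) / sd
    else:
        z = math.nan
    return ZScoreResult(
        real_score=real,
        null_scores=null_scores,
        z=z,
        n_shuffles=n_shuffles,
        null_kind=null_kind,
    )
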