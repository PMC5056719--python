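"""Core semantics: regulatory effects, unexplained target genes, the i-score.

Each transcription factor carries one of three differential activity states
between the two compared conditions: more active (``A_PLUS``), less active
(``A_MINUS``) or unchanged (``A_ZERO``). The regulatory effect of a TF on a
target is the direction of change its state implies through the signed edge:

===========  ========  ========  =========
state        ACT edge  INH edge  UNKNOWN
===========  ========  ========  =========
A_PLUS       PLUS      MINUS     EITHER
A_MINUS      MINUS     PLUS      EITHER
A_ZERO       ZERO      ZERO      ZERO
===========  ========  ========  =========

A differential target gene is *explained* if at least one regulator's effect
matches its direction (EITHER matches both — an unsigned edge is assumed to
have whichever sign helps). The activation function linking several
regulators to one gene is unknown, so a single matching effect suffices
(OR-like explanation). An unchanged gene is explained if at least one
regulator is itself unchanged (the A0 regulator could be limiting under an
AND-like activation function). Otherwise the gene is an unexplained target
gene (UTG).

The inconsistency score of an activity assignment is the summed weight of
its UTGs:

    i-score = sum over UTG of | min(|fc_t|, m_fc) - c |

Only genes that have at least one regulator in the network *and* a measured
fold change are scored; network targets missing from the profile are dropped
with a warning.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import DataError, ParseError
from .expression import ExpressionProfile, GeneCall, Status
from .network import RegulatoryNetwork, Sign

logger = logging.getLogger(__name__)

__all__ = [
    "TFState",
    "Effect",
    "ActivityAssignment",
    "ScoreResult",
    "ScoringInstance",
    "regulatory_effect",
    "is_explained",
    "compute_iscore",
    "read_activities",
    "score_prediction_file",
]


class TFState(enum.Enum):
    A_PLUS = "+"
    A_MINUS = "-"
    A_ZERO = "0"


class Effect(enum.Enum):
    PLUS = "+"
    MINUS = "-"
    ZERO = "0"
    EITHER = "either"


_EFFECT_TABLE: dict[tuple[Sign, TFState], Effect] = {
    (Sign.ACT, TFState.A_PLUS): Effect.PLUS,
    (Sign.ACT, TFState.A_MINUS): Effect.MINUS,
    (Sign.INH, TFState.A_PLUS): Effect.MINUS,
    (Sign.INH, TFState.A_MINUS): Effect.PLUS,
    (Sign.UNKNOWN, TFState.A_PLUS): Effect.EITHER,
    (Sign.UNKNOWN, TFState.A_MINUS): Effect.EITHER,
}


def regulatory_effect(sign: Sign, state: TFState) -> Effect:
    """Direction of change a TF in ``state`` implies through an edge of ``sign``."""
    if state is TFState.A_ZERO:
        return Effect.ZERO
    return _EFFECT_TABLE[(sign, state)]


class ActivityAssignment(Mapping[str, TFState]):
    """A mapping TF -> activity state; TFs absent from the map are A_ZERO."""

    def __init__(self, state: Mapping[str, TFState] | None = None):
        self._state = {
            tf: s for tf, s in (state or {}).items() if s is not TFState.A_ZERO
        }

    def __getitem__(self, tf: str) -> TFState:
        return self._state.get(tf, TFState.A_ZERO)

    def get(self, tf: str, default=None) -> TFState:  # Mapping.get would miss A_ZERO
        return self[tf]

    def __iter__(self):
        return iter(self._state)

    def __len__(self) -> int:
        return len(self._state)

    @property
    def active(self) -> dict[str, TFState]:
        """The differentially active TFs only (A+ / A-)."""
        return dict(self._state)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ActivityAssignment):
            return self._state == other._state
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._state.items()))

    def __repr__(self) -> str:
        inner = ", ".join(f"{tf}:{s.value}" for tf, s in sorted(self._state.items()))
        return f"ActivityAssignment({{{inner}}})"


@dataclass
class ScoreResult:
    """i-score of one assignment plus the per-gene breakdown."""

    iscore: float
    utg: set[str]
    n_utg: int
    per_gene: dict[str, tuple[bool, float]]  # gene -> (explained, weight)
    n_unscored: int = 0  # network targets without a measured fold change


def is_explained(
    gene: str,
    call: GeneCall,
    regulators: list[tuple[str, Sign]],
    assignment: ActivityAssignment,
) -> bool:
    """Whether ``gene``'s observed change is explainable under ``assignment``.

    UP needs some regulator effect in {PLUS, EITHER}; DOWN some effect in
    {MINUS, EITHER}; UNCHANGED needs at least one regulator with unchanged
    activity (A0).
    """
    if not regulators:
        raise DataError(f"gene {gene!r} has no regulators; it should not be scored")
    if call.status is Status.UNCHANGED:
        return any(assignment[tf] is TFState.A_ZERO for tf, _ in regulators)
    wanted = Effect.PLUS if call.status is Status.UP else Effect.MINUS
    for tf, sign in regulators:
        eff = regulatory_effect(sign, assignment[tf])
        if eff is wanted or eff is Effect.EITHER:
            return True
    return False


class ScoringInstance:
    """Preprocessed (network, profile) pair for fast repeated scoring.

    The optimizers evaluate thousands of assignments over a fixed instance;
    this index precomputes, per scored gene, its weight and the set of
    (TF, state) literals that would explain it, and per TF the genes it can
    touch. ``score_active`` then runs in time proportional to the targets of
    the active TFs rather than the whole gene set.
    """

    def __init__(self, net: RegulatoryNetwork, profile: ExpressionProfile):
        self.net = net
        self.profile = profile
        self.genes: list[str] = []
        self.weights: dict[str, float] = {}
        self.calls: dict[str, GeneCall] = {}
        # differential gene -> {tf: set of explaining active states}
        self.explainers: dict[str, dict[str, set[TFState]]] = {}
        # unchanged gene -> set of regulator TFs (explained while any is A0)
        self.unchanged_regs: dict[str, frozenset[str]] = {}
        # tf -> genes whose explanation status it can influence
        self.touches: dict[str, set[str]] = {tf: set() for tf in net.tfs}
        self.n_unscored = 0

        for gene, regs in net.regulators_of.items():
            if gene not in profile.fc:
                self.n_unscored += 1
                continue
            call = profile.call(gene)
            self.genes.append(gene)
            self.calls[gene] = call
            self.weights[gene] = call.weight
            if call.status is Status.UNCHANGED:
                tf_set = frozenset(tf for tf, _ in regs)
                self.unchanged_regs[gene] = tf_set
                for tf in tf_set:
                    self.touches[tf].add(gene)
            else:
                lits: dict[str, set[TFState]] = {}
                for tf, sign in regs:
                    for state in (TFState.A_PLUS, TFState.A_MINUS):
                        if regulatory_effect(sign, state) in (
                            Effect.EITHER,
                            Effect.PLUS if call.status is Status.UP else Effect.MINUS,
                        ):
                            lits.setdefault(tf, set()).add(state)
                self.explainers[gene] = lits
                for tf in lits:
                    self.touches[tf].add(gene)
        if self.n_unscored:
            logger.warning(
                "%d network target(s) have no measured fold change and are not scored",
                self.n_unscored,
            )
        # i-score of the all-A0 assignment: every unchanged gene is explained,
        # every differential gene is not.
        self.null_score = sum(
            self.weights[g] for g in self.genes if g in self.explainers
        )
        self.tfs = sorted(net.tfs)

    def score_active(self, active: Mapping[str, TFState]) -> float:
        """i-score of the assignment where ``active`` holds the non-A0 TFs."""
        active = {tf: s for tf, s in active.items() if s is not TFState.A_ZERO}
        score = self.null_score
        explained: set[str] = set()
        broken: set[str] = set()
        for tf, state in active.items():
            for gene in self.touches.get(tf, ()):
                lits = self.explainers.get(gene)
                if lits is not None:
                    if gene not in explained and state in lits.get(tf, ()):
                        explained.add(gene)
                        score -= self.weights[gene]
                elif gene not in broken:
                    # unchanged gene: loses its explanation only if every
                    # regulator is active
                    broken.add(gene)
                    if all(t in active for t in self.unchanged_regs[gene]):
                        score += self.weights[gene]
        return score

    def unexplained(self, active: Mapping[str, TFState]) -> set[str]:
        """The UTG set of the assignment given by ``active``."""
        utg: set[str] = set()
        for gene, lits in self.explainers.items():
            if not any(active.get(tf, TFState.A_ZERO) in states for tf, states in lits.items()):
                utg.add(gene)
        for gene, regs in self.unchanged_regs.items():
            if all(active.get(tf, TFState.A_ZERO) is not TFState.A_ZERO for tf in regs):
                utg.add(gene)
        return utg


def compute_iscore(
    net: RegulatoryNetwork,
    profile: ExpressionProfile,
    assignment: ActivityAssignment,
    genes: set[str] | None = None,
) -> ScoreResult:
    """i-score of ``assignment`` on (``net``, ``profile``).

    Scores exactly the genes with at least one regulator in the network and
    a measured fold change; pass ``genes`` to additionally restrict scoring
    to an allowlist (e.g. a signature or pathway).
    """
    utg: set[str] = set()
    per_gene: dict[str, tuple[bool, float]] = {}
    total = 0.0
    n_unscored = 0
    for gene, regs in net.regulators_of.items():
        if gene not in profile.fc:
            n_unscored += 1
            continue
        if genes is not None and gene not in genes:
            continue
        call = profile.call(gene)
        explained = is_explained(gene, call, regs, assignment)
        per_gene[gene] = (explained, call.weight)
        if not explained:
            utg.add(gene)
            total += call.weight
    if n_unscored:
        logger.warning(
            "%d network target(s) have no measured fold change and are not scored",
            n_unscored,
        )
    return ScoreResult(
        iscore=total, utg=utg, n_utg=len(utg), per_gene=per_gene, n_unscored=n_unscored
    )


_STATE_TOKENS = {
    "+": TFState.A_PLUS,
    "a+": TFState.A_PLUS,
    "more": TFState.A_PLUS,
    "up": TFState.A_PLUS,
    "-": TFState.A_MINUS,
    "a-": TFState.A_MINUS,
    "less": TFState.A_MINUS,
    "down": TFState.A_MINUS,
    "0": TFState.A_ZERO,
    "a0": TFState.A_ZERO,
    "unchanged": TFState.A_ZERO,
}


def read_activities(
    path: str | Path, top_k: int | None = None
) -> ActivityAssignment:
    """Read a TF activity TSV: ``TF <tab> STATE [<tab> MAGNITUDE]``.

    State tokens: ``+``/``A+``/``more``/``up``, ``-``/``A-``/``less``/
    ``down``, ``0``/``A0``/``unchanged``. With ``top_k`` set, only the
    ``top_k`` TFs with the largest magnitude keep their predicted state; the
    rest are forced to A0 (restriction to the top changing TFs).
    """
    path = Path(path)
    rows: list[tuple[str, TFState, float | None]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError("expected TF <tab> STATE", str(path), lineno)
            tf = row[0].strip()
            if tf in seen:
                raise ParseError(f"duplicate TF {tf!r}", str(path), lineno)
            seen.add(tf)
            token = row[1].strip().lower()
            if token not in _STATE_TOKENS:
                raise ParseError(f"unknown state token {row[1]!r}", str(path), lineno)
            mag: float | None = None
            if len(row) > 2 and row[2].strip():
                try:
                    mag = float(row[2])
                except ValueError:
                    raise ParseError(
                        f"non-numeric magnitude {row[2]!r}", str(path), lineno
                    ) from None
            rows.append((tf, _STATE_TOKENS[token], mag))
    if top_k is not None:
        if any(m is None for _, s, m in rows if s is not TFState.A_ZERO):
            raise DataError("top_k restriction requires a magnitude column")
        ranked = sorted(
            (r for r in rows if r[1] is not TFState.A_ZERO),
            key=lambda r: (-abs(r[2]), r[0]),
        )
        keep = {tf for tf, _, _ in ranked[:top_k]}
        rows = [(tf, s if tf in keep else TFState.A_ZERO, m) for tf, s, m in rows]
    return ActivityAssignment({tf: s for tf, s, _ in rows})


def score_prediction_file(
    net: RegulatoryNetwork,
    profile: ExpressionProfile,
    activity_path: str | Path,
    top_k: int | None = None,
    genes: set[str] | None = None,
) -> ScoreResult:
    """Score a TF activity prediction stored as a TSV file."""
    assignment = read_activities(activity_path, top_k=top_k)
    return compute_iscore(net, profile, assignment, genes=genes)
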