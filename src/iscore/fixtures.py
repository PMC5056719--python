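"""Synthetic networks and fold-change profiles with planted active TFs.

The generator builds a random TF->gene network, plants a small set of
differentially active TFs, and derives each gene's expression status from
its regulators under the same exists-an-explaining-TF semantics the scoring
uses: a gene is differential iff some planted regulator's effect pushes it,
with the direction decided by the majority of pushing effects (ties go UP;
unsigned edges from active TFs push either way and count for neither side).
Fold changes are then sampled around a status-consistent effect size with
Gaussian noise, and a configurable fraction of genes gets its status
flipped to a uniformly chosen different status (planted model violations).

This generative rule deliberately mirrors the explanation semantics rather
than, say, an additive expression model: in the noiseless, violation-free
limit the planted assignment has i-score exactly 0 and is recoverable — the
right null for testing the scoring and the optimizers, not a biological
claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .expression import ExpressionProfile, Status
from .network import Edge, RegulatoryNetwork, Sign
from .scoring import ActivityAssignment, Effect, TFState, regulatory_effect

__all__ = ["FixtureSpec", "generate", "worked_example", "WORKED_EXAMPLE_OPTIMUM"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic instance.

    Defaults describe a small but non-trivial study: 12 TFs regulating 120
    genes with 3 regulators each, the empirical roughly-2:1:1 mix of
    activating/inhibiting/unsigned annotations, two planted active TFs, a
    mean effect of 2.5 log2 units (comfortably above the differential cutoff
    of 1), mild noise and a 5% model-violation rate.
    """

    n_tfs: int = 12
    n_genes: int = 120
    edges_per_gene: int = 3
    sign_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)  # act, inh, unknown
    planted: dict[str, TFState] = field(default_factory=dict)
    n_planted: int = 2  # used only when `planted` is empty
    fc_effect: float = 2.5
    noise_sd: float = 0.3
    background_flip_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_genes < 1:
            raise DataError("need at least one TF and one gene")
        if self.edges_per_gene < 1 or self.edges_per_gene > self.n_tfs:
            raise DataError("edges_per_gene must be in [1, n_tfs]")
        if any(not 0 <= p <= 1 for p in self.sign_fractions) or not math.isclose(
            sum(self.sign_fractions), 1.0, abs_tol=1e-9
        ):
            raise DataError("sign_fractions must be in [0,1] and sum to 1")
        if not 0 <= self.background_flip_rate <= 1:
            raise DataError("background_flip_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be non-negative")
        if self.fc_effect <= 0:
            raise DataError("fc_effect must be positive")
        if not self.planted and not 0 <= self.n_planted <= self.n_tfs:
            raise DataError("n_planted must be in [0, n_tfs]")


_SIGNS = (Sign.ACT, Sign.INH, Sign.UNKNOWN)


def generate(
    spec: FixtureSpec,
) -> tuple[RegulatoryNetwork, ExpressionProfile, ActivityAssignment]:
    """Sample a (network, profile, planted-truth) triple from ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    tf_names = [f"TF{i + 1:02d}" for i in range(spec.n_tfs)]
    gene_names = [f"G{i + 1:04d}" for i in range(spec.n_genes)]

    edges: list[Edge] = []
    regulators: dict[str, list[tuple[str, Sign]]] = {}
    for gene in gene_names:
        tf_idx = rng.choice(spec.n_tfs, size=spec.edges_per_gene, replace=False)
        signs = rng.choice(3, size=spec.edges_per_gene, p=spec.sign_fractions)
        regs = [(tf_names[i], _SIGNS[s]) for i, s in zip(tf_idx, signs)]
        regulators[gene] = regs
        edges.extend(Edge(tf, gene, sign) for tf, sign in regs)
    net = RegulatoryNetwork(edges)

    if spec.planted:
        unknown = set(spec.planted) - set(tf_names)
        if unknown:
            raise DataError(f"planted TFs not in the fixture TF set: {sorted(unknown)}")
        planted = {
            tf: s for tf, s in spec.planted.items() if s is not TFState.A_ZERO
        }
    else:
        chosen = rng.choice(spec.n_tfs, size=spec.n_planted, replace=False)
        states = rng.choice(2, size=spec.n_planted)
        planted = {
            tf_names[i]: (TFState.A_PLUS if s == 0 else TFState.A_MINUS)
            for i, s in zip(chosen, states)
        }
    truth = ActivityAssignment(planted)

    def sample_fc(status: Status) -> float:
        if status is Status.UP:
            return spec.fc_effect + rng.normal(0.0, spec.noise_sd)
        if status is Status.DOWN:
            return -spec.fc_effect + rng.normal(0.0, spec.noise_sd)
        return rng.normal(0.0, spec.noise_sd)

    fc: dict[str, float] = {}
    for gene in gene_names:
        up = down = either = 0
        for tf, sign in regulators[gene]:
            eff = regulatory_effect(sign, truth[tf])
            if eff is Effect.PLUS:
                up += 1
            elif eff is Effect.MINUS:
                down += 1
            elif eff is Effect.EITHER:
                either += 1
        if up + down + either == 0:
            status = Status.UNCHANGED
        elif up >= down:
            status = Status.UP  # ties resolve UP by convention
        else:
            status = Status.DOWN
        if rng.random() < spec.background_flip_rate:
            others = [s for s in (Status.UP, Status.DOWN, Status.UNCHANGED) if s is not status]
            status = others[rng.integers(2)]
        fc[gene] = sample_fc(status)

    profile = ExpressionProfile(fc=fc)
    return net, profile, truth


#: hand-verified optimum of :func:`worked_example` (27 assignments enumerated)
WORKED_EXAMPLE_OPTIMUM = {
    "assignment": {"T1": TFState.A_PLUS, "T3": TFState.A_PLUS},
    "iscore": 1.0,
    "utg": {"G2", "G6"},
}


def worked_example() -> tuple[RegulatoryNetwork, ExpressionProfile]:
    """The fixed 3-TF, 6-gene instance used in the docs and test suite.

    Edges (8) and fold changes (cutoff c=1, trim m_fc=3):

    ========  ======  =======   ====  =====  =========  ======
    TF        target  sign      gene  fc     status     weight
    ========  ======  =======   ====  =====  =========  ======
    T1        G1      ACT       G1    2.5    UP         1.5
    T1        G2      ACT       G2    -1.5   DOWN       0.5
    T2        G2      INH       G3    0.0    UNCHANGED  1.0
    T2        G3      ACT       G4    1.8    UP         0.8
    T3        G4      UNKNOWN   G5    -4.0   DOWN       2.0
    T3        G5      INH       G6    0.5    UNCHANGED  0.5
    T1        G6      ACT
    T3        G6      ACT
    ========  ======  =======   ====  =====  =========  ======

    The unique optimum over all 27 assignments is {T1: A+, T3: A+} with
    i-score 1.0 and UTG {G2, G6}: T1=A+ explains G1, T3=A+ explains G4 (via
    the unsigned edge) and G5 (inhibiting edge, more active -> repression),
    G3 is explained by T2 staying at A0, while G2 (weight 0.5) and G6
    (weight 0.5, both regulators active) stay unexplained.
    """
    edges = [
        Edge("T1", "G1", Sign.ACT),
        Edge("T1", "G2", Sign.ACT),
        Edge("T2", "G2", Sign.INH),
        Edge("T2", "G3", Sign.ACT),
        Edge("T3", "G4", Sign.UNKNOWN),
        Edge("T3", "G5", Sign.INH),
        Edge("T1", "G6", Sign.ACT),
        Edge("T3", "G6", Sign.ACT),
    ]
    fc = {"G1": 2.5, "G2": -1.5, "G3": 0.0, "G4": 1.8, "G5": -4.0, "G6": 0.5}
    return RegulatoryNetwork(edges), ExpressionProfile(fc=fc)


def spec_from_yaml(path: str | Path) -> FixtureSpec:
    """Load a FixtureSpec from a YAML mapping (keys = dataclass fields)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError("fixture spec YAML must be a mapping")
    if "planted" in raw and raw["planted"]:
        raw["planted"] = {
            tf: TFState(str(tok)) for tf, tok in dict(raw["planted"]).items()
        }
    if "sign_fractions" in raw:
        raw["sign_fractions"] = tuple(raw["sign_fractions"])
    try:
        return FixtureSpec(**raw)
    except TypeError as exc:
        raise DataError(f"invalid fixture spec: {exc}") from None
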