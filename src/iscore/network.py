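"""Signed TF->target regulatory networks: parsing, validation, randomization.

A network is a set of directed edges from transcription factors (TFs) to
target genes. Each edge carries a regulation sign: activating (``Sign.ACT``),
inhibiting (``Sign.INH``) or unknown (``Sign.UNKNOWN``). Unknown signs are
resolved optimistically downstream — the edge may act as either sign,
whichever can explain the target's observed change.

Two null models are provided for network assessment: uniform edge
resampling with the TF/target node sets and edge count held fixed
(:func:`randomize_edges`), and degree-preserving double-edge swaps
(:func:`shuffle_degree_preserving`).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import DataError, InfeasibleError, ParseError

__all__ = [
    "Sign",
    "Edge",
    "RegulatoryNetwork",
    "parse_network",
    "write_network",
    "write_sif",
    "randomize_edges",
    "shuffle_degree_preserving",
]


class Sign(enum.Enum):
    """Annotated sign of a regulatory edge."""

    ACT = "+"
    INH = "-"
    UNKNOWN = "?"


#: accepted sign tokens in network TSV files (case-insensitive)
_SIGN_TOKENS = {
    "+": Sign.ACT,
    "activator": Sign.ACT,
    "act": Sign.ACT,
    "-": Sign.INH,
    "inhibitor": Sign.INH,
    "inh": Sign.INH,
    "?": Sign.UNKNOWN,
    "": Sign.UNKNOWN,
    "unknown": Sign.UNKNOWN,
}


@dataclass(frozen=True)
class Edge:
    """One directed regulation: ``tf`` regulates ``target`` with ``sign``."""

    tf: str
    target: str
    sign: Sign = Sign.UNKNOWN

    def __post_init__(self) -> None:
        if not self.tf or not self.target:
            raise DataError("edge endpoints must be non-empty identifiers")
        if not isinstance(self.sign, Sign):
            raise DataError(f"invalid edge sign: {self.sign!r}")


class RegulatoryNetwork:
    """An indexed, validated set of signed TF->target edges.

    Duplicate (tf, target) pairs are merged on construction; if the
    duplicates carry conflicting signs the merged edge gets ``Sign.UNKNOWN``
    (the information-preserving choice, since unknown signs are treated
    optimistically by the scoring semantics). A gene may appear both as a
    TF and as a target; self-loops are permitted.
    """

    def __init__(
        self,
        edges: Iterable[Edge],
        tfs: Iterable[str] = (),
        targets: Iterable[str] = (),
    ):
        merged: dict[tuple[str, str], Sign] = {}
        for e in edges:
            key = (e.tf, e.target)
            if key in merged and merged[key] is not e.sign:
                merged[key] = Sign.UNKNOWN
            elif key not in merged:
                merged[key] = e.sign
        if not merged:
            raise DataError("network has no edges")
        self._edges = frozenset(Edge(tf, tg, s) for (tf, tg), s in merged.items())
        # optional extra node names admit isolated TFs/targets, e.g. after
        # edge randomization that leaves an original node without edges
        self.tfs = frozenset(e.tf for e in self._edges) | frozenset(tfs)
        self.targets = frozenset(e.target for e in self._edges) | frozenset(targets)
        regs: dict[str, list[tuple[str, Sign]]] = {}
        for e in sorted(self._edges, key=lambda e: (e.target, e.tf)):
            regs.setdefault(e.target, []).append((e.tf, e.sign))
        self.regulators_of: dict[str, list[tuple[str, Sign]]] = regs

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegulatoryNetwork)
            and self._edges == other._edges
            and self.tfs == other.tfs
            and self.targets == other.targets
        )

    def __hash__(self) -> int:
        return hash(self._edges)

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({len(self._edges)} edges, "
            f"{len(self.tfs)} TFs, {len(self.targets)} targets)"
        )

    def out_degrees(self) -> dict[str, int]:
        deg = {t: 0 for t in self.tfs}
        for e in self._edges:
            deg[e.tf] += 1
        return deg

    def in_degrees(self) -> dict[str, int]:
        deg = {t: 0 for t in self.targets}
        for e in self._edges:
            deg[e.target] += 1
        return deg


def parse_network(path: str | Path) -> RegulatoryNetwork:
    """Read a network from a TSV edge list.

    Columns are ``TF <tab> TARGET [<tab> SIGN]``; lines starting with ``#``
    are comments. A missing sign column means unknown sign. Sign tokens:
    ``+``/``activator`` -> ACT, ``-``/``inhibitor`` -> INH, ``?`` or empty
    -> UNKNOWN.

    Raises
    ------
    ParseError
        On a row with fewer than two columns or an unrecognized sign token,
        naming the offending line.
    DataError
        If the file contains no edges.
    """
    path = Path(path)
    edges: list[Edge] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(
                    f"expected at least 2 tab-separated columns, got {len(row)}",
                    str(path),
                    lineno,
                )
            tf, target = row[0].strip(), row[1].strip()
            token = row[2].strip().lower() if len(row) > 2 else ""
            if token not in _SIGN_TOKENS:
                raise ParseError(f"unknown sign token {row[2]!r}", str(path), lineno)
            if not tf or not target:
                raise ParseError("empty TF or target identifier", str(path), lineno)
            edges.append(Edge(tf, target, _SIGN_TOKENS[token]))
    if not edges:
        raise DataError(f"network file {path} contains no edges")
    return RegulatoryNetwork(edges)


def write_network(net: RegulatoryNetwork, path: str | Path, header: str | None = None) -> None:
    """Write a network as a TSV edge list (same dialect parse_network reads)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for e in sorted(net.edges, key=lambda e: (e.tf, e.target)):
            fh.write(f"{e.tf}\t{e.target}\t{e.sign.value}\n")


_SIF_TYPE = {Sign.ACT: "act", Sign.INH: "inh", Sign.UNKNOWN: "reg"}


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Export to a SIF-like format: ``TF <tab> act|inh|reg <tab> TARGET``."""
    with open(path, "w") as fh:
        for e in sorted(net.edges, key=lambda e: (e.tf, e.target)):
            fh.write(f"{e.tf}\t{_SIF_TYPE[e.sign]}\t{e.target}\n")


def randomize_edges(net: RegulatoryNetwork, rng_seed: int) -> RegulatoryNetwork:
    """Random network null: same TFs, same targets, same edge count.

    Edges are drawn uniformly without replacement from tfs x targets. All
    random edges get ``Sign.UNKNOWN`` — the maximally permissive sign, so
    the random-network null scores as well as it possibly can (a
    conservative null for network assessment).
    """
    tfs = sorted(net.tfs)
    targets = sorted(net.targets)
    n_pairs = len(tfs) * len(targets)
    n_edges = len(net)
    if n_pairs < n_edges:
        raise InfeasibleError(
            f"cannot place {n_edges} distinct edges in {n_pairs} TF-target pairs"
        )
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n_pairs, size=n_edges, replace=False)
    n_t = len(targets)
    edges = [Edge(tfs[i // n_t], targets[i % n_t], Sign.UNKNOWN) for i in idx]
    return RegulatoryNetwork(edges, tfs=net.tfs, targets=net.targets)


def shuffle_degree_preserving(
    net: RegulatoryNetwork, n_swaps: int, rng_seed: int
) -> RegulatoryNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    A swap rewires ``(a->x), (b->y)`` to ``(a->y), (b->x)``; proposals that
    would duplicate an existing edge are rejected and retried, so every TF
    keeps its out-degree and every target its in-degree. Signs travel with
    the TF endpoint, conserving each TF's sign composition. ``n_swaps``
    counts accepted swaps; a total-attempt cap prevents non-termination on
    networks with no legal swap.
    """
    if len(net) < 2:
        raise DataError("need at least 2 edges to swap")
    if n_swaps < 0:
        raise DataError("n_swaps must be non-negative")
    rng = np.random.default_rng(rng_seed)
    edges = sorted(net.edges, key=lambda e: (e.tf, e.target))
    present = {(e.tf, e.target) for e in edges}
    accepted = 0
    attempts = 0
    max_attempts = max(1000, 50 * n_swaps)
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i], edges[j]
        if a.target == b.target or a.tf == b.tf:
            continue
        new_a, new_b = (a.tf, b.target), (b.tf, a.target)
        if new_a in present or new_b in present:
            continue
        present.discard((a.tf, a.target))
        present.discard((b.tf, b.target))
        present.add(new_a)
        present.add(new_b)
        edges[i] = Edge(a.tf, b.target, a.sign)
        edges[j] = Edge(b.tf, a.target, b.sign)
        accepted += 1
    return RegulatoryNetwork(edges, tfs=net.tfs, targets=net.targets)
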