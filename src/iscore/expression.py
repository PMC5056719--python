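"""Log fold-change profiles and differential gene calls.

A profile maps each gene to a log2 fold change between two conditions.
Genes are called UP if ``fc > c``, DOWN if ``fc < -c``, otherwise
UNCHANGED, for a differential cutoff ``c`` (default 1). Each gene also
carries a nonnegative weight

    weight = | min(|fc|, m_fc) - c |

— its contribution to the inconsistency score should it end up
unexplained. Fold changes are trimmed at ``m_fc`` (default 3) so that a
handful of extreme genes cannot dominate the score. Genes sitting exactly
at |fc| = c get weight 0, so the strict/non-strict choice at the boundary
cannot change any score.

When a p-value column is present and ``alpha`` is set, differential calls
additionally require ``p < alpha`` (weights are unchanged); the default is
fold-change-only calling.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import DataError, ParseError

__all__ = ["Status", "GeneCall", "ExpressionProfile", "load_profile", "write_profile"]


class Status(enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class GeneCall:
    """Differential status and UTG weight of one gene."""

    status: Status
    weight: float


@dataclass
class ExpressionProfile:
    """Per-gene log2 fold changes plus differential-call parameters.

    Parameters
    ----------
    fc
        Gene -> log2 fold change. Every value must be finite.
    c
        Differential cutoff on |log2 fc| (default 1).
    m_fc
        Trim ceiling for |log2 fc| in the weight (default 3); must exceed c.
    pvalue
        Optional gene -> p-value map.
    alpha
        Optional significance level; when set (and a p-value exists for the
        gene), UP/DOWN additionally require p < alpha.
    """

    fc: dict[str, float]
    c: float = 1.0
    m_fc: float = 3.0
    pvalue: dict[str, float] | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.c < self.m_fc):
            raise DataError(f"require 0 < c < m_fc, got c={self.c}, m_fc={self.m_fc}")
        for g, v in self.fc.items():
            if not math.isfinite(v):
                raise DataError(f"non-finite fold change for gene {g!r}")
        if self.pvalue is not None:
            for g, p in self.pvalue.items():
                if not (0.0 <= p <= 1.0):
                    raise DataError(f"p-value for gene {g!r} outside [0, 1]: {p}")

    @property
    def genes(self) -> set[str]:
        return set(self.fc)

    def call(self, gene: str) -> GeneCall:
        """Differential status and weight of ``gene`` (raises on unknown gene)."""
        if gene not in self.fc:
            raise DataError(f"gene {gene!r} not in profile")
        fc = self.fc[gene]
        weight = abs(min(abs(fc), self.m_fc) - self.c)
        significant = True
        if self.alpha is not None and self.pvalue is not None and gene in self.pvalue:
            significant = self.pvalue[gene] < self.alpha
        if fc > self.c and significant:
            status = Status.UP
        elif fc < -self.c and significant:
            status = Status.DOWN
        else:
            status = Status.UNCHANGED
        return GeneCall(status, weight)


def call_gene(profile: ExpressionProfile, gene: str) -> GeneCall:
    """Functional alias for :meth:`ExpressionProfile.call`."""
    return profile.call(gene)


def load_profile(
    path: str | Path,
    c: float = 1.0,
    m_fc: float = 3.0,
    alpha: float | None = None,
) -> ExpressionProfile:
    """Read a profile TSV: ``GENE <tab> LOG2FC [<tab> PVALUE]``.

    ``#`` comment lines are skipped. Duplicate gene rows and non-numeric
    fold changes are errors (reported with their line number).
    """
    path = Path(path)
    fc: dict[str, float] = {}
    pv: dict[str, float] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError("expected GENE <tab> LOG2FC", str(path), lineno)
            gene = row[0].strip()
            if gene in fc:
                raise ParseError(f"duplicate gene {gene!r}", str(path), lineno)
            try:
                value = float(row[1])
            except ValueError:
                raise ParseError(
                    f"non-numeric fold change {row[1]!r} for gene {gene!r}",
                    str(path),
                    lineno,
                ) from None
            if not math.isfinite(value):
                raise ParseError(f"non-finite fold change for {gene!r}", str(path), lineno)
            fc[gene] = value
            if len(row) > 2 and row[2].strip():
                try:
                    pv[gene] = float(row[2])
                except ValueError:
                    raise ParseError(
                        f"non-numeric p-value {row[2]!r}", str(path), lineno
                    ) from None
    if not fc:
        raise DataError(f"profile file {path} contains no genes")
    return ExpressionProfile(fc=fc, c=c, m_fc=m_fc, pvalue=pv or None, alpha=alpha)


def write_profile(profile: ExpressionProfile, path: str | Path, header: str | None = None) -> None:
    """Write a profile in the TSV dialect :func:`load_profile` reads."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for gene in sorted(profile.fc):
            row = f"{gene}\t{profile.fc[gene]:.10g}"
            if profile.pvalue and gene in profile.pvalue:
                row += f"\t{profile.pvalue[gene]:.10g}"
            fh.write(row + "\n")
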