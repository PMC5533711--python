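"""Domain types: matrices, gene sets and edge lists.

Matrices wrap a :class:`pandas.DataFrame` with genes as rows and arrays (or
experimental comparisons) as columns; ``NaN`` marks a missing cell.  All
identifiers are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "UPCMatrix",
    "DEMatrix",
    "GeneSet",
    "NetworkEdgeList",
]


def _check_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {what}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column ids in {what}: {dups[:5]}")
    return df.astype(float)


@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of normalized expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = _check_frame(self.values, "expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep])


@dataclass
class UPCMatrix:
    """Genes x arrays matrix of expression-call scores in [0, 1]."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = _check_frame(self.scores, "UPC matrix")
        vals = self.scores.to_numpy(float)
        bad = (vals < 0.0) | (vals > 1.0)
        if np.any(bad & ~np.isnan(vals)):
            g, a = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"UPC score outside [0, 1] at gene "
                f"{self.scores.index[g]!r}, array {self.scores.columns[a]!r}: "
                f"{vals[g, a]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class DEMatrix:
    """Genes x comparisons differential-expression values with p-values.

    ``de`` may contain missing cells; ``p`` never does — missing p-values are
    substituted with 1 at construction time so that an imputed entry can never
    count as significant.
    """

    de: pd.DataFrame
    p: pd.DataFrame

    def __post_init__(self) -> None:
        self.de = _check_frame(self.de, "DE matrix")
        self.p = _check_frame(self.p, "p-value matrix")
        if set(self.p.index) != set(self.de.index) or set(self.p.columns) != set(
            self.de.columns
        ):
            raise ValidationError("DE and p-value matrices have different ids")
        self.p = self.p.reindex(index=self.de.index, columns=self.de.columns)
        self.p = self.p.fillna(1.0)
        vals = self.p.to_numpy(float)
        if np.any((vals < 0.0) | (vals > 1.0)):
            raise ValidationError("p-values outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.de.index)

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.de.columns)

    def subset_genes(self, genes: Iterable[str]) -> "DEMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return DEMatrix(self.de.loc[keep], self.p.loc[keep])


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers (GMT-style)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate members")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class NetworkEdgeList:
    """Undirected, scored gene-gene edges; no self-loops, no duplicates.

    Scores are integers in [0, 1000] or ``None`` (score unknown / stripped,
    e.g. after filtering).  ``(a, b)`` and ``(b, a)`` are the same edge.
    """

    _edges: dict[tuple[str, str], Optional[int]] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, Optional[int]]]
    ) -> "NetworkEdgeList":
        """Build from (a, b, score) triples, deduplicating by max score."""
        net = cls()
        for a, b, score in edges:
            net.add(a, b, score)
        return net

    def add(self, a: str, b: str, score: Optional[int] = None) -> None:
        if a == b:
            raise ValidationError(f"self-loop edge ({a!r}, {b!r})")
        key = _edge_key(a, b)
        old = self._edges.get(key, None)
        if key in self._edges:
            # keep the max score; None loses to any number
            if old is None:
                self._edges[key] = score
            elif score is not None and score > old:
                self._edges[key] = score
        else:
            self._edges[key] = score

    def edges(self) -> list[tuple[str, str, Optional[int]]]:
        """Edges in deterministic lexicographic order."""
        return [(a, b, s) for (a, b), s in sorted(self._edges.items())]

    def nodes(self) -> list[str]:
        seen: set[str] = set()
        for a, b in self._edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    def score(self, a: str, b: str) -> Optional[int]:
        return self._edges[_edge_key(a, b)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _edge_key(*pair) in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkEdgeList):
            return NotImplemented
        return set(self._edges) == set(other._edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), s in self._edges.items():
            g.add_edge(a, b, score=s)
        return g
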