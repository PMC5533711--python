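"""Readers and writers for the external text formats.

Matrix files are TSV: first row holds column (array/comparison) ids, first
column holds gene ids; an empty cell or the token ``NA`` means missing.
Association-network link files are whitespace-separated triples
``node1 node2 score`` with scores in [0, 1000]; gene sets use the standard
GMT dialect.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyInputError,
    FormatError,
    ParseError,
    ValidationError,
)
from .types import DEMatrix, ExpressionMatrix, GeneSet, NetworkEdgeList, UPCMatrix

__all__ = [
    "read_matrix",
    "read_de_matrix",
    "read_string_links",
    "read_gmt",
    "read_id_mapping",
    "read_gene_list",
    "write_matrix",
    "write_edgelist",
    "write_gene_list",
]

_MISSING_TOKENS = {"", "NA"}


def _read_raw_matrix(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, header=0
    )
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j].strip() if isinstance(arr[i, j], str) else arr[i, j]
            if cell in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name}: non-numeric cell {cell!r} at row "
                    f"{raw.index[i]!r}, column {raw.columns[j]!r}"
                ) from None
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def read_matrix(
    path: Union[str, Path], kind: str = "expression"
) -> Union[ExpressionMatrix, UPCMatrix]:
    """Read a genes-x-columns TSV matrix.

    Parameters
    ----------
    path
        TSV file; first row column ids, first column gene ids.
    kind
        ``"expression"`` or ``"upc"``; UPC scores must lie in [0, 1].
    """
    frame = _read_raw_matrix(path)
    if kind == "expression":
        return ExpressionMatrix(frame)
    if kind == "upc":
        return UPCMatrix(frame)
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_de_matrix(
    values_path: Union[str, Path], pvalues_path: Union[str, Path]
) -> DEMatrix:
    """Read paired DE-value and p-value matrices.

    The two files must contain the same gene and comparison ids (order
    insensitive).  Missing p-values are substituted with 1; missing DE values
    stay missing.
    """
    de = _read_raw_matrix(values_path)
    p = _read_raw_matrix(pvalues_path)
    if set(de.index) != set(p.index):
        only_de = sorted(set(de.index) - set(p.index))[:5]
        only_p = sorted(set(p.index) - set(de.index))[:5]
        raise AlignmentError(
            f"gene ids differ between DE and p-value files "
            f"(only in DE: {only_de}, only in p: {only_p})"
        )
    if set(de.columns) != set(p.columns):
        raise AlignmentError("comparison ids differ between DE and p-value files")
    return DEMatrix(de, p.reindex(index=de.index, columns=de.columns))


def read_id_mapping(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column TSV mapping (e.g. protein id -> gene id)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"mapping line {lineno}: expected 2 columns")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_string_links(
    path: Union[str, Path],
    score_min: int = 700,
    mapping: Optional[dict[str, str]] = None,
) -> NetworkEdgeList:
    """Read a STRING-style link file and filter by combined score.

    Keeps edges with ``score >= score_min`` (scoreless lines — two tokens, as
    produced by :func:`write_edgelist` — always pass).  An optional id mapping
    is applied to both endpoints; edges with an unmapped endpoint are dropped
    and the drop count reported via a warning.  Self-loops are removed and
    duplicate undirected pairs collapsed keeping the maximum score.
    """
    net = NetworkEdgeList()
    n_unmapped = 0
    n_data = 0
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) < 2:
            raise ParseError(f"link line {lineno}: expected at least 2 columns")
        score: Optional[float]
        if len(tokens) == 2:
            score = None  # edgelist dialect with empty weight column
        else:
            try:
                score = float(tokens[2])
            except ValueError:
                if n_data == 0:
                    continue  # header line: non-numeric score token
                raise ParseError(
                    f"link line {lineno}: non-numeric score {tokens[2]!r}"
                ) from None
        n_data += 1
        a, b = tokens[0], tokens[1]
        if mapping is not None:
            if a not in mapping or b not in mapping:
                n_unmapped += 1
                continue
            a, b = mapping[a], mapping[b]
        if score is not None and score < score_min:
            continue
        if a == b:
            continue
        net.add(a, b, None if score is None else int(score))
    if n_data == 0:
        raise EmptyInputError(f"{path}: no parseable data lines")
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} edge(s) dropped because an endpoint had no mapping",
            stacklevel=2,
        )
    return net


def read_gmt(path: Union[str, Path]) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        if len(parts) < 3:
            raise FormatError(
                f"GMT line {lineno}: expected name, description and at least "
                f"one member (got {len(parts)} fields)"
            )
        name, description, members = parts[0], parts[1], parts[2:]
        members = [m for m in members if m]
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn(
                f"GMT line {lineno} ({name!r}): duplicate members collapsed",
                stacklevel=2,
            )
        sets.append(GeneSet(name, description, tuple(unique)))
    return sets


def read_gene_list(path: Union[str, Path]) -> list[str]:
    """Read a plain one-id-per-line gene list."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_matrix(frame_or_matrix, path: Union[str, Path]) -> None:
    """Write a matrix (or bare DataFrame) as TSV with empty cells for NaN."""
    if isinstance(frame_or_matrix, pd.DataFrame):
        frame = frame_or_matrix
    elif isinstance(frame_or_matrix, ExpressionMatrix):
        frame = frame_or_matrix.values
    elif isinstance(frame_or_matrix, UPCMatrix):
        frame = frame_or_matrix.scores
    else:
        raise TypeError("expected a DataFrame-backed matrix")
    frame.to_csv(path, sep="\t", na_rep="", index_label="")


def write_edgelist(network: NetworkEdgeList, path: Union[str, Path]) -> None:
    """Write an edge list as ``gene_a<TAB>gene_b<TAB>`` lines.

    The third (weight) column is intentionally left empty; edges are written
    in lexicographic order for determinism.
    """
    with open(path, "w") as fh:
        for a, b, _ in network.edges():
            fh.write(f"{a}\t{b}\t\n")
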