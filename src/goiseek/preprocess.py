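"""Expression-call filtering, missingness filtering and KNN imputation.

A gene is called expressed when its call score strictly exceeds the threshold
in at least one array.  Genes missing in strictly more than the allowed number
of columns are discarded; remaining holes are filled with a row-wise k-nearest
-neighbour mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import DEMatrix, ExpressionMatrix, GeneSet, UPCMatrix

__all__ = [
    "PreprocessConfig",
    "call_expressed_genes",
    "filter_missing_genes",
    "knn_impute",
]

Matrix = Union[ExpressionMatrix, DEMatrix]


@dataclass
class PreprocessConfig:
    upc_threshold: float = 0.5
    max_missing_fraction: float = 0.5
    knn_k: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.upc_threshold <= 1.0:
            raise ValidationError("upc_threshold must lie in [0, 1]")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")


def call_expressed_genes(upc: UPCMatrix, threshold: float = 0.5) -> GeneSet:
    """Genes whose maximum non-missing score strictly exceeds ``threshold``.

    Genes with every score missing are excluded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    if upc.scores.empty:
        raise ValidationError("empty UPC matrix")
    best = upc.scores.max(axis=1, skipna=True)  # NaN if all missing
    expressed = [g for g, v in best.items() if pd.notna(v) and v > threshold]
    return GeneSet("expressed", f"call score > {threshold}", tuple(expressed))


def _frame_of(matrix: Matrix) -> pd.DataFrame:
    return matrix.de if isinstance(matrix, DEMatrix) else matrix.values


def _rebuild(matrix: Matrix, frame: pd.DataFrame) -> Matrix:
    if isinstance(matrix, DEMatrix):
        return DEMatrix(frame, matrix.p.loc[frame.index])
    return ExpressionMatrix(frame)


def filter_missing_genes(
    matrix: Matrix,
    max_missing_fraction: float = 0.5,
    max_missing: Optional[int] = None,
) -> tuple[Matrix, list[str]]:
    """Drop genes missing in strictly more than the allowed number of columns.

    The cutoff is ``max_missing`` when given, else
    ``floor(max_missing_fraction * n_columns)``; a gene missing in exactly the
    cutoff number of columns is kept.
    """
    frame = _frame_of(matrix)
    if max_missing is None:
        if not 0.0 <= max_missing_fraction <= 1.0:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")
        cutoff = math.floor(max_missing_fraction * frame.shape[1])
    else:
        cutoff = int(max_missing)
    miss = frame.isna().sum(axis=1)
    keep = miss <= cutoff
    dropped = list(frame.index[~keep])
    return _rebuild(matrix, frame.loc[keep]), dropped


def knn_impute(matrix: Matrix, k: int = 10) -> Matrix:
    """Fill missing cells with the mean of the k nearest genes' values.

    Distance between two genes is the mean squared difference over the columns
    observed in both (so genes with different missingness remain comparable);
    a neighbour is eligible for cell (g, c) only if it is observed at column c
    and shares at least one observed column with g.  Fewer than k eligible
    neighbours -> use them all; none -> fall back to the column mean.
    Observed cells are returned bit-identical.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    frame = _frame_of(matrix)
    X = frame.to_numpy(float)
    obs = ~np.isnan(X)
    if X.size == 0:
        raise ValidationError("empty matrix")
    if not obs.any(axis=0).all():
        col = frame.columns[~obs.any(axis=0)][0]
        raise ValidationError(f"column {col!r} has no observed values")
    if not obs.any(axis=1).all():
        gene = frame.index[~obs.any(axis=1)][0]
        raise ValidationError(f"gene {gene!r} has no observed values")

    out = X.copy()
    col_means = np.nanmean(X, axis=0)
    n = X.shape[0]
    for g in np.where(~obs.all(axis=1))[0]:
        shared = obs & obs[g]  # n x m
        counts = shared.sum(axis=1)
        diff = np.where(shared, X - X[g], 0.0)
        with np.errstate(invalid="ignore"):
            dist = np.where(counts > 0, (diff**2).sum(axis=1) / counts, np.inf)
        dist[g] = np.inf
        for c in np.where(~obs[g])[0]:
            cand = np.where(obs[:, c] & np.isfinite(dist))[0]
            if cand.size == 0:
                out[g, c] = col_means[c]
                continue
            order = cand[np.argsort(dist[cand], kind="stable")]
            out[g, c] = X[order[:k], c].mean()
    return _rebuild(matrix, pd.DataFrame(out, index=frame.index, columns=frame.columns))
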