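"""Seed-gene biclustering.

Starting from a set of seed genes, arrays are greedily removed to maximise
the seeds' mean pairwise correlation (until it reaches a threshold or half
the arrays are gone), then genes from a candidate pool are greedily added
whenever they strictly increase the mean pairwise correlation of the growing
list.  The two phases alternate until a fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .types import ExpressionMatrix, GeneSet

__all__ = [
    "BiclusterConfig",
    "Bicluster",
    "ArrayRemovalStep",
    "GeneAdditionStep",
    "mean_pairwise_correlation",
    "reduce_arrays",
    "grow_genes",
    "run_bicluster",
]


@dataclass
class BiclusterConfig:
    c_threshold: float = 0.75
    max_removed_fraction: float = 0.5
    correlation_kind: str = "pearson"
    max_outer_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.c_threshold <= 1.0:
            raise ValidationError("c_threshold must lie in (0, 1]")
        if not 0.0 < self.max_removed_fraction <= 0.5 + 1e-9:
            raise ValidationError("max_removed_fraction must lie in (0, 0.5]")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValidationError("correlation_kind must be pearson or spearman")
        if self.max_outer_iterations < 1:
            raise ValidationError("max_outer_iterations must be >= 1")


@dataclass(frozen=True)
class ArrayRemovalStep:
    """One accepted array removal with correlation before/after."""

    removed_array: str
    c_before: float
    c_after: float


@dataclass(frozen=True)
class GeneAdditionStep:
    """One accepted gene addition with correlation before/after."""

    added_gene: str
    c_before: float
    c_after: float


@dataclass
class Bicluster:
    genes: list[str]  # seeds first, additions in acceptance order
    arrays: list[str]
    mean_correlation: float
    seed_mean_correlation: float
    trace: list[dict] = field(default_factory=list)


def _rank_rows(sub: np.ndarray) -> np.ndarray:
    return stats.rankdata(sub, axis=1)


def _complete_corr_matrix(sub: np.ndarray, kind: str) -> np.ndarray:
    if kind == "spearman":
        sub = _rank_rows(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(sub)


def _pair_corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    """Correlation over mutually observed positions; NaN if degenerate."""
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 3:
        return float("inf")  # sentinel: precondition violation
    xs, ys = x[mask], y[mask]
    if kind == "spearman":
        xs, ys = stats.rankdata(xs), stats.rankdata(ys)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = math.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0.0:
        return float("nan")
    return float((xs * ys).sum() / denom)


def mean_pairwise_correlation(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    arrays: Sequence[str],
    kind: str = "pearson",
) -> float:
    """Unweighted mean correlation over all unordered gene pairs.

    Correlations use pairwise-complete observations over ``arrays``; a pair
    with zero variance contributes 0 (with a warning).  Requires >= 2 genes,
    >= 3 arrays and >= 3 shared observations per pair.
    """
    genes = list(genes)
    arrays = list(arrays)
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes for pairwise correlation")
    if len(arrays) < 3:
        raise ValidationError("need at least 3 arrays for pairwise correlation")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[genes, arrays].to_numpy(float)
    n = len(genes)
    if not np.isnan(sub).any():
        corr = _complete_corr_matrix(sub, kind)
        iu = np.triu_indices(n, k=1)
        vals = corr[iu]
        if np.isnan(vals).any():
            warnings.warn(
                "zero-variance gene pair(s); correlation counted as 0",
                stacklevel=2,
            )
            vals = np.nan_to_num(vals, nan=0.0)
        return float(vals.mean())
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            c = _pair_corr(sub[i], sub[j], kind)
            if c == float("inf"):
                raise ValidationError(
                    f"gene pair ({genes[i]!r}, {genes[j]!r}) shares fewer than "
                    f"3 observed arrays"
                )
            if c != c:  # NaN: zero variance
                warnings.warn(
                    f"zero-variance pair ({genes[i]!r}, {genes[j]!r}); "
                    f"correlation counted as 0",
                    stacklevel=2,
                )
                c = 0.0
            total += c
    return total / (n * (n - 1) / 2)


def reduce_arrays(
    matrix: ExpressionMatrix,
    seeds: Sequence[str],
    config: Optional[BiclusterConfig] = None,
    *,
    arrays: Optional[Sequence[str]] = None,
    max_removals: Optional[int] = None,
) -> tuple[list[str], list[ArrayRemovalStep]]:
    """Greedily remove arrays to raise the seeds' mean pairwise correlation.

    At each step every retained array's single removal is evaluated; the one
    giving the largest strict increase is removed permanently (ties broken by
    smallest array id).  Stops when the correlation reaches
    ``config.c_threshold``, when ``max_removals`` arrays (default: half of the
    starting count, rounded down) have been removed, or when no removal
    strictly increases the correlation.
    """
    config = config or BiclusterConfig()
    seeds = list(seeds)
    missing = [s for s in seeds if s not in matrix.values.index]
    if missing:
        raise ValidationError(f"seed genes absent from matrix: {missing}")
    retained = list(arrays) if arrays is not None else list(matrix.array_ids)
    if len(retained) < 4:
        raise ValidationError("need at least 4 arrays for array reduction")
    budget = (
        max_removals
        if max_removals is not None
        else math.floor(config.max_removed_fraction * len(retained))
    )
    steps: list[ArrayRemovalStep] = []
    current = mean_pairwise_correlation(matrix, seeds, retained, config.correlation_kind)
    while True:
        if current >= config.c_threshold:
            break
        if len(steps) >= budget:
            break
        if len(retained) - 1 < 3:
            break
        best_array: Optional[str] = None
        best_corr = current
        for a in retained:
            trial = [x for x in retained if x != a]
            c = mean_pairwise_correlation(matrix, seeds, trial, config.correlation_kind)
            if c > best_corr or (c == best_corr and best_array is not None and a < best_array):
                best_array = a
                best_corr = c
        if best_array is None:
            break
        retained.remove(best_array)
        steps.append(ArrayRemovalStep(best_array, current, best_corr))
        current = best_corr
    return retained, steps


def _mean_corr_to_list(
    matrix: ExpressionMatrix,
    gene: str,
    members: Sequence[str],
    arrays: Sequence[str],
    kind: str,
) -> float:
    sub = matrix.values.loc[[gene, *members], arrays].to_numpy(float)
    total = 0.0
    for j in range(1, sub.shape[0]):
        c = _pair_corr(sub[0], sub[j], kind)
        if c == float("inf") or c != c:
            c = 0.0
        total += c
    return total / len(members)


def grow_genes(
    matrix: ExpressionMatrix,
    current_genes: Sequence[str],
    pool: GeneSet,
    arrays: Sequence[str],
    config: Optional[BiclusterConfig] = None,
) -> tuple[list[str], list[GeneAdditionStep]]:
    """Greedily add pool genes that strictly increase the mean correlation.

    Candidates are visited in descending mean correlation to the current list
    (ties lexicographic, order refreshed at the start of each pass); an
    accepted gene joins the list immediately.  Passes repeat until one adds
    nothing.
    """
    config = config or BiclusterConfig()
    current = list(current_genes)
    if not current:
        raise ValidationError("current gene list must be nonempty")
    overlap = [g for g in pool if g in set(current)]
    if overlap:
        warnings.warn(
            f"{len(overlap)} pool gene(s) already in the current list; dropped",
            stacklevel=2,
        )
    absent = [g for g in pool if g not in matrix.values.index]
    if absent:
        warnings.warn(
            f"{len(absent)} pool gene(s) absent from the matrix; dropped",
            stacklevel=2,
        )
    skip = set(current) | set(absent)
    candidates = [g for g in pool if g not in skip]
    arrays = list(arrays)
    steps: list[GeneAdditionStep] = []
    current_corr = mean_pairwise_correlation(
        matrix, current, arrays, config.correlation_kind
    ) if len(current) >= 2 else None
    while candidates:
        order = sorted(
            candidates,
            key=lambda g: (
                -_mean_corr_to_list(matrix, g, current, arrays, config.correlation_kind),
                g,
            ),
        )
        added_this_pass = False
        for g in order:
            new_corr = mean_pairwise_correlation(
                matrix, [*current, g], arrays, config.correlation_kind
            )
            if current_corr is None or new_corr > current_corr:
                steps.append(
                    GeneAdditionStep(
                        g,
                        float("nan") if current_corr is None else current_corr,
                        new_corr,
                    )
                )
                current.append(g)
                candidates.remove(g)
                current_corr = new_corr
                added_this_pass = True
        if not added_this_pass:
            break
    return current, steps


def run_bicluster(
    matrix: ExpressionMatrix,
    seeds: Sequence[str],
    pool: GeneSet,
    config: Optional[BiclusterConfig] = None,
) -> Bicluster:
    """Alternate array reduction and gene addition until a fixed point.

    Array reduction always re-runs against the full current gene list; the
    overall removal budget (half of the original array count) is shared across
    cycles.  Stops when one full cycle changes neither the array nor the gene
    list, or after ``config.max_outer_iterations`` cycles.
    """
    config = config or BiclusterConfig()
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValidationError("need at least 2 seed genes")
    arrays = list(matrix.array_ids)
    budget = math.floor(config.max_removed_fraction * len(arrays))
    genes = list(seeds)
    trace: list[dict] = []
    removed_total = 0
    for cycle in range(1, config.max_outer_iterations + 1):
        new_arrays, removal_steps = reduce_arrays(
            matrix,
            genes,
            config,
            arrays=arrays,
            max_removals=budget - removed_total,
        )
        removed_total += len(removal_steps)
        # genes accepted in earlier cycles are no longer candidates
        remaining_pool = GeneSet(
            pool.name, pool.description, tuple(g for g in pool if g not in set(genes))
        )
        new_genes, addition_steps = grow_genes(
            matrix, genes, remaining_pool, new_arrays, config
        )
        seed_mean = mean_pairwise_correlation(
            matrix, seeds, new_arrays, config.correlation_kind
        ) if len(seeds) >= 2 else float("nan")
        full_mean = mean_pairwise_correlation(
            matrix, new_genes, new_arrays, config.correlation_kind
        )
        trace.append(
            {
                "cycle": cycle,
                "removals": removal_steps,
                "additions": addition_steps,
                "seed_mean_correlation": seed_mean,
                "full_mean_correlation": full_mean,
            }
        )
        changed = new_arrays != arrays or new_genes != genes
        arrays, genes = new_arrays, new_genes
        if not changed:
            break
    return Bicluster(
        genes=genes,
        arrays=arrays,
        mean_correlation=mean_pairwise_correlation(
            matrix, genes, arrays, config.correlation_kind
        ),
        seed_mean_correlation=mean_pairwise_correlation(
            matrix, seeds, arrays, config.correlation_kind
        ),
        trace=trace,
    )
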