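"""Differential-expression correlation ranking.

For each seed gene the comparison set is reduced to those where the seed is
significantly differentially expressed; every other gene then receives a
correlation (vs the seed, over the reduced comparisons) and a significance
fraction.  Genes exceeding a selection threshold on either quantity for any
seed are ranked twice per seed (by absolute correlation and by fraction,
midrank ties) and aggregated by the geometric mean of the 2n ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import DEMatrix

__all__ = [
    "DecaConfig",
    "SeedProfile",
    "DecaResult",
    "reduce_comparisons",
    "seed_profile",
    "select_candidates",
    "rank_candidates",
    "run_deca",
]


@dataclass
class DecaConfig:
    sig_alpha: float = 0.01
    selection_threshold: float = 0.6
    selection_mode: str = "any_seed"  # or "every_seed"
    correlation_kind: str = "pearson"
    min_reduced_comparisons: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.sig_alpha < 1.0:
            raise ValidationError("sig_alpha must lie in (0, 1)")
        if not 0.0 < self.selection_threshold < 1.0:
            raise ValidationError("selection_threshold must lie in (0, 1)")
        if self.selection_mode not in ("any_seed", "every_seed"):
            raise ValidationError("selection_mode must be any_seed or every_seed")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValidationError("correlation_kind must be pearson or spearman")
        if self.min_reduced_comparisons < 1:
            raise ValidationError("min_reduced_comparisons must be >= 1")


@dataclass
class SeedProfile:
    """Per-gene correlation and significance fraction for one seed."""

    seed: str
    reduced_comparisons: list[str]
    correlation: pd.Series  # index: candidate genes
    significance_fraction: pd.Series


@dataclass
class DecaResult:
    seeds: list[str]
    profiles: dict[str, SeedProfile]
    selected_genes: list[str]
    component_ranks: pd.DataFrame  # selected genes x 2n rank columns
    final_ranks: pd.Series  # geometric mean of the 2n ranks
    ordering: list[str]  # ascending final rank, ties by gene id
    universe: list[str] = field(default_factory=list)  # all candidate genes


def reduce_comparisons(
    de: DEMatrix,
    seed: str,
    sig_alpha: float = 0.01,
    min_reduced_comparisons: int = 3,
) -> list[str]:
    """Comparisons where the seed has p < ``sig_alpha`` and a DE value."""
    if seed not in de.de.index:
        raise ValidationError(f"seed gene {seed!r} absent from DE matrix")
    mask = (de.p.loc[seed] < sig_alpha) & de.de.loc[seed].notna()
    comps = list(de.de.columns[mask.to_numpy(bool)])
    if len(comps) < min_reduced_comparisons:
        raise ValidationError(
            f"seed gene {seed!r} is significant in only {len(comps)} "
            f"comparison(s) (< {min_reduced_comparisons}); choose another seed"
        )
    return comps


def _corr_vs_seed(
    sub: np.ndarray, seed_vec: np.ndarray, kind: str, genes: Sequence[str]
) -> np.ndarray:
    """Row-wise correlation against the seed, pairwise-complete; NaN -> 0."""
    n_warn = 0
    out = np.zeros(sub.shape[0])
    seed_obs = ~np.isnan(seed_vec)
    if not np.isnan(sub).any() and seed_obs.all():
        x = sub
        s = seed_vec
        if kind == "spearman":
            x = stats.rankdata(x, axis=1)
            s = stats.rankdata(s)
        xc = x - x.mean(axis=1, keepdims=True)
        sc = s - s.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ sc) / denom
        bad = ~np.isfinite(r)
        n_warn = int(bad.sum())
        out = np.where(bad, 0.0, r)
    else:
        for i in range(sub.shape[0]):
            mask = ~np.isnan(sub[i]) & seed_obs
            if mask.sum() < 2:
                n_warn += 1
                continue
            xs, ys = sub[i][mask], seed_vec[mask]
            if kind == "spearman":
                xs, ys = stats.rankdata(xs), stats.rankdata(ys)
            xs = xs - xs.mean()
            ys = ys - ys.mean()
            denom = np.sqrt((xs**2).sum() * (ys**2).sum())
            if denom == 0.0:
                n_warn += 1
                continue
            out[i] = float((xs * ys).sum() / denom)
    if n_warn:
        warnings.warn(
            f"{n_warn} undefined correlation(s) vs seed counted as 0",
            stacklevel=3,
        )
    return out


def seed_profile(
    de: DEMatrix,
    seed: str,
    config: Optional[DecaConfig] = None,
    exclude: Optional[Sequence[str]] = None,
) -> SeedProfile:
    """Correlations and significance fractions of every gene vs one seed.

    ``exclude`` removes genes (typically all seeds) from the candidate list;
    the seed itself is always excluded.
    """
    config = config or DecaConfig()
    comps = reduce_comparisons(
        de, seed, config.sig_alpha, config.min_reduced_comparisons
    )
    drop = set(exclude) if exclude is not None else set()
    drop.add(seed)
    genes = [g for g in de.gene_ids if g not in drop]
    sub = de.de.loc[genes, comps].to_numpy(float)
    seed_vec = de.de.loc[seed, comps].to_numpy(float)
    corr = _corr_vs_seed(sub, seed_vec, config.correlation_kind, genes)
    frac = (de.p.loc[genes, comps] < config.sig_alpha).sum(axis=1) / len(comps)
    return SeedProfile(
        seed=seed,
        reduced_comparisons=comps,
        correlation=pd.Series(corr, index=genes),
        significance_fraction=frac.astype(float),
    )


def select_candidates(
    profiles: Sequence[SeedProfile], config: Optional[DecaConfig] = None
) -> list[str]:
    """Genes with |correlation| or significance fraction strictly above the
    threshold, for at least one seed (``any_seed``) or all seeds
    (``every_seed``)."""
    config = config or DecaConfig()
    if not profiles:
        raise ValidationError("need at least one seed profile")
    t = config.selection_threshold
    per_seed = []
    for prof in profiles:
        cond = (prof.correlation.abs() > t) | (prof.significance_fraction > t)
        per_seed.append(cond)
    table = pd.concat(per_seed, axis=1).fillna(False)
    hit = table.any(axis=1) if config.selection_mode == "any_seed" else table.all(axis=1)
    return list(table.index[hit.to_numpy(bool)])


def rank_candidates(
    profiles: Sequence[SeedProfile], selected: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-seed |correlation| and fraction rankings plus the aggregate rank.

    Rank 1 is best (largest value); ties get the average of the tied
    positions.  The final rank is the geometric mean of the 2n component
    ranks; the ordering sorts ascending by final rank, ties broken by gene id.
    """
    selected = list(selected)
    if not selected:
        raise ValidationError("no selected genes to rank")
    cols = {}
    for prof in profiles:
        ac = prof.correlation.loc[selected].abs().to_numpy(float)
        fr = prof.significance_fraction.loc[selected].to_numpy(float)
        cols[f"{prof.seed}|corr_rank"] = stats.rankdata(-ac, method="average")
        cols[f"{prof.seed}|frac_rank"] = stats.rankdata(-fr, method="average")
    component = pd.DataFrame(cols, index=selected)
    final = pd.Series(
        np.exp(np.log(component.to_numpy(float)).mean(axis=1)), index=selected
    )
    ordering = sorted(selected, key=lambda g: (final[g], g))
    return component, final, ordering


def run_deca(
    de: DEMatrix, seeds: Sequence[str], config: Optional[DecaConfig] = None
) -> DecaResult:
    """Full pipeline: profiles per seed, selection, 2n ranks, final ordering.

    Seeds are excluded from the candidate list.  Deterministic: seed
    processing is independent, so input order does not matter beyond the
    column order of the rank table.
    """
    config = config or DecaConfig()
    seeds = list(seeds)
    if not seeds:
        raise ValidationError("need at least one seed gene")
    if len(set(seeds)) != len(seeds):
        raise ValidationError("duplicate seed genes")
    profiles: dict[str, SeedProfile] = {}
    for seed in seeds:
        try:
            profiles[seed] = seed_profile(de, seed, config, exclude=seeds)
        except ValidationError as exc:
            raise ValidationError(f"seed {seed!r} failed: {exc}") from exc
    ordered_profiles = [profiles[s] for s in seeds]
    selected = select_candidates(ordered_profiles, config)
    if selected:
        component, final, ordering = rank_candidates(ordered_profiles, selected)
    else:
        component = pd.DataFrame(index=pd.Index([], dtype=object))
        final = pd.Series(dtype=float)
        ordering = []
    return DecaResult(
        seeds=seeds,
        profiles=profiles,
        selected_genes=selected,
        component_ranks=component,
        final_ranks=final,
        ordering=ordering,
        universe=[g for g in de.gene_ids if g not in set(seeds)],
    )
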