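"""In silico pathway-recovery assessment of the ranking algorithm.

For each pathway, seed triples are drawn at random from members with enough
significant comparisons, the ranking is run, and two statistics are recorded:
the fraction of (non-seed) pathway genes recovered in the top slice of the
ranking, and a one-sided Welch t-test asking whether pathway members obtain
better (lower) final ranks than the rest of the ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .deca import DecaConfig, DecaResult, run_deca
from .errors import ValidationError
from .types import DEMatrix, GeneSet

__all__ = [
    "AssessmentConfig",
    "AssessmentRow",
    "eligible_seed_genes",
    "pathway_recovery",
    "rank_enrichment_test",
    "run_assessment",
]


@dataclass
class AssessmentConfig:
    n_seeds_per_run: int = 3
    min_sig_experiments: int = 15
    top_fraction: float = 0.10
    n_runs: int = 10
    rng_seed: int = 0
    sig_alpha: float = 0.01
    min_abs_de: Optional[float] = None  # optional fold-change gate on seeds

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValidationError("top_fraction must lie in (0, 1]")
        if self.n_seeds_per_run < 1 or self.n_runs < 1:
            raise ValidationError("n_seeds_per_run and n_runs must be >= 1")
        if self.min_sig_experiments < 1:
            raise ValidationError("min_sig_experiments must be >= 1")


@dataclass
class AssessmentRow:
    pathway: str
    run: int
    seeds: list[str]
    recovery_fraction: float
    welch_t: float
    welch_p: float
    n_selected: int
    error: Optional[str] = None


def eligible_seed_genes(
    de: DEMatrix, pathway: GeneSet, config: Optional[AssessmentConfig] = None
) -> list[str]:
    """Pathway members significant in at least ``min_sig_experiments``
    comparisons (inclusive), optionally gated on |DE| >= ``min_abs_de``."""
    config = config or AssessmentConfig()
    if len(pathway) == 0:
        raise ValidationError(f"pathway {pathway.name!r} is empty")
    members = [g for g in pathway if g in de.de.index]
    eligible = []
    for g in members:
        sig = (de.p.loc[g] < config.sig_alpha) & de.de.loc[g].notna()
        if config.min_abs_de is not None:
            sig &= de.de.loc[g].abs() >= config.min_abs_de
        if int(sig.sum()) >= config.min_sig_experiments:
            eligible.append(g)
    if len(eligible) < config.n_seeds_per_run:
        raise ValidationError(
            f"pathway {pathway.name!r}: only {len(eligible)} eligible seed "
            f"gene(s), need {config.n_seeds_per_run}"
        )
    return eligible


def pathway_recovery(
    result: DecaResult, pathway: GeneSet, top_fraction: float = 0.10
) -> float:
    """Fraction of the pathway's non-seed genes found in the ranking's top
    ``ceil(top_fraction * m)`` entries.

    Seeds are excluded from numerator and denominator; the denominator counts
    pathway non-seed members present in the candidate universe.
    """
    if not result.ordering:
        raise ValidationError("empty ranking")
    seeds = set(result.seeds)
    members = set(pathway) - seeds
    denom = len(members & set(result.universe))
    if denom == 0:
        return float("nan")
    top_n = ceil(top_fraction * len(result.ordering))
    top = set(result.ordering[:top_n])
    return len(top & members) / denom


def rank_enrichment_test(
    result: DecaResult, pathway: GeneSet
) -> tuple[float, float]:
    """One-sided Welch t-test: do pathway members get better (lower) final
    ranks than non-members within the ranked list?"""
    members = set(pathway) - set(result.seeds)
    in_ranks = result.final_ranks[[g for g in result.final_ranks.index if g in members]]
    out_ranks = result.final_ranks[
        [g for g in result.final_ranks.index if g not in members]
    ]
    if len(in_ranks) < 2 or len(out_ranks) < 2:
        raise ValidationError(
            "need >= 2 pathway and >= 2 non-pathway genes in the ranking"
        )
    t, p = stats.ttest_ind(
        in_ranks.to_numpy(float),
        out_ranks.to_numpy(float),
        equal_var=False,
        alternative="less",
    )
    return float(t), float(p)


def run_assessment(
    de: DEMatrix,
    pathways: Sequence[GeneSet],
    config: Optional[AssessmentConfig] = None,
    deca_config: Optional[DecaConfig] = None,
) -> list[AssessmentRow]:
    """Repeated random-seed assessment over a list of pathways.

    Per pathway, ``n_runs`` seed draws (without replacement, seeded RNG) are
    evaluated; failures are recorded in the row rather than aborting the other
    pathways.  Fully deterministic given ``config.rng_seed``.
    """
    config = config or AssessmentConfig()
    deca_config = deca_config or DecaConfig(sig_alpha=config.sig_alpha)
    rng = np.random.default_rng(config.rng_seed)
    rows: list[AssessmentRow] = []
    for pathway in pathways:
        try:
            eligible = eligible_seed_genes(de, pathway, config)
        except ValidationError as exc:
            for run in range(1, config.n_runs + 1):
                rows.append(
                    AssessmentRow(
                        pathway.name, run, [], float("nan"), float("nan"),
                        float("nan"), 0, error=str(exc),
                    )
                )
            continue
        for run in range(1, config.n_runs + 1):
            seeds = list(
                rng.choice(eligible, size=config.n_seeds_per_run, replace=False)
            )
            try:
                result = run_deca(de, seeds, deca_config)
                recovery = pathway_recovery(result, pathway, config.top_fraction)
                t, p = rank_enrichment_test(result, pathway)
                rows.append(
                    AssessmentRow(
                        pathway.name, run, seeds, recovery, t, p,
                        len(result.selected_genes),
                    )
                )
            except ValidationError as exc:
                rows.append(
                    AssessmentRow(
                        pathway.name, run, seeds, float("nan"), float("nan"),
                        float("nan"), 0, error=str(exc),
                    )
                )
    return rows
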