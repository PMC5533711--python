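"""Synthetic data with truth labels.

Three generators: an expression matrix with one planted co-expressed
gene x array block, a DE matrix in which designated target genes track seed
profiles on the seeds' significant comparisons, and an Erdos-Renyi scored
edge list.  All generators are pure functions of their parameters: the same
``rng_seed`` reproduces the output bit for bit.

The planted signals use a latent-factor construction (shared profile plus
independent Gaussian noise), so the expected within-module correlation has
the closed form ``rho = var_latent / (var_latent + noise_sd**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import DEMatrix, ExpressionMatrix, NetworkEdgeList

__all__ = [
    "BiclusterSimParams",
    "DecaSimParams",
    "SimTruth",
    "make_bicluster_matrix",
    "make_deca_matrix",
    "make_toy_network",
    "noise_sd_for_correlation",
]


def noise_sd_for_correlation(rho: float, latent_sd: float = 1.0) -> float:
    """Noise sd giving expected within-module correlation ``rho`` under the
    latent-factor model ``x = latent + noise``."""
    if not 0.0 < rho <= 1.0:
        raise ValidationError("rho must lie in (0, 1]")
    return latent_sd * float(np.sqrt(1.0 / rho - 1.0))


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels for a simulated dataset."""

    planted_genes: tuple[str, ...]
    planted_columns: tuple[str, ...]  # module arrays / active comparisons
    roles: dict[str, str] = field(default_factory=dict)  # gene -> seed|target|background

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]


@dataclass
class BiclusterSimParams:
    n_genes: int = 200
    n_arrays: int = 60
    module_genes: int = 12
    module_arrays: int = 30
    within_noise_sd: float = 0.33
    background_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_arrays < 3:
            raise ValidationError("need n_genes >= 2 and n_arrays >= 3")
        if not 0 < self.module_genes <= self.n_genes:
            raise ValidationError("module_genes must lie in [1, n_genes]")
        if not 0 < self.module_arrays <= self.n_arrays:
            raise ValidationError("module_arrays must lie in [1, n_arrays]")
        if self.within_noise_sd < 0 or self.background_sd <= 0:
            raise ValidationError("invalid noise parameters")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def make_bicluster_matrix(
    params: BiclusterSimParams,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression matrix with one planted co-expressed block.

    Module genes share, over the module arrays, a standard-normal latent
    profile plus ``within_noise_sd`` Gaussian noise; every other cell is
    independent ``N(0, background_sd)``.
    """
    rng = np.random.default_rng(params.rng_seed)
    genes = _gene_ids(params.n_genes)
    arrays = [f"A{j:04d}" for j in range(1, params.n_arrays + 1)]
    module_g = sorted(rng.choice(params.n_genes, params.module_genes, replace=False))
    module_a = sorted(rng.choice(params.n_arrays, params.module_arrays, replace=False))
    X = rng.normal(0.0, params.background_sd, size=(params.n_genes, params.n_arrays))
    latent = rng.normal(0.0, 1.0, size=params.module_arrays)
    noise = rng.normal(
        0.0, params.within_noise_sd, size=(params.module_genes, params.module_arrays)
    )
    X[np.ix_(module_g, module_a)] = latent[None, :] + noise
    frame = pd.DataFrame(X, index=genes, columns=arrays)
    roles = {g: "background" for g in genes}
    planted = tuple(genes[i] for i in module_g)
    for g in planted:
        roles[g] = "target"
    truth = SimTruth(
        planted_genes=planted,
        planted_columns=tuple(arrays[j] for j in module_a),
        roles=roles,
    )
    return ExpressionMatrix(frame), truth


@dataclass
class DecaSimParams:
    n_genes: int = 1000
    n_comparisons: int = 80
    n_seeds: int = 3
    n_targets: int = 20
    seed_active_comparisons: int = 30
    target_correlation: float = 0.8
    noise_sd: float = 1.0
    sig_effect: float = 1.0
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 1 or self.n_targets < 0:
            raise ValidationError("need n_seeds >= 1 and n_targets >= 0")
        if self.n_seeds + self.n_targets > self.n_genes:
            raise ValidationError("n_seeds + n_targets must be <= n_genes")
        if not 0 < self.seed_active_comparisons <= self.n_comparisons:
            raise ValidationError("seed_active_comparisons out of range")
        if not 0.0 < self.target_correlation <= 1.0:
            raise ValidationError("target_correlation must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.sig_effect < 0:
            raise ValidationError("invalid noise parameters")


def _seed_de_profile(rng: np.random.Generator, n: int, sig_effect: float) -> np.ndarray:
    """DE values of guaranteed magnitude >= sig_effect with random sign."""
    x = rng.normal(0.0, 1.0, size=n)
    return np.sign(np.where(x == 0, 1.0, x)) * (sig_effect + np.abs(x))


def _seed_profile_sd(sig_effect: float) -> float:
    # population sd of sign(x)*(c+|x|), x ~ N(0,1):
    # E[(c+|x|)^2] = c^2 + 2c*E|x| + 1 with E|x| = sqrt(2/pi)
    c = sig_effect
    return float(np.sqrt(c**2 + 2.0 * c * np.sqrt(2.0 / np.pi) + 1.0))


def make_deca_matrix(params: DecaSimParams) -> tuple[DEMatrix, SimTruth]:
    """DE matrix with planted seed-correlated target genes.

    All seeds share one active comparison set on which they are strongly and
    significantly differentially expressed (|DE| >= ``sig_effect``,
    p < 0.01).  Each target copies one seed's active profile plus noise
    calibrated so its expected correlation with that seed equals
    ``target_correlation``; target cells are significant wherever
    |DE| >= ``sig_effect``.  Background genes (and all inactive cells) carry
    independent null noise with p ~ Uniform(0.05, 1].  Missing cells are
    injected into non-seed rows at ``missing_rate``; their p-values are left
    missing and hence substituted with 1 by the matrix constructor.
    """
    rng = np.random.default_rng(params.rng_seed)
    genes = _gene_ids(params.n_genes)
    comps = [f"C{j:04d}" for j in range(1, params.n_comparisons + 1)]
    role_idx = rng.choice(
        params.n_genes, params.n_seeds + params.n_targets, replace=False
    )
    seed_idx = sorted(role_idx[: params.n_seeds])
    target_idx = sorted(role_idx[params.n_seeds :])
    active = sorted(
        rng.choice(params.n_comparisons, params.seed_active_comparisons, replace=False)
    )

    de = rng.normal(0.0, params.noise_sd, size=(params.n_genes, params.n_comparisons))
    p = 0.05 + rng.uniform(0.0, 0.95, size=de.shape)  # null p ~ U(0.05, 1]

    seed_profiles = {}
    for s in seed_idx:
        prof = _seed_de_profile(rng, params.seed_active_comparisons, params.sig_effect)
        de[s, active] = prof
        p[s, active] = rng.uniform(0.0, 0.01, len(active))
        seed_profiles[s] = prof

    sd = _seed_profile_sd(params.sig_effect)
    eps_sd = sd * float(np.sqrt(1.0 / params.target_correlation**2 - 1.0))
    for i, t in enumerate(target_idx):
        parent = seed_idx[i % params.n_seeds]
        prof = seed_profiles[parent] + rng.normal(
            0.0, eps_sd, size=params.seed_active_comparisons
        )
        de[t, active] = prof
        sig = np.abs(prof) >= params.sig_effect
        p[t, np.asarray(active)[sig]] = rng.uniform(0.0, 0.01, int(sig.sum()))

    if params.missing_rate > 0:
        protect = np.zeros(de.shape, dtype=bool)
        protect[seed_idx, :] = True
        holes = rng.uniform(size=de.shape) < params.missing_rate
        holes &= ~protect
        de[holes] = np.nan
        p[holes] = np.nan

    de_frame = pd.DataFrame(de, index=genes, columns=comps)
    p_frame = pd.DataFrame(p, index=genes, columns=comps)
    roles = {g: "background" for g in genes}
    for s in seed_idx:
        roles[genes[s]] = "seed"
    for t in target_idx:
        roles[genes[t]] = "target"
    truth = SimTruth(
        planted_genes=tuple(genes[i] for i in [*seed_idx, *target_idx]),
        planted_columns=tuple(comps[j] for j in active),
        roles=roles,
    )
    return DEMatrix(de_frame, p_frame), truth


def make_toy_network(
    n_nodes: int,
    edge_prob: float,
    score_range: tuple[int, int] = (0, 1000),
    rng_seed: int = 0,
) -> NetworkEdgeList:
    """Erdos-Renyi undirected graph with uniform integer edge scores."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValidationError("edge_prob must lie in [0, 1]")
    lo, hi = score_range
    if lo > hi:
        raise ValidationError("score_range must be (low, high) with low <= high")
    rng = np.random.default_rng(rng_seed)
    nodes = [f"N{i:04d}" for i in range(1, n_nodes + 1)]
    net = NetworkEdgeList()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < edge_prob:
                net.add(nodes[i], nodes[j], int(rng.integers(lo, hi + 1)))
    return net
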