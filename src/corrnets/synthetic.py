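"""Seeded synthetic feature tables with planted correlation structure.

The generator emulates the statistical skeleton the pipeline assumes in
real microbiome data: groups of co-varying taxa (blocks driven by a shared
latent factor) plus independent noise taxa.  Because Spearman correlation
is rank-based, a Gaussian latent-factor construction is sufficient —
monotone marginal transforms cannot change any rank correlation — and it
keeps planted correlations exact when the member noise is zero.  An
optional exponentiation produces positive "abundance-like" tables for
testing the clr transform.

A block of size m with sign +1 gives all m members the same latent vector
(plus member noise): all C(m, 2) within-block pairs are strong positive
correlations.  A sign of -1 alternates the loading (members at odd
positions get the negated latent), planting a mix of strong positive and
strong negative pairs inside the block — the signed-edge case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables import FeatureTable

__all__ = [
    "Block",
    "SyntheticDesign",
    "generate_feature_table",
    "generate_paired_tables",
    "planted_pairs",
    "paired_block_designs",
]


@dataclass(frozen=True)
class Block:
    """A group of features driven by one latent factor.

    Parameters
    ----------
    size : int
        Number of member features (>= 2).
    sign : int
        +1: uniform loadings (all pairs positively correlated);
        -1: alternating loadings (opposite-sign members anticorrelated).
    latent_noise_sd : float
        Standard deviation of the independent Gaussian noise added to each
        member on top of the latent factor; 0 plants exact rank correlations.
    """

    size: int
    sign: int = 1
    latent_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"block size must be >= 2, got {self.size}")
        if self.sign not in (+1, -1):
            raise ValueError(f"block sign must be +1 or -1, got {self.sign}")
        if self.latent_noise_sd < 0:
            raise ValueError("latent_noise_sd must be nonnegative")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of one synthetic feature table."""

    n_samples: int = 30
    blocks: tuple[Block, ...] = ()
    n_noise_features: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.n_samples < 5:
            raise ValueError(f"need n_samples >= 5, got {self.n_samples}")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be nonnegative")
        if self.total_features < 1:
            raise ValueError("design has no features")

    @property
    def total_features(self) -> int:
        return self.n_noise_features + sum(b.size for b in self.blocks)


def _member_signs(block: Block) -> np.ndarray:
    """Per-member loading signs: uniform for sign=+1, alternating for -1."""
    if block.sign == 1:
        return np.ones(block.size)
    return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(block.size)])


def generate_feature_table(
    design: SyntheticDesign,
    feature_prefix: str = "F",
    exponentiate: bool = False,
) -> FeatureTable:
    """Draw one feature table from a design; deterministic per seed.

    Block features come first (in block order), then noise features.
    ``exponentiate`` maps every value x to exp(x), yielding a strictly
    positive table with identical rank structure (log-normal-like margins).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    columns = []
    for block in design.blocks:
        latent = rng.standard_normal(n)
        signs = _member_signs(block)
        for j in range(block.size):
            noise = (
                rng.standard_normal(n) * block.latent_noise_sd
                if block.latent_noise_sd > 0
                else 0.0
            )
            columns.append(signs[j] * latent + noise)
    for _ in range(design.n_noise_features):
        columns.append(rng.standard_normal(n))

    values = np.column_stack(columns)
    if exponentiate:
        values = np.exp(values)
    sample_ids = tuple(f"S{i + 1}" for i in range(n))
    feature_ids = tuple(f"{feature_prefix}{j + 1}" for j in range(values.shape[1]))
    return FeatureTable(sample_ids, feature_ids, values)


def generate_paired_tables(
    design_a: SyntheticDesign,
    design_b: SyntheticDesign,
    feature_prefix: str = "F",
    exponentiate: bool = False,
) -> tuple[FeatureTable, FeatureTable]:
    """Two independent tables with a shared feature-id set.

    The designs must agree on the total feature count so downstream network
    comparisons see nominally identical feature panels.
    """
    if design_a.total_features != design_b.total_features:
        raise ValueError(
            f"designs have different feature totals: "
            f"{design_a.total_features} vs {design_b.total_features}"
        )
    a = generate_feature_table(design_a, feature_prefix, exponentiate)
    b = generate_feature_table(design_b, feature_prefix, exponentiate)
    return a, b


def planted_pairs(design: SyntheticDesign, feature_prefix: str = "F") -> dict[tuple[str, str], int]:
    """The within-block feature pairs a perfect recovery would find.

    Maps each label-sorted pair to the sign of its planted correlation
    (+1 same loading sign, -1 opposite).
    """
    pairs: dict[tuple[str, str], int] = {}
    offset = 0
    for block in design.blocks:
        signs = _member_signs(block)
        labels = [f"{feature_prefix}{offset + j + 1}" for j in range(block.size)]
        for i in range(block.size):
            for j in range(i + 1, block.size):
                u, v = sorted((labels[i], labels[j]))
                pairs[(u, v)] = int(signs[i] * signs[j])
        offset += block.size
    return pairs


def paired_block_designs(
    seed: int,
    n_samples: int = 30,
    latent_noise_sd: float = 0.3,
) -> tuple[SyntheticDesign, SyntheticDesign]:
    """Default paired designs with unequal planted structure (12 vs 6 pairs).

    Design A plants two blocks of four (one all-positive, one signed) —
    12 strong pairs; design B plants a single block of four — 6 strong
    pairs — plus extra noise features so both tables have 12 features.
    Seeds for the two tables are derived from ``seed`` so a run is fully
    reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    design_a = SyntheticDesign(
        n_samples=n_samples,
        blocks=(Block(4, +1, latent_noise_sd), Block(4, -1, latent_noise_sd)),
        n_noise_features=4,
        seed=seed_a,
    )
    design_b = SyntheticDesign(
        n_samples=n_samples,
        blocks=(Block(4, +1, latent_noise_sd),),
        n_noise_features=8,
        seed=seed_b,
    )
    return design_a, design_b
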