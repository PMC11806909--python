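"""Bootstrap resampling of feature tables.

The resampling unit is the sample (a whole row of the feature table): each
bootstrap replicate draws n row indices uniformly with replacement, so every
replicate has the original's shape and every replicate row is identical to
some original row.  Replicate sampling distributions of downstream network
statistics quantify the uncertainty the single observed network hides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import FeatureTable

__all__ = ["ReplicateSet", "bootstrap_replicates"]


@dataclass(frozen=True)
class ReplicateSet:
    """Ordered collection of bootstrap replicates of one feature table."""

    replicates: tuple[FeatureTable, ...]
    iterations: int
    seed: int | None
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)

    def __getitem__(self, i: int) -> FeatureTable:
        return self.replicates[i]


def bootstrap_replicates(
    table: FeatureTable,
    iterations: int = 100,
    seed: int | None = None,
) -> ReplicateSet:
    """Generate ``iterations`` bootstrap replicates of ``table``.

    A single seeded generator drives all replicates, so an identical
    ``(table, iterations, seed)`` triple reproduces the ReplicateSet exactly.

    Parameters
    ----------
    table : FeatureTable
        Source table with at least two samples.
    iterations : int
        Number of replicates B (default 100).
    seed : int or None
        Seed for the random generator; None draws from OS entropy.
    """
    n, p = table.values.shape
    if n < 2:
        raise ValueError(f"resampling needs at least 2 samples, got {n}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(iterations, n))
    replicates = []
    for b in range(iterations):
        idx = draws[b]
        # suffix with the draw position to keep sample ids unique
        sample_ids = tuple(f"{table.sample_ids[i]}#{j}" for j, i in enumerate(idx))
        replicates.append(FeatureTable(sample_ids, table.feature_ids, table.values[idx]))
    return ReplicateSet(tuple(replicates), iterations, seed, (n, p))
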