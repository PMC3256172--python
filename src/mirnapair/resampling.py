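"""Shared resampling primitives for the permutation nulls.

Both association measures build their null distribution the same way:
pool every value of the mRNA profile matrix, redraw a same-shaped matrix
i.i.d. from that pool (the "jumbled" matrix), then resample its rows with
replacement to obtain ``n_rep`` pseudo-mRNA profiles that carry no genuine
relationship to the miRNA under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationConfig", "pseudo_profiles", "spawn_rngs"]


@dataclass(frozen=True)
class PermutationConfig:
    """Number of resampling replicates and the RNG seed governing them."""

    n_rep: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def pseudo_profiles(
    pool_matrix: np.ndarray, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_rep`` pseudo-profiles from a Z x C pool matrix.

    Stage 1 redraws a Z x C matrix whose entries are sampled uniformly
    (with replacement) from the flattened pool; stage 2 samples ``n_rep``
    of its rows with replacement.  Both stages are kept, so the null
    carries the row-resampling noise as well as the pooling.

    Returns an ``n_rep x C`` array.
    """
    pool_matrix = np.asarray(pool_matrix)
    if pool_matrix.ndim != 2 or pool_matrix.size == 0:
        raise ValueError("pool matrix must be a non-empty 2-d array")
    n_rows, n_cols = pool_matrix.shape
    flat = pool_matrix.ravel()
    jumbled = rng.choice(flat, size=(n_rows, n_cols), replace=True)
    row_idx = rng.integers(0, n_rows, size=n_rep)
    return jumbled[row_idx]


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Expand one seed into ``n`` independent child generators.

    Children are deterministic functions of (seed, position), so adding a
    later consumer never perturbs the draws of an earlier one.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
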