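"""Shared machinery for randomization nulls: subset draws, SES, rank p-values."""

from __future__ import annotations

from math import comb
from itertools import combinations

import numpy as np

from .phylo_io import ValidationError

#: largest number of distinct subsets enumerated in exhaustive mode
EXHAUSTIVE_CAP = 200_000


def subset_draws(
    pool_size: int,
    k: int,
    n_reps: int,
    rng: np.random.Generator,
    mode: str = "montecarlo",
) -> np.ndarray:
    """Index matrix of null draws: each row a size-``k`` subset of ``range(pool_size)``.

    ``montecarlo`` draws ``n_reps`` uniform subsets without replacement within a
    draw; ``exhaustive`` enumerates every distinct subset (C(pool, k) rows),
    refusing when that count exceeds :data:`EXHAUSTIVE_CAP`.
    """
    if k > pool_size:
        raise ValidationError(f"sample size {k} exceeds pool size {pool_size}")
    if mode == "exhaustive":
        total = comb(pool_size, k)
        if total > EXHAUSTIVE_CAP:
            raise ValidationError(
                f"exhaustive enumeration of C({pool_size},{k})={total} draws "
                f"exceeds cap {EXHAUSTIVE_CAP}"
            )
        return np.array(list(combinations(range(pool_size), k)), dtype=np.intp)
    if mode != "montecarlo":
        raise ValidationError(f"unknown null mode: {mode!r}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    # vectorised sampling without replacement: rank k iid uniforms per row
    keys = rng.random((n_reps, pool_size))
    return np.argpartition(keys, k - 1, axis=1)[:, :k].astype(np.intp)


def ses(observed: float, null_values: np.ndarray) -> tuple[float, float, float]:
    """(null_mean, null_sd, standardized effect size) with population SD.

    A degenerate null (SD = 0) yields an effect size of exactly 0 rather than
    NaN; callers label the result accordingly.
    """
    null_values = np.asarray(null_values, dtype=float)
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=0))
    # identical draws can leave an SD of pure summation noise; treat as zero
    if sd <= 1e-12 * max(abs(mean), 1.0):
        return mean, 0.0, 0.0
    return mean, sd, (observed - mean) / sd


def rank_p_two_tailed(observed: float, null_values: np.ndarray) -> float:
    """Two-tailed permutation rank p with ties split evenly.

    r = #{null < observed} + ½·#{null == observed};
    p = 2·min(r + 1, m + 1 − r) / (m + 1) for m null draws, capped at 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    m = null_values.size
    r = float(np.count_nonzero(null_values < observed))
    r += 0.5 * float(np.count_nonzero(null_values == observed))
    p = 2.0 * min(r + 1.0, m + 1.0 - r) / (m + 1.0)
    return min(p, 1.0)
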