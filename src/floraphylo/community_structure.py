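"""Community phylogenetic structure: MNTD and the nearest taxon index (NTI).

MNTD is the mean, over the taxa of a sample, of the patristic distance to each
taxon's nearest co-occurring relative.  NTI standardizes it against a
richness-preserving null that draws the observed number of taxa uniformly from
a sampling pool (by default every tip in the phylogeny) and flips the sign:

    NTI = −(MNTD_obs − mean(MNTD_null)) / SD(MNTD_null),

so positive values indicate phylogenetic clustering (samples closer than
chance, the habitat-filtering signature) and negative values phylogenetic
overdispersion (the competitive-exclusion signature).  Incidence only — the
checklists carry no abundances.  The null SD is the population SD over draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._null import rank_p_two_tailed, ses as _ses, subset_draws
from .phylo_io import DistanceMatrix, ValidationError

__all__ = ["NtiResult", "mntd", "nti", "classify_structure"]

_CHUNK = 2000  # null draws scored per block to bound the (reps, k, k) workspace


def mntd(sample, d: DistanceMatrix) -> float:
    """Mean nearest taxon distance of ``sample`` (tip labels) under ``d``, in Ma.

    Needs at least two taxa: with a single taxon there is no nearest relative
    (the reason a 5-genus gymnosperm tree yields no index).  Ties in nearest
    distance are irrelevant — only the minimum value enters the mean.
    """
    idx = d.indices(sorted(set(sample)))
    if idx.size < 2:
        raise ValidationError("MNTD needs at least 2 taxa in the sample")
    sub = d.d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_mntd(d: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """MNTD of each row of ``draws`` (index subsets), vectorised in blocks."""
    n_reps, k = draws.shape
    out = np.empty(n_reps)
    eye = np.eye(k, dtype=bool)
    for start in range(0, n_reps, _CHUNK):
        block = draws[start:start + _CHUNK]
        sub = d[block[:, :, None], block[:, None, :]]
        sub[:, eye] = np.inf
        out[start:start + block.shape[0]] = sub.min(axis=2).mean(axis=1)
    return out


@dataclass
class NtiResult:
    site: str
    mntd_observed: float
    null_mean: float
    null_sd: float
    nti: float
    rank_p: float
    n_taxa: int
    n_reps: int
    classification: Literal["clustered", "dispersed", "nonsignificant", "degenerate"]


def nti(
    sample,
    d: DistanceMatrix,
    pool=None,
    n_reps: int = 999,
    seed: int | np.random.Generator | None = None,
    mode: str = "montecarlo",
    alpha: float = 0.05,
    site: str = "",
) -> NtiResult:
    """Nearest taxon index of ``sample`` against a richness null over ``pool``.

    ``pool`` defaults to every label in the distance matrix (whole-study pool).
    ``mode="exhaustive"`` enumerates all C(|pool|, |sample|) subsets instead of
    Monte-Carlo sampling.  Significance is rank-based at ``alpha`` (two-tailed,
    ties split); the ±1.96 shortcut is available through the SES value itself.
    """
    sample = sorted(set(sample))
    pool = sorted(set(pool)) if pool is not None else list(d.labels)
    if not set(sample) <= set(pool):
        extra = sorted(set(sample) - set(pool))
        raise ValidationError(f"sample taxa not in pool: {extra}")
    observed = mntd(sample, d)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_idx = d.indices(pool)
    draws_local = subset_draws(len(pool), len(sample), n_reps, rng, mode=mode)
    draws = pool_idx[draws_local]
    null_vals = _null_mntd(d.d, draws)

    null_mean, null_sd, effect = _ses(observed, null_vals)
    result = NtiResult(
        site=site,
        mntd_observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        nti=-effect,
        rank_p=rank_p_two_tailed(observed, null_vals),
        n_taxa=len(sample),
        n_reps=draws.shape[0],
        classification="degenerate",
    )
    if null_sd > 0:
        result.classification = classify_structure(result, alpha=alpha)
    return result


def classify_structure(result: NtiResult, alpha: float = 0.05) -> str:
    """Clustered if NTI > 0 and rank p < alpha; dispersed if NTI < 0 likewise."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if result.null_sd == 0:
        return "degenerate"
    if result.rank_p < alpha:
        if result.nti > 0:
            return "clustered"
        if result.nti < 0:
            return "dispersed"
    return "nonsignificant"
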