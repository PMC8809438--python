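"""Flora divergence time: MDT, median flora age, and permutation SES-MDT.

The mean divergence time of an assemblage is the species-count-weighted mean
of its genus-level crown ages,

    MDT = Σᵢ AGEᵢ·Sᵢ / Σᵢ Sᵢ   [Ma],

where AGEᵢ is the crown age of genus *i* and Sᵢ its species count in the
sample.  SES-MDT standardizes the observed MDT against randomized assemblages
drawn from a genus pool: each null draw keeps the observed number of genera
(richness-preserving) and every drawn genus carries its pool-level species
count.  Assemblages with SES-MDT > 1.96 are significantly ancient floras and
those with SES-MDT < −1.96 significantly young; a permutation rank p-value is
reported alongside the ±1.96 rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._null import rank_p_two_tailed, ses as _ses, subset_draws
from .phylo_io import ValidationError

__all__ = [
    "CladeAgeTable",
    "MdtResult",
    "SesResult",
    "read_clade_table",
    "mdt",
    "median_flora_age",
    "ses_mdt",
    "classify_flora",
    "GENUS_CLASSES",
    "SES_THRESHOLD",
]

GENUS_CLASSES = ("dominant", "common", "occasional", "endemic")

#: two-sided normal critical value pairing with p < 0.05
SES_THRESHOLD = 1.96

_SITE_COUNT_PREFIX = "count_"


@dataclass
class CladeAgeTable:
    """Genus-level clades with crown ages (Ma), species counts and origin labels.

    ``df`` columns: ``genus`` (unique), ``age_ma`` (> 0), ``species_count``
    (pool-level, ≥ 1), ``origin`` (category label or ``"Unknown"``),
    ``genus_class`` (dominant | common | occasional | endemic).  Optional
    per-site count columns named ``count_<site>`` (≥ 0; a zero means the genus
    is absent from that site) allow county-specific species weights.
    """

    df: pd.DataFrame
    sites: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("genus", "age_ma", "species_count"):
            if col not in df.columns:
                raise ValidationError(f"clade table missing column {col!r}")
        if df["genus"].duplicated().any():
            dupes = sorted(df.loc[df["genus"].duplicated(), "genus"].unique())
            raise ValidationError(f"duplicate genus labels: {dupes}")
        ages = pd.to_numeric(df["age_ma"], errors="coerce")
        if ages.isna().any() or not np.isfinite(ages).all() or (ages <= 0).any():
            raise ValidationError("crown ages must be finite and positive (Ma)")
        counts = pd.to_numeric(df["species_count"], errors="coerce")
        if counts.isna().any() or (counts < 1).any():
            raise ValidationError("species_count must be >= 1")
        df = df.copy()
        df["age_ma"] = ages.astype(float)
        df["species_count"] = counts.astype(int)
        if "origin" not in df.columns:
            df["origin"] = "Unknown"
        if "genus_class" not in df.columns:
            df["genus_class"] = "occasional"
        site_cols = [c for c in df.columns if c.startswith(_SITE_COUNT_PREFIX)]
        for c in site_cols:
            v = pd.to_numeric(df[c], errors="coerce").fillna(0)
            if (v < 0).any():
                raise ValidationError(f"negative per-site count in {c!r}")
            df[c] = v.astype(int)
        self.df = df.reset_index(drop=True)
        self.sites = tuple(c[len(_SITE_COUNT_PREFIX):] for c in site_cols)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genera(self) -> list[str]:
        return list(self.df["genus"])

    @property
    def ages(self) -> np.ndarray:
        return self.df["age_ma"].to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.df["species_count"].to_numpy()

    def for_site(self, site: str) -> "CladeAgeTable":
        """Restrict to genera present at ``site``, carrying the site's counts."""
        col = _SITE_COUNT_PREFIX + site
        if col not in self.df.columns:
            raise ValidationError(f"no per-site counts for site {site!r}")
        sub = self.df[self.df[col] > 0].copy()
        if sub.empty:
            raise ValidationError(f"no clades present at site {site!r}")
        sub["species_count"] = sub[col]
        keep = [c for c in sub.columns if not c.startswith(_SITE_COUNT_PREFIX)]
        return CladeAgeTable(sub[keep])

    def subset(self, genera) -> "CladeAgeTable":
        genera = list(genera)
        mask = self.df["genus"].isin(genera)
        if mask.sum() != len(set(genera)):
            missing = sorted(set(genera) - set(self.df["genus"]))
            raise ValidationError(f"genera absent from clade table: {missing}")
        return CladeAgeTable(self.df[mask])

    def with_counts(self, counts: dict[str, int]) -> "CladeAgeTable":
        """Replace species counts (e.g. with site-level counts from a checklist)."""
        sub = self.subset(counts.keys())
        df = sub.df.copy()
        df["species_count"] = df["genus"].map(counts).astype(int)
        return CladeAgeTable(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_clade_table(path) -> CladeAgeTable:
    """Read a clade-age CSV (genus, age_ma, species_count[, count_<site>...])."""
    return CladeAgeTable(pd.read_csv(path))


@dataclass
class MdtResult:
    site: str
    mdt: float
    median_age: float
    n_clades: int
    n_species: int


def mdt(sample: CladeAgeTable, site: str = "", weighted_median: bool = False) -> MdtResult:
    """Species-weighted mean divergence time of one assemblage.

    ``median_age`` is the unweighted median of clade crown ages by default; the
    species-weighted variant (lower weighted median) is available via
    ``weighted_median=True``.
    """
    if len(sample) == 0:
        raise ValidationError("empty clade-age sample")
    ages = sample.ages
    counts = sample.counts
    value = float(np.dot(ages, counts) / counts.sum())
    med = median_flora_age(sample, weighted=weighted_median)
    return MdtResult(
        site=site,
        mdt=value,
        median_age=med,
        n_clades=len(sample),
        n_species=int(counts.sum()),
    )


def median_flora_age(sample: CladeAgeTable, weighted: bool = False) -> float:
    """Median clade crown age; optionally species-count weighted."""
    if len(sample) == 0:
        raise ValidationError("empty clade-age sample")
    if not weighted:
        return float(np.median(sample.ages))
    order = np.argsort(sample.ages, kind="stable")
    ages = sample.ages[order]
    w = sample.counts[order].astype(float)
    cum = np.cumsum(w)
    return float(ages[np.searchsorted(cum, 0.5 * cum[-1])])


@dataclass
class SesResult:
    site: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    rank_p: float
    n_reps: int
    classification: Literal["ancient", "young", "nonsignificant", "degenerate"]


def ses_mdt(
    sample: CladeAgeTable,
    pool: CladeAgeTable,
    n_reps: int = 999,
    seed: int | np.random.Generator | None = None,
    mode: str = "montecarlo",
    site: str = "",
) -> SesResult:
    """Standardized effect size of MDT against richness-preserving random draws.

    Null assemblages are uniform subsets of the pool's genera of the observed
    genus richness; each drawn genus carries its pool species count.  The null
    SD is the population SD over draws; a zero SD (e.g. sample = pool) yields
    SES = 0 labelled ``degenerate``.
    """
    k = len(sample)
    if k == 0:
        raise ValidationError("empty clade-age sample")
    if k > len(pool):
        raise ValidationError(
            f"sample has {k} genera but pool only {len(pool)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = mdt(sample, site=site).mdt

    draws = subset_draws(len(pool), k, n_reps, rng, mode=mode)
    ages = pool.ages[draws]
    counts = pool.counts[draws]
    null_mdt = (ages * counts).sum(axis=1) / counts.sum(axis=1)

    null_mean, null_sd, effect = _ses(observed, null_mdt)
    p = rank_p_two_tailed(observed, null_mdt)
    result = SesResult(
        site=site,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=effect,
        rank_p=p,
        n_reps=draws.shape[0],
        classification="degenerate",
    )
    if null_sd > 0:
        result.classification = classify_flora(result)
    return result


def classify_flora(result: SesResult | float) -> str:
    """Classify a flora by SES-MDT: > 1.96 ancient, < −1.96 young, else nonsignificant."""
    if isinstance(result, SesResult):
        if result.null_sd == 0:
            return "degenerate"
        value = result.ses
    else:
        value = float(result)
    if value > SES_THRESHOLD:
        return "ancient"
    if value < -SES_THRESHOLD:
        return "young"
    return "nonsignificant"
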