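"""Descriptive checklist tabulations: richness, endemism, growth forms, monotypy.

Regional counts use union semantics — a region's species set is the union of
its member counties' sets, never the sum — and a monotypic genus is one with
exactly one species *within the checklist* (the data cannot speak to global
monotypy).  Printed percentages round half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .phylo_io import OccurrenceMatrix, ValidationError

__all__ = ["RichnessSummary", "summarize", "round_percent"]


def round_percent(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ValidationError("zero denominator in percentage")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RichnessSummary:
    overall: dict
    per_site: pd.DataFrame
    per_region: pd.DataFrame
    growth_forms: dict[str, int]

    def to_csv(self, site_path=None, region_path=None) -> None:
        if site_path is not None:
            self.per_site.to_csv(site_path, index_label="site")
        if region_path is not None:
            self.per_region.to_csv(region_path, index_label="region")


def _counts_for(meta: pd.DataFrame, species: list) -> dict:
    sub = meta.loc[species]
    rec = {
        "n_species": len(species),
        "n_genera": sub["genus"].nunique(),
        "n_endemic_species": int(sub["endemic"].sum()),
        "n_endemic_genera": int(
            sub.groupby("genus")["endemic"].all().sum()
        ) if len(species) else 0,
    }
    if "family" in meta.columns:
        rec["n_families"] = sub["family"].nunique()
    return rec


def summarize(m: OccurrenceMatrix, regions: dict[str, str]) -> RichnessSummary:
    """Per-site, per-region and overall richness/endemism tabulation.

    ``regions`` maps every site ID to a region label; an unmapped site is an
    error.  An endemic genus is one whose checklist species are all endemic.
    """
    unmapped = sorted(set(m.sites) - set(regions))
    if unmapped:
        raise ValidationError(f"sites without a region: {unmapped}")

    meta = m.species_meta
    site_rows = {site: _counts_for(meta, m.species_at(site)) for site in m.sites}
    per_site = pd.DataFrame.from_dict(site_rows, orient="index").sort_index()

    region_species: dict[str, set] = {}
    for site in m.sites:
        region_species.setdefault(regions[site], set()).update(m.species_at(site))
    per_region = pd.DataFrame.from_dict(
        {r: _counts_for(meta, sorted(sp)) for r, sp in region_species.items()},
        orient="index",
    ).sort_index()

    all_species = m.species
    overall = _counts_for(meta, all_species)
    overall["endemic_percent"] = round_percent(
        overall["n_endemic_species"], overall["n_species"]
    )
    genus_sizes = meta.loc[all_species, "genus"].value_counts()
    overall["n_monotypic_genera"] = int((genus_sizes == 1).sum())

    gf = (
        meta.loc[all_species, "growth_form"].value_counts().to_dict()
        if "growth_form" in meta.columns
        else {}
    )
    return RichnessSummary(
        overall=overall,
        per_site=per_site,
        per_region=per_region,
        growth_forms={str(k): int(v) for k, v in gf.items()},
    )
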