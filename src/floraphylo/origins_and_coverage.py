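"""Geographical-origin tabulations, age-threshold filters, and coverage checks.

Origin labels on clades are inputs from published phylogeographies, not
inferred here.  Categories (e.g. "Eastern Asia", "Tethyan", "Africa") roll up
into supergroups (Laurasian / Gondwanan / Unknown) through an editable mapping
shipped as YAML with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .divergence_metrics import CladeAgeTable
from .phylo_io import ValidationError

__all__ = [
    "OriginSummary",
    "load_supergroup_map",
    "default_supergroup_map",
    "tabulate_origins",
    "count_older_than",
    "representativeness",
]


def default_supergroup_map() -> dict[str, str]:
    """The category → supergroup map bundled with the package."""
    text = resources.files("floraphylo").joinpath("data/origin_supergroups.yaml").read_text()
    return dict(yaml.safe_load(text))


def load_supergroup_map(path) -> dict[str, str]:
    """Load a user category → supergroup map from YAML or JSON-compatible YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValidationError("supergroup map must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


@dataclass
class OriginSummary:
    category_counts: dict[str, int]
    supergroup_counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.total:
            raise ValidationError("category counts do not sum to total")
        if sum(self.supergroup_counts.values()) != self.total:
            raise ValidationError("supergroup counts do not sum to total")


def tabulate_origins(
    table: CladeAgeTable, mapping: dict[str, str] | None = None
) -> OriginSummary:
    """Count clades per origin category and per supergroup.

    Every non-"Unknown" origin label must be present in ``mapping`` (defaults
    to the bundled map); an unmapped label is an error listing the offenders.
    """
    if mapping is None:
        mapping = default_supergroup_map()
    origins = list(table.df["origin"]) if len(table) else []
    unmapped = sorted({o for o in origins if o != "Unknown" and o not in mapping})
    if unmapped:
        raise ValidationError(f"origin categories missing from supergroup map: {unmapped}")
    cat: dict[str, int] = {}
    grp: dict[str, int] = {}
    for o in origins:
        cat[o] = cat.get(o, 0) + 1
        g = mapping.get(o, "Unknown")
        grp[g] = grp.get(g, 0) + 1
    return OriginSummary(cat, grp, len(origins))


def count_older_than(table: CladeAgeTable, threshold: float) -> tuple[int, float]:
    """(count, proportion) of clades with crown age strictly greater than ``threshold`` Ma."""
    if threshold <= 0:
        raise ValidationError("age threshold must be positive (Ma)")
    if len(table) == 0:
        raise ValidationError("empty clade table")
    count = int((table.ages > threshold).sum())
    return count, count / len(table)


def representativeness(
    table: CladeAgeTable, vegetation_genera: dict[str, list[str]]
) -> dict[str, float]:
    """Fraction of each labelled genus list (e.g. dominant, common) covered by the table.

    Measures how well the collected clades represent the region's vegetation:
    a flora-age estimate is only as representative as the dominant and common
    genera it includes.
    """
    present = set(table.genera)
    out: dict[str, float] = {}
    for label, genera in vegetation_genera.items():
        if not genera:
            raise ValidationError(f"empty genus list for {label!r}")
        out[label] = sum(g in present for g in genera) / len(genera)
    return out
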