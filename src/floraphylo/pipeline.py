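"""End-to-end orchestration: read inputs → MDT/SES-MDT → NTI → origins → summaries.

A run is driven by a :class:`RunConfig` (YAML-serialisable, round-trips
exactly).  Outputs are five CSV tables plus a run-metadata JSON; every CSV
carries the config hash in a leading ``#`` comment line so results are
traceable to the exact configuration.  All randomness flows from the single
configured seed; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .checklist_summaries import summarize
from .community_structure import nti
from .divergence_metrics import CladeAgeTable, classify_flora, mdt, read_clade_table, ses_mdt
from .origins_and_coverage import count_older_than, default_supergroup_map, load_supergroup_map, tabulate_origins
from .phylo_io import (
    OccurrenceMatrix,
    Phylogeny,
    ValidationError,
    patristic_matrix,
    read_newick,
    read_occurrence,
)

logger = logging.getLogger("floraphylo")

__all__ = ["RunConfig", "Finding", "validate", "run"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the study protocol
    (999 randomizations, α = 0.05, ±1.96, whole-phylogeny sampling pool)."""

    tree: str
    occurrence: str
    clade_table: str
    region_map: str | None = None
    origin_map: str | None = None
    out_dir: str = "results"
    n_reps: int = 999
    seed: int = 0
    alpha: float = 0.05
    pool_scope: str = "phylogeny"  # or "occurrence"
    weighted_median: bool = False
    age_threshold_ma: float = 5.3

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.pool_scope not in ("phylogeny", "occurrence"):
            raise ValidationError("pool_scope must be 'phylogeny' or 'occurrence'")
        if self.age_threshold_ma <= 0:
            raise ValidationError("age_threshold_ma must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(s, encoding="utf-8")
        return s

    def config_hash(self) -> str:
        """Hash of the analytic configuration (the output location is excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Finding:
    level: str  # fatal | warning | info
    message: str


def _load_inputs(config: RunConfig):
    tree = read_newick(config.tree)
    occ = read_occurrence(config.occurrence)
    clades = read_clade_table(config.clade_table)
    region_map = None
    if config.region_map:
        df = pd.read_csv(config.region_map, dtype=str)
        if not {"site", "region"} <= set(df.columns):
            raise ValidationError("region map CSV needs 'site' and 'region' columns")
        region_map = dict(zip(df["site"], df["region"]))
    origin_map = (
        load_supergroup_map(config.origin_map) if config.origin_map else default_supergroup_map()
    )
    return tree, occ, clades, region_map, origin_map


def validate(config: RunConfig) -> list[Finding]:
    """Dry-run cross-checks; returns findings instead of raising."""
    findings: list[Finding] = []
    try:
        tree, occ, clades, region_map, origin_map = _load_inputs(config)
    except Exception as exc:
        return [Finding("fatal", str(exc))]

    tips = set(tree.tips)
    species = set(occ.species)
    covered = species & tips
    pct = 100.0 * len(covered) / len(species)
    level = "info" if pct >= 50 else "warning"
    missing = sorted(species - tips)
    findings.append(
        Finding(
            level,
            f"{len(covered)}/{len(species)} checklist species on the tree "
            f"({pct:.1f}% coverage)"
            + (f"; absent: {missing[:10]}{'...' if len(missing) > 10 else ''}" if missing else ""),
        )
    )

    table_genera = set(clades.genera)
    occ_genera = set(occ.species_meta["genus"])
    orphan = sorted(occ_genera - table_genera)
    if orphan:
        findings.append(
            Finding(
                "warning",
                f"{len(orphan)} genera in the checklist lack clade ages and are "
                f"excluded from MDT: {orphan[:10]}{'...' if len(orphan) > 10 else ''}",
            )
        )

    if clades.sites:
        mismatch = sorted(set(clades.sites) - set(occ.sites))
        if mismatch:
            findings.append(
                Finding("fatal", f"clade-table site columns not in checklist: {mismatch}")
            )
    if region_map is not None:
        unmapped = sorted(set(occ.sites) - set(region_map))
        if unmapped:
            findings.append(Finding("fatal", f"sites without a region: {unmapped}"))

    unmapped_origins = sorted(
        {o for o in clades.df["origin"] if o != "Unknown" and o not in origin_map}
    )
    if unmapped_origins:
        findings.append(
            Finding("fatal", f"origin categories missing from supergroup map: {unmapped_origins}")
        )
    return findings


def _site_sample(clades: CladeAgeTable, occ: OccurrenceMatrix, site: str) -> CladeAgeTable | None:
    """Per-site clade sample: table's own per-site counts if present, else
    species counts per genus derived from the checklist."""
    if site in clades.sites:
        return clades.for_site(site)
    counts = occ.genus_counts_at(site)
    counts = counts[counts.index.isin(clades.genera)]
    if counts.empty:
        return None
    return clades.with_counts(counts.to_dict())


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, seed: int) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed} floraphylo={__version__}\n")
        df.to_csv(fh, index=False)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name → path map of outputs.

    Emits mdt_ses.csv, nti.csv, origin_summary.csv, richness_sites.csv,
    richness_regions.csv and run_metadata.json in ``config.out_dir``.  Partial
    outputs are removed if any stage fails.
    """
    findings = validate(config)
    fatal = [f for f in findings if f.level == "fatal"]
    if fatal:
        raise ValidationError("; ".join(f.message for f in fatal))
    for f in findings:
        logger.log(logging.WARNING if f.level == "warning" else logging.INFO, f.message)

    t0 = time.perf_counter()
    tree, occ, clades, region_map, origin_map = _load_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    written: dict[str, Path] = {}
    rng = np.random.default_rng(config.seed)

    try:
        # --- MDT / SES-MDT per site -----------------------------------------
        rows = []
        for site in occ.sites:
            sample = _site_sample(clades, occ, site)
            if sample is None:
                logger.warning("site %s has no clades with ages; skipped in MDT", site)
                continue
            m = mdt(sample, site=site, weighted_median=config.weighted_median)
            s = ses_mdt(sample, clades, n_reps=config.n_reps, seed=rng, site=site)
            rows.append(
                {
                    "site": site,
                    "n_clades": m.n_clades,
                    "n_species": m.n_species,
                    "mdt_ma": m.mdt,
                    "median_age_ma": m.median_age,
                    "ses_null_mean": s.null_mean,
                    "ses_null_sd": s.null_sd,
                    "ses_mdt": s.ses,
                    "rank_p": s.rank_p,
                    "classification": s.classification,
                }
            )
        _write_csv(pd.DataFrame(rows), out_dir / "mdt_ses.csv", chash, config.seed)
        written["mdt_ses"] = out_dir / "mdt_ses.csv"

        # --- NTI per site ----------------------------------------------------
        dm = patristic_matrix(tree)
        tips = set(tree.tips)
        if config.pool_scope == "phylogeny":
            pool = sorted(tips)
        else:
            present = {sp for site in occ.sites for sp in occ.species_at(site)}
            pool = sorted(present & tips)
        n_dropped_total = 0
        rows = []
        for site in occ.sites:
            sp = occ.species_at(site)
            on_tree = sorted(set(sp) & tips)
            n_dropped_total += len(sp) - len(on_tree)
            if len(on_tree) < 2:
                logger.warning("site %s has <2 taxa on the tree; NTI undefined", site)
                continue
            r = nti(
                on_tree, dm, pool=pool, n_reps=config.n_reps,
                seed=rng, alpha=config.alpha, site=site,
            )
            rows.append(
                {
                    "site": site,
                    "n_taxa": r.n_taxa,
                    "mntd_ma": r.mntd_observed,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "nti": r.nti,
                    "rank_p": r.rank_p,
                    "classification": r.classification,
                }
            )
        if n_dropped_total:
            logger.warning(
                "%d site-species records dropped from NTI (species off the tree)",
                n_dropped_total,
            )
        _write_csv(pd.DataFrame(rows), out_dir / "nti.csv", chash, config.seed)
        written["nti"] = out_dir / "nti.csv"

        # --- Origins ---------------------------------------------------------
        osum = tabulate_origins(clades, origin_map)
        count, prop = count_older_than(clades, config.age_threshold_ma)
        rows = [
            {"kind": "category", "label": k, "clades": v}
            for k, v in sorted(osum.category_counts.items())
        ]
        rows += [
            {"kind": "supergroup", "label": k, "clades": v}
            for k, v in sorted(osum.supergroup_counts.items())
        ]
        rows.append({"kind": "total", "label": "all", "clades": osum.total})
        rows.append(
            {
                "kind": f"older_than_{config.age_threshold_ma}_ma",
                "label": f"{100 * prop:.1f}%",
                "clades": count,
            }
        )
        _write_csv(pd.DataFrame(rows), out_dir / "origin_summary.csv", chash, config.seed)
        written["origin_summary"] = out_dir / "origin_summary.csv"

        # --- Richness summaries ---------------------------------------------
        if region_map is None:
            region_map = {site: "all" for site in occ.sites}
        rich = summarize(occ, region_map)
        _write_csv(
            rich.per_site.reset_index(names="site"),
            out_dir / "richness_sites.csv", chash, config.seed,
        )
        written["richness_sites"] = out_dir / "richness_sites.csv"
        _write_csv(
            rich.per_region.reset_index(names="region"),
            out_dir / "richness_regions.csv", chash, config.seed,
        )
        written["richness_regions"] = out_dir / "richness_regions.csv"

        meta = {
            "config": config.to_dict(),
            "config_hash": chash,
            "seed": config.seed,
            "n_reps": config.n_reps,
            "floraphylo_version": __version__,
            "overall_richness": rich.overall,
            "growth_forms": rich.growth_forms,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        (out_dir / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
        )
        written["run_metadata"] = out_dir / "run_metadata.json"
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
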