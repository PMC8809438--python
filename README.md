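# floraphylo

Tools for asking two questions about a regional flora from checklist and
phylogeny data: **how old is it?** and **how are its communities assembled?**

The package targets the kind of dataset produced by floristic surveys of
mountain regions — a species checklist split into county-level geographical
units, a table of genus-level crown ages collected from published
phylogeographies, and a dated phylogeny of the species — and computes:

- **MDT (mean divergence time)** — the species-count-weighted mean of genus
  crown ages in an assemblage,

  `MDT = Σᵢ AGEᵢ·Sᵢ / Σᵢ Sᵢ`  [Ma],

  where `AGEᵢ` is the crown age of genus *i* and `Sᵢ` its species count in
  the sample, plus the (optionally species-weighted) median flora age.
- **SES-MDT** — the standardized effect size of MDT against randomized
  assemblages: `(MDT_obs − mean MDT_null) / SD(MDT_null)`, with a
  richness-preserving null (999 draws by default) that samples the observed
  number of genera uniformly from the genus pool. Values above +1.96 flag
  significantly *ancient* floras, below −1.96 significantly *young* ones; a
  two-tailed permutation rank p-value is reported alongside.
- **MNTD / NTI** — the mean nearest taxon distance (mean patristic distance
  from each taxon to its closest co-occurring relative) and the nearest
  taxon index `NTI = −(MNTD_obs − mean MNTD_null)/SD(MNTD_null)` against a
  null that draws the observed number of taxa uniformly from the whole
  phylogeny. Positive NTI = phylogenetic clustering (the habitat-filtering
  signature); negative = overdispersion (the competitive-exclusion signature).
- **Descriptive tabulations** — per-county and per-region richness (regional
  species sets are unions, never sums), endemism counts and percentages,
  growth-form breakdowns, monotypic genera, geographic-origin categories
  rolled up to Laurasian/Gondwanan/Unknown supergroups, and age-threshold
  filters (e.g. clades older than 5.3 Ma).
- **Synthetic data generators** — Yule/birth–death dated trees (via dendropy),
  clade-age tables, and site-by-species checklists assembled under *neutral*,
  *filtering*, or *repulsion* regimes, so the entire pipeline is testable
  without any data download.

## Worked example

```python
>>> import floraphylo as fp
>>> tree, clades, occ, regions = fp.make_fixture("kunlun-mini")
>>> r = fp.mdt(clades)
>>> round(r.mdt, 2), round(r.median_age, 2), r.n_clades
(22.67, 16.11, 20)
```

The fixture flora has a species-weighted mean divergence time of 22.67 Ma
and a median clade age of 16.11 Ma over its 20 genus-level clades — an
"early Miocene" flora in the sense that most of its standing lineages split
from their relatives around 16–23 Ma.

```python
>>> dm = fp.patristic_matrix(tree)
>>> site = occ.sites[2]
>>> res = fp.nti(occ.species_at(site), dm, n_reps=999, seed=1)
>>> round(res.nti, 2), round(res.rank_p, 3), res.classification
(2.6, 0.034, 'clustered')
```

Site `S3`'s species are on average much closer to their nearest co-occurring
relative than 999 random same-sized draws from the tree (NTI = +2.60,
rank p = 0.034): significantly clustered, as expected — the fixture's
communities were assembled under a habitat-filtering regime.

The same analyses run from the shell:

```sh
floraphylo simulate --out-dir demo            # write the fixture's four input files
floraphylo run --tree demo/tree.nwk --occurrence demo/occurrence.csv \
    --clade-table demo/clade_table.csv --region-map demo/region_map.csv \
    --out-dir demo/results --seed 1
```

which emits `mdt_ses.csv`, `nti.csv`, `origin_summary.csv`,
`richness_sites.csv`, `richness_regions.csv` (each with a `# config_hash=…`
header line) and `run_metadata.json`. Identical config + seed gives
byte-identical CSVs. Subcommands `mdt`, `nti`, `origins`, `summarize` and
`validate` expose the individual stages; exit codes are 0 (ok),
1 (validation error), 2 (runtime error).

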