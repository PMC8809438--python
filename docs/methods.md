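# Methods

## The statistics

**Mean divergence time (MDT).** For an assemblage of genus-level clades with
crown ages `AGEᵢ` (Ma) and species counts `Sᵢ`,

```
MDT = Σᵢ AGEᵢ·Sᵢ / Σᵢ Sᵢ
```

MDT is bounded by the youngest and oldest clade age, is invariant to scaling
all `Sᵢ` by a constant, and reduces to the plain mean when all `Sᵢ` are
equal (all three are property-tested). Crown ages are inputs from published
phylogeographies; the package does no divergence-time estimation. The
reported *median flora age* is by default the unweighted median of clade
crown ages; a species-count-weighted median (lower weighted median) is
available via `weighted_median=True`. Both readings of "median age of a
flora" are defensible; the unweighted one is the default because a median of
ages is most naturally a statement about clades, not species records.

**SES-MDT.** The observed MDT is standardized against randomized assemblages:

```
SES-MDT = (MDT_obs − mean MDT_null) / SD(MDT_null)
```

The null must fix something; here it fixes the *number of genera* in the
sample (richness-preserving), drawing that many genera uniformly without
replacement from the pool, each drawn genus carrying its pool-level species
count. This is the community-phylogenetics standard conditioning and is the
package's documented choice, not a claim about how any particular published
analysis conditioned its null. Assemblages with SES-MDT > +1.96 are labelled
`ancient`, < −1.96 `young` (strict inequalities), otherwise
`nonsignificant`; a permutation rank p accompanies the ±1.96 rule but the
classification is driven by the threshold.

**MNTD and NTI.** MNTD is the mean over a sample's taxa of the patristic
distance (sum of branch lengths on the tip-to-tip path) to the nearest other
taxon in the sample; it needs ≥ 2 taxa — a single-taxon sample has no
nearest relative, which is why a tiny (e.g. five-genus gymnosperm) tree
yields no index. The nearest taxon index flips the sign of the standardized
MNTD so that clustering is positive:

```
NTI = −(MNTD_obs − mean MNTD_null) / SD(MNTD_null)
```

The null draws the observed number of taxa uniformly from a sampling pool,
999 times by default; the pool defaults to every tip in the phylogeny
(configurable to the set of taxa observed anywhere in the checklist).
Incidence only — no abundance weighting. Classification is rank-based:
`clustered` iff NTI > 0 and rank p < α (default 0.05), `dispersed` iff
NTI < 0 and rank p < α. NTI is invariant to a global rescaling of branch
lengths (numerator and denominator scale together).

## Null-model conventions

- **SD convention:** the null SD is the *population* SD over replicates
  (divide-by-n). The choice is visible in the exhaustive worked examples
  (e.g. a 4-draw null with values {10,10,10,30} has SD √75) and must be
  fixed for reproducibility; the sample-SD variant would shrink every effect
  size by √(m/(m−1)).
- **Rank p:** two-tailed with ties split evenly. With m null draws and
  r = #{null < obs} + ½·#{null = obs}, p = 2·min(r+1, m+1−r)/(m+1), capped
  at 1. Under the null this is uniform on a grid of spacing 2/(m+1), which
  the calibration tests check by Kolmogorov–Smirnov.
- **Degenerate nulls:** when every draw is identical (e.g. sample = pool)
  the SD is zero up to floating-point summation noise; any SD below
  1e-12 × max(|null mean|, 1) is treated as exactly zero, the effect size is
  defined as 0 (never NaN), and the result is labelled `degenerate`.
- **Exhaustive mode** enumerates all C(pool, k) subsets (used by the worked
  examples and the Monte-Carlo-agreement tests) and refuses beyond 200 000
  subsets. Monte-Carlo subsets are drawn by ranking iid uniforms per
  replicate, vectorised; null MNTDs are scored in blocks of 2000 draws to
  bound the (reps × k × k) workspace.
- **Seeding:** every routine accepts either an integer seed or a shared
  `numpy.random.Generator`; the pipeline threads one generator, seeded from
  the config, through all sites in order, so identical config + seed gives
  byte-identical CSV outputs.

## Input handling

Trees are parsed with dendropy. Polytomies are kept verbatim and zero-length
branches are legal (collapsed edges are common in dated supertrees); a
missing branch length is a hard error — a dated analysis must not zero-fill.
Patristic distances are computed from node depths and lowest common
ancestors in one postorder pass; tests check the matrix against both an
independent ancestor-walk path-summation oracle and dendropy's
`PhylogeneticDistanceMatrix`. Ties in nearest-taxon distance need no
breaking: only the minimum value enters MNTD.

Occurrence checklists are long-format CSV (site, species, genus,
growth_form, endemic). Duplicate (site, species) rows collapse with a logged
warning; a species mapped to two genera is an error. Infraspecific taxa are
simply distinct species records. Species present in the checklist but absent
from the phylogeny are dropped from MNTD/NTI with a logged count — real
megatree-based analyses typically cover only part of a checklist (on the
order of 60% of species), so partial coverage is the expected case, and the
`validate` command reports the coverage percentage and the missing names
before a run.

Clade tables carry pool-level species counts and, optionally, per-site
counts in `count_<site>` columns. When a site has no count column, the
pipeline derives per-genus species counts from the checklist itself, so
either convention (county-specific or pool-wide weights) is supported.

## Synthetic data

The generators reproduce the *statistical shape* of a mountain-flora survey,
not any real flora. Defaults encode the study conditions the pipeline
targets: 126 clades; crown ages lognormal with mean 19.40 Ma and median
13.75 Ma (the two-parameter lognormal is fixed exactly by that pair);
species-per-clade counts shifted-geometric with mean 9; origin-category
frequencies matching the published 126-clade tabulation; 28 sites; endemism
rate 0.30; growth-form frequencies of a 1911-species checklist. Trees are
Yule or birth–death (dendropy), ultrametric over extant tips, with the stem
edge removed so tree depth is crown height; the simulated Yule crown height
is checked against its analytic expectation Σ_{k=2}^{n−1} 1/(kλ).

Assembly regimes encode only the *causal directions* the indices are meant
to detect, with deliberately simple monotone kernels: filtering picks a
uniform focal tip per site and samples taxa with weight `exp(−s·d(tip,
focal))` (implemented exactly via Gumbel top-k); repulsion samples
sequentially with weight `(min distance to already-chosen)^s`; strength
s = 0 reduces both to uniform draws, bit-identically. Genera are assigned as
contiguous blocks of the tree's leaf order (genera are clades), growth forms
and endemic flags independently per species. What the generator does *not*
emulate: spatial autocorrelation among neighbouring counties, richness
gradients, range dynamics, abundances, or taxonomic error — so passing tests
demonstrate the statistics and nulls behave correctly, not that any
ecological conclusion about a real flora is right.

The `kunlun-mini` fixture (60 tips rescaled to 40 Ma depth, 20 clades, 8
sites in 4 regions, filtering strength 0.15, fixed internal seed) is built
so the clade table's per-site counts agree exactly with the checklist's
genus counts, which integration tests verify.

## Problem sizes in the tests

Oracle-equivalence tests enumerate all subsets of random trees of 4–8 tips;
Monte-Carlo vs exhaustive agreement uses pools of 8–9 taxa with 9999 draws,
compared within 3 bootstrap standard errors of the effect size; null
calibration uses 1000 simulated assemblages of 10 taxa from 40-taxon pools
at 199 draws each (mean within ±0.1, SD within [0.85, 1.15], KS uniformity
at α = 0.01); regime-sign recovery uses 200 sites of 12 taxa on a 64-tip
tree (one-sided t, p < 0.01) and a monotonicity check over strengths
{0, 0.5, 1, 2, 4}. These sizes keep the whole suite under a minute while
leaving each statistical check well-powered.

## Known limitations

- Origin supergroup assignment is a lookup through an editable YAML map; no
  ancestral-range inference is attempted.
- The pipeline assumes one genus per species name; homonyms across families
  must be disambiguated upstream.
- Exhaustive mode is capped; very large pools are Monte-Carlo only.
- The ±1.96 rule and the rank p can disagree near the boundary (they test
  slightly different things); both are reported, and each classifier states
  which it uses.
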