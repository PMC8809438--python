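"""Phylogeny and occurrence-table I/O, plus the patristic distance matrix.

Every downstream statistic (MNTD, NTI) consumes patristic distances — the sum
of branch lengths along the unique tip-to-tip path through a rooted tree with
branch lengths in units of Ma (million years).  Trees are parsed with dendropy;
polytomies are accepted verbatim and zero-length branches are legal (dated
supertrees are frequently polytomous with collapsed edges).  Missing branch
lengths are rejected outright: a dated analysis cannot silently zero-fill.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("floraphylo")

__all__ = [
    "FloraPhyloError",
    "NewickParseError",
    "ValidationError",
    "Phylogeny",
    "DistanceMatrix",
    "OccurrenceMatrix",
    "read_newick",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "read_occurrence",
    "GROWTH_FORMS",
]


class FloraPhyloError(Exception):
    """Base class for all package errors."""


class NewickParseError(FloraPhyloError):
    """Malformed Newick input; message carries the parser's position report."""


class ValidationError(FloraPhyloError):
    """Structurally parseable input that violates a domain invariant."""


GROWTH_FORMS = (
    "tree",
    "shrub",
    "liana",
    "annual herb",
    "perennial herb",
    "herbaceous climber",
)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Ma.

    Wraps a :class:`dendropy.Tree`.  Invariants enforced at construction:
    unique tip labels, every non-root edge carries a nonnegative length.
    """

    tree: dendropy.Tree
    tips: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValidationError("unlabeled tip encountered")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue  # a root edge length is optional in Newick
            if node.edge.length is None:
                raise ValidationError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'!r}; "
                    "dated analyses do not zero-fill"
                )
            if node.edge.length < 0:
                raise ValidationError(
                    f"negative branch length {node.edge.length} above "
                    f"{node.taxon.label if node.taxon else 'an internal node'!r}"
                )
        self.tips = tuple(sorted(labels))

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()]
        dmax = max(depths)
        return dmax == 0 or (dmax - min(depths)) <= rel_tol * dmax

    def max_depth(self) -> float:
        return max(leaf.distance_from_root() for leaf in self.tree.leaf_node_iter())


def parse_newick(newick: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels in Newick: {exc}") from exc
    except Exception as exc:  # dendropy's reader errors report line/column
        raise NewickParseError(str(exc)) from exc
    if tree.seed_node is None or len(tree.leaf_nodes()) == 0:
        raise NewickParseError("empty tree")
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a rooted, dated Newick tree from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(phylogeny: Phylogeny, path=None) -> str:
    """Serialise to Newick (branch lengths always written); optionally to ``path``."""
    s = phylogeny.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix over ordered tip labels (Ma)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValidationError("negative patristic distance")
        self._index = {lbl: i for i, lbl in enumerate(self.labels)}

    def indices(self, labels) -> np.ndarray:
        try:
            return np.array([self._index[l] for l in labels], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"label not in distance matrix: {exc.args[0]!r}") from exc

    def distance(self, a: str, b: str) -> float:
        i, j = self._index[a], self._index[b]
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="taxon")


def patristic_matrix(phylogeny: Phylogeny) -> DistanceMatrix:
    """All-pairs patristic distances.

    Uses node depths and lowest common ancestors via a single postorder pass:
    for tips i, j whose LCA is node v, d(i, j) = depth(i) + depth(j) − 2·depth(v).
    O(n²) time, exact on trees because patristic distances are additive.
    """
    leaves = list(phylogeny.tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValidationError("patristic distances need at least 2 tips")
    labels = tuple(sorted(leaf.taxon.label for leaf in leaves))
    idx = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)

    depth: dict[int, float] = {id(phylogeny.tree.seed_node): 0.0}
    for node in phylogeny.tree.preorder_node_iter():
        if node is phylogeny.tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    d = np.zeros((n, n), dtype=float)
    tipsets: dict[int, list[tuple[int, float]]] = {}
    for node in phylogeny.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [(idx[node.taxon.label], depth[id(node)])]
            continue
        groups = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        # pairs whose LCA is this node live in distinct child subtrees
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.array([t[0] for t in groups[a]], dtype=np.intp)
                da = np.array([t[1] for t in groups[a]])
                ib = np.array([t[0] for t in groups[b]], dtype=np.intp)
                db = np.array([t[1] for t in groups[b]])
                dist = da[:, None] + db[None, :] - 2.0 * depth[id(node)]
                d[ia[:, None], ib[None, :]] = dist
                d[ib[:, None], ia[None, :]] = dist.T
        tipsets[id(node)] = [t for g in groups for t in g]
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Occurrence matrix
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceMatrix:
    """Sites × species incidence with per-species metadata.

    ``incidence`` is a 0/1 DataFrame (rows = site IDs, columns = species IDs);
    ``species_meta`` is indexed by species with columns ``genus``,
    ``growth_form``, ``endemic`` (bool) and optionally ``family``.
    """

    incidence: pd.DataFrame
    species_meta: pd.DataFrame

    def __post_init__(self) -> None:
        inc = self.incidence
        if inc.index.has_duplicates:
            raise ValidationError("duplicate site IDs")
        if inc.columns.has_duplicates:
            raise ValidationError("duplicate species IDs")
        vals = inc.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("incidence must be strictly 0/1")
        self.incidence = inc.astype(np.int8)
        missing = set(inc.columns) - set(self.species_meta.index)
        if missing:
            raise ValidationError(f"species without metadata: {sorted(missing)[:5]}")
        if "genus" not in self.species_meta.columns:
            raise ValidationError("species_meta must carry a 'genus' column")

    @property
    def sites(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    def species_at(self, site: str) -> list[str]:
        row = self.incidence.loc[site]
        return list(row.index[row == 1])

    def genus_counts_at(self, site: str) -> pd.Series:
        """Species count per genus present at a site."""
        sp = self.species_at(site)
        return self.species_meta.loc[sp, "genus"].value_counts()

    def to_long(self) -> pd.DataFrame:
        recs = []
        for site in self.sites:
            for sp in self.species_at(site):
                meta = self.species_meta.loc[sp]
                rec = {
                    "site": site,
                    "species": sp,
                    "genus": meta["genus"],
                    "growth_form": meta.get("growth_form", ""),
                    "endemic": bool(meta.get("endemic", False)),
                }
                if "family" in self.species_meta.columns:
                    rec["family"] = meta["family"]
                recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


_REQUIRED_OCC_COLS = ("site", "species", "genus", "growth_form", "endemic")


def read_occurrence(path) -> OccurrenceMatrix:
    """Read a long-format occurrence CSV (site, species, genus, growth_form, endemic).

    Duplicate (site, species) rows are collapsed with a logged warning; a
    species mapped to more than one genus is a hard error listing offenders.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_OCC_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"occurrence CSV missing columns: {missing}")
    if df.empty:
        raise ValidationError("occurrence CSV has no rows")

    genus_map = df.groupby("species")["genus"].nunique()
    conflicted = sorted(genus_map.index[genus_map > 1])
    if conflicted:
        raise ValidationError(
            f"species mapped to multiple genera: {conflicted}"
        )

    n_dupes = int(df.duplicated(subset=["site", "species"]).sum())
    if n_dupes:
        logger.warning("collapsed %d duplicate (site, species) rows", n_dupes)
        df = df.drop_duplicates(subset=["site", "species"])

    meta_cols = ["genus", "growth_form", "endemic"]
    if "family" in df.columns:
        meta_cols.append("family")
    meta = df.groupby("species")[meta_cols].first()
    meta["endemic"] = meta["endemic"].str.strip().str.lower().isin(
        {"1", "true", "yes", "y"}
    )

    sites = sorted(df["site"].unique())
    species = sorted(df["species"].unique())
    inc = pd.DataFrame(0, index=sites, columns=species, dtype=np.int8)
    for site, sp in zip(df["site"], df["species"]):
        inc.at[site, sp] = 1
    return OccurrenceMatrix(inc, meta)


def read_occurrence_string(text: str) -> OccurrenceMatrix:
    """Convenience: parse occurrence CSV content from a string."""
    return read_occurrence(io.StringIO(text))
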