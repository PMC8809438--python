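"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths: patristic distances
are computed by walking parent pointers on a freshly parsed dendropy tree and
summing branch lengths along the tip-to-tip path; MNTD by a plain double loop.
"""

from itertools import combinations

import dendropy
import numpy as np


def patristic_oracle(newick: str) -> dict[tuple[str, str], float]:
    """All-pairs path-sum distances by explicit ancestor walks."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaves = list(tree.leaf_node_iter())

    def ancestors(leaf):
        # node -> cumulative distance from the leaf up to that node
        out, node, total = {}, leaf, 0.0
        while node is not None:
            out[id(node)] = total
            if node.edge.length is not None:
                total += node.edge.length
            node = node.parent_node
        return out

    walks = {leaf.taxon.label: ancestors(leaf) for leaf in leaves}
    dist = {}
    for a, b in combinations(sorted(walks), 2):
        wa, wb = walks[a], walks[b]
        # lowest common ancestor = shared node minimizing the summed walk
        d = min(wa[k] + wb[k] for k in wa.keys() & wb.keys())
        dist[(a, b)] = dist[(b, a)] = d
    return dist


def mntd_oracle(sample, dist: dict[tuple[str, str], float]) -> float:
    """Double-loop mean nearest taxon distance."""
    sample = sorted(set(sample))
    nearest = []
    for i in sample:
        nearest.append(min(dist[(i, j)] for j in sample if j != i))
    return float(np.mean(nearest))


def bootstrap_se(null_values: np.ndarray, observed: float, stat, n_boot: int,
                 rng: np.random.Generator) -> float:
    """Bootstrap standard error of a statistic of (observed, null sample)."""
    null_values = np.asarray(null_values, dtype=float)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        resample = null_values[rng.integers(0, null_values.size, null_values.size)]
        vals[b] = stat(observed, resample)
    return float(vals.std(ddof=1))
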