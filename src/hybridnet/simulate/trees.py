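"""Random supported trees for exercising the branch-consensus machinery."""

from __future__ import annotations

import dendropy
import numpy as np

from ..phylo import METRIC_RANGES, SupportedTree

DEFAULT_METRICS = ("aBayes", "SH_aLRT", "RBS", "PP")


def simulate_supported_tree(
    n_taxa: int,
    metric_names: tuple[str, ...] = DEFAULT_METRICS,
    seed: int = 0,
) -> SupportedTree:
    """Random binary topology with per-internal-branch support draws.

    Supports are uniform over each metric's legal range (probabilities in
    [0, 1]; bootstrap percents in [0, 100]). An unrooted binary tree over n
    taxa has n - 3 internal branches. Bit-reproducible for a fixed seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    unknown = [m for m in metric_names if m not in METRIC_RANGES]
    if unknown:
        raise ValueError(f"unknown support metric(s): {unknown}")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa - 1))
    ns = dendropy.TaxonNamespace([f"T{i:0{width}d}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for taxon in ns:
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.uniform(0.01, 1.0))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.01, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for node in nodes:
        tree.seed_node.add_child(node)
    supported = SupportedTree(tree=tree, supports={})
    supports = {}
    for bip in supported.internal_bipartitions():
        supports[bip] = {
            m: float(rng.uniform(*METRIC_RANGES[m])) for m in metric_names
        }
    supported.supports = supports
    return supported
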