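"""Alignment-column masking and multi-metric branch-support consensus.

Phylogenies inferred with different programs come with different support
statistics: parametric ones (aBayes approximate likelihood-ratio test,
Bayesian posterior probability PP) tend to be powerful but can inflate
under model violation, while non-parametric ones (SH-aLRT, rapid bootstrap
RBS) are conservative. A branch is therefore treated as significantly
supported only when at least two metrics clear their thresholds and the
passing set mixes the two kinds — at least one parametric and one
non-parametric.

Trees are handled unrooted; branches are matched across trees by the leaf
bipartition they induce. Multi-metric supports serialize as extended newick
branch comments, e.g. ``[&aBayes=0.95,SH_aLRT=0.85,RBS=70,PP=0.98]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

#: Legal value range per support metric (probabilities vs percents).
METRIC_RANGES: dict[str, tuple[float, float]] = {
    "aBayes": (0.0, 1.0),
    "SH_aLRT": (0.0, 1.0),
    "RBS": (0.0, 100.0),
    "PP": (0.0, 1.0),
}


@dataclass(frozen=True)
class SupportPolicy:
    """Significance thresholds and metric kinds for the consensus rule."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"aBayes": 0.9, "SH_aLRT": 0.80, "RBS": 70.0, "PP": 0.95}
    )
    parametric: frozenset[str] = frozenset({"aBayes", "PP"})
    nonparametric: frozenset[str] = frozenset({"SH_aLRT", "RBS"})

    def __post_init__(self):
        if self.parametric & self.nonparametric:
            raise ValueError("parametric and nonparametric metric sets overlap")


@dataclass
class ScoredAlignment:
    """Aligned sequences with one external column score per position."""

    names: list[str]
    sequences: list[str]
    column_scores: list[float]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if self.sequences and len(self.column_scores) != len(self.sequences[0]):
            raise ValueError("need exactly one score per alignment column")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def mask_columns(alignment: ScoredAlignment, top_fraction: float) -> ScoredAlignment:
    """Keep the ceil(q*N) highest-scoring columns, in original order.

    Score ties are broken in favour of the lower column index.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    n = alignment.n_columns
    n_keep = math.ceil(top_fraction * n)
    order = sorted(range(n), key=lambda i: (-alignment.column_scores[i], i))
    keep = sorted(order[:n_keep])
    return ScoredAlignment(
        names=list(alignment.names),
        sequences=["".join(s[i] for i in keep) for s in alignment.sequences],
        column_scores=[alignment.column_scores[i] for i in keep],
    )


Bipartition = frozenset  # canonical side of an unrooted split (see _split_key)


@dataclass
class SupportedTree:
    """Unrooted topology plus per-internal-branch support values.

    ``supports`` maps each internal bipartition (the split side *not*
    containing the lexicographically smallest taxon) to a metric -> value
    mapping.
    """

    tree: dendropy.Tree
    supports: dict[Bipartition, dict[str, float]]

    def __post_init__(self):
        taxa = self.taxa
        for bip, metrics in self.supports.items():
            if not bip <= taxa:
                raise ValueError(f"bipartition {set(bip)} not over the leaf set")
            for name, value in metrics.items():
                lo, hi = METRIC_RANGES.get(name, (-math.inf, math.inf))
                if not lo <= value <= hi:
                    raise ValueError(f"{name}={value} outside legal range [{lo}, {hi}]")

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    def internal_bipartitions(self) -> list[Bipartition]:
        return _internal_splits(self.tree)

    # -- newick I/O ---------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, metric: str | None = None) -> "SupportedTree":
        """Parse a newick string or file path.

        Multi-metric supports are read from ``[&name=value]`` branch
        comments; with ``metric`` given, plain internal-node support labels
        (or label-less numeric node names) are read as that single metric.
        """
        kwargs = dict(schema="newick", extract_comment_metadata=True)
        if "(" in source:
            tree = dendropy.Tree.get(data=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
        supports: dict[Bipartition, dict[str, float]] = {}
        ref = min(t.label for t in tree.taxon_namespace)
        all_taxa = frozenset(t.label for t in tree.taxon_namespace)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            key = _split_key(_leafset(node), all_taxa, ref)
            if len(key) < 2 or len(all_taxa - key) < 2:
                continue
            metrics: dict[str, float] = {}
            for ann in node.annotations:
                try:
                    metrics[ann.name] = float(ann.value)
                except (TypeError, ValueError):
                    continue
            if metric is not None and node.label is not None:
                try:
                    metrics[metric] = float(node.label)
                except ValueError:
                    pass
            if metrics:
                supports[key] = supports.get(key, {}) | metrics
        return cls(tree=tree, supports=supports)

    def to_newick(self) -> str:
        """Serialize with supports as ``[&...]`` branch comments."""
        tree = self.tree.clone(depth=1)
        ref = min(t.label for t in tree.taxon_namespace)
        all_taxa = self.taxa
        for node in tree.preorder_node_iter():
            node.annotations.clear()
            if node.is_leaf() or node.parent_node is None:
                continue
            key = _split_key(_leafset(node), all_taxa, ref)
            for name, value in sorted(self.supports.get(key, {}).items()):
                node.annotations.add_new(name, repr(float(value)))
        return tree.as_string(
            schema="newick", suppress_annotations=False, suppress_rooting=True
        )


def _leafset(node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _split_key(side: frozenset[str], all_taxa: frozenset[str], ref: str) -> Bipartition:
    return frozenset(all_taxa - side) if ref in side else side


def _internal_splits(tree: dendropy.Tree) -> list[Bipartition]:
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_taxa)
    seen = []
    found = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = _leafset(node)
        if len(below) < 2 or len(all_taxa - below) < 2:
            continue
        key = _split_key(below, all_taxa, ref)
        if key not in found:
            found.add(key)
            seen.append(key)
    return seen


def flag_significant_branches(
    tree: SupportedTree, policy: SupportPolicy | None = None
) -> dict[Bipartition, bool]:
    """Apply the two-metric parametric + non-parametric consensus rule.

    A branch is significant iff >= 2 metrics meet their thresholds, with at
    least one passing metric parametric and one non-parametric. Metrics
    absent from a branch count as not passing.
    """
    policy = policy or SupportPolicy()
    known = set(policy.thresholds) | policy.parametric | policy.nonparametric
    out: dict[Bipartition, bool] = {}
    for bip in tree.internal_bipartitions():
        metrics = tree.supports.get(bip, {})
        unknown = set(metrics) - known
        if unknown:
            raise ValueError(f"unknown support metric(s): {sorted(unknown)}")
        passing = {
            name
            for name, value in metrics.items()
            if name in policy.thresholds and value >= policy.thresholds[name]
        }
        out[bip] = (
            len(passing) >= 2
            and bool(passing & policy.parametric)
            and bool(passing & policy.nonparametric)
        )
    return out


@dataclass
class MergeResult:
    tree: SupportedTree
    conflicts: list[tuple[int, Bipartition]]  # (source tree index, unmatched split)


def merge_supports(trees: list[SupportedTree]) -> MergeResult:
    """Combine supports from several trees onto the first tree's topology.

    Branches are matched by leaf bipartition; a metric value attaches only
    where the source tree contains the same split. Splits of a source tree
    absent from the reference topology are reported as conflicts.
    """
    if not trees:
        raise ValueError("need at least one tree")
    ref_taxa = trees[0].taxa
    for i, t in enumerate(trees[1:], start=1):
        if t.taxa != ref_taxa:
            raise ValueError(f"tree {i} has a different leaf set")
    reference = trees[0]
    ref_splits = set(reference.internal_bipartitions())
    merged: dict[Bipartition, dict[str, float]] = {
        bip: dict(reference.supports.get(bip, {})) for bip in ref_splits
    }
    conflicts: list[tuple[int, Bipartition]] = []
    for i, t in enumerate(trees[1:], start=1):
        for bip in t.internal_bipartitions():
            if bip in ref_splits:
                merged[bip] = merged[bip] | t.supports.get(bip, {})
            elif t.supports.get(bip):
                conflicts.append((i, bip))
    merged = {bip: m for bip, m in merged.items() if m}
    return MergeResult(
        tree=SupportedTree(tree=reference.tree, supports=merged), conflicts=conflicts
    )
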