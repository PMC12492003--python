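"""Node dating: relative depths from a phylogram plus one calibration.

A rooted tree with branch lengths in substitutions/site is converted to
relative node depths by mean-path smoothing (each node's depth is the mean
root-ward path length over the leaves below it, reconciled so a parent is
never shallower than a child), then linearly scaled so that one calibrated
node takes a known age in Mya.  This is a deliberately simple relative-rate
approximation: it assumes rate variation averages out along lineages and
provides no confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


@dataclass(frozen=True)
class Calibration:
    """Age (Mya) of the most recent common ancestor of two named taxa."""

    taxon_a: str
    taxon_b: str
    age: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration age must be positive")
        if self.taxon_a == self.taxon_b:
            raise ValueError("calibration needs two distinct taxa")


@dataclass
class TimeTree:
    """A rooted topology with node ages in Mya (leaves at 0)."""

    tree: dendropy.Tree
    ages: dict[int, float]          # id(node) -> age
    calibration: Calibration

    def age_of(self, *leaf_labels: str) -> float:
        """Age of the MRCA of the given leaves."""
        node = self.tree.mrca(taxon_labels=list(leaf_labels))
        return self.ages[id(node)]

    @property
    def root_age(self) -> float:
        return self.ages[id(self.tree.seed_node)]


def ultrametricize(tree: dendropy.Tree) -> dict[int, float]:
    """Relative depth of every node by mean-path smoothing.

    depth(leaf) = 0; depth(internal) = mean over descendant leaves of the
    path length down to them, raised to max(child depth + 0) if the mean
    would invert the parent/child order.  Already-ultrametric trees are a
    fixed point.
    """
    depths: dict[int, float] = {}
    # (sum of node-to-leaf path lengths, leaf count) per node
    agg: dict[int, tuple[float, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depths[id(node)] = 0.0
            agg[id(node)] = (0.0, 1)
        else:
            total = 0.0
            count = 0
            max_child = 0.0
            for child in node.child_nodes():
                t = child.edge.length
                if t is None:
                    t = 0.0
                if t < 0:
                    raise ValueError("negative branch length")
                s, c = agg[id(child)]
                total += s + c * t
                count += c
                max_child = max(max_child, depths[id(child)])
            agg[id(node)] = (total, count)
            depths[id(node)] = max(total / count, max_child)
    return depths


def date_tree(tree: dendropy.Tree, cal: Calibration) -> TimeTree:
    """Scale relative depths so the calibrated node's age is exact.

    Every node age is (relative depth) x (cal.age / depth of the
    calibration node); the calibrated node therefore equals ``cal.age``
    exactly and all other ages inherit the same linear scaling.
    """
    depths = ultrametricize(tree)
    node = tree.mrca(taxon_labels=[cal.taxon_a, cal.taxon_b])
    if node is None:
        raise ValueError("calibration node not resolvable in tree")
    if node.is_leaf():
        raise ValueError("calibration node is a leaf")
    d = depths[id(node)]
    if d <= 0:
        raise ValueError("calibration node has zero relative depth")
    scale = cal.age / d
    ages = {k: v * scale for k, v in depths.items()}
    return TimeTree(tree, ages, cal)
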