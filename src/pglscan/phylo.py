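"""Rooted phylogenies and the tip-pair geometry consumed by the GLS covariance models.

A tree enters as a Newick string (branch lengths required on every non-root
edge) and is reduced to two symmetric matrices over an explicit tip order:

* ``mrca_depth`` — root-to-MRCA path length per tip pair, with tip depths on
  the diagonal.  This is the Brownian-motion covariance up to a rate factor.
* ``patristic`` — tip-to-tip path length, linked to the former through
  ``D[i, j] = C[i, i] + C[j, j] - 2 C[i, j]``.

A root edge length, when present, is ignored: it adds the same constant to
every covariance entry and is confounded with the regression intercept.
Trees need not be ultrametric and polytomies are accepted as-is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeGeometry",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "geometry",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths and uniquely labeled tips.

    Wraps a :class:`dendropy.Tree`; use :func:`parse_newick` to construct
    one from text.
    """

    _tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tip_labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        _validate(self._tree, self.tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def to_newick(self) -> str:
        """Serialize back to a Newick string (branch lengths preserved)."""
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def geometry(self, tip_order: list[str] | None = None) -> "TreeGeometry":
        return geometry(self, tip_order)


@dataclass(frozen=True)
class TreeGeometry:
    """Shared-path and patristic distance matrices over a fixed tip order."""

    tip_order: tuple[str, ...]
    mrca_depth: np.ndarray
    patristic: np.ndarray

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def subset(self, keep: list[str]) -> "TreeGeometry":
        """Geometry restricted to a subset of tips.

        Removing tips changes neither MRCA depths nor patristic distances
        among the remaining tips, so the restriction equals the geometry of
        the pruned tree.
        """
        index = {lab: i for i, lab in enumerate(self.tip_order)}
        missing = [lab for lab in keep if lab not in index]
        if missing:
            raise KeyError(f"labels not in geometry: {missing}")
        idx = np.array([index[lab] for lab in keep])
        return TreeGeometry(
            tip_order=tuple(keep),
            mrca_depth=self.mrca_depth[np.ix_(idx, idx)],
            patristic=self.patristic[np.ix_(idx, idx)],
        )

    def drop(self, label: str) -> "TreeGeometry":
        return self.subset([lab for lab in self.tip_order if lab != label])

    def to_tsv(self, which: str = "mrca_depth") -> str:
        """Export one matrix as TSV with a header row of tip labels."""
        mat = getattr(self, which)
        lines = ["\t".join(self.tip_order)]
        for row in mat:
            lines.append("\t".join(format(v, ".10g") for v in row))
        return "\n".join(lines) + "\n"


def _validate(tree: dendropy.Tree, tip_labels: list[str]) -> None:
    if len(tip_labels) < 2:
        raise TreeValidationError("tree must have at least 2 tips")
    if any(lab is None for lab in tip_labels):
        raise TreeValidationError("every tip must be labeled")
    dupes = {lab for lab in tip_labels if tip_labels.count(lab) > 1}
    if dupes:
        raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length
        if length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeValidationError(f"missing branch length on edge above {name!r}")
        if length < 0:
            name = node.taxon.label if node.taxon else "<internal>"
            raise TreeValidationError(
                f"negative branch length {length} on edge above {name!r}"
            )


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Raises
    ------
    NewickParseError
        If the string is not well-formed Newick; the message carries the
        parser's position report.
    TreeValidationError
        On negative branch lengths, missing lengths, duplicate or missing
        tip labels, or fewer than 2 tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types with position info
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from None
        raise NewickParseError(f"malformed Newick: {exc}") from None
    if tree.seed_node is None or tree.seed_node.is_leaf():
        raise TreeValidationError("tree must have at least 2 tips")
    return PhyloTree(tree)


def geometry(tree: PhyloTree, tip_order: list[str] | None = None) -> TreeGeometry:
    """Compute MRCA-depth and patristic matrices ordered by ``tip_order``.

    ``tip_order`` must be a permutation of the tree's tip labels; by default
    the tree's own leaf iteration order is used.
    """
    if tip_order is None:
        tip_order = list(tree.tip_labels)
    else:
        missing = sorted(set(tip_order) - set(tree.tip_labels))
        extra = sorted(set(tree.tip_labels) - set(tip_order))
        if missing or len(tip_order) != len(tree.tip_labels) or extra:
            raise KeyError(
                f"tip_order must be a permutation of tip labels; "
                f"unknown={missing}, absent={extra}"
            )
    index = {lab: i for i, lab in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))

    root = tree._tree.seed_node
    depth: dict[int, float] = {id(root): 0.0}
    for node in tree._tree.preorder_node_iter():
        if node is root:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # Postorder sweep: tips under each child subtree of a node have their
    # MRCA at that node, so fill pair blocks with the node's depth.
    tips_below: dict[int, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
            continue
        child_sets = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.array(child_sets[a])
                ib = np.array(child_sets[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tips_below[id(node)] = [i for s in child_sets for i in s]

    diag = np.diag(C)
    D = diag[:, None] + diag[None, :] - 2.0 * C
    return TreeGeometry(tip_order=tuple(tip_order), mrca_depth=C, patristic=D)
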