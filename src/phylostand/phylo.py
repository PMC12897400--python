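"""Phylogeny handling: Newick parsing, validation and patristic distances.

A :class:`Phylogeny` is a thin, validated wrapper around a rooted dendropy
tree with uniquely labelled tips and a finite, non-negative branch length on
every edge.  Polytomies are accepted as-is and trees are *not* assumed or
forced to be ultrametric: branch lengths are used exactly as given, so the
patristic distance between two tips is simply the sum of branch lengths
along the unique tip-to-tip path.

Missing branch lengths are a hard error rather than being defaulted to 1;
a silently invented length would propagate straight into every downstream
distance-based statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError

__all__ = [
    "Phylogeny",
    "PatristicDistanceMatrix",
    "parse_newick",
    "read_newick",
    "patristic_distances",
]


@dataclass
class Phylogeny:
    """A rooted phylogeny with unique tip labels and branch lengths.

    Parameters
    ----------
    tree
        The underlying ``dendropy.Tree``.  Construct instances through
        :func:`parse_newick` (or :func:`phylostand.synthetic.simulate_tree`)
        so the invariants below are guaranteed:

        * tip labels unique and non-empty,
        * every edge has a finite branch length >= 0,
        * at least two tips.
    """

    tree: dendropy.Tree
    tips: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tips = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        _validate_tree(self.tree, self.tips)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def to_newick(self) -> str:
        """Serialize as a Newick string with decimal branch lengths."""
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def pruned_to(self, labels) -> "Phylogeny":
        """Return a copy of the tree restricted to ``labels`` (>= 2 required).

        Degree-two internal nodes created by pruning are suppressed and their
        branch lengths merged, so patristic distances among retained tips are
        unchanged.
        """
        wanted = set(labels)
        missing = sorted(wanted - set(self.tips))
        if missing:
            raise ValidationError(
                f"cannot prune: labels not in tree: {', '.join(missing)}"
            )
        if len(wanted) < 2:
            raise ValidationError("a pruned phylogeny needs at least 2 tips")
        clone = self.tree.clone(depth=1)
        keep = [t for t in clone.taxon_namespace if t.label in wanted]
        clone.retain_taxa(keep)
        # retain_taxa may leave a unifurcation at the root; merge its edge.
        clone.suppress_unifurcations()
        return Phylogeny(clone)


@dataclass
class PatristicDistanceMatrix:
    """Symmetric matrix of tip-to-tip path-length distances.

    ``d[i, j]`` is the sum of branch lengths on the unique path between
    ``labels[i]`` and ``labels[j]``; the diagonal is exactly zero.
    """

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix has non-finite entries")
        if np.any(self.d < 0):
            raise ValidationError("distance matrix has negative entries")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T, rtol=0, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    def submatrix(self, labels) -> "PatristicDistanceMatrix":
        idx = [self.index[lab] for lab in labels]
        return PatristicDistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])


def _validate_tree(tree: dendropy.Tree, tips: list[str]) -> None:
    if len(tips) < 2:
        raise ValidationError(f"phylogeny must have >= 2 tips, got {len(tips)}")
    seen: set[str] = set()
    for lab in tips:
        if not lab:
            raise ValidationError("empty tip label")
        if lab in seen:
            raise ValidationError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root has no subtending branch
        bl = edge.length
        if bl is None:
            raise ValidationError(
                "missing branch length on edge above "
                f"{_describe_node(edge.head_node)}; branch lengths are required"
            )
        if not np.isfinite(bl):
            raise ValidationError("non-finite branch length")
        if bl < 0:
            raise ValidationError(
                f"negative branch length {bl} above {_describe_node(edge.head_node)}"
            )


def _describe_node(node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    labs = [lf.taxon.label for lf in node.leaf_iter()]
    return f"internal node spanning {{{', '.join(sorted(labs)[:4])}...}}"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Bracketed comments are ignored (standard dialect).  Raises
    :class:`NewickParseError` for syntax errors and :class:`ValidationError`
    for structural violations (duplicate labels, negative or missing branch
    lengths, fewer than two tips).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a Newick file (first tree only)."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def patristic_distances(tree: Phylogeny) -> PatristicDistanceMatrix:
    """Compute all pairwise tip-to-tip path-length distances.

    Uses a single post-order sweep: each node carries the distances from
    itself down to every tip in its subtree; tip pairs are charged at their
    lowest common ancestor, where the two subtree lists first meet.  O(n^2)
    overall, stored dense — species pools here are a few hundred tips.
    """
    labels = tree.tips
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n), dtype=float)

    # node -> (tip indices, distances from this node), built post-order
    carry: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            carry[node] = ([index[node.taxon.label]], np.zeros(1))
            continue
        merged_idx: list[int] = []
        merged_dist = np.empty(0)
        for child in node.child_nodes():
            cidx, cdist = carry.pop(child)
            cdist = cdist + child.edge.length
            if merged_idx:
                # pairs split between already-merged subtrees and this child
                # have this node as their LCA
                pair = merged_dist[:, None] + cdist[None, :]
                d[np.ix_(merged_idx, cidx)] = pair
                d[np.ix_(cidx, merged_idx)] = pair.T
            merged_idx.extend(cidx)
            merged_dist = np.concatenate([merged_dist, cdist])
        carry[node] = (merged_idx, merged_dist)

    return PatristicDistanceMatrix(labels, d)
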