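"""Rooted time-tree data model and primitive operations.

The package stores branch lengths as the primitive (node ages are always
derived), matching the newick convention and avoiding dual bookkeeping.
Parsing and serialization of newick and NEXUS TREES blocks are delegated to
:mod:`dendropy`; the in-memory representation is a minimal node structure
tailored to the tree surgery the assembly pipeline performs (pruning,
edge-cutting, grafting, age jittering).

Units are tracked as a tag on the tree: ``"absolute-Ma"`` for
fossil-calibrated trees, ``"relative"`` for clock trees normalized to a unit
root depth, and ``"substitutions"`` for raw engine output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "TreeSet",
    "TreeParseError",
    "TreeValidationError",
    "parse_tree",
    "parse_trees",
    "node_ages",
    "mrca",
    "prune_to",
    "bind_at_edge",
    "is_ultrametric",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised when tree text cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a structurally valid tree violates a contract."""


class Node:
    """A node in a rooted tree; ``length`` is the edge to the parent."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def copy(self) -> "Node":
        clone = Node(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r}, length={self.length:g})"


class TimeTree:
    """Rooted tree with branch lengths and a length-unit tag.

    Invariants: exactly one root, branch lengths >= 0, unique tip labels.
    Polytomies are accepted on ingest (supertrees from other studies) but
    the assembly operations never produce them.
    """

    def __init__(self, root: Node, units: str = "absolute-Ma"):
        self.root = root
        self.units = units
        self.validate()

    # -- basic structure -------------------------------------------------

    def validate(self) -> None:
        labels = [n.label for n in self.root.preorder() if n.is_leaf]
        if any(lab is None for lab in labels):
            raise TreeValidationError("every tip must carry a label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.root.preorder():
            if node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} at {node.label or 'internal node'}"
                )

    def tips(self) -> list[Node]:
        return self.root.leaves()

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find_tip(self, label: str) -> Node:
        for node in self.root.preorder():
            if node.is_leaf and node.label == label:
                return node
        raise KeyError(f"tip label not in tree: {label!r}")

    def copy(self) -> "TimeTree":
        return TimeTree(self.root.copy(), units=self.units)

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.preorder() if not n.is_leaf
        )

    # -- depths and ages -------------------------------------------------

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (the root itself is at depth 0)."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.root.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + node.length
        return out

    def max_tip_depth(self) -> float:
        depths = self.depths()
        return max(depths[t] for t in self.tips())

    def write(self, path=None, schema: str = "newick") -> str | None:
        text = _to_dendropy(self).as_string(
            schema=schema, suppress_rooting=True, unquoted_underscores=True
        )
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree({self.n_tips} tips, units={self.units!r})"


@dataclass
class TreeSet:
    """Ordered collection of posterior tree samples with provenance.

    All samples must share the same tip-label set; ordering is significant
    because downstream assembly pairs backbone and patch samples by index.
    """

    trees: list[TimeTree]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [("run0", i) for i in range(len(self.trees))]
        if len(self.provenance) != len(self.trees):
            raise TreeValidationError("provenance length must match tree count")
        if self.trees:
            universe = frozenset(self.trees[0].tip_labels)
            for i, t in enumerate(self.trees):
                if frozenset(t.tip_labels) != universe:
                    raise TreeValidationError(
                        f"sample {i} has a different tip-label set"
                    )

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self.trees[0].tip_labels) if self.trees else frozenset()

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i) -> TimeTree:
        return self.trees[i]

    def __iter__(self) -> Iterator[TimeTree]:
        return iter(self.trees)

    def write(self, path, schema: str = "newick") -> None:
        with open(path, "w") as fh:
            for tree in self.trees:
                fh.write(tree.write(schema="newick"))


# ---------------------------------------------------------------------------
# dendropy bridge (I/O only)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: "dendropy.Tree", units: str) -> TimeTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return TimeTree(convert(dtree.seed_node), units=units)


def _to_dendropy(tree: TimeTree) -> "dendropy.Tree":
    ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)

    def convert(node: Node, dnode) -> None:
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = ns.new_taxon(label=node.label)
        for child in node.children:
            convert(child, dnode.new_child())

    convert(tree.root, dtree.seed_node)
    dtree.seed_node.edge.length = None if tree.root.length == 0 else tree.root.length
    return dtree


def _sniff_schema(text: str) -> str:
    return "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"


def parse_tree(text: str, units: str = "absolute-Ma") -> TimeTree:
    """Parse a single newick string or NEXUS TREES block into a TimeTree.

    NEXUS translate tables are resolved to full tip names. Malformed input
    raises :class:`TreeParseError`; duplicate tip labels raise
    :class:`TreeValidationError`.
    """
    schema = _sniff_schema(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except TreeValidationError:
        raise
    except Exception as exc:  # dendropy raises schema-specific errors
        if "uplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
    return _from_dendropy(dtree, units)


def parse_trees(
    source: str, units: str = "absolute-Ma", run_id: str = "run0"
) -> TreeSet:
    """Read a multi-tree newick or nexus string/file into a TreeSet (file order)."""
    text = source
    if "\n" not in source and ("(" not in source):
        with open(source) as fh:
            text = fh.read()
    schema = _sniff_schema(text)
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"could not parse {schema} tree list: {exc}") from exc
    trees = [_from_dendropy(t, units) for t in dtrees]
    return TreeSet(trees, [(run_id, i) for i in range(len(trees))])


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def is_ultrametric(tree: TimeTree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL) -> bool:
    """True iff tip depths agree to within ``rel_tol`` of the maximum depth.

    A zero-depth tree (all branch lengths zero, or a single tip at the root)
    is ultrametric by definition.
    """
    depths = tree.depths()
    tip_depths = [depths[t] for t in tree.tips()]
    dmax = max(tip_depths)
    if dmax == 0:
        return True
    return (dmax - min(tip_depths)) / dmax <= rel_tol


def node_ages(
    tree: TimeTree, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> dict[Node, float]:
    """Map node -> age (time before present), requiring an ultrametric tree.

    Tip ages are exactly zero; an internal node's age is the maximum path
    length from it to any descendant tip, so float drift never makes a tip
    age nonzero.
    """
    if not is_ultrametric(tree, rel_tol):
        depths = tree.depths()
        tip_depths = [depths[t] for t in tree.tips()]
        raise TreeValidationError(
            "tree is not ultrametric: tip depth spread "
            f"{max(tip_depths) - min(tip_depths):.6g} exceeds rel_tol {rel_tol:g} "
            f"of max depth {max(tip_depths):.6g}"
        )
    ages: dict[Node, float] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            ages[node] = 0.0
        else:
            ages[node] = max(ages[c] + c.length for c in node.children)
    return ages


def mrca(tree: TimeTree, tips: Iterable[str]) -> Node:
    """Most recent common ancestor of the given tip labels."""
    wanted = set(tips)
    if not wanted:
        raise ValueError("mrca requires at least one tip label")
    have = set(tree.tip_labels)
    missing = wanted - have
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    # postorder accumulation of covered label counts
    counts: dict[Node, int] = {}
    target = len(wanted)
    for node in tree.root.postorder():
        if node.is_leaf:
            counts[node] = 1 if node.label in wanted else 0
        else:
            counts[node] = sum(counts[c] for c in node.children)
        if counts[node] == target:
            return node
    raise AssertionError("unreachable: root must cover all tips")


def clade_tips(node: Node) -> frozenset[str]:
    """Descendant tip-label set of a node."""
    return frozenset(n.label for n in node.leaves())


def prune_to(tree: TimeTree, keep: Iterable[str]) -> TimeTree:
    """Restrict a tree to the given tip labels.

    Degree-2 nodes produced by pruning are suppressed with their branch
    lengths summed, so every retained tip keeps its original root-to-tip
    depth. The original root is retained even if it becomes unary (its sole
    remaining child keeps its full edge), preserving retained node ages.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep set must be non-empty")
    missing = keep_set - set(tree.tip_labels)
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")

    def rebuild(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep_set:
                return Node(node.label, node.length)
            return None
        kept = [c2 for c2 in (rebuild(c) for c in node.children) if c2 is not None]
        if not kept:
            return None
        if len(kept) == 1 and node.parent is not None:
            # suppress degree-2 node, summing the two edge lengths
            kept[0].length += node.length
            return kept[0]
        new = Node(node.label, node.length)
        for c2 in kept:
            new.add_child(c2)
        return new

    new_root = rebuild(tree.root)
    assert new_root is not None
    return TimeTree(new_root, units=tree.units)


def bind_at_edge(
    host: TimeTree, graft: TimeTree, tip_label: str, attach_depth: float
) -> TimeTree:
    """Cut the pendant edge of ``tip_label`` at age ``attach_depth`` and fuse
    the graft's root there, removing the host tip.

    ``attach_depth`` is an age (time before present) and must lie within the
    pendant edge span of ``tip_label``; the graft's root age must not exceed
    it (a shallower graft root gets a connecting stem edge). Both inputs are
    left untouched; a new tree is returned.
    """
    host = host.copy()
    target = host.find_tip(tip_label)
    parent = target.parent
    if parent is None:
        raise TreeValidationError("cannot bind onto a single-tip tree root")
    ages = node_ages(host) if is_ultrametric(host) else None
    if ages is not None:
        parent_age = ages[parent]
    else:
        # fall back to path lengths for non-ultrametric hosts
        depths = host.depths()
        parent_age = host.max_tip_depth() - depths[parent]
    if not (0.0 <= attach_depth <= parent_age + 1e-12):
        raise TreeValidationError(
            f"attach depth {attach_depth:g} outside the pendant edge span "
            f"[0, {parent_age:g}] of tip {tip_label!r} (negative-branch guard)"
        )
    graft_root = graft.root.copy()
    graft_age = _subtree_age(graft_root)
    if graft_age > attach_depth + 1e-9 * max(attach_depth, 1.0):
        raise TreeValidationError(
            f"graft root age {graft_age:g} exceeds attach depth {attach_depth:g}"
        )
    graft_root.length = parent_age - graft_age
    idx = parent.children.index(target)
    parent.children[idx] = graft_root
    graft_root.parent = parent
    target.parent = None
    return TimeTree(host.root, units=host.units)


def _subtree_age(node: Node) -> float:
    """Max path length from node to a descendant tip."""
    best = 0.0
    stack = [(node, 0.0)]
    while stack:
        n, d = stack.pop()
        if n.is_leaf:
            best = max(best, d)
        for c in n.children:
            stack.append((c, d + c.length))
    return best


def renormalize_tip_depths(tree: TimeTree) -> TimeTree:
    """Adjust pendant edges so every tip sits exactly at the mean tip depth.

    Used after grafting to absorb float drift; never alters topology, and
    the adjustment is bounded by the tree's ultrametricity tolerance.
    """
    tree = tree.copy()
    depths = tree.depths()
    tips = tree.tips()
    mean_depth = sum(depths[t] for t in tips) / len(tips)
    for tip in tips:
        delta = mean_depth - depths[tip]
        if tip.length + delta < 0:
            raise TreeValidationError(
                "tip-depth renormalization would create a negative pendant edge"
            )
        tip.length += delta
    return TimeTree(tree.root, units=tree.units)


def scale_branch_lengths(tree: TimeTree, factor: float, units: str | None = None) -> TimeTree:
    """Multiply every branch length by ``factor`` (returns a new tree)."""
    if factor < 0:
        raise ValueError("scale factor must be non-negative")
    out = tree.copy()
    for node in out.root.preorder():
        node.length *= factor
    if units is not None:
        out.units = units
    return out
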