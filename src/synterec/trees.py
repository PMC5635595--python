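"""Lightweight rooted-tree containers shared by the whole package.

Two tree flavours are used throughout: a dated species tree (an ultrametric
chronogram whose internal nodes carry ages, time before present) and a gene
tree whose leaves are genes mapped to species.  Both use a single canonical
node naming scheme: ``s<k>`` / ``g<k>`` where ``k`` is the 1-based postorder
index of the node (children visited in stored order, left before right).
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Leaf name (taxon or gene identifier); None for internal nodes
        unless the input supplied one.
    label : str
        Canonical postorder label (``s<k>`` or ``g<k>``), assigned by the
        owning tree.
    age : float
        Time before present (species trees only; leaves are 0).
    length : float
        Branch length to the parent (as parsed; species trees derive ages
        from these).
    """

    __slots__ = ("children", "parent", "name", "label", "age", "length", "index")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.name = name
        self.label: str = ""
        self.age: float = 0.0
        self.length: float = length
        self.index: int = -1  # 0-based postorder index

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for ch in reversed(node.children):
                stack.append(ch)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]


class PolytomyError(ValueError):
    """Raised when a tree that must be binary has a multifurcating node."""


class _BaseTree:
    label_prefix = "n"

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()
        self._check_binary()

    def _index(self) -> None:
        self.nodes: list[TreeNode] = list(self.root.postorder())
        for i, node in enumerate(self.nodes):
            node.index = i
            node.label = f"{self.label_prefix}{i + 1}"
        self.by_label = {n.label: n for n in self.nodes}
        self.by_name = {n.name: n for n in self.nodes if n.name is not None}

    def _check_binary(self) -> None:
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                who = node.name or node.label
                raise PolytomyError(
                    f"node {who!r} has {len(node.children)} children; "
                    "trees must be strictly binary"
                )

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    def node(self, label: str) -> TreeNode:
        return self.by_label[label]

    def depth(self, node: TreeNode) -> int:
        """Topological depth: number of edges from the root."""
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def lca(self, nodes: list[TreeNode]) -> TreeNode:
        if not nodes:
            raise ValueError("lca of an empty node set is undefined")
        current = nodes[0]
        for other in nodes[1:]:
            current = self._lca2(current, other)
        return current

    def _lca2(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        return frozenset(l.name for l in node.leaves())


class DatedSpeciesTree(_BaseTree):
    """Rooted binary ultrametric species tree with node ages.

    Ages are derived from branch lengths (leaf age 0, parent age = child
    age + child branch length) and checked for ultrametricity.
    """

    label_prefix = "s"

    def __init__(self, root: TreeNode, rel_tol: float = 1e-6):
        super().__init__(root)
        self._assign_ages(rel_tol)

    def _assign_ages(self, rel_tol: float) -> None:
        for node in self.nodes:  # postorder
            if node.is_leaf:
                node.age = 0.0
            else:
                ages = [c.age + c.length for c in node.children]
                scale = max(max(ages), 1.0)
                if max(ages) - min(ages) > rel_tol * scale:
                    raise ValueError(
                        f"tree is not ultrametric at node {node.label}: "
                        f"child path ages {ages}"
                    )
                node.age = sum(ages) / len(ages)
        for node in self.nodes:
            if node.parent is not None and node.parent.age <= node.age:
                raise ValueError(
                    f"parent age not greater than child age at {node.label}"
                )

    @property
    def taxa(self) -> list[str]:
        return [l.name for l in self.leaves]


class GeneTree(_BaseTree):
    """Rooted binary gene tree whose leaves are genes mapped to species.

    The species of each leaf comes from ``species_map`` when given, or is
    parsed from the leaf name by splitting off a trailing ``_<suffix>``
    (the convention used by the synthetic-data generator, e.g. ``Aspni_3``
    is a gene from species ``Aspni``).
    """

    label_prefix = "g"

    def __init__(
        self,
        root: TreeNode,
        species_map: Optional[dict[str, str]] = None,
        species_tree: Optional[DatedSpeciesTree] = None,
    ):
        super().__init__(root)
        if species_map is None:
            species_map = {
                l.name: default_species_of(l.name) for l in self.leaves
            }
        self.species_map = dict(species_map)
        missing = [l.name for l in self.leaves if l.name not in self.species_map]
        if missing:
            raise ValueError(f"gene leaves without a species mapping: {missing}")
        if species_tree is not None:
            self.validate_against(species_tree)

    def validate_against(self, species_tree: DatedSpeciesTree) -> None:
        taxa = set(species_tree.taxa)
        offenders = sorted(
            {self.species_map[l.name] for l in self.leaves} - taxa
        )
        if offenders:
            raise ValueError(
                "gene-tree leaf species absent from the species tree: "
                f"{offenders}"
            )

    def species_of(self, leaf: TreeNode) -> str:
        return self.species_map[leaf.name]


def default_species_of(gene_id: str) -> str:
    """Species name implied by a gene id of the form ``<species>_<n>``."""
    if "_" in gene_id:
        return gene_id.rsplit("_", 1)[0]
    return gene_id


def build_tree(
    newick_like: "object",
    leaf_name: Callable[["object"], str],
    children: Callable[["object"], list],
    length: Callable[["object"], float],
) -> TreeNode:
    """Generic converter from any nested tree object to :class:`TreeNode`."""

    def convert(obj) -> TreeNode:
        kids = children(obj)
        node = TreeNode(None if kids else leaf_name(obj), length(obj))
        for k in kids:
            node.add_child(convert(k))
        return node

    return convert(newick_like)
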