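"""Species trees, gene trees, and node-feature sets.

Trees are parsed from newick (via dendropy) into a lightweight rooted node
structure with deterministic post-order ids, so that every downstream module
can address species-tree nodes stably across runs.  Internal-node labels of
gene trees are read as bootstrap-style support values on the 0-100 scale;
internal-node labels of species trees are kept as plain names.

The gene-tip naming convention used throughout the package is
``<species><delimiter><gene-id>``: the species identifier is everything
before the *first* occurrence of the delimiter (default ``"|"``), so gene
identifiers may themselves contain the delimiter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

DEFAULT_DELIMITER = "|"


class TreeError(ValueError):
    """Malformed newick, bad labels, or failed tree-level validation."""


class LabelError(TreeError):
    """A tip label does not follow the species|gene convention."""


def species_of_gene(label: str, delimiter: str = DEFAULT_DELIMITER) -> str:
    """Species identifier encoded in a gene tip label.

    Everything before the first ``delimiter`` is the species id; the
    remainder (which may itself contain the delimiter) is the gene id.
    """
    idx = label.find(delimiter)
    if idx < 0:
        raise LabelError(
            f"gene tip label {label!r} does not contain delimiter {delimiter!r}"
        )
    if idx == 0:
        raise LabelError(f"gene tip label {label!r} has an empty species prefix")
    return label[:idx]


class Node:
    """One node of a rooted tree.

    ``support`` is meaningful on gene trees only: it is the support of the
    edge between this node and its parent (the bipartition that edge
    induces), on a 0-100 scale, or None when the input carried no label.
    """

    __slots__ = ("label", "length", "support", "children", "parent", "id")

    def __init__(self, label=None, length=None, support=None):
        self.label: str | None = label
        self.length: float | None = length
        self.support: float | None = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.id: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self):
        stack, out = [(self, False)], []
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node id={self.id} {kind} label={self.label!r}>"


class BaseTree:
    """Rooted tree with deterministic post-order node ids."""

    def __init__(self, root: Node):
        self.root = root
        self.nodes: list[Node] = []
        self._tip_index: dict[str, Node] = {}
        self._clade_tips: dict[int, frozenset] = {}
        self._depth: dict[int, int] = {}
        self.reindex()

    # -- indexing -----------------------------------------------------------

    def reindex(self) -> None:
        """Assign post-order ids and rebuild caches (call after rerooting)."""
        self.nodes = self.root.postorder()
        for i, node in enumerate(self.nodes):
            node.id = i
        self._tip_index = {}
        for node in self.nodes:
            if node.is_tip and node.label is not None:
                self._tip_index.setdefault(node.label, node)
        self._clade_tips = {}
        for node in self.nodes:  # post-order: children first
            if node.is_tip:
                self._clade_tips[node.id] = frozenset([node.label])
            else:
                acc = frozenset().union(
                    *(self._clade_tips[c.id] for c in node.children)
                )
                self._clade_tips[node.id] = acc
        self._depth = {}
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            self._depth[node.id] = d
            for c in node.children:
                stack.append((c, d + 1))

    # -- basic queries ------------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.nodes if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_tip]

    def node(self, node_id: int) -> Node:
        return self.nodes[node_id]

    def tip(self, label: str) -> Node:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def clade_tips(self, node: Node | int) -> frozenset:
        node_id = node if isinstance(node, int) else node.id
        return self._clade_tips[node_id]

    def depth(self, node: Node) -> int:
        return self._depth[node.id]

    def mrca_nodes(self, a: Node, b: Node) -> Node:
        """MRCA of two nodes by walking up from the deeper one."""
        while self._depth[a.id] > self._depth[b.id]:
            a = a.parent
        while self._depth[b.id] > self._depth[a.id]:
            b = b.parent
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def mrca(self, tip_labels) -> Node:
        """MRCA of a nonempty set of tip labels."""
        labels = list(tip_labels)
        if not labels:
            raise TreeError("mrca of an empty tip set is undefined")
        node = self.tip(labels[0])
        for label in labels[1:]:
            node = self.mrca_nodes(node, self.tip(label))
        return node

    def is_ancestor_or_equal(self, anc: Node, node: Node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    # -- output -------------------------------------------------------------

    def write_newick(self, support_as_label: bool = False) -> str:
        """Newick string; internal labels are supports when asked for."""

        def fmt_len(x):
            return "" if x is None else f":{x:.12g}"

        def fmt_support(s):
            if s is None:
                return ""
            return f"{int(s)}" if float(s).is_integer() else f"{s:.6g}"

        buf = io.StringIO()

        def walk(node):
            if node.is_tip:
                buf.write(node.label or "")
            else:
                buf.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        buf.write(",")
                    walk(c)
                buf.write(")")
                if support_as_label:
                    buf.write(fmt_support(node.support))
                elif node.label:
                    buf.write(node.label)
            buf.write(fmt_len(node.length))

        walk(self.root)
        buf.write(";")
        return buf.getvalue()


class SpeciesTree(BaseTree):
    """Rooted reference phylogeny; the coordinate system for all features.

    Tip labels are species identifiers and must be unique.  Branch lengths,
    when present, are in time units; this module does not interpret them.
    """

    def __init__(self, root: Node):
        super().__init__(root)
        labels = self.tip_labels
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate species tips: {sorted(dupes)}")
        self._label_index = {
            n.label: n for n in self.nodes if n.label and not n.is_tip
        }

    def node_by_label(self, label: str) -> Node | None:
        """Internal node by its name label, or a tip by species id."""
        if label in self._label_index:
            return self._label_index[label]
        return self._tip_index.get(label)

    def has_polytomies(self) -> bool:
        return any(len(n.children) > 2 for n in self.internal_nodes)


class GeneTree(BaseTree):
    """Gene family tree whose tips encode species identity.

    Internal-node newick labels are bootstrap-style supports in [0, 100].
    """

    def __init__(self, root: Node, delimiter: str = DEFAULT_DELIMITER,
                 name: str | None = None):
        super().__init__(root)
        self.delimiter = delimiter
        self.name = name

    def species_of(self, node: Node) -> str:
        if not node.is_tip:
            raise TreeError("species_of is defined for tips only")
        return species_of_gene(node.label, self.delimiter)

    def species_set(self, node: Node | int | None = None) -> frozenset:
        """Species represented in the clade below ``node`` (default: all)."""
        if node is None:
            node = self.root
        return frozenset(
            species_of_gene(t, self.delimiter) for t in self.clade_tips(node)
        )

    def validate_against(self, stree: SpeciesTree) -> None:
        known = set(stree.tip_labels)
        for t in self.tips:
            sp = self.species_of(t)
            if sp not in known:
                raise TreeError(
                    f"gene tip {t.label!r} resolves to species {sp!r}, "
                    "absent from the species tree"
                )


# -- parsing ----------------------------------------------------------------


def _convert_dendropy(dnode: "dendropy.Node", kind: str) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon else dnode.label
        return Node(label=label, length=dnode.edge.length)
    node = Node(length=dnode.edge.length)
    raw = dnode.label
    if kind == "gene":
        if raw is not None and raw != "":
            try:
                support = float(raw)
            except ValueError:
                raise TreeError(
                    f"internal label {raw!r} is not a numeric support"
                ) from None
            if not 0.0 <= support <= 100.0:
                raise TreeError(f"support {support} outside [0, 100]")
            node.support = support
    else:
        node.label = raw
    for child in dnode.child_nodes():
        node.add_child(_convert_dendropy(child, kind))
    return node


def parse_newick(text: str, kind: str = "species",
                 delimiter: str = DEFAULT_DELIMITER,
                 name: str | None = None):
    """Parse one newick string into a :class:`SpeciesTree` or :class:`GeneTree`.

    Parameters
    ----------
    text:
        A single newick tree description.
    kind:
        ``"species"`` (internal labels are node names) or ``"gene"``
        (internal labels are supports on the 0-100 scale).
    delimiter:
        Species/gene separator in gene tip labels (gene trees only).
    """
    if kind not in ("species", "gene"):
        raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        offset = getattr(exc, "column", None)
        where = f" near character {offset}" if offset is not None else ""
        raise TreeError(f"malformed newick{where}: {exc}") from exc
    root = _convert_dendropy(dtree.seed_node, kind)
    if kind == "species":
        return SpeciesTree(root)
    return GeneTree(root, delimiter=delimiter, name=name)


# -- feature node sets ------------------------------------------------------


@dataclass(frozen=True)
class FeatureNodeSet:
    """A named set of species-tree node ids (rate shifts, transitions, GDs)."""

    name: str
    nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", frozenset(self.nodes))

    def __len__(self):
        return len(self.nodes)

    def validate_against(self, tree: SpeciesTree) -> None:
        n = len(tree.nodes)
        bad = [i for i in self.nodes if not (0 <= i < n)]
        if bad:
            raise TreeError(f"feature set {self.name!r}: unknown node ids {bad}")


def read_feature_nodes(path, tree: SpeciesTree, name: str | None = None
                       ) -> FeatureNodeSet:
    """Read a feature node set from a one-column TSV.

    Each nonempty row is either an internal-node label (or species id) or a
    comma-separated species tip set, resolved to its MRCA.  Blank lines and
    lines starting with ``#`` are skipped.
    """
    node_ids = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            row = line.strip()
            if not row or row.startswith("#"):
                continue
            row = row.split("\t")[0]
            if "," in row:
                tips = [t.strip() for t in row.split(",") if t.strip()]
                try:
                    node = tree.mrca(tips)
                except TreeError as exc:
                    raise TreeError(f"{path}, row {lineno}: {exc}") from exc
            else:
                node = tree.node_by_label(row)
                if node is None:
                    raise TreeError(
                        f"{path}, row {lineno}: no node labelled {row!r}"
                    )
            node_ids.add(node.id)
    fset = FeatureNodeSet(name or str(path), frozenset(node_ids))
    fset.validate_against(tree)
    return fset


def write_feature_nodes(path, fset: FeatureNodeSet, tree: SpeciesTree) -> None:
    """Write a feature set as tip-set rows (MRCA-resolvable, portable)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for node_id in sorted(fset.nodes):
            tips = sorted(tree.clade_tips(node_id))
            fh.write(",".join(tips) + "\n")
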