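"""LCA reconciliation of gene trees against a species tree.

Each gene-tree node is mapped to the most recent common ancestor (in the
species tree) of the species represented in its clade.  A gene node is a
duplication when its image coincides with the image of at least one of its
children; the event is retained when both child branches of the duplication
node carry bootstrap-style support at or above a threshold (the field's
standard "both subclades credible" filter, default 50).

Retained duplications are classified by how completely both duplicate
copies survived across the two descendant lineages (A and B) of the mapped
species node:

* ``ABAB`` - each subclade of the duplication contains species from both A
  and B: the retention pattern expected after a genuine ancestral
  duplication such as a WGD;
* ``partial`` - at least one subclade lacks one lineage (loss or sampling);
* ``tip`` - the duplication maps to a terminal species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import GeneTree, Node, SpeciesTree, TreeError

logger = logging.getLogger(__name__)

TIP_SUPPORT = 100.0


class UnrootableError(TreeError):
    """No outgroup tip present; the gene tree cannot be outgroup-rooted."""


@dataclass(frozen=True)
class DuplicationEvent:
    """One gene-tree duplication node mapped onto the species tree."""

    gene_tree_id: str
    gene_node_id: int
    species_node_id: int
    support: float
    dup_type: str  # "ABAB" | "partial" | "tip"
    subclade_tips: tuple = ()  # gene tip labels of the two subclades


# -- rooting ----------------------------------------------------------------


def _unrooted_edges(gtree: GeneTree):
    """Undirected edge list ``(u, v, length, support, edge_key)``.

    ``edge_key`` is the post-order id of the original child node, used for
    deterministic tie-breaking.  A degree-2 root is suppressed (its two
    incident edges are one unrooted edge).
    """
    root = gtree.root
    edges = []
    merge = len(root.children) == 2
    if merge:
        c1, c2 = root.children
        length = (c1.length or 0.0) + (c2.length or 0.0)
        support = c1.support if c1.support is not None else c2.support
        edges.append((c1, c2, length, support, min(c1.id, c2.id)))
    for node in gtree.nodes:
        if node.parent is None:
            continue
        if merge and node.parent is root:
            continue
        edges.append((node.parent, node, node.length, node.support, node.id))
    return edges


def root_by_outgroup(gtree: GeneTree, outgroup_species) -> GeneTree:
    """Root a gene tree on the branch separating the outgroup.

    The root is placed on the unrooted edge whose bipartition best isolates
    the present outgroup tips: the side with maximal Jaccard similarity to
    the outgroup tip set (1.0 exactly when the outgroup is monophyletic),
    smallest side then lowest post-order edge id breaking ties.  Edge
    length is split evenly across the new root.
    """
    outgroup_species = set(outgroup_species)
    og_tips = frozenset(
        t.label for t in gtree.tips if gtree.species_of(t) in outgroup_species
    )
    if not og_tips:
        raise UnrootableError(
            f"gene tree {gtree.name!r}: no tip from outgroup species "
            f"{sorted(outgroup_species)}"
        )
    all_tips = frozenset(gtree.tip_labels)
    if len(all_tips) < 3 or og_tips == all_tips:
        return _rebuild(gtree)  # nothing to re-root on

    edges = _unrooted_edges(gtree)
    best = None
    for u, v, length, support, key in edges:
        side_v = gtree.clade_tips(v)  # v is never the (possibly merged) root
        for side in (side_v, all_tips - side_v):
            if not side or side == all_tips:
                continue
            jac = len(side & og_tips) / len(side | og_tips)
            cand = (-jac, len(side), key)
            if best is None or cand < best[0]:
                best = (cand, (u, v, length, support, side == side_v))
    u, v, length, support, og_is_v_side = best[1]
    return _reroot_on_edge(gtree, u, v, length, support,
                           outgroup_first=og_is_v_side)


def _adjacency(gtree: GeneTree):
    adj = {n.id: [] for n in gtree.nodes}
    for u, v, length, support, _ in _unrooted_edges(gtree):
        adj[u.id].append((v, length, support))
        adj[v.id].append((u, length, support))
    return adj


def _rebuild(gtree: GeneTree) -> GeneTree:
    """Deep copy (keeps the existing rooting)."""
    def copy(node):
        new = Node(label=node.label, length=node.length, support=node.support)
        for c in node.children:
            new.add_child(copy(c))
        return new

    return GeneTree(copy(gtree.root), delimiter=gtree.delimiter,
                    name=gtree.name)


def _reroot_on_edge(gtree: GeneTree, u: Node, v: Node, length, support,
                    outgroup_first: bool) -> GeneTree:
    adj = _adjacency(gtree)
    half = None if length is None else length / 2.0

    def orient(node, came_from, edge_length, edge_support):
        new = Node(label=node.label, length=edge_length)
        if node.is_tip:
            return new
        new.support = edge_support  # supports attach to bipartitions
        for nbr, ln, sup in adj[node.id]:
            if nbr is came_from:
                continue
            new.add_child(orient(nbr, node, ln, sup))
        return new

    root = Node()
    a, b = (v, u) if outgroup_first else (u, v)  # outgroup side written first
    root.add_child(orient(a, b, half, support))
    root.add_child(orient(b, a, half, support))
    new = GeneTree(root, delimiter=gtree.delimiter, name=gtree.name)
    _suppress_unifurcations(new)
    return new


def _suppress_unifurcations(tree: GeneTree) -> None:
    changed = False
    for node in list(tree.nodes):
        while len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0) \
                if (child.length is not None or node.length is not None) else None
            child.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = child
            changed = True
            node = child
    while len(tree.root.children) == 1:
        tree.root = tree.root.children[0]
        tree.root.parent = None
        tree.root.length = None
        changed = True
    if changed:
        tree.reindex()


# -- LCA mapping and duplication detection ----------------------------------


def lca_map(gtree: GeneTree, stree: SpeciesTree) -> dict:
    """Map every gene-tree node id to its species-tree image node.

    Tips map to their species tip; an internal node maps to the MRCA of its
    children's images.  The map is monotone along gene-tree edges.
    """
    gtree.validate_against(stree)
    image: dict[int, Node] = {}
    for node in gtree.nodes:  # post-order: children before parents
        if node.is_tip:
            image[node.id] = stree.tip(gtree.species_of(node))
        else:
            img = image[node.children[0].id]
            for c in node.children[1:]:
                img = stree.mrca_nodes(img, image[c.id])
            image[node.id] = img
    return image


def classify_duplication(subclade_species, species_node: Node,
                         stree: SpeciesTree) -> str:
    """ABAB / partial / tip call for a duplication at ``species_node``.

    ``subclade_species`` is the pair of species sets of the duplication
    node's subclades.  ABAB requires every subclade to contain species from
    at least two descendant lineages of the species node (both A and B on a
    binary tree).
    """
    if species_node.is_tip:
        return "tip"
    lineages = [stree.clade_tips(c) for c in species_node.children]

    def spans(sset):
        return sum(1 for lin in lineages if sset & lin) >= 2

    return "ABAB" if all(spans(s) for s in subclade_species) else "partial"


def _branch_support(node: Node, missing_support: str) -> float:
    if node.is_tip:
        return TIP_SUPPORT
    if node.support is None:
        return TIP_SUPPORT if missing_support == "pass" else -np.inf
    return node.support


def detect_duplications(gtree: GeneTree, stree: SpeciesTree,
                        min_support: float = 50.0,
                        missing_support: str = "fail") -> list[DuplicationEvent]:
    """All retained duplication events of one rooted gene tree.

    A binary gene node is a duplication iff its species image equals the
    image of at least one child; it is retained iff the minimum of its two
    child-branch supports is >= ``min_support`` (tips count as 100;
    internal nodes without a support value fail the filter unless
    ``missing_support="pass"``).  Polytomous gene nodes are treated as soft:
    never duplications themselves, but their descendants are scanned.
    """
    if missing_support not in ("fail", "pass"):
        raise ValueError("missing_support must be 'fail' or 'pass'")
    image = lca_map(gtree, stree)
    events = []
    for node in gtree.nodes:
        if node.is_tip or len(node.children) != 2:
            continue
        c1, c2 = node.children
        img = image[node.id]
        if image[c1.id] is not img and image[c2.id] is not img:
            continue  # speciation node
        support = min(_branch_support(c1, missing_support),
                      _branch_support(c2, missing_support))
        if support < min_support:
            continue
        subclades = (gtree.species_set(c1), gtree.species_set(c2))
        events.append(DuplicationEvent(
            gene_tree_id=gtree.name or "",
            gene_node_id=node.id,
            species_node_id=img.id,
            support=float(support),
            dup_type=classify_duplication(subclades, img, stree),
            subclade_tips=(gtree.clade_tips(c1), gtree.clade_tips(c2)),
        ))
    return events


# -- per-node summary -------------------------------------------------------


def relevant_for_node(gtree: GeneTree, species_node: Node,
                      stree: SpeciesTree) -> bool:
    """Whether a duplication at ``species_node`` is observable in ``gtree``.

    Internal node: the tree must sample at least one species from each
    descendant lineage.  Tip node: the tree must carry at least two gene
    copies of that species.
    """
    if species_node.is_tip:
        count = sum(1 for t in gtree.tips
                    if gtree.species_of(t) == species_node.label)
        return count >= 2
    present = gtree.species_set()
    return all(present & stree.clade_tips(c) for c in species_node.children)


def summarize_by_node(events, gtrees, stree: SpeciesTree,
                      ratio_denominator: str = "relevant") -> pd.DataFrame:
    """Per-species-node duplication statistics.

    Parameters
    ----------
    events:
        Retained :class:`DuplicationEvent` objects pooled over ``gtrees``.
    gtrees:
        The gene-tree collection the events came from (needed for the
        relevant-tree denominators).
    ratio_denominator:
        ``"relevant"`` (default): gd_ratio divides the number of trees with
        at least one retained duplication at the node by the number of
        trees in which such a duplication is observable.  ``"all"``:
        divides by the total number of gene trees.

    Returns a DataFrame indexed by species node id with columns
    ``gd_count``, ``abab_count``, ``abab_fraction``, ``relevant_tree_count``,
    ``trees_with_gd``, ``gd_ratio``.  ``gd_ratio`` and ``abab_fraction`` are
    NaN where their denominators are zero.
    """
    if ratio_denominator not in ("relevant", "all"):
        raise ValueError("ratio_denominator must be 'relevant' or 'all'")
    gtrees = list(gtrees)
    n_nodes = len(stree.nodes)
    gd_count = np.zeros(n_nodes, dtype=int)
    abab_count = np.zeros(n_nodes, dtype=int)
    relevant = np.zeros(n_nodes, dtype=int)
    trees_with_gd = np.zeros(n_nodes, dtype=int)

    by_tree: dict[str, set] = {}
    for ev in events:
        gd_count[ev.species_node_id] += 1
        if ev.dup_type == "ABAB":
            abab_count[ev.species_node_id] += 1
        by_tree.setdefault(ev.gene_tree_id, set()).add(ev.species_node_id)
    for nodes in by_tree.values():
        for nid in nodes:
            trees_with_gd[nid] += 1
    for gtree in gtrees:
        for node in stree.nodes:
            if relevant_for_node(gtree, node, stree):
                relevant[node.id] += 1

    denom = relevant.astype(float) if ratio_denominator == "relevant" \
        else np.full(n_nodes, float(len(gtrees)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gd_ratio = np.where(denom > 0, trees_with_gd / denom, np.nan)
        abab_fraction = np.where(gd_count > 0, abab_count / gd_count, np.nan)

    df = pd.DataFrame({
        "species_node_id": np.arange(n_nodes),
        "is_tip": [n.is_tip for n in stree.nodes],
        "clade": [";".join(sorted(stree.clade_tips(n))) for n in stree.nodes],
        "gd_count": gd_count,
        "abab_count": abab_count,
        "abab_fraction": abab_fraction,
        "relevant_tree_count": relevant,
        "trees_with_gd": trees_with_gd,
        "gd_ratio": gd_ratio,
    }).set_index("species_node_id")
    df.attrs["ratio_denominator"] = ratio_denominator
    df.attrs["n_trees"] = len(gtrees)
    return df


def map_duplications(gtrees, stree: SpeciesTree, min_support: float = 50.0,
                     outgroup_species=None, missing_support: str = "fail"):
    """Root (optionally), reconcile, and pool duplications over gene trees.

    Returns ``(events, used_trees, skipped)``: the retained events, the
    rooted trees actually analysed, and the names of trees skipped because
    no outgroup tip was present.
    """
    events: list[DuplicationEvent] = []
    used, skipped = [], []
    for gtree in gtrees:
        if outgroup_species is not None:
            try:
                gtree = root_by_outgroup(gtree, outgroup_species)
            except UnrootableError as exc:
                logger.warning("skipping %s: %s", gtree.name, exc)
                skipped.append(gtree.name or "")
                continue
        used.append(gtree)
        events.extend(detect_duplications(
            gtree, stree, min_support=min_support,
            missing_support=missing_support))
    return events, used, skipped


def events_to_frame(events) -> pd.DataFrame:
    """Tabular view of duplication events (one row per event)."""
    return pd.DataFrame(
        [(e.gene_tree_id, e.gene_node_id, e.species_node_id, e.support,
          e.dup_type) for e in events],
        columns=["gene_tree_id", "gene_node_id", "species_node_id",
                 "support", "dup_type"],
    )
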