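"""Ground-truth simulation of gene families on a species tree.

Gene families evolve by a birth-death process along the branches of a
known species tree: each gene lineage duplicates at rate ``dup_rate`` and
dies at rate ``loss_rate`` (both per lineage per unit branch-time).  At
designated WGD nodes every lineage alive at the node is duplicated with a
per-copy retention probability ``r`` immediately before the speciation, so
a retained WGD duplication reconciles exactly to that node with the ABAB
pattern unless losses erode one side.  Losses are simulated as lineage
death inside branches - not post-hoc pruning - so downstream reconciliation
faces realistic missing-taxon patterns, which is what produces partial
(non-ABAB) duplication types.

Sequences are simulated on the resulting gene trees with synonymous-site
substitutions only: a Poisson number of events per branch (rate =
``syn_rate`` x synonymous sites) applied as equal-rate exchanges among
synonymous codons.  Nonsynonymous divergence is therefore ~0 by design,
isolating the Ks machinery from selection modelling.

Every output is reproducible bit-exactly from (config, seed); per-family
random streams are spawned from the master seed so families are
independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

from .trees import (DEFAULT_DELIMITER, GeneTree, Node, SpeciesTree,
                    parse_newick, species_of_gene)
from .ks import _BASES, _CODON_TABLE

EIGHT_TIP_NEWICK = (
    "(((s1:0.25,s2:0.25)n12:0.35,(s3:0.25,s4:0.25)n34:0.35)n1234:0.4,"
    "((s5:0.25,s6:0.25)n56:0.35,(s7:0.25,s8:0.25)n78:0.35)n5678:0.4)root;"
)


def default_species_tree() -> SpeciesTree:
    """Balanced 8-species reference tree of unit depth (time units)."""
    return parse_newick(EIGHT_TIP_NEWICK, kind="species")


@dataclass
class SimulationConfig:
    """Parameters of one simulated gene-family dataset.

    Rates are per lineage per unit of species-tree branch length;
    ``wgd_events`` is a list of ``(species_node_id, retention)`` pairs.
    ``support_model`` is ``("constant", value)`` or ``("jitter", lo, hi)``
    (uniform integer supports, assigned independently per internal node).
    """

    species_tree: SpeciesTree
    n_families: int = 300
    dup_rate: float = 0.05
    loss_rate: float = 0.1
    wgd_events: list = field(default_factory=list)
    support_model: tuple = ("constant", 100)
    seed: int = 0
    delimiter: str = DEFAULT_DELIMITER
    syn_rate: float = 0.5
    n_codons: int = 300

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        for node_id, r in self.wgd_events:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention {r} outside [0, 1]")
            if self.species_tree.node(node_id).is_tip:
                raise ValueError(f"WGD node {node_id} is a tip")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        stree = parse_newick(raw["species_tree"], kind="species")
        wgd = []
        for item in raw.get("wgd_events", []):
            spec = str(item["node"])
            if "," in spec:
                node = stree.mrca(t.strip() for t in spec.split(","))
            else:
                node = stree.node_by_label(spec)
                if node is None:
                    raise ValueError(f"unknown WGD node {spec!r}")
            wgd.append((node.id, float(item["retention"])))
        sup = raw.get("support", {"model": "constant", "value": 100})
        if sup["model"] == "constant":
            support_model = ("constant", int(sup.get("value", 100)))
        else:
            support_model = ("jitter", int(sup["low"]), int(sup["high"]))
        return cls(
            species_tree=stree,
            n_families=int(raw.get("n_families", 300)),
            dup_rate=float(raw.get("dup_rate", 0.05)),
            loss_rate=float(raw.get("loss_rate", 0.1)),
            wgd_events=wgd,
            support_model=support_model,
            seed=int(raw.get("seed", 0)),
            delimiter=str(raw.get("delimiter", DEFAULT_DELIMITER)),
            syn_rate=float(raw.get("syn_rate", 0.5)),
            n_codons=int(raw.get("n_codons", 300)),
        )


@dataclass(frozen=True)
class GroundTruthEvent:
    """One surviving (observable) duplication, as simulated."""

    family: str
    gene_node_id: int
    species_node_id: int
    kind: str  # "wgd" | "background"


class _SimNode:
    __slots__ = ("children", "length", "species", "event")

    def __init__(self, length=0.0, species=None, event=None):
        self.children: list[_SimNode] = []
        self.length = length
        self.species = species  # tip species id, tips only
        self.event = event  # (species_node_id, kind) for duplication nodes


def _simulate_family(stree: SpeciesTree, dup_rate: float, loss_rate: float,
                     wgd: dict, rng) -> _SimNode | None:
    total_rate = dup_rate + loss_rate

    def at_node(snode, past_wgd=False):
        """Lineage positioned exactly at species node ``snode``."""
        if not past_wgd and snode.id in wgd and rng.random() < wgd[snode.id]:
            left = at_node(snode, past_wgd=True)
            right = at_node(snode, past_wgd=True)
            if left is None and right is None:
                return None
            if left is None or right is None:
                return left if right is None else right
            node = _SimNode(event=(snode.id, "wgd"))
            node.children = [left, right]
            return node
        return speciate(snode)

    def speciate(snode):
        if snode.is_tip:
            return _SimNode(species=snode.label)
        kids = []
        for child in snode.children:
            sub = along_branch(child, child.length or 0.0)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # pass-through; length already accumulated
        node = _SimNode()
        node.children = kids
        return node

    def along_branch(snode, remaining):
        """One lineage entering the branch above ``snode`` with
        ``remaining`` time to go; returns the surviving subtree with
        ``length`` measured from the entry point."""
        elapsed = 0.0
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 \
                else np.inf
            if wait >= remaining:
                node = at_node(snode)
                if node is not None:
                    node.length += elapsed + remaining
                return node
            elapsed += wait
            remaining -= wait
            if rng.random() < loss_rate / total_rate:
                return None  # lineage dies on the branch
            left = along_branch(snode, remaining)
            right = along_branch(snode, remaining)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if right is None else right
                survivor.length += elapsed
                return survivor
            node = _SimNode(length=elapsed, event=(snode.id, "background"))
            node.children = [left, right]
            return node

    return at_node(stree.root)


def _to_gene_tree(sim_root: _SimNode, family: str, support_model, rng,
                  delimiter: str):
    """Convert a survivor subtree to a GeneTree + ground-truth events."""
    copy_counter: dict[str, int] = {}
    pairs = []  # (trees.Node, _SimNode)

    def convert(sim):
        node = Node(length=sim.length)
        if sim.species is not None:
            k = copy_counter.get(sim.species, 0) + 1
            copy_counter[sim.species] = k
            node.label = f"{sim.species}{delimiter}{family}_{k}"
        else:
            if support_model[0] == "constant":
                node.support = float(support_model[1])
            else:
                node.support = float(rng.integers(support_model[1],
                                                  support_model[2] + 1))
            for c in sim.children:
                node.add_child(convert(c))
        pairs.append((node, sim))
        return node

    root = convert(sim_root)
    root.length = None
    gtree = GeneTree(root, delimiter=delimiter, name=family)
    events = [
        GroundTruthEvent(family=family, gene_node_id=node.id,
                         species_node_id=sim.event[0], kind=sim.event[1])
        for node, sim in pairs if sim.event is not None
    ]
    events.sort(key=lambda e: e.gene_node_id)
    return gtree, events


def simulate_gene_tree(config: SimulationConfig, family_index: int,
                       rng=None, max_attempts: int = 100):
    """One gene family: ``(GeneTree | None, ground-truth events)``.

    Extinct families (no surviving tip) are resimulated up to
    ``max_attempts`` times; if all attempts die out, ``(None, [])`` is
    returned as an empty-family record.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(config.n_families)
            [family_index])
    wgd = dict(config.wgd_events)
    family = f"fam{family_index:04d}"
    for _ in range(max_attempts):
        sim_root = _simulate_family(config.species_tree, config.dup_rate,
                                    config.loss_rate, wgd, rng)
        if sim_root is not None:
            return _to_gene_tree(sim_root, family, config.support_model,
                                 rng, config.delimiter)
    return None, []


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gene_trees: list
    ground_truth: list  # GroundTruthEvent, pooled over families
    n_extinct: int = 0

    def true_node_tally(self, kind: str | None = None) -> dict:
        """True duplication count per species node id."""
        tally: dict[int, int] = {}
        for ev in self.ground_truth:
            if kind is None or ev.kind == kind:
                tally[ev.species_node_id] = tally.get(ev.species_node_id,
                                                      0) + 1
        return tally


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """All families of one configuration, reproducible from config.seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_families)
    gtrees, truth, n_extinct = [], [], 0
    for i in range(config.n_families):
        gtree, events = simulate_gene_tree(
            config, i, rng=np.random.default_rng(seeds[i]))
        if gtree is None:
            n_extinct += 1
            continue
        gtrees.append(gtree)
        truth.extend(events)
    return SimulatedDataset(config=config, gene_trees=gtrees,
                            ground_truth=truth, n_extinct=n_extinct)


# -- sequence simulation ----------------------------------------------------

_SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")
_SYN_NEIGHBOURS: dict[str, list] = {}
for _codon in _SENSE_CODONS:
    opts = []
    for _pos in range(3):
        for _b in _BASES:
            if _b == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _b + _codon[_pos + 1:]
            if _CODON_TABLE[_alt] == _CODON_TABLE[_codon]:
                opts.append(_alt)
    _SYN_NEIGHBOURS[_codon] = opts


def simulate_codon_sequences(gtree: GeneTree, syn_rate: float,
                             n_codons: int, seed=None) -> dict:
    """Aligned CDS for every gene tip, mutated at synonymous sites only.

    The root sequence is drawn uniformly from the sense codons.  Along each
    branch, substitution events arrive at rate ``syn_rate`` x (synonymous
    sites of the current sequence); each event applies one uniformly chosen
    synonymous single-nucleotide exchange.  Sequences are aligned by
    construction and contain no stop codons.
    """
    if n_codons < 50:
        import warnings

        warnings.warn("n_codons < 50: Ks estimates will be high-variance",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    root_seq = [
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]

    def evolve(seq, branch_length):
        seq = list(seq)
        counts = np.array([len(_SYN_NEIGHBOURS[c]) for c in seq], dtype=float)
        total = counts.sum()
        t = 0.0
        while total > 0:
            # synonymous sites = (# synonymous neighbour changes) / 3
            rate = syn_rate * total / 3.0
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= branch_length:
                break
            i = rng.choice(len(seq), p=counts / total)
            opts = _SYN_NEIGHBOURS[seq[i]]
            seq[i] = opts[rng.integers(0, len(opts))]
            counts[i] = len(_SYN_NEIGHBOURS[seq[i]])
            total = counts.sum()
        return seq

    out: dict[str, str] = {}

    def walk(node, seq):
        if node.is_tip:
            out[node.label] = "".join(seq)
            return
        for child in node.children:
            walk(child, evolve(seq, child.length or 0.0))

    walk(gtree.root, root_seq)
    return out


# -- planted feature sets ---------------------------------------------------


def plant_feature_sets(tree: SpeciesTree, association: str, k_each: int,
                       p: float = 0.5, seed=None):
    """Two feature sets with a controlled degree of coincidence.

    ``association``: ``"none"`` - independent uniform draws; ``"full"`` -
    B = A; ``"partial"`` - B shares ceil(p * k) nodes with A, the rest
    drawn uniformly from the eligible complement of A.
    """
    from .correlation import eligible_nodes
    from .trees import FeatureNodeSet

    rng = np.random.default_rng(seed)
    pool = eligible_nodes(tree)
    if k_each > len(pool):
        raise ValueError(f"k_each={k_each} exceeds {len(pool)} internal nodes")
    a = rng.choice(pool, size=k_each, replace=False)
    if association == "none":
        b = rng.choice(pool, size=k_each, replace=False)
    elif association == "full":
        b = a.copy()
    elif association == "partial":
        n_shared = int(np.ceil(p * k_each))
        if not 0 <= n_shared <= k_each:
            raise ValueError(f"infeasible sharing fraction p={p}")
        complement = np.setdiff1d(pool, a)
        n_new = k_each - n_shared
        if n_new > len(complement):
            raise ValueError("not enough non-A nodes for the unshared part")
        shared = rng.choice(a, size=n_shared, replace=False)
        fresh = rng.choice(complement, size=n_new, replace=False)
        b = np.concatenate([shared, fresh])
    else:
        raise ValueError(f"unknown association {association!r}")
    return (FeatureNodeSet("A", frozenset(int(x) for x in a)),
            FeatureNodeSet("B", frozenset(int(x) for x in b)))


# -- ground-truth paralog pairs ---------------------------------------------


def true_pair_distance(gtree: GeneTree, tip_a: str, tip_b: str) -> float:
    """Path length (time units) between two gene tips."""
    a, b = gtree.tip(tip_a), gtree.tip(tip_b)
    anc = gtree.mrca_nodes(a, b)
    dist = 0.0
    for node in (a, b):
        while node is not anc:
            dist += node.length or 0.0
            node = node.parent
    return dist


def wgd_paralog_pairs(gtree: GeneTree, events, species: str,
                      delimiter: str = DEFAULT_DELIMITER) -> list:
    """Ground-truth paralog pairing: per WGD event, the lexicographically
    first gene of ``species`` in each subclade (matching the deterministic
    choice of the Ks pair collector on fully aligned families)."""
    pairs = []
    for ev in events:
        if ev.kind != "wgd":
            continue
        node = gtree.node(ev.gene_node_id)
        if len(node.children) != 2:
            continue
        sides = []
        for child in node.children:
            genes = sorted(
                t for t in gtree.clade_tips(child)
                if species_of_gene(t, delimiter) == species)
            sides.append(genes)
        if sides[0] and sides[1]:
            pairs.append((sides[0][0], sides[1][0]))
    return pairs
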