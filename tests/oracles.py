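"""Independent brute-force oracles used only by the test suite.

These are written deliberately naively - direct recomputation from
definitions, no shared code paths with the package internals - so they can
arbitrate the main implementation.
"""

from __future__ import annotations

import itertools


# -- brute-force reconciliation --------------------------------------------
#
# Trees are nested tuples: a leaf is a species-id string, an internal node
# is a 2-tuple (left, right).  The species tree is given the same way.


def leaf_set(tree):
    if isinstance(tree, str):
        return frozenset([tree])
    out = frozenset()
    for child in tree:
        out |= leaf_set(child)
    return out


def species_clades(stree):
    """Every clade (frozenset of species) of the species tree, plus the
    mapping clade -> (child clades)."""
    clades = {}

    def walk(node):
        tips = leaf_set(node)
        if isinstance(node, str):
            clades[tips] = ()
        else:
            clades[tips] = tuple(leaf_set(c) for c in node)
            for c in node:
                walk(c)
        return tips

    walk(stree)
    return clades


def brute_mrca_clade(species_set, clades):
    """Smallest species-tree clade containing ``species_set``."""
    best = None
    for clade in clades:
        if species_set <= clade and (best is None or len(clade) < len(best)):
            best = clade
    return best


def brute_reconcile(gtree, stree):
    """All duplication nodes of a gene tree (species-labelled leaves).

    Returns a sorted list of (mapped-clade-tips, dup_type) tuples, one per
    duplication node.  A node is a duplication iff at least one of its
    subclades spans two or more child lineages of its mapped species clade
    (equivalently: the mapped clade is a single species).  ABAB requires
    both subclades to span two or more child lineages.
    """
    clades = species_clades(stree)
    dups = []

    def walk(node):
        if isinstance(node, str):
            return
        s1, s2 = leaf_set(node[0]), leaf_set(node[1])
        mapped = brute_mrca_clade(s1 | s2, clades)
        children = clades[mapped]
        if len(mapped) == 1:
            dups.append((tuple(sorted(mapped)), "tip"))
        else:
            def spans(s):
                return sum(1 for lin in children if s & lin) >= 2

            if spans(s1) or spans(s2):
                dup_type = "ABAB" if spans(s1) and spans(s2) else "partial"
                dups.append((tuple(sorted(mapped)), dup_type))
        for child in node:
            walk(child)

    walk(gtree)
    return sorted(dups)


def all_rooted_topologies(leaves):
    """Every rooted binary topology over an ordered leaf list (as nested
    tuples); leaves with equal labels still yield distinct placements, so
    callers should deduplicate if they enumerate label multisets."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    # insert the first leaf into every edge of every topology on the rest
    first, rest = leaves[0], leaves[1:]
    for sub in all_rooted_topologies(rest):
        for tree in _insert_everywhere(first, sub):
            yield tree


def _insert_everywhere(leaf, tree):
    yield (leaf, tree)
    if not isinstance(tree, str):
        left, right = tree
        for new_left in _insert_everywhere(leaf, left):
            yield (new_left, right)
        for new_right in _insert_everywhere(leaf, right):
            yield (left, new_right)


def all_species_labelled_trees(n_leaves, species, _cache={}):
    """All distinct species-labelled rooted binary tree shapes with
    ``n_leaves`` leaves coloured from ``species`` (children unordered)."""
    key = (n_leaves, tuple(species))
    if key in _cache:
        return _cache[key]
    if n_leaves == 1:
        result = [s for s in species]
    else:
        seen = set()
        result = []
        for k in range(1, n_leaves // 2 + 1):
            for left in all_species_labelled_trees(k, species):
                for right in all_species_labelled_trees(n_leaves - k,
                                                        species):
                    tree = tuple(sorted((left, right), key=repr))
                    if tree not in seen:
                        seen.add(tree)
                        result.append(tree)
    _cache[key] = result
    return result


# -- brute-force Nei-Gojobori ----------------------------------------------

_BASES = "ACGT"
_GENETIC_CODE = {}


def _fill_code():
    from Bio.Seq import Seq

    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                _GENETIC_CODE[codon] = str(Seq(codon).translate())


_fill_code()


def brute_ng86(seq_a, seq_b):
    """Naive NG86: returns (S, N, Sd, Nd, ps, pn, ks, ka).

    Same conventions as the package (stop-creating mutations are
    nonsynonymous sites; pathways through stops dropped, all-pathway
    fallback; gap/ambiguous/stop codon columns skipped), but recomputed
    from scratch with per-codon pathway enumeration and no caching.
    """
    import math

    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S_a = S_b = Sd = Nd = 0.0
    ncod = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if _GENETIC_CODE[ca] == "*" or _GENETIC_CODE[cb] == "*":
            continue
        ncod += 1
        for codon, acc in ((ca, "a"), (cb, "b")):
            syn = 0
            for pos in range(3):
                for base in _BASES:
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1:]
                    if _GENETIC_CODE[mut] == _GENETIC_CODE[codon]:
                        syn += 1
            if acc == "a":
                S_a += syn / 3.0
            else:
                S_b += syn / 3.0
        diff_pos = [p for p in range(3) if ca[p] != cb[p]]
        if diff_pos:
            ok_paths, all_paths = [], []
            for order in itertools.permutations(diff_pos):
                cur, syn, non, through_stop = ca, 0, 0, False
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    if _GENETIC_CODE[nxt] == "*":
                        through_stop = True
                    if _GENETIC_CODE[nxt] == _GENETIC_CODE[cur]:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                all_paths.append((syn, non))
                if not through_stop:
                    ok_paths.append((syn, non))
            paths = ok_paths if ok_paths else all_paths
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
    S = (S_a + S_b) / 2.0
    N = 3.0 * ncod - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return S, N, Sd, Nd, ps, pn, jc(ps), jc(pn)
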