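"""Randomization tests for coincidence of node features on a species tree.

Features (duplication bursts, diversification-rate upshifts, trait
transitions) are sets of species-tree nodes.  The coincidence of two sets
A and B is the number of A-nodes having a B-node within a configurable
branch radius (radius 0: exact node identity, i.e. |A and B|).  The
observed coincidence is compared against nulls in which one of the two
sets is re-placed uniformly at random (without replacement) over the
eligible nodes - internal nodes including the root, since features are
anchored at MRCAs.  One test draws ``n_rand`` random placements and
estimates P with the add-one rule P = (1 + #{null >= observed}) /
(1 + n_rand); the whole test is repeated ``n_repeats`` times to yield a
P-value distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import FeatureNodeSet, SpeciesTree

SCHEMES = ("randomize-A", "randomize-B")


@dataclass(frozen=True)
class CoincidenceResult:
    """Observed coincidence, null scheme, and the per-repeat P values."""

    feature_a: str
    feature_b: str
    radius: int
    observed: int
    null_scheme: str
    n_rand: int
    n_repeats: int
    p_values: tuple
    seed: object = None

    def summary(self) -> dict:
        p = np.asarray(self.p_values)
        return {
            "median_p": float(np.median(p)),
            "q25_p": float(np.quantile(p, 0.25)),
            "q75_p": float(np.quantile(p, 0.75)),
            "min_p": float(p.min()),
            "max_p": float(p.max()),
        }


def _as_ids(feature) -> frozenset:
    if isinstance(feature, FeatureNodeSet):
        return feature.nodes
    return frozenset(feature)


def eligible_nodes(tree: SpeciesTree) -> np.ndarray:
    """Nodes a randomized feature may occupy: internal nodes incl. root."""
    return np.array(sorted(n.id for n in tree.internal_nodes), dtype=int)


def _adjacency(tree: SpeciesTree) -> dict:
    adj: dict[int, list] = {n.id: [] for n in tree.nodes}
    for node in tree.nodes:
        if node.parent is not None:
            adj[node.id].append(node.parent.id)
            adj[node.parent.id].append(node.id)
    return adj


def nodes_within(tree: SpeciesTree, sources, radius: int) -> frozenset:
    """All node ids within ``radius`` edges of any source node (BFS)."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    sources = set(sources)
    if radius == 0:
        return frozenset(sources)
    adj = _adjacency(tree)
    seen = set(sources)
    frontier = set(sources)
    for _ in range(radius):
        frontier = {n for f in frontier for n in adj[f]} - seen
        seen |= frontier
    return frozenset(seen)


def coincidence_count(a, b, tree: SpeciesTree, radius: int = 0) -> int:
    """Number of A-nodes with some B-node within ``radius`` edges."""
    a_ids, b_ids = _as_ids(a), _as_ids(b)
    near_b = nodes_within(tree, b_ids, radius)
    return sum(1 for x in a_ids if x in near_b)


def randomize_feature_nodes(tree: SpeciesTree, k: int, eligible=None,
                            rng=None, name: str = "random") -> FeatureNodeSet:
    """Uniform sample of ``k`` eligible nodes without replacement."""
    rng = np.random.default_rng(rng)
    pool = eligible_nodes(tree) if eligible is None \
        else np.asarray(sorted(eligible), dtype=int)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds {len(pool)} eligible nodes")
    picked = rng.choice(pool, size=k, replace=False)
    return FeatureNodeSet(name, frozenset(int(x) for x in picked))


def _sample_matrix(rng, n_rand: int, n_pool: int, k: int) -> np.ndarray:
    """Boolean (n_rand, n_pool) matrix, each row k True uniform w/o repl."""
    if k == n_pool:
        return np.ones((n_rand, n_pool), dtype=bool)
    u = rng.random((n_rand, n_pool))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    out = np.zeros((n_rand, n_pool), dtype=bool)
    np.put_along_axis(out, idx, True, axis=1)
    return out


def _null_counts(tree, fixed_ids, k_random, scheme, radius, pool, rng,
                 n_rand):
    """Coincidence counts for n_rand random placements.

    ``scheme`` 'randomize-A': statistic = |sample intersect near(B)| with B
    fixed.  'randomize-B': statistic = #{a in A : sample hits near(a)} with
    A fixed.
    """
    S = _sample_matrix(rng, n_rand, len(pool), k_random)
    if scheme == "randomize-A":
        near_fixed = nodes_within(tree, fixed_ids, radius)
        ind = np.fromiter((p in near_fixed for p in pool), dtype=bool,
                          count=len(pool))
        return S[:, ind].sum(axis=1)
    # randomize-B: rows of M are the neighbourhoods of each fixed A-node
    M = np.zeros((len(fixed_ids), len(pool)), dtype=bool)
    for i, a in enumerate(sorted(fixed_ids)):
        near_a = nodes_within(tree, [a], radius)
        M[i] = np.fromiter((p in near_a for p in pool), dtype=bool,
                           count=len(pool))
    return (S @ M.T.astype(np.int64) > 0).sum(axis=1)


def permutation_test(a, b, tree: SpeciesTree,
                     null_scheme: str = "randomize-A",
                     n_rand: int = 1000, n_repeats: int = 100,
                     radius: int = 0, seed=None,
                     name_a: str = "A", name_b: str = "B"
                     ) -> CoincidenceResult:
    """Randomized-placement coincidence test between two feature sets.

    Each of ``n_repeats`` independent repeats draws ``n_rand`` random
    placements of the designated set (preserving its cardinality) over the
    internal nodes and computes the add-one tail probability of the
    observed coincidence.  Repeats use seeds spawned from ``seed``, so the
    full P-value list is reproducible bit-exactly.
    """
    if null_scheme not in SCHEMES:
        raise ValueError(f"null_scheme must be one of {SCHEMES}")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    a_ids, b_ids = _as_ids(a), _as_ids(b)
    if isinstance(a, FeatureNodeSet):
        name_a = a.name
    if isinstance(b, FeatureNodeSet):
        name_b = b.name
    if not a_ids or not b_ids:
        raise ValueError("degenerate feature set: |A| and |B| must be > 0")
    pool = eligible_nodes(tree)
    observed = coincidence_count(a_ids, b_ids, tree, radius)
    if null_scheme == "randomize-A":
        fixed_ids, k_random = b_ids, len(a_ids)
    else:
        fixed_ids, k_random = a_ids, len(b_ids)
    if k_random > len(pool):
        raise ValueError("feature set larger than the eligible node pool")
    master = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seed_seqs = master.spawn(n_repeats)
    p_values = []
    for ss in seed_seqs:
        rng = np.random.default_rng(ss)
        counts = _null_counts(tree, fixed_ids, k_random, null_scheme,
                              radius, pool, rng, n_rand)
        p = (1 + int((counts >= observed).sum())) / (1 + n_rand)
        p_values.append(p)
    return CoincidenceResult(
        feature_a=name_a, feature_b=name_b, radius=radius,
        observed=observed, null_scheme=null_scheme, n_rand=n_rand,
        n_repeats=n_repeats, p_values=tuple(p_values), seed=seed)


def run_pairwise_tests(features: dict, tree: SpeciesTree,
                       n_rand: int = 1000, n_repeats: int = 100,
                       radius: int = 0, seed=None) -> list:
    """Both null schemes for every unordered pair of feature sets."""
    names = sorted(features)
    if len(names) < 2:
        raise ValueError("need at least two feature sets")
    pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1:]]
    seeds = np.random.SeedSequence(seed).spawn(len(pairs) * len(SCHEMES))
    results = []
    i = 0
    for name_a, name_b in pairs:
        for scheme in SCHEMES:
            results.append(permutation_test(
                features[name_a], features[name_b], tree,
                null_scheme=scheme, n_rand=n_rand, n_repeats=n_repeats,
                radius=radius, seed=seeds[i], name_a=name_a, name_b=name_b))
            i += 1
    return results


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "feature_a": r.feature_a, "feature_b": r.feature_b,
            "null_scheme": r.null_scheme, "radius": r.radius,
            "observed": r.observed, "n_rand": r.n_rand,
            "n_repeats": r.n_repeats,
        }
        row.update(r.summary())
        rows.append(row)
    return pd.DataFrame(rows)
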