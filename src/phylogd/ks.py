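"""Synonymous divergence (Ks) of paralog pairs and Ks-distribution peaks.

Ks/Ka are estimated with the Nei-Gojobori (1986) counting method: codon
sites are partitioned into synonymous and nonsynonymous fractions, observed
codon differences are resolved by averaging over all single-substitution
pathways, and the resulting proportions are corrected for multiple hits
with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

Conventions fixed here (and matched by the test-suite oracle):

* mutations that would create a stop codon count as nonsynonymous in the
  site tally, so S + N always equals 3 x (codons compared);
* substitution pathways passing through a stop codon are excluded from the
  averaging; if every pathway is blocked, all pathways are used;
* codon columns containing a gap, an ambiguous base, or a stop codon in
  either sequence are excluded pairwise.

Paralog pairs with p_s >= 3/4 are flagged saturated (Ks undefined) and are
excluded from peak detection.  Peaks are located as the argmax of a
Gaussian kernel density (Silverman bandwidth by default) evaluated on a
1,000-point grid over the search range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .trees import species_of_gene

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON_TABLE = _build_codon_table()
_SITE_CACHE: dict[str, float] = {}
_PATH_CACHE: dict[tuple, tuple] = {}


class KsError(ValueError):
    pass


@dataclass(frozen=True)
class KsResult:
    """Nei-Gojobori site/difference counts and corrected rates for a pair."""

    pair_id: str
    n_codons: int  # codon columns actually compared
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float  # NaN when saturated
    ka: float  # NaN when saturated
    saturated: bool


@dataclass(frozen=True)
class ParalogPair:
    """Two same-species genes descending from one duplication event."""

    species: str
    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    event_id: str = ""

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}__{self.gene_b}"


@dataclass(frozen=True)
class KsPeak:
    location: float
    density: float
    bandwidth: float
    search_range: tuple
    n_used: int
    n_saturated: int


def _syn_sites(codon: str) -> float:
    """Synonymous site fraction of one codon (0..3).

    Each of the nine single-nucleotide neighbours contributes 1/3 of a
    site; neighbours that are stop codons count as nonsynonymous.
    """
    try:
        return _SITE_CACHE[codon]
    except KeyError:
        pass
    aa = _CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa:
                syn += 1
    s = syn / 3.0
    _SITE_CACHE[codon] = s
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple:
    """Average (synonymous, nonsynonymous) step counts between two codons."""
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    try:
        return _PATH_CACHE[key]
    except KeyError:
        pass
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        result = (0.0, 0.0)
        _PATH_CACHE[key] = result
        return result
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                blocked = True  # pathway through a stop codon
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        paths.append((blocked, syn, non))
    open_paths = [(s, n) for b, s, n in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    result = (sd, nd)
    _PATH_CACHE[key] = result
    return result


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_pair(cds_a: str, cds_b: str, pair_id: str = "") -> KsResult:
    """Ks/Ka between two pre-aligned in-frame CDS sequences.

    Sequences must have equal length divisible by 3.  Codon columns with a
    gap character, an ambiguous base, or a stop codon in either sequence
    are skipped pairwise.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise KsError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise KsError(f"aligned length {len(a)} is not a multiple of 3")
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(x not in _BASES for x in ca + cb):
            continue  # gap or ambiguity column
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            continue
        n_codons += 1
        s_a += _syn_sites(ca)
        s_b += _syn_sites(cb)
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise KsError("no comparable codon columns")
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = bool(np.isnan(ks))
    return KsResult(pair_id=pair_id, n_codons=n_codons, S=S, N=N, Sd=sd,
                    Nd=nd, ps=ps, pn=pn, ks=ks, ka=ka, saturated=saturated)


def _has_internal_stop(seq: str) -> bool:
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    coding = [c for c in codons if all(x in _BASES for x in c)]
    if coding and _CODON_TABLE.get(coding[-1]) == "*":
        coding = coding[:-1]  # a terminal stop is fine
    return any(_CODON_TABLE.get(c) == "*" for c in coding)


def collect_paralog_pairs(events, sequences, species: str,
                          delimiter: str = "|") -> list[ParalogPair]:
    """One paralog pair per duplication event for a focal species.

    For each event whose two subclades both contain genes of ``species``,
    the pair with the longest aligned overlap (non-gap columns shared by
    both sequences) is chosen; ties break on lexicographic gene ids.
    Events lacking the species on either side contribute nothing; missing
    sequences and sequences with internal stop codons are skipped with a
    log entry.
    """
    pairs = []
    for ev in events:
        sides = []
        for tips in ev.subclade_tips:
            sides.append(sorted(
                t for t in tips if species_of_gene(t, delimiter) == species))
        if len(sides) != 2 or not sides[0] or not sides[1]:
            continue
        best = None
        for ga in sides[0]:
            for gb in sides[1]:
                if ga not in sequences or gb not in sequences:
                    logger.warning("missing sequence for %s or %s", ga, gb)
                    continue
                sa, sb = sequences[ga], sequences[gb]
                if len(sa) != len(sb):
                    logger.warning("unaligned pair %s / %s skipped", ga, gb)
                    continue
                if _has_internal_stop(sa) or _has_internal_stop(sb):
                    logger.warning("internal stop in %s / %s; skipped", ga, gb)
                    continue
                overlap = sum(
                    1 for x, y in zip(sa.upper(), sb.upper())
                    if x in _BASES and y in _BASES)
                cand = (-overlap, ga, gb)
                if best is None or cand < best[0]:
                    best = (cand, (ga, gb, sa, sb))
        if best is None:
            continue
        ga, gb, sa, sb = best[1]
        pairs.append(ParalogPair(
            species=species, gene_a=ga, gene_b=gb, seq_a=sa, seq_b=sb,
            event_id=f"{ev.gene_tree_id}:{ev.gene_node_id}"))
    return pairs


def ks_peak(ks_values, search_range: tuple = (0.01, 2.0),
            bandwidth=None, grid_points: int = 1000,
            min_values: int = 20) -> KsPeak:
    """Locate the mode of a Ks distribution by Gaussian KDE.

    ``bandwidth`` is either None (Silverman's rule on the in-range values)
    or an absolute kernel standard deviation in Ks units.  Requires at
    least ``min_values`` finite values inside ``search_range``.
    """
    lo, hi = search_range
    if lo >= hi:
        raise KsError(f"empty search range {search_range}")
    values = np.asarray(list(ks_values), dtype=float)
    finite = values[np.isfinite(values)]
    n_saturated = len(values) - len(finite)
    used = finite[(finite >= lo) & (finite <= hi)]
    if len(used) < min_values:
        raise KsError(
            f"insufficient data: {len(used)} usable Ks values in "
            f"[{lo}, {hi}], need {min_values}")
    grid = np.linspace(lo, hi, grid_points)
    sd = used.std(ddof=1)
    if sd == 0.0:
        # degenerate distribution: the mode is the common value
        loc = float(used[0])
        return KsPeak(location=float(grid[np.argmin(np.abs(grid - loc))]),
                      density=float("inf"), bandwidth=0.0,
                      search_range=(lo, hi), n_used=len(used),
                      n_saturated=n_saturated)
    if bandwidth is None:
        kde = gaussian_kde(used, bw_method="silverman")
    else:
        kde = gaussian_kde(used, bw_method=float(bandwidth) / sd)
    density = kde(grid)
    idx = int(np.argmax(density))
    return KsPeak(location=float(grid[idx]), density=float(density[idx]),
                  bandwidth=float(np.sqrt(kde.covariance[0, 0])),
                  search_range=(lo, hi), n_used=len(used),
                  n_saturated=n_saturated)


def ks_results_to_frame(results):
    import pandas as pd

    return pd.DataFrame(
        [(r.pair_id, r.n_codons, r.S, r.N, r.Sd, r.Nd, r.ps, r.pn, r.ks,
          r.ka, r.saturated) for r in results],
        columns=["pair_id", "n_codons", "S", "N", "Sd", "Nd", "ps", "pn",
                 "ks", "ka", "saturated"],
    )
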