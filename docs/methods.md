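# Methods

This note documents the models, conventions, and numerical choices behind
`phylogd`, and what the simulation-based tests do and do not demonstrate.

## Trees and the gene-label convention

Species trees and gene trees are newick; internal-node labels of gene
trees are read as bootstrap-style supports on the 0–100 scale.  Node ids
are assigned in post-order and are stable across runs on identical input;
every species-tree node is addressable by id, by its internal label, or as
the MRCA of a tip set (the format used by feature tables).

Gene tips follow `species<delimiter>gene`, species being everything before
the **first** delimiter occurrence (default `|`), because assembled
transcript ids frequently contain the delimiter themselves.  The delimiter
is configurable everywhere.

Supports are properties of bipartitions, not of nodes: when a gene tree is
re-rooted the support attached to each internal node follows the edge
whose bipartition it described, and the two children of the new root share
the root-edge support.  Internal nodes lacking a support value fail the
retention filter by default (`missing_support="pass"` treats them as
unassessed-but-credible); tips count as support 100.

## Outgroup rooting

Gene trees are rooted on the unrooted edge whose bipartition best isolates
the tips of the configured outgroup species: the side with maximal Jaccard
similarity to the outgroup tip set (exactly 1 when the outgroup is
monophyletic, in which case this is the branch subtending the smallest
clade containing all present outgroup tips), breaking ties by smaller side
then lowest post-order edge id.  Trees containing no outgroup tip are
skipped and logged rather than midpoint-rooted, since midpoint rooting can
relocate duplications.  Edge length is split evenly at the new root.

## Duplication detection and classification

Each gene-tree node maps to the MRCA (in the species tree) of the species
in its clade, computed bottom-up; the map is monotone along gene-tree
edges.  A binary gene node is a **duplication** iff its image equals the
image of at least one child — equivalently, iff at least one subclade
contains species from two or more descendant lineages of the image node.
Polytomies are treated as soft: a polytomous node is never itself called a
duplication (conservative), but duplications below it are detected
normally.

An event's support is the minimum of its two child-branch supports (both
subclades must be credible); the default retention threshold is 50.
Classification: **tip** if the image is a terminal species; **ABAB** if
each subclade intersects at least two descendant lineages of the image
(both A and B on a binary tree); otherwise **partial**.  Partial patterns
arise from gene loss or incomplete taxon sampling after a real
duplication, so the ABAB fraction discriminates genuine ancestral bursts
from mapping artifacts.

### The GD-ratio denominator

"Relevant trees" for a node — the denominator of the GD ratio — are the
gene trees in which a duplication at that node is observable: trees
sampling at least one species from *each* descendant lineage (for a tip
node: at least two gene copies of that species).  This makes ratios
comparable across nodes with uneven taxon occupancy.  Whether upstream
tools define the denominator identically is not verifiable, so the
summary table carries a `ratio_denominator` metadata column and a flag
switches to the all-trees denominator.

## Burst calling

A node passes when `gd_count ≥ min_gd` AND `gd_ratio ≥ min_ratio` AND
`abab_fraction ≥ min_abab`, all comparisons inclusive.  Defaults
600 / 0.06 / 0.30 are calibrated to a ~45,722-tree survey;
`scale_thresholds` rescales the count threshold proportionally
(round-half-up, floor 1) so the rule is meaningful at desk scale — the
ratio and ABAB thresholds are scale-free and are not rescaled.  Nodes with
an undefined ratio (no relevant trees) or undefined ABAB fraction (no
duplications) cannot pass and carry a reason code.

## Ks estimation

Nei–Gojobori (1986) counting with equal-pathway averaging and
Jukes–Cantor correction, chosen because it is closed-form and
oracle-checkable.  Conventions (fixed here and mirrored by the test
oracle):

* synonymous sites per codon are counted over all nine single-nucleotide
  neighbours, with changes creating stop codons counted as nonsynonymous —
  this keeps the invariant S + N = 3 × codons exact;
* multi-position codon differences are averaged over all substitution
  orderings, excluding pathways that pass through a stop codon (falling
  back to all pathways if every ordering is blocked);
* codon columns containing a gap, an ambiguous base, or a stop codon in
  either sequence are skipped pairwise;
* pairs with p_s ≥ 3/4 are flagged saturated (Ks undefined) and excluded
  from peak detection but tallied.

Inputs must be pre-aligned in frame; codon-alignment heuristics are
deliberately outside the package (the simulator emits aligned families).
One paralog pair is collected per duplication event per species — one gene
from each subclade, preferring the longest aligned overlap, ties broken by
lexicographic gene id — so a burst contributes one Ks value per retained
event rather than all-vs-all pairs.

Peak detection: Gaussian KDE over the values clipped to the search range
(default 0.01–2.0), Silverman's-rule bandwidth (absolute bandwidth
overridable), argmax on a 1,000-point grid; at least 20 usable values are
required.  A degenerate (zero-variance) sample returns its common value.
Pathway averaging attributes small nonsynonymous fractions to multi-hit
codons even under purely synonymous evolution (e.g. AGA→CGC), so Ka ≈ 0
rather than exactly 0 in the synonymous-only simulations.

## Coincidence tests

Features are sets of species-tree nodes; eligible positions for
randomization are internal nodes including the root, because bursts,
transitions and rate shifts are all MRCA-anchored.  The coincidence of A
with B at radius *r* is the number of A-nodes with some B-node within *r*
edges (radius 0 = exact identity, the default; radius is exposed rather
than guessed because "near-node" associations are plausible).  One test
draws `n_rand` uniform placements of the designated set without
replacement, preserving cardinality, and estimates
`P = (1 + #{null ≥ observed}) / (1 + n_rand)` — the add-one rule keeps
P ≥ 1/(n_rand+1).  The test is repeated `n_repeats` times (defaults
1,000 × 100) with per-repeat seeds spawned from the master seed, so the
P-value list is bit-reproducible.  Both null directions are run for every
feature pair.

Because the radius-0 null is hypergeometric and therefore coarse on small
trees, the estimator is conservative: the exact expected rejection rate at
α = 0.05 for independent features on a 30-internal-node pool peaks at
≈ 0.038 (feature sizes 12 and 13), not 0.05.  The calibration test uses
those sizes; users should expect conservative, never anti-conservative,
P values on small trees.

## Simulator

Gene families start as one lineage at the species root.  Along each
species branch every lineage independently duplicates at rate λ and dies
at rate μ (Gillespie); at a WGD node each arriving lineage duplicates with
probability *r* immediately before the speciation, so retained WGD
duplications reconcile exactly to that node and (absent loss) are ABAB.
Losses are real lineage deaths inside branches, not post-hoc pruning, so
missing-taxon patterns and partial duplication types emerge naturally.
Dead-end lineages are unifurcation-suppressed with branch lengths merged;
families with no survivor are resimulated up to 100 times, then recorded
as empty.  Ground truth records every surviving duplication (gene node,
species node, WGD/background) and the true paralog pairing.

Default study conditions (used by tests and the acceptance script): a
balanced 8-species tree of unit depth, 300 families, λ = 0.05, μ = 0.1,
one WGD with r = 0.6 at a 4-species ancestor (age 0.6).  These sizes keep
every stage's signal comfortably above its detection threshold while a
full run stays in seconds; with them background duplication yields
per-node GD ratios ≈ 2 %, well below the 6 % bar, so burst calls separate
cleanly.

Sequences: the root is uniform over the 61 sense codons; substitution
events arrive at rate `syn_rate × synonymous sites` and apply a uniformly
chosen synonymous single-nucleotide exchange, so sequences stay aligned
and stop-free and the expected NG86 Ks between two tips equals
`syn_rate × path time` (to JC accuracy).  Support values are constant 100
by default or i.i.d. uniform integers in a configured range ("jitter") to
exercise the support filter; jitter is deliberately crude — it models no
correlation between support and branch length.

What the simulations do **not** emulate: incomplete lineage sorting and
hybridization (no coalescent), nonsynonymous/selective sequence evolution,
codon-usage bias, alignment error, and gene-tree estimation error beyond
the support-jitter knob.  Passing tests therefore certify the
correctness of the counting, mapping, and testing machinery under the
duplication–loss model, not robustness to phylogenetic error in real
transcriptome data.

## Numerical and determinism choices

* Post-order ids, sorted output tables, and `%.10g` float formatting make
  CLI outputs byte-stable; rerunning any subcommand with the same inputs
  and seed is byte-identical.
* All randomness flows from `numpy` `SeedSequence` spawning (per family,
  per repeat, per section), so subsets are independent and reproducible.
* Threshold comparisons are inclusive (≥) throughout; `scale_thresholds`
  rounds half-up with floor 1.
* `mrca` on an empty tip set, features referencing unknown nodes, negative
  radii, zero-size feature sets, and non-positive threshold inputs raise
  errors rather than guessing.

## Known limitations

* LCA reconciliation assumes duplication–loss only; ILS or hybridization
  inflate apparent duplications near short internal branches.
* The NG86 estimator saturates near Ks ≈ 1–2; older WGDs need
  ML/codon-model estimators, out of scope here.
* The coincidence test conditions on feature-set sizes and treats internal
  nodes as exchangeable; it does not model clade size or branch length as
  placement covariates.
* Burst thresholds rescale only the count criterion; on very small tree
  sets (tens of trees) the ratio criterion dominates and is noisy.
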