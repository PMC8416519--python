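# Methods

This note documents the models, algorithms and numerical choices behind
`vartig`, and what the bundled simulator does and does not emulate.

## Gain/loss model

Gene-family presence/absence evolves as a two-state continuous-time Markov
chain with gain rate g (0→1) and loss rate l (1→0), in events per unit
branch length. The transition kernel over time t is closed-form:

    P01(t) = g/(g+l) · (1 − e^{−(g+l)t}),   P10(t) = l/(g+l) · (1 − e^{−(g+l)t})

Rate variation across families is modelled on both rates independently:
per-family rates are g0·r and l0·s with r, s ~ Gamma(α, mean 1). For
inference the two gamma laws are discretised into K categories each
(mean-of-bin, default K = 4), giving a K×K mixture with equal priors; each
family's likelihood is computed by Felsenstein pruning per category pair
and averaged. The root prior is the per-category stationary distribution
(l, g)/(g+l) — parameter-free and consistent with how the simulator draws
root states. Likelihoods are rescaled per node (log-scale accumulators) so
deep trees cannot underflow.

Parameters (g0, l0, α_gain, α_loss) are estimated by maximising the summed
log-likelihood: a 3×3 grid over starting scales followed by Nelder–Mead on
log-parameters, clipped to e^[−7, 7]. The optimisation is deterministic.
Note that when the phyletic pattern contains many single-genome families
(e.g. island genes), the fitted scales are inflated relative to the
background process; the posterior-difference calls below are robust to
this because single-genome families still yield confident terminal gains.

Ancestral presence probabilities are marginal posteriors from the up–down
(inside–outside) recursion, computed per category pair and weighted by the
category posterior given the data; leaves return their observed state
exactly. Events are called per branch from posterior differences with the
strict rule ΔP > 0.5 (gain) / ΔP < −0.5 (loss); a difference of exactly
0.5 makes no call.

**Islands** are maximal runs of genes, in a genome's gene order, whose
families are called gained on that genome's terminal branch. Defaults:
`max_gap = 0` (no intervening non-gained genes; with a positive gap the
bridged genes are included in the island span and the run length counts
positions, not gained genes) and `min_size = 1`, since single-gene
acquisitions are biologically real. Islands never span contigs. All
gene-order coordinates are 1-based closed intervals over gene indices, not
nucleotides. Anchor retrieval keeps islands containing at least one gene
of a user-supplied family set; the neighborhood scan reports per-gene
windows (5 genes per side, truncated at contig edges) and loci of ≥ 2
marked genes separated by ≤ 5 other genes.

## Ortholog construction

Sequences are clustered greedily in decreasing length order: a sequence
joins the first existing centroid with global-alignment identity ≥ 0.5,
else founds a cluster. Identity is matches / alignment-length under a
global affine-gap alignment (BLOSUM62, open 11, extend 1, via Biopython's
PairwiseAligner); the choice of denominator makes a sequence fused from
two domains score ≤ 0.5 against either single domain, which is what lets
fusions separate from their components.

Cluster alignments are progressive profile–profile alignments over an
average-linkage guide tree on 3-mer distances; the profile–profile step is
a global Gotoh alignment whose column score is the BLOSUM62-weighted dot
product of column frequency vectors (gaps dilute a column's vector), with
the same 11/1 gap costs in half-bit units. Consensus sequences take the
plurality residue of every column with occupancy ≥ 0.5 (ties broken
alphabetically). PSSMs are per-column half-bit log-odds of pseudocounted
frequencies (pseudocount 0.5, BLOSUM62-marginal background).

Profile searches run Smith–Waterman of the PSSM against each database
sequence (numba kernels). Significance is calibrated per target by fitting
a Gumbel distribution to the scores of 100 residue-shuffled copies of that
target; the e-value is the Gumbel tail probability times the database
size, cutoff 1e-4. A match covering ≥ 75% of the query profile is
full-length (boundary inclusive). Mutual full-length matches merge two
clusters (profile–profile alignment); a one-way full-length match from a
deeper cluster into a longer, shallower one cuts the longer alignment into
before/within/after segments at the footprint — putative domains.

Family trees are neighbor joining on Poisson-corrected p-distances
(p computed over columns where both rows have residues, capped at 0.95
before −ln(1−p)), midpoint-rooted. Ortholog clades are peeled off
iteratively: among all nodes of the current induced tree — leaves included,
which guarantees termination on paralog-only trees — the subtree maximising
S_C²/(S_T·N_C) is extracted and its leaves pruned; S_T stays fixed at the
full tree's species count. Ties prefer larger clades, then earlier
preorder position (both tie-breaks are repo conventions; the index itself
does not order them). A cluster is re-examined by tree extraction when its
mean paralog count per species exceeds 1.5 — a repo default, exposed as a
parameter. The merge-and-split round repeats until the partition is stable
(default ≤ 10 iterations, warning on non-convergence).

## Conservation profiles and homogeneity

Occupancy is the fraction of selected rows with a residue in a column; the
row subset is a predicate (e.g. unaligned length < 700 or > 700 residues,
the two panels used for modular-protein alignments). Homogeneity is

    h = (S̄_obs − S̄_rand) / (S̄_self − S̄_rand), clipped to [0, 1]

with S̄_obs the mean pairwise BLOSUM62 score among the column's residues,
S̄_rand the expected pair score under the background composition (a
constant, ≈ −0.58 half-bits), and S̄_self the composition-weighted mean
diagonal score. The two anchors are exact: a fully conserved column scores
1 regardless of residue identity, and background-random columns score 0 in
expectation (the clipping truncates sampling noise below 0, leaving a mean
|h| ≈ 0.01 for 30-row columns). This specific functional form is this
package's operationalisation of a "1 = conserved, 0 = random mixture"
conservation scale; columns with fewer than two residues are masked (NaN).
Smoothing is a centred moving average (default window 25 columns, odd
windows only) that ignores masked entries and truncates at the edges.
Region calling reports maximal runs below/above a threshold with a minimum
length.

## C-terminal tree, clades and the recombination test

The C-terminal region is the last n alignment columns (default 200 — the
approximate cassette length; adjustable); rows entirely gapped in the
window are dropped. Its tree is NJ/Poisson/midpoint as above, with branch
supports from column-bootstrap replicates (default 100; supports are the
fraction of replicates containing the same unrooted split). Tight clades
are maximal clades with support ≥ 0.7 and patristic diameter ≤ 0.1
substitutions/site, labelled A, B, … in preorder; both thresholds are repo
defaults exposed as flags, since "well-supported branches of closely
similar sequences" admits several operationalisations.

The incongruence statistic D̄ is the mean species-tree patristic distance
between the species of same-clade member pairs (same-species pairs
contribute 0). The null permutes species labels across all clade members
(default 999 permutations, seeded); the report carries the null mean/sd, a
z-score, and the one-sided p_low = P(null ≤ observed). Small p_low means
same-cassette sequences sit close on the species tree — vertical
inheritance; p_low compatible with uniform (z ≈ 0) means cassette sharing
ignores the species tree — the recombination signature. The test direction
and α = 0.05 are package choices for a qualitative claim; no breakpoint
detection is attempted (nucleotide-level recombination mapping is out of
scope).

Motif scanning uses a small degenerate-pattern grammar (literal residues,
`[..]` classes, `x` wildcard) with an optional window restricting matches
to the last w residues (w = 15 for the `D[ND]NxxxG[GD]` sorting signal).
Conserved-column queries report columns where a residue or residue class
reaches a frequency threshold among non-gap rows (default 0.9), with a
helper for consecutive-column motifs such as the GN di-column.

## Simulator: what it emulates, and what it does not

`simulate_species_tree` draws a pure-birth (Yule) tree, unit birth rate,
rescaled to height 1 so all rates are per total-depth units; leaves are
G01…; determinism is per seed. `simulate_gene_content` draws per-family
rates (gamma × scale), a stationary root state, and then node states from
the exact transition kernel — states are sampled at nodes, so the truth
log records net per-branch endpoint changes (at most one event per family
and branch), which is exactly what ΔP-based inference can hope to see.
`simulate_islands` inserts blocks of novel families (sizes uniform on
1–25 by default) at distinct points of one genome's gene order; island
families occur in that genome only, as one contiguous block, and are
logged with coordinates and as terminal-branch gains.

`simulate_vartig_proteins` builds 740-residue proteins: a 380-residue
conserved core carrying a GN di-column and an invariant serine, a
160-residue tandem-repeat region, and a 200-residue C-terminal cassette
drawn from a pool of `cterm_pool_size` unrelated variants. Every variant
carries two fixed cysteine columns in its distal half and a
`D[ND]NxxxG[GD]` signal inside the last 15 residues; these feature columns
are frozen during sequence evolution. The core evolves along the tree by
per-site replacement with probability 1 − e^{−sub_rate·t}, replacement
residues drawn from BLOSUM62-conditional frequencies; each protein's
cassette gets the same substitution process over a fixed small divergence
time (0.2 units) so that same-variant cassettes stay tight (~4% distance)
while different variants stay saturated. Cassette choice is the model's
recombination knob: lineage-matched variant (contiguous blocks of the tip
order share a variant) with probability 1 − recomb_prob, else uniform from
the pool — applied to the long loci and to the one short cassette-only
paralog per genome alike. The emitted "true alignment" has no indels (long
rows fill all columns, short rows occupy the cassette columns), so
alignment reconstruction is deliberately not part of what downstream tests
exercise. Indels, codon/DNA-level evolution and any mechanistic model of
how cassette variants arise are intentionally absent: the pool-based
shuffle is a modelling device for exchange, not a claim about mechanism.

Defaults are the standing study conditions: 10 genomes, 500 background
families, g0 = 0.5 and l0 = 1.0 with α = 1 (gain slower than loss, as in
prokaryotic gene-content analyses), 15 islands of 1–25 genes, 2 long loci
per genome, cassette pool 6, recomb_prob 0.8, sub_rate 0.1. Because these
passing tests run on no-indel truth alignments and single-contig genomes,
they demonstrate correctness of the inference chain, not robustness to
alignment error, assembly fragmentation or annotation noise in real data.

At this background turnover roughly 40% of terminal-branch gains in the
truth are background families, and a minority of those are genuinely
ambiguous (the sampled history differs from the posterior mode — e.g. a
single-leaf presence produced by a deep gain plus losses). Island-recovery
runs therefore measure, at gene level, about 0.83 sensitivity/precision
against the full truth even when the true generating parameters are
supplied — the Bayes limit of the ΔP rule under these conditions — while
recovering planted island genes essentially completely.

## Numerical conventions

- All intervals in tables and APIs are 1-based and closed.
- p-distances are capped at 0.95 before Poisson correction; negative NJ
  branch lengths are clamped to 0 before midpoint rooting.
- Consensus ties break alphabetically; clade-extraction ties break by
  size then preorder; greedy clustering orders by length then id.
- Gumbel fits degenerate decoy score sets (sd < 1e-9) fall back to a 0/1
  p-value by score comparison.
- All randomness flows from explicit seeds; identical seeds give
  byte-identical artifacts end to end (this is tested).

## Problem sizes used by the checks

Oracle equivalences run on trees of ≤ 6 leaves (likelihood/posteriors,
exhaustive enumeration) and ≤ 12 leaves (clade extraction, independent
dendropy-based enumeration), 100 instances each. Parameter recovery uses
1000 families on 20 genomes; island recovery the default 10-genome
configuration; the recombination-regime check 20 replicates per regime
with 499 permutations; the motif oracle 10^4 random sequences. These sizes
were chosen to make every property measurable in seconds to a few minutes
on one core.
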