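# vartig

Comparative-genomics tooling for discovering and characterising
**hypervariable, recently acquired gene modules** in prokaryotic genomes —
the analysis pattern behind lineage-specific surface/immunity systems whose
loci are gained as genomic islands on terminal branches and whose key
protein carries a hypervariable, recombining C-terminal Ig-domain cassette.

The package is aimed at microbial comparative genomicists who have a set of
proteomes, a species tree and per-genome gene orders, and want to run the
whole chain in a reproducible, testable form:

1. **Ortholog construction** (`vartig.cogs`): greedy clustering at global
   identity ≥ 0.5, progressive profile alignment, consensus/PSSM searches
   with shuffle-calibrated e-values (cutoff 1e-4), the 75% full-length rule
   for merging clusters and cutting fused alignments at domain footprints,
   and iterative extraction of ortholog clades from midpoint-rooted NJ
   family trees by maximising the trade-off index
   **S_C² / (S_T · N_C)** (N_C = leaves in the clade, S_C / S_T = species in
   the clade / in the whole tree).
2. **Gene gain/loss reconstruction** (`vartig.gainloss`): a two-state
   Markov model of presence/absence with independent gamma-distributed gain
   and loss rates (discretised, Felsenstein pruning, stationary root
   prior), marginal ancestral posteriors, and event calls from posterior
   differences: **ΔP = P_descendant − P_ancestral > 0.5 ⇒ gain**,
   ΔP < −0.5 ⇒ loss. Maximal runs of genes gained on a genome's terminal
   branch are reported as **recently acquired islands**; anchor-family
   retrieval and gene-neighborhood scans (≥2 marked genes separated by ≤5
   others) reproduce the locus-hunting strategies used on real genomes.
3. **Hypervariability & recombination analysis** (`vartig.variability`):
   per-column alignment occupancy and **homogeneity** (1 = perfectly
   conserved column, 0 = random residue mixture), smoothed profiles and
   region calling; extraction of the ~200-column C-terminal region, a
   bootstrap-supported NJ tree of it, tight clades (support ≥ 0.7,
   patristic diameter ≤ 0.1) labelled A, B, …, and a permutation test for
   whether those clades follow the species tree (vertical signal) or are
   scattered across it (the recombination signature); PROSITE-style
   degenerate motif scans such as `D[ND]NxxxG[GD]` restricted to the last
   15 residues, and conserved-column queries (invariant Ser, paired Cys,
   GN di-column).
4. **A forward simulator** (`vartig.simulate`) generating species trees,
   gene-content histories with island-style terminal acquisitions (island
   sizes 1–25 genes), and modular proteins with a conserved core and a
   shuffled C-terminal cassette — with a full ground-truth log, so every
   stage is testable without downloading anything.

## Worked example

Run the full pipeline on a simulated dataset (10 genomes, 500 background
gene families, 15 planted islands, 8-species C-terminal cassette pool with
recombination probability 0.8):

```python
from vartig.pipeline import RunConfig, run_pipeline
from vartig.simulate import SimConfig

cfg = RunConfig(sim=SimConfig(seed=7), n_boot=50, n_perm=499)
res = run_pipeline(cfg, "demo_out")
```

which prints (via the summary fields of `res`):

```
fitted gain/loss scales: g0=0.727, l0=5.367
gain/loss calls: 561
islands detected: 176 (anchored: 12)
tight C-terminal clades: 6
incongruence: D-bar=1.406, null=1.369+-0.079, p_low=0.626
proteins with the C-terminal sorting signal: 30/30
island sizes: min=1, max=23
```

Reading this: the model calls 561 gain/loss events; 176 maximal runs of
terminally gained genes are flagged as islands, 12 of which contain an
anchor gene of the simulated hypervariable module (one per planted locus,
matching the plant). Note the fitted turnover scales are inflated relative
to the background process because the ~200 island families — each present
in a single genome — look like fast-cycling genes to the model; that is
expected, and the ΔP>0.5 calls on terminal branches are insensitive to it.
The C-terminal tree resolves 6 tight clades of closely similar cassettes,
and the incongruence test does **not** find a vertical signal
(`p_low = 0.626`, D-bar ≈ null mean): the cassette variants are scattered
across the species tree, exactly the recombination signature the module
was simulated with (`recomb_prob = 0.8`). All 30 proteins carry the
`D[ND]NxxxG[GD]` sorting signal within their last 15 residues. Re-running
with `recomb_prob=0` flips the test to `p_low ≈ 0.002` (vertical
inheritance detected).

The same stages are available from a shell:

```bash
vartig simulate --seed 7 --out sim/
vartig build-cogs --faa sim/proteins.faa --out cogs/
vartig gainloss --tree sim/species_tree.nwk --pattern sim/pattern.tsv \
    --genes sim/genes_G01.tsv --out gl/
vartig cterm --aln sim/true_alignment.afa --species-tree sim/species_tree.nwk --out ct/
vartig motifs --faa sim/proteins.faa --out motifs.tsv
vartig run-all --seed 7 --out run/
```

All tables are TSV with 1-based closed coordinates (stated in their header
comments); trees are newick; every stage is byte-deterministic given the
config seed.

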