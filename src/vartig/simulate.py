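"""Forward simulator for gene-content evolution and modular surface proteins.

The generator produces everything the downstream stages consume, plus a
ground-truth log:

* a pure-birth (Yule) species tree rescaled to height 1;
* per-family presence/absence histories under a two-state Markov gain/loss
  process with gamma-distributed per-family rates;
* ordered per-genome gene tables with island-style blocks of novel families
  inserted on terminal branches (block sizes 1-25 genes by default);
* multi-domain "VARTIG-like" protein families: a conserved N-terminal core
  (embedding a GN motif and an invariant serine), a low-complexity repeat
  region, and a ~200-residue C-terminal cassette drawn from a small pool of
  variants that is exchanged across lineages with probability
  ``recomb_prob`` — the recombination knob. Every long protein carries two
  conserved cysteines in the distal segment and a D[ND]NxxxG[GD] sorting
  signal within its last 15 residues; short paralogs consist of the
  C-terminal cassette only.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as vio
from .alphabet import AA, BACKGROUND, REPLACEMENT_PROBS, decode
from .cogs import Msa, SequenceRecord
from .gainloss import PhyleticPattern
from .trees import tree_arrays

# --- protein architecture constants (residue coordinates, 0-based) ---------
CORE_LEN = 380          # conserved N-terminal core
REPEAT_LEN = 160        # low-complexity repeat region
CTERM_LEN = 200         # exchangeable C-terminal cassette
LONG_LEN = CORE_LEN + REPEAT_LEN + CTERM_LEN  # 740 > 700
GN_COL = 150            # G of the GN motif (core coordinates)
SER_COL = 170           # invariant serine
CYS_COLS = (60, 110)    # paired cysteines (cassette coordinates)
MOTIF_START = 189       # D[ND]NxxxG[GD] start (cassette coordinates)
REPEAT_UNIT = 20
# per-protein divergence time applied to the drawn cassette, in the same
# branch-length units as the tree (height 1): keeps same-variant cassettes
# tight and distinct variants clearly separated
CTERM_NOISE_TIME = 0.2


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults are the standing setup."""

    n_genomes: int = 10
    n_families: int = 500
    gain_scale: float = 0.5     # g0, events per unit branch length
    loss_scale: float = 1.0     # l0
    alpha_gain: float = 1.0     # gamma shape of per-family gain rates
    alpha_loss: float = 1.0
    n_islands: int = 15
    island_size_range: tuple[int, int] = (1, 25)
    n_vartig_loci: int = 2      # long proteins per genome
    cterm_pool_size: int = 6
    recomb_prob: float = 0.8
    sub_rate: float = 0.1       # substitutions/site per unit branch length
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.island_size_range
        if not (1 <= lo <= hi <= 10_000):
            raise ValueError("island_size_range must lie within [1, 10^4]")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ValueError("recomb_prob must be in [0, 1]")
        for name in ("gain_scale", "loss_scale", "alpha_gain", "alpha_loss", "sub_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.cterm_pool_size < 1:
            raise ValueError("cterm_pool_size must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        if "island_size_range" in d:
            d["island_size_range"] = tuple(d["island_size_range"])
        return cls(**d)


@dataclass
class TruthLog:
    """Ground truth emitted by the simulator.

    events: (branch id = child node name, family id, "gain"|"loss") — net
    endpoint changes per branch. islands: dicts with genome, contig,
    start, end (1-based closed gene positions) and family ids.
    """

    events: list = field(default_factory=list)
    islands: list = field(default_factory=list)
    cterm_assignments: dict = field(default_factory=dict)
    motif_positions: dict = field(default_factory=dict)

    def terminal_gains(self, genomes) -> dict:
        """Per-genome set of families gained on that terminal branch."""
        gset = set(genomes)
        out = {g: set() for g in gset}
        for branch, fam, kind in self.events:
            if kind == "gain" and branch in gset:
                out[branch].add(fam)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [list(e) for e in self.events],
                "islands": self.islands,
                "cterm_assignments": self.cterm_assignments,
                "motif_positions": self.motif_positions,
            },
            indent=1,
            sort_keys=True,
        )


# --------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth tree with ``n_taxa`` leaves, rescaled to height 1.

    Lineages split at unit rate; leaf labels G01.. are assigned in tree
    (tip) order, internal nodes are named N1.. with the root named "root".
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name="root")
    c1, c2 = TreeNode(), TreeNode()
    root.extend([c1, c2])
    active = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.length = t - born
        a, b = TreeNode(), TreeNode()
        node.extend([a, b])
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / n_taxa)
    for node, born in active:
        node.length = t - born
    for node in root.traverse(include_self=False):
        node.length = node.length / t
    width = max(2, len(str(n_taxa)))
    for i, tip in enumerate(root.tips(), 1):
        tip.name = f"G{i:0{width}d}"
    j = 0
    for node in root.traverse(include_self=False):
        if not node.is_tip():
            j += 1
            node.name = f"N{j}"
    return root


# --------------------------------------------------------------------------
# gene content


def _draw_rates(cfg: SimConfig, rng, n: int):
    if cfg.alpha_gain > 0 and cfg.gain_scale > 0:
        g = cfg.gain_scale * rng.gamma(cfg.alpha_gain, 1.0 / cfg.alpha_gain, size=n)
    else:
        g = np.full(n, cfg.gain_scale)
    if cfg.alpha_loss > 0 and cfg.loss_scale > 0:
        l = cfg.loss_scale * rng.gamma(cfg.alpha_loss, 1.0 / cfg.alpha_loss, size=n)
    else:
        l = np.full(n, cfg.loss_scale)
    return g, l


def simulate_gene_content(
    tree: TreeNode, cfg: SimConfig, rng=None, truth: TruthLog | None = None
) -> tuple[PhyleticPattern, TruthLog]:
    """Evolve presence/absence for ``cfg.n_families`` families on the tree.

    Per-family gain/loss rates are gamma(alpha) * scale; the root state is
    drawn from the per-family stationary distribution; states at child
    nodes are sampled from the exact two-state transition probabilities.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = TruthLog()
    ta = tree_arrays(tree)
    nfam = cfg.n_families
    g, l = _draw_rates(cfg, rng, nfam)
    tot = g + l
    with np.errstate(invalid="ignore", divide="ignore"):
        pi1 = np.where(tot > 0, g / np.where(tot > 0, tot, 1.0), 0.5)
    states = np.zeros((ta.n_nodes, nfam), dtype=bool)
    states[ta.root] = rng.random(nfam) < pi1
    families = [f"FAM{i:05d}" for i in range(nfam)]
    for node in ta.postorder[::-1]:
        if node == ta.root:
            continue
        t = ta.length[node]
        decay = np.where(tot > 0, -np.expm1(-tot * t), 0.0)
        p01 = pi1 * decay
        p10 = np.where(tot > 0, l / np.where(tot > 0, tot, 1.0), 0.5) * decay
        parent_state = states[ta.parent[node]]
        u = rng.random(nfam)
        child = np.where(parent_state, u >= p10, u < p01)
        states[node] = child
        name = ta.node_names[node]
        for f in np.nonzero(child & ~parent_state)[0]:
            truth.events.append((name, families[f], "gain"))
        for f in np.nonzero(parent_state & ~child)[0]:
            truth.events.append((name, families[f], "loss"))
    presence = states[: ta.n_leaves].T.astype(np.int8)
    pattern = PhyleticPattern(families=families, genomes=list(ta.leaf_names), presence=presence)
    return pattern, truth


def make_gene_tables(pattern: PhyleticPattern, rng) -> pd.DataFrame:
    """Ordered background gene tables: one contig per genome, random order."""
    rows = []
    for j, genome in enumerate(pattern.genomes):
        fams = [pattern.families[i] for i in np.nonzero(pattern.presence[:, j])[0]]
        order = rng.permutation(len(fams))
        for pos, k in enumerate(order, start=1):
            rows.append((genome, "c1", pos, f"{genome}_g{pos:04d}", fams[k]))
    return pd.DataFrame(rows, columns=vio.GENE_TABLE_COLUMNS)


def simulate_islands(
    tree: TreeNode, genes: pd.DataFrame, cfg: SimConfig, rng=None,
    truth: TruthLog | None = None,
) -> tuple[pd.DataFrame, TruthLog]:
    """Insert blocks of novel families on terminal branches.

    Each island is a contiguous block of new families inserted into one
    genome's gene order; island families occur nowhere else. Coordinates
    and membership go to the truth log, and a terminal-branch gain event
    is recorded per island family.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = TruthLog()
    genomes = [t.name for t in tree.tips()]
    lo, hi = cfg.island_size_range
    plan: dict[str, list] = {g: [] for g in genomes}
    for i in range(cfg.n_islands):
        genome = genomes[int(rng.integers(len(genomes)))]
        size = int(rng.integers(lo, hi + 1))
        fams = [f"ISL{i:03d}_{j:02d}" for j in range(size)]
        plan[genome].append((i, fams))
    out = []
    for genome in genomes:
        sub = genes[genes.genome == genome].sort_values("position")
        background = list(sub.itertuples(index=False))
        if plan[genome]:
            cap = len(background)
            if cap == 0:
                raise ValueError(
                    f"cannot insert an island into {genome}: its contig has "
                    "no capacity (no background genes)"
                )
            if len(plan[genome]) > cap + 1:
                raise ValueError(
                    f"more islands than insertion points in {genome}"
                )
            gaps = rng.choice(cap + 1, size=len(plan[genome]), replace=False)
            inserts = dict(zip(np.sort(gaps), [plan[genome][k] for k in np.argsort(gaps)]))
        else:
            inserts = {}
        pos = 0
        rows = []

        def emit(contig, gene_id, fam):
            nonlocal pos
            pos += 1
            rows.append((genome, contig, pos, gene_id, fam))

        for gap in range(len(background) + 1):
            if gap in inserts:
                idx, fams = inserts[gap]
                start = pos + 1
                for j, fam in enumerate(fams):
                    emit("c1", f"{genome}_i{idx:03d}_{j:02d}", fam)
                    truth.events.append((genome, fam, "gain"))
                truth.islands.append(
                    {"genome": genome, "contig": "c1", "start": start,
                     "end": pos, "families": list(fams)}
                )
            if gap < len(background):
                row = background[gap]
                emit(row.contig, row.gene_id, row.family_id)
        out.append(pd.DataFrame(rows, columns=vio.GENE_TABLE_COLUMNS))
    merged = pd.concat(out, ignore_index=True)
    return merged, truth


def extend_pattern(pattern: PhyleticPattern, truth: TruthLog) -> PhyleticPattern:
    """Append island families (present in their single genome) to a pattern."""
    extra_fams = []
    cols = []
    gidx = {g: j for j, g in enumerate(pattern.genomes)}
    for isl in truth.islands:
        for fam in isl["families"]:
            v = np.zeros(len(pattern.genomes), dtype=np.int8)
            v[gidx[isl["genome"]]] = 1
            extra_fams.append(fam)
            cols.append(v)
    if not extra_fams:
        return pattern
    presence = np.vstack([pattern.presence, np.array(cols, dtype=np.int8)])
    return PhyleticPattern(
        families=list(pattern.families) + extra_fams,
        genomes=list(pattern.genomes),
        presence=presence,
    )


# --------------------------------------------------------------------------
# VARTIG-like proteins


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.choice(20, size=n, p=BACKGROUND).astype(np.int8)


def _evolve(seq: np.ndarray, t: float, sub_rate: float, rng, frozen=None) -> np.ndarray:
    """Per-site replacement with prob 1-exp(-sub_rate*t); BLOSUM62-conditional
    replacement residues; frozen positions never change."""
    p = -np.expm1(-sub_rate * t)
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    if frozen is not None:
        hit &= ~frozen
    for i in np.nonzero(hit)[0]:
        out[i] = rng.choice(20, p=REPLACEMENT_PROBS[out[i]])
    return out


def _make_variant(rng) -> np.ndarray:
    """A C-terminal cassette: random 200-mer with paired Cys and the
    D[ND]NxxxG[GD] sorting signal inside the last 15 residues."""
    v = _random_seq(rng, CTERM_LEN)
    c = AA.index("C")
    v[CYS_COLS[0]] = c
    v[CYS_COLS[1]] = c
    motif = [
        AA.index("D"),
        AA.index("ND"[int(rng.integers(2))]),
        AA.index("N"),
        int(rng.choice(20, p=BACKGROUND)),
        int(rng.choice(20, p=BACKGROUND)),
        int(rng.choice(20, p=BACKGROUND)),
        AA.index("G"),
        AA.index("GD"[int(rng.integers(2))]),
    ]
    v[MOTIF_START : MOTIF_START + 8] = motif
    return v


def _cterm_frozen_mask() -> np.ndarray:
    m = np.zeros(CTERM_LEN, dtype=bool)
    m[list(CYS_COLS)] = True
    m[MOTIF_START : MOTIF_START + 8] = True
    return m


def lineage_variants(tree: TreeNode, pool_size: int) -> dict:
    """Map each leaf to its lineage-matched cassette variant.

    Leaves in tip order are split into ``pool_size`` contiguous groups, so
    neighbouring lineages on the tree share a variant; this is the vertical
    (no-recombination) expectation.
    """
    leaves = [t.name for t in tree.tips()]
    groups = np.array_split(np.arange(len(leaves)), pool_size)
    out = {}
    for vid, grp in enumerate(groups):
        for i in grp:
            out[leaves[i]] = vid
    return out


def simulate_vartig_proteins(
    tree: TreeNode, cfg: SimConfig, rng=None, truth: TruthLog | None = None
) -> tuple[list[SequenceRecord], Msa, TruthLog]:
    """Simulate long (>700 aa) modular proteins plus short cassette paralogs.

    Long protein = core (evolved vertically along the tree) + repeats +
    cassette drawn from the pool (lineage-matched with prob 1-recomb_prob,
    else uniform). The true alignment has no indels: long rows fill all 740
    columns, short rows occupy the last 200.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = TruthLog()
    ta = tree_arrays(tree)
    core_frozen = np.zeros(CORE_LEN + REPEAT_LEN, dtype=bool)
    core_frozen[[GN_COL, GN_COL + 1, SER_COL]] = True
    root_core = _random_seq(rng, CORE_LEN + REPEAT_LEN)
    unit = _random_seq(rng, REPEAT_UNIT)
    for k in range(REPEAT_LEN // REPEAT_UNIT):
        root_core[CORE_LEN + k * REPEAT_UNIT : CORE_LEN + (k + 1) * REPEAT_UNIT] = unit
    root_core[GN_COL] = AA.index("G")
    root_core[GN_COL + 1] = AA.index("N")
    root_core[SER_COL] = AA.index("S")

    node_core = {ta.root: root_core}
    for node in ta.postorder[::-1]:
        if node == ta.root:
            continue
        parent = node_core[ta.parent[node]]
        node_core[node] = _evolve(parent, ta.length[node], cfg.sub_rate, rng, core_frozen)

    pool = [_make_variant(rng) for _ in range(cfg.cterm_pool_size)]
    cfrozen = _cterm_frozen_mask()
    lineage = lineage_variants(tree, cfg.cterm_pool_size)

    records: list[SequenceRecord] = []
    rows: list[tuple[str, str, str]] = []
    motif_pos_long = [
        ("GN", GN_COL + 1),
        ("SER", SER_COL + 1),
        ("CYS", CORE_LEN + REPEAT_LEN + CYS_COLS[0] + 1),
        ("CYS", CORE_LEN + REPEAT_LEN + CYS_COLS[1] + 1),
        ("CTERM_SORT", CORE_LEN + REPEAT_LEN + MOTIF_START + 1),
    ]
    for li, leaf in enumerate(ta.leaf_names):
        core = node_core[li]
        tlen = ta.length[li]
        for k in range(cfg.n_vartig_loci):
            if rng.random() < cfg.recomb_prob:
                vid = int(rng.integers(cfg.cterm_pool_size))
            else:
                vid = lineage[leaf]
            cterm = _evolve(pool[vid], CTERM_NOISE_TIME, cfg.sub_rate, rng, cfrozen)
            seq = decode(np.concatenate([core, cterm]))
            pid = f"{leaf}_V{k + 1}"
            records.append(SequenceRecord(id=pid, genome=leaf, residues=seq))
            rows.append((pid, leaf, seq))
            truth.cterm_assignments[pid] = vid
            truth.motif_positions[pid] = list(motif_pos_long)
        # one short paralog per genome: the cassette alone, drawn under the
        # same lineage-vs-pool rule as the long loci
        if rng.random() < cfg.recomb_prob:
            svid = int(rng.integers(cfg.cterm_pool_size))
        else:
            svid = lineage[leaf]
        scterm = _evolve(pool[svid], CTERM_NOISE_TIME, cfg.sub_rate, rng, cfrozen)
        sid = f"{leaf}_S1"
        sseq = decode(scterm)
        records.append(SequenceRecord(id=sid, genome=leaf, residues=sseq))
        rows.append((sid, leaf, "-" * (CORE_LEN + REPEAT_LEN) + sseq))
        truth.cterm_assignments[sid] = svid
        truth.motif_positions[sid] = [
            ("CYS", CYS_COLS[0] + 1),
            ("CYS", CYS_COLS[1] + 1),
            ("CTERM_SORT", MOTIF_START + 1),
        ]
        _ = tlen
    aln = Msa(rows=rows)
    return records, aln, truth


# --------------------------------------------------------------------------
# orchestration


def simulate_all(cfg: SimConfig, outdir=None):
    """Run every generator stage from one seed; optionally write artifacts.

    Returns dict with tree, pattern (islands included), genes, records,
    alignment, truth.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    tree = simulate_species_tree(cfg.n_genomes, cfg.seed)
    truth = TruthLog()
    pattern, truth = simulate_gene_content(
        tree, cfg, rng=np.random.default_rng(seeds[0]), truth=truth
    )
    genes = make_gene_tables(pattern, rng=np.random.default_rng(seeds[1]))
    genes, truth = simulate_islands(
        tree, genes, cfg, rng=np.random.default_rng(seeds[2]), truth=truth
    )
    full_pattern = extend_pattern(pattern, truth)
    records, aln, truth = simulate_vartig_proteins(
        tree, cfg, rng=np.random.default_rng(seeds[3]), truth=truth
    )
    result = {
        "tree": tree,
        "pattern": full_pattern,
        "genes": genes,
        "records": records,
        "alignment": aln,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vio.write_newick(tree, outdir / "species_tree.nwk")
        vio.write_fasta(records, outdir / "proteins.faa")
        vio.write_alignment(aln, outdir / "true_alignment.afa")
        for genome in full_pattern.genomes:
            vio.write_gene_table(
                genes[genes.genome == genome], outdir / f"genes_{genome}.tsv"
            )
        vio.write_pattern(full_pattern.to_frame(), outdir / "pattern.tsv")
        (outdir / "truth.json").write_text(truth.to_json() + "\n")
        (outdir / "simconfig.json").write_text(cfg.to_json() + "\n")
    return result
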