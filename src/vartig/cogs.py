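"""Lineage-specific clusters of orthologs from protein sets.

The construction follows the classic consensus/profile workflow: greedy
length-sorted clustering at a global-identity threshold, progressive
profile alignment, consensus extraction, PSSM searches of every cluster
profile against the consensus database with shuffle-calibrated e-values,
the 75% full-length rule to decide merging (mutual full-length matches)
versus domain splitting (a deeper alignment hitting part of a longer,
shallower one cuts it at the footprint), and finally tree-based ortholog
extraction: clades maximising S_C^2 / (S_T * N_C) — N_C leaves, S_C
species in the clade, S_T species in the whole tree — are peeled off a
midpoint-rooted NJ family tree until no leaves remain. Merge-and-split
rounds repeat until the partition is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.stats import gumbel_r
from Bio import Align
from Bio.Align import substitution_matrices

from ._align import gotoh_global, sw_pssm
from .alphabet import AA, BACKGROUND, BLOSUM62, GAP, encode
from .trees import nj_midpoint, p_distance_matrix, poisson_correct

GAP_OPEN = 11.0  # half-bit units, matching BLOSUM62
GAP_EXT = 1.0


@dataclass
class SequenceRecord:
    id: str
    genome: str
    residues: str

    def __post_init__(self):
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(AA + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self):
        return len(self.residues)


@dataclass
class Msa:
    """Aligned rows of (id, genome, gapped residues); columns all equal length."""

    rows: list

    def __post_init__(self):
        if self.rows:
            lens = {len(r[2]) for r in self.rows}
            if len(lens) != 1:
                raise ValueError("rows differ in length")
        self._mat = None

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        if self._mat is None:
            self._mat = np.vstack([encode(r[2]) for r in self.rows])
        return self._mat

    def ids(self) -> list:
        return [r[0] for r in self.rows]

    def drop_gap_columns(self) -> "Msa":
        mat = self.matrix()
        keep = (mat >= 0).any(axis=0)
        rows = [(i, g, "".join(s[j] for j in np.nonzero(keep)[0])) for i, g, s in self.rows]
        return Msa(rows=rows)


@dataclass
class Pssm:
    name: str
    scores: np.ndarray  # (n_cols, 20), half-bit log-odds
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())

    @property
    def n_cols(self) -> int:
        return self.scores.shape[0]


@dataclass
class FootprintMatch:
    query: str
    target: str
    query_start: int  # 1-based closed
    query_end: int
    target_start: int
    target_end: int
    score: float
    evalue: float


@dataclass
class CladeScore:
    n_leaves: int  # N_C
    n_species: int  # S_C
    n_species_total: int  # S_T
    index: float  # S_C^2 / (S_T * N_C)


# --------------------------------------------------------------------------
# clustering


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -GAP_OPEN
    a.extend_gap_score = -GAP_EXT
    a.mode = "global"
    return a


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (BLOSUM62,
    gap open 11, extend 1)."""
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def greedy_cluster(seqs, id_threshold: float = 0.5) -> list:
    """Centroid clustering: length-sorted sequences join the first centroid
    with identity >= threshold, otherwise found a new cluster."""
    if not 0 < id_threshold <= 1:
        raise ValueError("id_threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda r: (-len(r.residues), r.id))
    centroids: list[SequenceRecord] = []
    clusters: list[list[SequenceRecord]] = []
    for rec in ordered:
        placed = False
        for k, cen in enumerate(centroids):
            if pairwise_identity(cen.residues, rec.residues) >= id_threshold:
                clusters[k].append(rec)
                placed = True
                break
        if not placed:
            centroids.append(rec)
            clusters.append([rec])
    return clusters


# --------------------------------------------------------------------------
# profile alignment


def _freq_matrix(aln: Msa) -> np.ndarray:
    """(n_cols, 20) per-column residue frequencies over all rows (gaps
    dilute the column)."""
    mat = aln.matrix()
    ncol = mat.shape[1]
    f = np.zeros((ncol, 20))
    for a in range(20):
        f[:, a] = (mat == a).sum(axis=0)
    return f / max(mat.shape[0], 1)


def merge_profiles(a: Msa, b: Msa) -> Msa:
    """Global profile-profile alignment: column score is the BLOSUM62-
    weighted dot product of the column frequency vectors; affine gaps."""
    if not a.rows or not b.rows:
        raise ValueError("profiles must be non-empty")
    fa = _freq_matrix(a)
    fb = _freq_matrix(b)
    scores = fa @ BLOSUM62 @ fb.T
    n, apath, bpath = gotoh_global(scores, GAP_OPEN, GAP_EXT)
    rows = []
    for rid, genome, seq in a.rows:
        rows.append((rid, genome, "".join(seq[apath[k]] if apath[k] >= 0 else GAP for k in range(n))))
    for rid, genome, seq in b.rows:
        rows.append((rid, genome, "".join(seq[bpath[k]] if bpath[k] >= 0 else GAP for k in range(n))))
    return Msa(rows=rows)


def _kmer_set(seq: str, k: int = 3) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_cluster(members) -> Msa:
    """Progressive profile alignment over a k-mer-distance guide tree."""
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        m = members[0]
        return Msa(rows=[(m.id, m.genome, m.residues)])
    profiles = [Msa(rows=[(m.id, m.genome, m.residues)]) for m in members]
    if len(members) == 2:
        return merge_profiles(profiles[0], profiles[1])
    ksets = [_kmer_set(m.residues) for m in members]
    n = len(members)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(ksets[i]), len(ksets[j])) or 1
            cond.append(1.0 - len(ksets[i] & ksets[j]) / denom)
    z = linkage(np.array(cond), method="average")
    nodes = {i: profiles[i] for i in range(n)}
    for step, (i, j, _, _) in enumerate(z):
        nodes[n + step] = merge_profiles(nodes[int(i)], nodes[int(j)])
        del nodes[int(i)], nodes[int(j)]
    (result,) = nodes.values()
    return result


def consensus_with_map(aln: Msa, name: str = "consensus"):
    """Consensus sequence plus the alignment column index (0-based) of each
    consensus position. Columns with occupancy < 0.5 are skipped; plurality
    residue, ties broken alphabetically."""
    if not aln.rows:
        raise ValueError("empty alignment")
    mat = aln.matrix()
    nrow = mat.shape[0]
    out = []
    colmap = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        nongap = col[col >= 0]
        if len(nongap) / nrow < 0.5:
            continue
        counts = np.bincount(nongap, minlength=20)
        best = int(np.argmax(counts))  # argmax takes the lowest index on ties
        out.append(AA[best])
        colmap.append(j)
    return SequenceRecord(id=name, genome="", residues="".join(out)), colmap


def consensus_of(aln: Msa) -> SequenceRecord:
    rec, _ = consensus_with_map(aln)
    return rec


def build_pssm(aln: Msa, pseudocount: float = 0.5, name: str = "pssm") -> Pssm:
    """Per-column half-bit log-odds of pseudocounted frequencies versus the
    background composition."""
    if not aln.rows:
        raise ValueError("empty alignment")
    mat = aln.matrix()
    ncol = mat.shape[1]
    counts = np.zeros((ncol, 20))
    for a in range(20):
        counts[:, a] = (mat == a).sum(axis=0)
    n = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount * BACKGROUND) / (n + pseudocount)
    scores = 2.0 * np.log2(freq / BACKGROUND)
    return Pssm(name=name, scores=scores)


def profile_search(
    query: Pssm,
    db,
    evalue_cutoff: float = 1e-4,
    n_decoys: int = 100,
    seed: int = 0,
) -> list[FootprintMatch]:
    """Local PSSM search against a sequence database.

    Each target is scored by Smith-Waterman with affine gaps; significance
    comes from a Gumbel (extreme-value) fit to the scores of ``n_decoys``
    residue-shuffled copies of that target, scaled by the database size.
    Matches with e-value <= cutoff are returned best first.
    """
    if n_decoys < 10:
        raise ValueError("n_decoys must be >= 10 for a stable extreme-value fit")
    if not db:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    out = []
    for rec in db:
        enc = encode(rec.residues)
        score, qs, qe, ts, te = sw_pssm(query.scores, enc, GAP_OPEN, GAP_EXT)
        if qs < 0:
            continue
        decoys = np.empty(n_decoys)
        for d in range(n_decoys):
            decoys[d] = sw_pssm(query.scores, rng.permutation(enc), GAP_OPEN, GAP_EXT)[0]
        if decoys.std() < 1e-9:
            pval = 0.0 if score > decoys.mean() else 1.0
        else:
            loc, scale = gumbel_r.fit(decoys)
            pval = float(gumbel_r.sf(score, loc, scale))
        evalue = pval * len(db)
        if evalue <= evalue_cutoff:
            out.append(
                FootprintMatch(
                    query=query.name, target=rec.id,
                    query_start=qs + 1, query_end=qe + 1,
                    target_start=ts + 1, target_end=te + 1,
                    score=float(score), evalue=evalue,
                )
            )
    out.sort(key=lambda m: (-m.score, m.target))
    return out


def classify_match(m: FootprintMatch, query_len: int) -> str:
    """"full_length" when the query footprint covers at least 75% of the
    query, else "partial"."""
    if not (1 <= m.query_start <= m.query_end <= query_len):
        raise ValueError("footprint outside query bounds")
    coverage = (m.query_end - m.query_start + 1) / query_len
    return "full_length" if coverage >= 0.75 else "partial"


def split_by_footprint(aln: Msa, footprint: tuple) -> list[Msa]:
    """Cut an alignment into before / within / after a column footprint
    (1-based closed); empty blocks are dropped, row order preserved."""
    start, end = footprint
    if start > end:
        raise ValueError("inverted footprint interval")
    if not (1 <= start and end <= aln.n_cols):
        raise ValueError("footprint outside alignment")
    bounds = [(0, start - 1), (start - 1, end), (end, aln.n_cols)]
    out = []
    for lo, hi in bounds:
        if hi > lo:
            out.append(Msa(rows=[(i, g, s[lo:hi]) for i, g, s in aln.rows]))
    return out


# --------------------------------------------------------------------------
# family trees and clade extraction


def family_tree(aln: Msa):
    """Midpoint-rooted NJ tree from Poisson-corrected p-distances."""
    if aln.n_rows < 3:
        raise ValueError("family tree needs at least 3 sequences")
    d = poisson_correct(p_distance_matrix(aln.matrix()))
    return nj_midpoint(d, aln.ids())


def extract_clades(tree, species_of: dict) -> list:
    """Iteratively peel off the subtree maximising S_C^2 / (S_T * N_C).

    All nodes (leaves included) of the current induced tree are candidates;
    S_T is fixed to the species count of the full tree. Ties prefer larger
    clades, then earlier preorder position. Returns (member list,
    CladeScore) pairs; members partition the leaf set.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [x for x in leaves if x not in species_of]
    if missing:
        raise ValueError(f"leaves without species mapping: {missing}")
    s_total = len({species_of[x] for x in leaves})
    preorder_clades = []
    for rank, node in enumerate(tree.preorder(include_self=True)):
        clade = frozenset(t.name for t in node.tips(include_self=True))
        preorder_clades.append((rank, clade))
    remaining = set(leaves)
    result = []
    while remaining:
        best_key = None
        best_clade = None
        seen = set()
        for rank, clade in preorder_clades:
            c = clade & remaining
            if not c:
                continue
            fc = frozenset(c)
            if fc in seen:
                continue
            seen.add(fc)
            nc = len(c)
            sc = len({species_of[x] for x in c})
            idx = sc * sc / (s_total * nc)
            key = (idx, nc, -rank)
            if best_key is None or key > best_key:
                best_key = key
                best_clade = fc
        members = sorted(best_clade)
        nc = len(members)
        sc = len({species_of[x] for x in members})
        result.append(
            (members, CladeScore(n_leaves=nc, n_species=sc, n_species_total=s_total,
                                 index=sc * sc / (s_total * nc)))
        )
        remaining -= best_clade
    return result


# --------------------------------------------------------------------------
# iterative COG construction


@dataclass
class Cog:
    id: str
    members: list  # SequenceRecord
    alignment: Msa


def _mean_paralogs_per_species(aln: Msa) -> float:
    species = [g for _, g, _ in aln.rows]
    if not species:
        return 0.0
    uniq = set(species)
    return len(species) / len(uniq)


def _partition_key(alns) -> frozenset:
    return frozenset(frozenset(a.ids()) for a in alns)


def cog_iterate(
    seqs,
    species_of: dict,
    max_iter: int = 10,
    id_threshold: float = 0.5,
    evalue_cutoff: float = 1e-4,
    n_decoys: int = 100,
    paralog_threshold: float = 1.5,
    seed: int = 0,
) -> list[Cog]:
    """Full COG construction: cluster, align, merge-and-split via profile
    searches and the 75% rule, then tree-based ortholog extraction for
    paralog-rich clusters; repeated until the partition stops changing."""
    seqs = list(seqs)
    rec_of = {s.id: s for s in seqs}
    clusters = greedy_cluster(seqs, id_threshold)
    alns = [align_cluster(c) for c in clusters]
    for it in range(max_iter):
        before = _partition_key(alns)
        alns = _merge_split_round(alns, evalue_cutoff, n_decoys, seed + it)
        alns = _extract_round(alns, species_of, paralog_threshold)
        if _partition_key(alns) == before:
            break
    else:
        warnings.warn(f"cog_iterate did not converge in {max_iter} iterations")
    cogs = []
    for k, a in enumerate(sorted(alns, key=lambda a: sorted(a.ids()))):
        members = [rec_of[i] for i in a.ids()]
        cogs.append(Cog(id=f"COG{k + 1:04d}", members=members, alignment=a))
    return cogs


def _merge_split_round(alns, evalue_cutoff, n_decoys, seed):
    cons = []
    for k, a in enumerate(alns):
        rec, colmap = consensus_with_map(a, name=str(k))
        cons.append((rec, colmap))
    db = [rec for rec, _ in cons if rec.residues]
    full = {}
    for k, a in enumerate(alns):
        pssm = build_pssm(a, name=str(k))
        try:
            matches = profile_search(pssm, db, evalue_cutoff, n_decoys, seed=seed + k)
        except ValueError:
            continue
        for m in matches:
            j = int(m.target)
            if j == k:
                continue
            if classify_match(m, pssm.n_cols) == "full_length":
                full[(k, j)] = m
    # mutual full-length matches merge (union-find over cluster indices)
    parent = list(range(len(alns)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged_idx = set()
    for (k, j) in sorted(full):
        if (j, k) in full:
            a, b = find(k), find(j)
            if a != b:
                parent[max(a, b)] = min(a, b)
            merged_idx.update((k, j))
    # one-way full-length match from a deeper cluster into a longer,
    # shallower one: cut the longer alignment at the footprint
    splits = {}
    for (k, j), m in sorted(full.items()):
        if (j, k) in full or k in merged_idx or j in merged_idx or j in splits:
            continue
        if alns[k].n_rows > alns[j].n_rows and alns[j].n_cols > alns[k].n_cols:
            colmap = cons[j][1]
            lo = colmap[m.target_start - 1] + 1
            hi = colmap[m.target_end - 1] + 1
            splits[j] = (lo, hi)
    groups = {}
    for k in range(len(alns)):
        groups.setdefault(find(k), []).append(k)
    out = []
    for root, idxs in sorted(groups.items()):
        if len(idxs) == 1:
            k = idxs[0]
            if k in splits:
                out.extend(s.drop_gap_columns() for s in split_by_footprint(alns[k], splits[k]))
            else:
                out.append(alns[k])
        else:
            acc = alns[idxs[0]]
            for k in idxs[1:]:
                acc = merge_profiles(acc, alns[k])
            out.append(acc)
    return out


def _extract_round(alns, species_of, paralog_threshold):
    out = []
    for a in alns:
        if a.n_rows >= 3 and _mean_paralogs_per_species(a) > paralog_threshold:
            tree = family_tree(a)
            parts = extract_clades(tree, {i: species_of[i] for i in a.ids()})
            if len(parts) > 1:
                by_id = {i: (i, g, s) for i, g, s in a.rows}
                for members, _ in parts:
                    sub = Msa(rows=[by_id[m] for m in members])
                    out.append(sub.drop_gap_columns())
                continue
        out.append(a)
    return out
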