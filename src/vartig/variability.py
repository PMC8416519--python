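"""Alignment hypervariability, C-terminal phylogeny and recombination signal.

Conservation is profiled per alignment column with two tracks: occupancy
(fraction of selected rows with a residue) and homogeneity, a BLOSUM62-based
score rescaled so that 1 means a perfectly conserved column and 0 the
expectation for a random background mixture:

    h = (S_obs - S_rand) / (S_self - S_rand), clipped to [0, 1]

where S_obs is the mean pairwise substitution score among the column's
residues, S_rand the expected pair score under background frequencies, and
S_self the composition-weighted mean diagonal score.

The recombination analysis extracts the last ~200 alignment columns, builds
a bootstrap-supported NJ tree, collects tight clades (well supported, small
patristic diameter), and tests whether same-clade sequences are close on
the species tree: mean same-clade species patristic distance against a
species-label permutation null. A small one-sided p (p_low) means vertical
inheritance; p_low near uniform with z ~ 0 means the variants are scattered
across the species tree — the recombination signature.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass

import numpy as np

from .alphabet import AA, AA_INDEX, BLOSUM62, RANDOM_PAIR_SCORE
from .cogs import Msa
from .trees import bipartitions, nj_midpoint, p_distance_matrix, patristic_matrix, poisson_correct


@dataclass
class AlignmentProfile:
    occupancy: np.ndarray
    homogeneity: np.ndarray  # NaN where fewer than 2 residues
    window: int | None = None
    occupancy_smooth: np.ndarray | None = None
    homogeneity_smooth: np.ndarray | None = None

    @property
    def n_cols(self) -> int:
        return len(self.occupancy)


@dataclass
class RegionCall:
    start: int  # 1-based closed column interval
    end: int
    mean_value: float
    label: str  # "hypervariable" | "conserved"


@dataclass
class CTermClade:
    label: str
    members: list
    support: float
    max_distance: float


@dataclass
class CTermCladeSet:
    clades: list

    def labels_of(self) -> dict:
        return {m: c.label for c in self.clades for m in c.members}

    def __iter__(self):
        return iter(self.clades)

    def __len__(self):
        return len(self.clades)


@dataclass
class IncongruenceReport:
    statistic: float  # mean same-clade species patristic distance
    null_mean: float
    null_sd: float
    z_score: float
    p_low: float
    n_perm: int
    n_pairs: int
    seed: int


@dataclass
class MotifHit:
    position: int  # 1-based start in the full sequence
    match: str


# --------------------------------------------------------------------------
# profiles


def _select_rows(aln: Msa, subset) -> list[int]:
    if subset is None:
        return list(range(aln.n_rows))
    if callable(subset):
        idx = [i for i, row in enumerate(aln.rows) if subset(row)]
    else:
        wanted = set(subset)
        idx = [i for i, (rid, _, _) in enumerate(aln.rows) if rid in wanted]
    return idx


def occupancy_profile(aln: Msa, subset=None) -> np.ndarray:
    """Per-column fraction of selected rows with a non-gap residue.

    ``subset`` is a predicate over (id, genome, gapped_seq) tuples, a
    collection of row ids, or None for all rows.
    """
    idx = _select_rows(aln, subset)
    if not idx:
        raise ValueError("subset selects no rows")
    mat = aln.matrix()[idx]
    return (mat >= 0).mean(axis=0)


def _column_counts(mat: np.ndarray) -> np.ndarray:
    """(n_cols, 20) residue counts; gaps and X excluded."""
    ncol = mat.shape[1]
    counts = np.zeros((ncol, 20))
    for a in range(20):
        counts[:, a] = (mat == a).sum(axis=0)
    return counts


def homogeneity_profile(aln: Msa, subset=None) -> np.ndarray:
    """Per-column homogeneity in [0, 1]; NaN where < 2 residues.

    1.0 exactly for any fully conserved column; ~0 on average for columns
    drawn from the background composition.
    """
    idx = _select_rows(aln, subset)
    if not idx:
        raise ValueError("subset selects no rows")
    counts = _column_counts(aln.matrix()[idx])
    n = counts.sum(axis=1)
    diag = np.diag(BLOSUM62)
    pair_sum = 0.5 * (np.einsum("ca,ab,cb->c", counts, BLOSUM62, counts) - counts @ diag)
    n_pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s_obs = pair_sum / n_pairs
        s_self = (counts @ diag) / n
        h = (s_obs - RANDOM_PAIR_SCORE) / (s_self - RANDOM_PAIR_SCORE)
    h = np.clip(h, 0.0, 1.0)
    h[n < 2] = np.nan
    return h


def column_homogeneity(residues: str) -> float:
    """Homogeneity of a single column given as a residue string."""
    counts = np.zeros(20)
    for c in residues:
        if c in AA_INDEX:
            counts[AA_INDEX[c]] += 1
    n = counts.sum()
    if n < 2:
        return float("nan")
    diag = np.diag(BLOSUM62)
    pair_sum = 0.5 * float(counts @ BLOSUM62 @ counts - counts @ diag)
    s_obs = pair_sum / (n * (n - 1) / 2.0)
    s_self = float(counts @ diag) / n
    return float(np.clip((s_obs - RANDOM_PAIR_SCORE) / (s_self - RANDOM_PAIR_SCORE), 0.0, 1.0))


def smooth_profile(values: np.ndarray, window: int = 25) -> np.ndarray:
    """Centered moving average; edges use the available part of the window.

    NaN entries are ignored (average over defined neighbours)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise ValueError("window longer than track")
    if window == 1:
        return values.copy()
    half = window // 2
    ok = np.isfinite(values)
    v = np.where(ok, values, 0.0)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(ok.astype(float), kernel, mode="same")
    # "same" already truncates at edges; half retained for clarity
    _ = half
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def profile(aln: Msa, subset=None, window: int = 25) -> AlignmentProfile:
    occ = occupancy_profile(aln, subset)
    hom = homogeneity_profile(aln, subset)
    return AlignmentProfile(
        occupancy=occ,
        homogeneity=hom,
        window=window,
        occupancy_smooth=smooth_profile(occ, window),
        homogeneity_smooth=smooth_profile(hom, window),
    )


def find_regions(
    track: np.ndarray, threshold: float, min_len: int = 1, mode: str = "below"
) -> list[RegionCall]:
    """Maximal runs of columns below (<) or above (>=) a threshold."""
    if mode not in ("below", "above"):
        raise ValueError("mode must be 'below' or 'above'")
    track = np.asarray(track, dtype=float)
    ok = np.isfinite(track)
    passing = (track < threshold) if mode == "below" else (track >= threshold)
    passing &= ok
    label = "hypervariable" if mode == "below" else "conserved"
    regions = []
    i = 0
    n = len(track)
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        if j - i + 1 >= min_len:
            regions.append(
                RegionCall(start=i + 1, end=j + 1,
                           mean_value=float(np.nanmean(track[i : j + 1])), label=label)
            )
        i = j + 1
    return regions


# --------------------------------------------------------------------------
# C-terminal tree and clades


def extract_cterm(aln: Msa, n_cols: int = 200) -> Msa:
    """Last ``n_cols`` alignment columns; all-gap rows in the window dropped."""
    if n_cols > aln.n_cols:
        raise ValueError("n_cols exceeds alignment length")
    rows = []
    for rid, genome, seq in aln.rows:
        window = seq[aln.n_cols - n_cols :]
        if set(window) <= {"-", "."}:
            continue
        rows.append((rid, genome, window))
    return Msa(rows=rows)


def _nj_with_lengths(aln_mat: np.ndarray, ids: list[str]):
    d = poisson_correct(p_distance_matrix(aln_mat))
    return nj_midpoint(d, ids)


def cterm_tree(aln: Msa, n_boot: int = 100, seed: int = 0):
    """Bootstrap-supported NJ tree (Poisson distances, midpoint-rooted).

    Supports (fraction of column-resampled replicates containing each
    split) are stored on internal nodes as ``node.support``; with
    n_boot=0 supports are left unset.
    """
    if aln.n_rows < 4:
        raise ValueError("need at least 4 rows for a supported tree")
    mat = aln.matrix()
    ids = [r[0] for r in aln.rows]
    tree = _nj_with_lengths(mat, ids)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        for _ in range(n_boot):
            cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
            rep = _nj_with_lengths(mat[:, cols], ids)
            for split in bipartitions(rep):
                counts[split] = counts.get(split, 0) + 1
        all_leaves = frozenset(ids)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            split = frozenset((side, all_leaves - side))
            if 1 < len(side) < len(all_leaves) - 1:
                node.support = counts.get(split, 0) / n_boot
            else:
                node.support = 1.0
    return tree


def tight_clades(
    tree, support_min: float = 0.7, dist_max: float = 0.1
) -> CTermCladeSet:
    """Maximal well-supported clades of closely similar sequences.

    A clade qualifies when its support is >= ``support_min`` and the
    largest patristic distance among its leaves is <= ``dist_max``.
    Maximal qualifying clades are labelled A, B, ... in preorder; the
    root itself is never a clade.
    """
    ids, pat = patristic_matrix(tree)
    idx = {name: i for i, name in enumerate(ids)}
    clades = []

    def diameter(node) -> float:
        leaf_idx = [idx[t.name] for t in node.tips()]
        return float(pat[np.ix_(leaf_idx, leaf_idx)].max())

    def visit(node, is_root):
        if node.is_tip():
            return
        support = getattr(node, "support", None)
        if (
            not is_root
            and support is not None
            and support >= support_min
            and diameter(node) <= dist_max
        ):
            clades.append(node)
            return  # maximal: do not descend
        for child in node.children:
            visit(child, False)

    visit(tree, True)
    labels = list(string.ascii_uppercase)
    out = []
    for i, node in enumerate(clades):
        label = labels[i] if i < len(labels) else f"Z{i}"
        members = [t.name for t in node.tips()]
        out.append(
            CTermClade(label=label, members=members,
                       support=float(getattr(node, "support", 1.0)),
                       max_distance=diameter(node))
        )
    return CTermCladeSet(clades=out)


def incongruence_test(
    clades: CTermCladeSet,
    species_of: dict,
    species_tree,
    n_perm: int = 999,
    seed: int = 0,
) -> IncongruenceReport:
    """Do tight C-terminal clades track the species tree?

    Statistic: mean species-tree patristic distance over all same-clade
    member pairs (0 for same-species pairs). The null permutes the species
    labels across all clade members. p_low is the one-sided probability of
    a statistic this low under the null: small p_low = vertical signal;
    p_low compatible with uniform and z ~ 0 = variants scattered across
    the species tree.
    """
    members = [m for c in clades for m in c.members]
    groups = [[m for m in c.members] for c in clades if len(c.members) >= 2]
    if not groups:
        raise ValueError("no clade with at least 2 members")
    ids, pat = patristic_matrix(species_tree)
    sp_idx = {s: i for i, s in enumerate(ids)}
    labels = np.array([sp_idx[species_of[m]] for m in members])
    member_pos = {m: i for i, m in enumerate(members)}
    pair_idx = []
    for grp in groups:
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                pair_idx.append((member_pos[grp[i]], member_pos[grp[j]]))
    pair_idx = np.array(pair_idx)

    def stat(lab):
        return float(pat[lab[pair_idx[:, 0]], lab[pair_idx[:, 1]]].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = stat(rng.permutation(labels))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else 0.0
    p_low = (1 + int((null <= observed + 1e-12).sum())) / (n_perm + 1)
    return IncongruenceReport(
        statistic=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=float(z),
        p_low=float(p_low),
        n_perm=n_perm,
        n_pairs=len(pair_idx),
        seed=seed,
    )


# --------------------------------------------------------------------------
# motifs and conserved columns


@dataclass
class MotifPattern:
    """PROSITE-like degenerate pattern: literals, [..] classes, x wildcard.

    ``window``: restrict the search to the last ``window`` residues of the
    sequence; None searches the whole sequence.
    """

    pattern: str
    window: int | None = None

    def __post_init__(self):
        self.elements = _parse_motif(self.pattern)
        if self.window is not None and self.window < len(self.elements):
            raise ValueError("window shorter than the pattern")

    def __len__(self):
        return len(self.elements)


def _parse_motif(pattern: str) -> list[frozenset]:
    elements = []
    i = 0
    valid = set(AA)
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed class in motif {pattern!r}")
            cls = pattern[i + 1 : j]
            if not cls or not set(cls) <= valid:
                raise ValueError(f"bad residue class {cls!r} in motif {pattern!r}")
            elements.append(frozenset(cls))
            i = j + 1
        elif c in ("x", "X"):
            elements.append(frozenset(AA))
            i += 1
        elif c in valid:
            elements.append(frozenset(c))
            i += 1
        else:
            raise ValueError(f"bad character {c!r} in motif {pattern!r}")
    if not elements:
        raise ValueError("empty motif")
    return elements


#: The C-terminal sorting-signal motif searched in the last 15 residues.
SORTING_SIGNAL = "D[ND]NxxxG[GD]"


def scan_motif(seq: str, pattern) -> list[MotifHit]:
    """All matches of a degenerate motif, 1-based positions in ``seq``.

    With a windowed pattern, only matches lying entirely within the last
    ``window`` residues are reported."""
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    seq = seq.upper()
    m = len(pattern.elements)
    lo = 0
    if pattern.window is not None:
        lo = max(0, len(seq) - pattern.window)
    rx = re.compile(
        "".join(
            "." if len(e) == 20 else (next(iter(e)) if len(e) == 1 else "[" + "".join(sorted(e)) + "]")
            for e in pattern.elements
        )
    )
    hits = []
    for k in range(lo, len(seq) - m + 1):
        if rx.fullmatch(seq, k, k + m):
            hits.append(MotifHit(position=k + 1, match=seq[k : k + m]))
    return hits


def conserved_columns(aln: Msa, residue, min_frac: float = 0.9) -> list[int]:
    """1-based columns where a residue (or class) reaches ``min_frac`` of
    the non-gap rows."""
    wanted = set(residue)
    mat = aln.matrix()
    hits = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        nongap = col >= 0
        n = int(nongap.sum())
        if n == 0:
            continue
        cnt = sum(1 for v in col[nongap] if AA[v] in wanted)
        if cnt / n >= min_frac:
            hits.append(j + 1)
    return hits


def conserved_runs(aln: Msa, motif: str, min_frac: float = 0.9) -> list[int]:
    """Start columns (1-based) of consecutive columns conserved as the given
    residues — e.g. ``"GN"`` finds the conserved G-then-N di-column."""
    per_residue = [set(conserved_columns(aln, c, min_frac)) for c in motif]
    starts = []
    for c in sorted(per_residue[0]):
        if all((c + k) in per_residue[k] for k in range(1, len(motif))):
            starts.append(c)
    return starts
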