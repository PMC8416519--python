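"""Gene gain/loss reconstruction on a species tree.

The model is a two-state (absent/present) continuous-time Markov process
with per-family gain rate g and loss rate l, gamma rate variation across
families on both rates (discretised into K categories per rate, mean-of-bin),
equal category priors and the per-category stationary distribution as the
root prior. Likelihoods use Felsenstein pruning, vectorised across families;
ancestral presence probabilities come from the up-down (inside-outside)
recursion, weighted by category posteriors.

Events are called from posterior differences along branches: a gain on a
branch when P_descendant - P_ancestral > 0.5, a loss when the drop exceeds
0.5 (strict inequalities). Islands are maximal runs of terminally gained
genes in a genome's gene order. Gene-order coordinates are 1-based closed
intervals over gene indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import gamma as _gamma_dist

from .trees import TreeArrays, tree_arrays


@dataclass
class PhyleticPattern:
    """Family x genome presence/absence matrix."""

    families: list
    genomes: list
    presence: np.ndarray  # (n_families, n_genomes), entries 0/1

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.families), len(self.genomes)):
            raise ValueError("presence matrix does not match id lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.families, columns=self.genomes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhyleticPattern":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class GainLossParams:
    g0: float = 0.5
    l0: float = 1.0
    alpha_gain: float = 1.0
    alpha_loss: float = 1.0
    K: int = 4

    def __post_init__(self):
        if min(self.g0, self.l0, self.alpha_gain, self.alpha_loss) <= 0:
            raise ValueError("rates and gamma shapes must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class EventCall:
    family: str
    parent: str
    child: str
    type: str  # "gain" | "loss"
    delta: float


@dataclass
class GenomicIsland:
    genome: str
    contig: str
    start: int  # 1-based closed, gene-order coordinates
    end: int
    genes: list
    families: list

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AncestralStateMap:
    """P(present) per family at every node; leaves carry observed 0/1."""

    families: list
    node_names: list
    probs: np.ndarray  # (n_families, n_nodes)

    def get(self, family, node) -> float:
        return float(
            self.probs[self.families.index(family), self.node_names.index(node)]
        )


# --------------------------------------------------------------------------
# model core


def transition_matrix(g: float, l: float, t: float) -> np.ndarray:
    """2x2 transition probabilities of the two-state chain over time t.

    P01(t) = g/(g+l) * (1 - exp(-(g+l) t)); P10 symmetric with l.
    State order: 0 = absent, 1 = present.
    """
    if g < 0 or l < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    tot = g + l
    if tot == 0 or t == 0:
        return np.eye(2)
    decay = -np.expm1(-tot * t)
    p01 = (g / tot) * decay
    p10 = (l / tot) * decay
    return np.array([[1 - p01, p01], [p10, 1 - p10]])


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-of-bin discretisation of a mean-1 gamma(alpha) into K categories."""
    if K == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.linspace(0, 1, K + 1), alpha, scale=1.0 / alpha)
    cdf_hi = _gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    return K * np.diff(cdf_hi)


def _leaf_matrix(ta: TreeArrays, patterns: np.ndarray) -> np.ndarray:
    """(n_nodes, F, 2) conditional likelihood arrays with leaves filled."""
    nfam = patterns.shape[0]
    L = np.ones((ta.n_nodes, nfam, 2))
    for i in range(ta.n_leaves):
        L[i, :, 0] = patterns[:, i] == 0
        L[i, :, 1] = patterns[:, i] == 1
    return L


def _category_logliks(ta: TreeArrays, patterns: np.ndarray, params: GainLossParams):
    """Per-category-pair log-likelihood vectors, shape (K, K, F)."""
    rg = params.g0 * discrete_gamma_rates(params.alpha_gain, params.K)
    rl = params.l0 * discrete_gamma_rates(params.alpha_loss, params.K)
    nfam = patterns.shape[0]
    out = np.empty((params.K, params.K, nfam))
    for a, g in enumerate(rg):
        for b, l in enumerate(rl):
            L = _leaf_matrix(ta, patterns)
            scale = np.zeros(nfam)
            for node in ta.postorder:
                kids = ta.children[node]
                if not kids:
                    continue
                acc = np.ones((nfam, 2))
                for c in kids:
                    P = transition_matrix(g, l, ta.length[c])
                    acc *= L[c] @ P.T
                m = acc.max(axis=1)
                nz = m > 0
                acc[nz] /= m[nz, None]
                with np.errstate(divide="ignore"):
                    scale += np.where(nz, np.log(np.maximum(m, 1e-300)), -np.inf)
                L[node] = acc
            pi = np.array([l, g]) / (g + l) if g + l > 0 else np.array([0.5, 0.5])
            lik = L[ta.root] @ pi
            with np.errstate(divide="ignore"):
                out[a, b] = np.log(np.maximum(lik, 1e-300)) + scale
    return out


def loglik_families(
    tree_or_arrays, patterns: np.ndarray, params: GainLossParams
) -> np.ndarray:
    """Mixture log-likelihood per family (equal category priors)."""
    ta = tree_or_arrays if isinstance(tree_or_arrays, TreeArrays) else tree_arrays(tree_or_arrays)
    patterns = np.atleast_2d(np.asarray(patterns))
    if patterns.shape[1] != ta.n_leaves:
        raise ValueError("pattern width does not match number of leaves")
    cat = _category_logliks(ta, patterns, params)
    K2 = params.K * params.K
    return logsumexp(cat.reshape(K2, -1), axis=0) - np.log(K2)


def family_loglik(tree, pattern, params: GainLossParams) -> float:
    """Log-likelihood of one family's presence/absence vector.

    ``pattern`` may be a dict leaf-name -> 0/1 or an array in the tree's
    tip order.
    """
    ta = tree_arrays(tree)
    if isinstance(pattern, dict):
        missing = [n for n in ta.leaf_names if n not in pattern]
        if missing:
            raise ValueError(f"pattern missing leaves: {missing}")
        vec = np.array([pattern[n] for n in ta.leaf_names])
    else:
        vec = np.asarray(pattern)
        if vec.shape[0] != ta.n_leaves:
            raise ValueError("pattern length does not match number of leaves")
    return float(loglik_families(ta, vec[None, :], params)[0])


def fit_params(
    patterns: PhyleticPattern, tree, K: int = 4, max_iter: int = 400
) -> GainLossParams:
    """Maximum-likelihood (g0, l0, alpha_gain, alpha_loss) by a starting-point
    grid followed by Nelder-Mead on log-parameters. Deterministic."""
    ta = tree_arrays(tree)
    genome_order = [patterns.genomes.index(n) for n in ta.leaf_names]
    mat = patterns.presence[:, genome_order]
    if mat.min() == mat.max():
        warnings.warn("degenerate phyletic pattern (all present or all absent); "
                      "returning boundary estimate")
        if mat.min() == 1:
            return GainLossParams(g0=100.0, l0=1e-3, alpha_gain=1.0, alpha_loss=1.0, K=K)
        return GainLossParams(g0=1e-3, l0=100.0, alpha_gain=1.0, alpha_loss=1.0, K=K)

    def neg_loglik(theta):
        theta = np.clip(theta, -7.0, 7.0)
        p = GainLossParams(*np.exp(theta), K=K)
        return -float(loglik_families(ta, mat, p).sum())

    starts = []
    for g0 in (0.2, 1.0, 5.0):
        for l0 in (0.2, 1.0, 5.0):
            starts.append(np.log([g0, l0, 1.0, 1.0]))
    best_start = min(starts, key=neg_loglik)
    res = minimize(
        neg_loglik,
        best_start,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-7},
    )
    g0, l0, ag, al = np.exp(np.clip(res.x, -7.0, 7.0))
    return GainLossParams(g0=float(g0), l0=float(l0),
                          alpha_gain=float(ag), alpha_loss=float(al), K=K)


def ancestral_posteriors(tree, pattern, params: GainLossParams) -> AncestralStateMap:
    """Marginal posterior P(present) at every node, per family.

    Up-down recursion per category pair; categories are weighted by their
    posterior probability given the data. Leaves return the observed state
    exactly. ``pattern`` may be a PhyleticPattern, a dict (single family)
    or an array (families x leaves, tree tip order).
    """
    ta = tree_arrays(tree)
    if isinstance(pattern, PhyleticPattern):
        order = [pattern.genomes.index(n) for n in ta.leaf_names]
        mat = pattern.presence[:, order]
        families = list(pattern.families)
    elif isinstance(pattern, dict):
        mat = np.array([[pattern[n] for n in ta.leaf_names]])
        families = ["fam0"]
    else:
        mat = np.atleast_2d(np.asarray(pattern))
        families = [f"fam{i}" for i in range(mat.shape[0])]
    nfam = mat.shape[0]
    rg = params.g0 * discrete_gamma_rates(params.alpha_gain, params.K)
    rl = params.l0 * discrete_gamma_rates(params.alpha_loss, params.K)

    cat_ll = np.empty((params.K * params.K, nfam))
    cat_post1 = np.empty((params.K * params.K, nfam, ta.n_nodes))
    ci = 0
    for g in rg:
        for l in rl:
            L = _leaf_matrix(ta, mat)
            up = np.empty((ta.n_nodes, nfam, 2))  # message node -> parent
            scale = np.zeros(nfam)
            for node in ta.postorder:
                kids = ta.children[node]
                if kids:
                    acc = np.ones((nfam, 2))
                    for c in kids:
                        acc *= up[c]
                    m = np.maximum(acc.max(axis=1), 1e-300)
                    acc /= m[:, None]
                    scale += np.log(m)
                    L[node] = acc
                if node != ta.root:
                    P = transition_matrix(g, l, ta.length[node])
                    up[node] = L[node] @ P.T
            pi = np.array([l, g]) / (g + l) if g + l > 0 else np.array([0.5, 0.5])
            lik = np.maximum(L[ta.root] @ pi, 1e-300)
            cat_ll[ci] = np.log(lik) + scale
            D = np.empty((ta.n_nodes, nfam, 2))
            D[ta.root] = pi
            for node in ta.postorder[::-1]:
                for c in ta.children[node]:
                    part = D[node].copy()
                    for s in ta.children[node]:
                        if s != c:
                            part *= up[s]
                    P = transition_matrix(g, l, ta.length[c])
                    D[c] = part @ P
                    m = np.maximum(D[c].max(axis=1), 1e-300)
                    D[c] /= m[:, None]
            joint = L * D  # (n_nodes, F, 2)
            tot = joint.sum(axis=2)
            with np.errstate(invalid="ignore"):
                post1 = np.where(tot > 0, joint[:, :, 1] / np.maximum(tot, 1e-300), 0.5)
            cat_post1[ci] = post1.T
            ci += 1
    w = np.exp(cat_ll - cat_ll.max(axis=0, keepdims=True))
    w /= w.sum(axis=0, keepdims=True)
    probs = np.einsum("cf,cfn->fn", w, cat_post1)
    probs[:, : ta.n_leaves] = mat  # leaves are observed
    return AncestralStateMap(families=families, node_names=list(ta.node_names), probs=probs)


def call_events(post: AncestralStateMap, tree) -> list[EventCall]:
    """Gain/loss calls from posterior differences along branches.

    Strict rule: delta = P_child - P_parent; > 0.5 is a gain, < -0.5 a
    loss; at most one call per (family, branch)."""
    ta = tree_arrays(tree)
    name_to_col = {n: i for i, n in enumerate(post.node_names)}
    calls = []
    for fi, fam in enumerate(post.families):
        row = post.probs[fi]
        for node in range(ta.n_nodes):
            p = ta.parent[node]
            if p < 0:
                continue
            delta = row[name_to_col[ta.node_names[node]]] - row[name_to_col[ta.node_names[p]]]
            if delta > 0.5:
                calls.append(EventCall(fam, ta.node_names[p], ta.node_names[node], "gain", float(delta)))
            elif delta < -0.5:
                calls.append(EventCall(fam, ta.node_names[p], ta.node_names[node], "loss", float(delta)))
    return calls


def terminal_gain_families(calls: list[EventCall], genomes) -> dict:
    """Families called gained on each genome's terminal branch."""
    gset = set(genomes)
    out = {g: set() for g in gset}
    for c in calls:
        if c.type == "gain" and c.child in gset:
            out[c.child].add(c.family)
    return out


# --------------------------------------------------------------------------
# gene order: islands, anchors, neighborhoods


def detect_islands(
    genes: pd.DataFrame,
    terminal_gains: dict,
    max_gap: int = 0,
    min_size: int = 1,
) -> list[GenomicIsland]:
    """Maximal runs of terminally gained genes per (genome, contig).

    Up to ``max_gap`` intervening non-gained genes may be bridged; runs
    spanning fewer than ``min_size`` gene positions are discarded; islands
    never span contigs. At the default max_gap=0 every member gene is
    itself terminally gained.
    """
    islands = []
    for (genome, contig), sub in genes.groupby(["genome", "contig"], sort=True):
        gained = terminal_gains.get(genome, set())
        sub = sub.sort_values("position")
        rows = list(sub.itertuples(index=False))
        flags = [r.family_id in gained for r in rows]
        i = 0
        n = len(rows)
        while i < n:
            if not flags[i]:
                i += 1
                continue
            end = i
            j = i + 1
            gap = 0
            while j < n:
                if flags[j]:
                    end = j
                    gap = 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
                j += 1
            span = rows[i : end + 1]
            if len(span) >= min_size:
                islands.append(
                    GenomicIsland(
                        genome=genome,
                        contig=contig,
                        start=int(span[0].position),
                        end=int(span[-1].position),
                        genes=[r.gene_id for r in span],
                        families=[r.family_id for r in span],
                    )
                )
            i = end + 1
    return islands


def anchored_islands(islands: list[GenomicIsland], anchors) -> list[GenomicIsland]:
    """Islands containing at least one gene of an anchor family."""
    anchors = set(anchors)
    return [isl for isl in islands if anchors & set(isl.families)]


@dataclass
class Locus:
    genome: str
    contig: str
    start: int
    end: int
    genes: list  # labeled gene ids in the locus, genomic order


@dataclass
class NeighborhoodScan:
    windows: dict  # gene id -> {"upstream": [...], "downstream": [...]}
    loci: list = field(default_factory=list)


def neighborhood_scan(
    genes: pd.DataFrame, labeled, flank: int = 5, max_sep: int = 5
) -> NeighborhoodScan:
    """Windows around labeled genes and loci of clustered labeled genes.

    A locus is a maximal group of >= 2 labeled genes in which consecutive
    labeled genes are separated by at most ``max_sep`` other genes.
    Windows hold up to ``flank`` genes per side, truncated at contig edges.
    """
    labeled = set(labeled)
    windows = {}
    loci = []
    for (genome, contig), sub in genes.groupby(["genome", "contig"], sort=True):
        sub = sub.sort_values("position")
        rows = list(sub.itertuples(index=False))
        pos_of = {r.gene_id: k for k, r in enumerate(rows)}
        hits = [r for r in rows if r.gene_id in labeled]
        for r in hits:
            k = pos_of[r.gene_id]
            windows[r.gene_id] = {
                "upstream": [x.gene_id for x in rows[max(0, k - flank) : k]],
                "downstream": [x.gene_id for x in rows[k + 1 : k + 1 + flank]],
            }
        group = []
        for r in hits:
            if group and (r.position - group[-1].position - 1) > max_sep:
                if len(group) >= 2:
                    loci.append(Locus(genome, contig, int(group[0].position),
                                      int(group[-1].position), [x.gene_id for x in group]))
                group = []
            group.append(r)
        if len(group) >= 2:
            loci.append(Locus(genome, contig, int(group[0].position),
                              int(group[-1].position), [x.gene_id for x in group]))
    return NeighborhoodScan(windows=windows, loci=loci)
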