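"""End-to-end orchestration: simulate -> build-cogs -> gainloss -> profile ->
cterm -> motifs -> report, with JSON-configured stages and deterministic
artifacts (identical config and seed give byte-identical outputs).

The locus report mirrors a per-island summary: each island's genes in
genomic order with family id, anchor flag, the C-terminal clade letter of
the associated protein where one exists, and motif hits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .cogs import cog_iterate
from .gainloss import (
    GainLossParams,
    PhyleticPattern,
    anchored_islands,
    ancestral_posteriors,
    call_events,
    detect_islands,
    fit_params,
    terminal_gain_families,
)
from .simulate import SimConfig, simulate_all
from .variability import (
    SORTING_SIGNAL,
    MotifPattern,
    cterm_tree,
    extract_cterm,
    incongruence_test,
    profile as make_profile,
    scan_motif,
    tight_clades,
)

log = logging.getLogger("vartig")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All stage toggles and parameters for a pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    run_build_cogs: bool = True
    run_gainloss: bool = True
    run_profile: bool = True
    run_cterm: bool = True
    run_motifs: bool = True
    run_report: bool = True
    K: int = 4
    max_gap: int = 0
    min_size: int = 1
    window: int = 25
    cterm_cols: int = 200
    n_boot: int = 100
    support_min: float = 0.7
    dist_max: float = 0.1
    n_perm: int = 999
    id_threshold: float = 0.5
    evalue_cutoff: float = 1e-4

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        sim = SimConfig.from_json(json.dumps(d.pop("sim", {})))
        return cls(sim=sim, **d)

    def validate(self):
        if self.run_report and not (self.run_gainloss and self.run_cterm and self.run_motifs):
            raise ConfigError("report requires the gainloss, cterm and motifs stages")


def _tag_vartig_anchors(sim: dict, cfg: RunConfig):
    """Place the simulated long proteins at the head of their genome's
    islands: the first gene of the k-th island in a genome becomes the
    anchor family of long protein Vk. Returns (gene_id -> protein id,
    anchor family set)."""
    genes = sim["genes"]
    truth = sim["truth"]
    pattern = sim["pattern"]
    gene2prot = {}
    anchors = set()
    per_genome: dict[str, int] = {}
    rename: dict[str, str] = {}
    for isl in truth.islands:
        g = isl["genome"]
        k = per_genome.get(g, 0)
        if k >= cfg.sim.n_vartig_loci:
            continue
        per_genome[g] = k + 1
        pid = f"{g}_V{k + 1}"
        fam_old = isl["families"][0]
        fam_new = f"VARTIG_{pid}"
        rename[fam_old] = fam_new
        isl["families"][0] = fam_new
        anchors.add(fam_new)
        row = genes[(genes.genome == g) & (genes.family_id == fam_old)]
        gene2prot[row.iloc[0].gene_id] = pid
    if rename:
        genes["family_id"] = genes["family_id"].map(lambda f: rename.get(f, f))
        pattern.families = [rename.get(f, f) for f in pattern.families]
        truth.events = [(b, rename.get(f, f), k) for b, f, k in truth.events]
    return gene2prot, anchors


def make_report(islands, clade_labels: dict, motif_hits: dict, genes: pd.DataFrame,
                gene2prot: dict, anchors) -> tuple[pd.DataFrame, str]:
    """Per-island gene-by-gene table plus a markdown rendering.

    clade_labels: protein id -> clade letter; motif_hits: protein id ->
    list of MotifHit. Raises on island genes absent from the gene table.
    """
    known = set(genes.gene_id)
    anchors = set(anchors)
    rows = []
    lines = ["# Hypervariable locus report", ""]
    for n, isl in enumerate(islands, 1):
        lines.append(f"## Island {n}: {isl.genome} {isl.contig} "
                     f"[{isl.start},{isl.end}] ({isl.length} genes)")
        for gid, fam in zip(isl.genes, isl.families):
            if gid not in known:
                raise ValueError(f"island gene {gid} not present in the gene table")
            pid = gene2prot.get(gid, "")
            letter = clade_labels.get(pid, "") if pid else ""
            hits = motif_hits.get(pid, []) if pid else []
            hit_str = ";".join(f"{h.match}@{h.position}" for h in hits)
            is_anchor = fam in anchors
            rows.append((n, isl.genome, isl.contig, gid, fam, is_anchor, letter, hit_str))
            mark = " *anchor*" if is_anchor else ""
            clade = f" clade={letter}" if letter else ""
            motif = f" motifs={hit_str}" if hit_str else ""
            lines.append(f"- {gid} ({fam}){mark}{clade}{motif}")
        lines.append("")
    df = pd.DataFrame(
        rows,
        columns=["island", "genome", "contig", "gene_id", "family_id",
                 "anchor", "clade", "motif_hits"],
    )
    return df, "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order; write all artifacts.

    Returns the in-memory results dict. All randomness derives from
    cfg.sim.seed.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run_pipeline seed=%d outdir=%s", cfg.seed, outdir)
    (outdir / "runconfig.json").write_text(cfg.to_json() + "\n")

    results: dict = {}
    log.info("stage simulate: %s", cfg.sim)
    sim = simulate_all(cfg.sim, outdir=None)
    gene2prot, anchors = _tag_vartig_anchors(sim, cfg)
    results["sim"] = sim
    vio.write_newick(sim["tree"], outdir / "species_tree.nwk")
    vio.write_fasta(sim["records"], outdir / "proteins.faa")
    vio.write_pattern(sim["pattern"].to_frame(), outdir / "pattern.tsv")
    vio.write_gene_table(sim["genes"], outdir / "genes.tsv")
    (outdir / "truth.json").write_text(sim["truth"].to_json() + "\n")

    if cfg.run_build_cogs:
        log.info("stage build-cogs: id_threshold=%s evalue=%s",
                 cfg.id_threshold, cfg.evalue_cutoff)
        species_of = {r.id: r.genome for r in sim["records"]}
        cogs = cog_iterate(
            sim["records"], species_of,
            id_threshold=cfg.id_threshold,
            evalue_cutoff=cfg.evalue_cutoff,
            seed=cfg.seed,
        )
        results["cogs"] = cogs
        rows = [(c.id, m.id, m.genome) for c in cogs for m in c.members]
        vio.write_tsv(pd.DataFrame(rows, columns=["cluster_id", "seq_id", "genome"]),
                      outdir / "cogs.tsv", "cluster membership")

    if cfg.run_gainloss:
        log.info("stage gainloss: K=%d max_gap=%d min_size=%d",
                 cfg.K, cfg.max_gap, cfg.min_size)
        pattern: PhyleticPattern = sim["pattern"]
        params = fit_params(pattern, sim["tree"], K=cfg.K)
        post = ancestral_posteriors(sim["tree"], pattern, params)
        calls = call_events(post, sim["tree"])
        gains = terminal_gain_families(calls, pattern.genomes)
        islands = detect_islands(sim["genes"], gains,
                                 max_gap=cfg.max_gap, min_size=cfg.min_size)
        anchored = anchored_islands(islands, anchors)
        results.update(params=params, calls=calls, islands=islands, anchored=anchored)
        (outdir / "params.json").write_text(json.dumps(
            dataclasses.asdict(params), indent=2, sort_keys=True) + "\n")
        vio.write_tsv(
            pd.DataFrame(
                [(c.family, c.parent, c.child, c.type, round(c.delta, 6)) for c in calls],
                columns=["family", "parent", "child", "type", "delta"],
            ),
            outdir / "events.tsv", "gain/loss calls, |delta P| > 0.5",
        )
        vio.write_tsv(
            pd.DataFrame(
                [(i.genome, i.contig, i.start, i.end, i.length,
                  ",".join(i.genes), ",".join(i.families), i in anchored)
                 for i in islands],
                columns=["genome", "contig", "start", "end", "length",
                         "genes", "families", "anchored"],
            ),
            outdir / "islands.tsv", "terminal-branch islands",
        )

    aln = sim["alignment"]
    if cfg.run_profile:
        log.info("stage profile: window=%d", cfg.window)
        short = make_profile(aln, subset=lambda r: len(r[2].replace("-", "")) < 700,
                             window=cfg.window)
        long_p = make_profile(aln, subset=lambda r: len(r[2].replace("-", "")) > 700,
                              window=cfg.window)
        results.update(profile_short=short, profile_long=long_p)
        df = pd.DataFrame({
            "column": np.arange(1, aln.n_cols + 1),
            "occupancy_short": np.round(short.occupancy, 6),
            "homogeneity_long": np.round(long_p.homogeneity, 6),
            "occupancy_short_smooth": np.round(short.occupancy_smooth, 6),
            "homogeneity_long_smooth": np.round(long_p.homogeneity_smooth, 6),
        })
        vio.write_tsv(df, outdir / "profile.tsv",
                      "occupancy over <700 aa rows; homogeneity over >700 aa rows")

    clade_labels: dict = {}
    if cfg.run_cterm:
        log.info("stage cterm: cols=%d n_boot=%d n_perm=%d",
                 cfg.cterm_cols, cfg.n_boot, cfg.n_perm)
        cterm = extract_cterm(aln, cfg.cterm_cols)
        tree = cterm_tree(cterm, n_boot=cfg.n_boot, seed=cfg.seed)
        clades = tight_clades(tree, cfg.support_min, cfg.dist_max)
        species_of = {rid: genome for rid, genome, _ in cterm.rows}
        report = incongruence_test(clades, species_of, sim["tree"],
                                   n_perm=cfg.n_perm, seed=cfg.seed)
        clade_labels = clades.labels_of()
        results.update(cterm_tree=tree, clades=clades, incongruence=report)
        for node in tree.non_tips(include_self=False):
            node.name = format(getattr(node, "support", None) or 0.0, ".2f")
        vio.write_newick(tree, outdir / "cterm.nwk")
        vio.write_tsv(
            pd.DataFrame(
                [(c.label, m, round(c.support, 4), round(c.max_distance, 6))
                 for c in clades for m in c.members],
                columns=["clade", "member", "support", "max_distance"],
            ),
            outdir / "clades.tsv", "tight C-terminal clades",
        )
        (outdir / "incongruence.json").write_text(json.dumps(
            dataclasses.asdict(report), indent=2, sort_keys=True) + "\n")

    motif_hits: dict = {}
    if cfg.run_motifs:
        log.info("stage motifs: pattern=%s window=15", SORTING_SIGNAL)
        pat = MotifPattern(SORTING_SIGNAL, window=15)
        rows = []
        for rec in sim["records"]:
            hits = scan_motif(rec.residues, pat)
            motif_hits[rec.id] = hits
            for h in hits:
                rows.append((rec.id, SORTING_SIGNAL, h.position, h.match))
        results["motifs"] = motif_hits
        vio.write_tsv(pd.DataFrame(rows, columns=["protein", "pattern", "position", "match"]),
                      outdir / "motifs.tsv", "sorting-signal hits in the last 15 residues")

    if cfg.run_report:
        log.info("stage report")
        df, md = make_report(results["islands"], clade_labels, motif_hits,
                             sim["genes"], gene2prot, anchors)
        vio.write_tsv(df, outdir / "report.tsv", "per-island locus report")
        (outdir / "report.md").write_text(md)
        results["report"] = df
    log.info("pipeline complete")
    return results
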