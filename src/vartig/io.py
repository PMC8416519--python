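"""File formats: FASTA, newick, and the TSV tables exchanged between stages.

Coordinate convention for all tables is 1-based closed intervals over gene
positions; every written table says so in a ``#`` header comment.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

GENE_TABLE_COLUMNS = ["genome", "contig", "position", "gene_id", "family_id"]


def read_fasta(path) -> list:
    """Read protein FASTA into SequenceRecord objects (residues uppercased)."""
    from .cogs import SequenceRecord

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(None, 1)
        genome = desc[1].strip() if len(desc) > 1 else ""
        records.append(SequenceRecord(id=rec.id, genome=genome, residues=str(rec.seq).upper()))
    return records


def write_fasta(records, path) -> None:
    recs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.genome or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_alignment(path):
    """Read aligned FASTA into an Msa (gaps preserved, residues uppercased)."""
    from .cogs import Msa

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.split(None, 1)
        genome = desc[1].strip() if len(desc) > 1 else ""
        rows.append((rec.id, genome, str(rec.seq).upper()))
    return Msa(rows=rows)


def write_alignment(aln, path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description=g or "") for i, g, s in aln.rows]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def _format_length(x: float) -> str:
    return format(x, ".10g")


def _write_clade(node: TreeNode, out: _io.StringIO) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_clade(child, out)
        out.write(")")
    if node.name:
        out.write(str(node.name))
    if node.length is not None:
        out.write(":" + _format_length(float(node.length)))


def newick_string(tree: TreeNode) -> str:
    out = _io.StringIO()
    _write_clade(tree, out)
    out.write(";")
    return out.getvalue()


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(path) -> TreeNode:
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"empty newick file: {path}")
    return TreeNode.read(_io.StringIO(text), convert_underscores=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"position": int})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    return df[GENE_TABLE_COLUMNS]


def write_gene_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# positions are 1-based, consecutive within a contig\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pattern(path) -> pd.DataFrame:
    """Family x genome 0/1 matrix with family ids as the index."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(int)


def write_pattern(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# presence/absence: rows=families, columns=genomes\n")
        df.to_csv(fh, sep="\t")


def write_tsv(df: pd.DataFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# intervals are 1-based, closed\n")
        df.to_csv(fh, sep="\t", index=False)
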