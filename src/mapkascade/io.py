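"""Readers and writers for FASTA, GFF3 and expression tables.

GFF3 files are 1-based closed on disk; all in-memory spans are 0-based
half-open.  FASTA goes through Bio.SeqIO, GFF3 parsing through gffutils.
"""

from __future__ import annotations

import logging
import os
import tempfile
from typing import Iterable

import pandas as pd
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import ExpressionMatrix, GeneModel, Transcript

log = logging.getLogger("mapkascade")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, uppercased sequence).

    Raises ValueError on duplicate ids or empty records.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ----------------------------------------------------------------- GFF3

def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModel objects.

    Transcripts (mRNA features) are grouped under their parent genes;
    exon/CDS children are grouped under transcripts.  UTR features are
    accepted but UTR lengths are derived from exon/CDS geometry.
    Raises ValueError for unknown Parent references; CDS segments that
    fall outside exon bounds fail Transcript validation.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    gene_ids = {g.id for g in db.features_of_type("gene")}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        for p in parents:
            if p not in gene_ids:
                raise ValueError(f"mRNA {mrna.id}: unknown parent {p!r}")
    for feat in db.features_of_type(("exon", "CDS", "five_prime_UTR", "three_prime_UTR")):
        for p in feat.attributes.get("Parent", []):
            try:
                db[p]
            except gffutils.FeatureNotFoundError:
                raise ValueError(f"{feat.featuretype} at {feat.start}: unknown parent {p!r}")
    for gene in db.features_of_type("gene"):
        transcripts: dict[str, Transcript] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            transcripts[mrna.id] = Transcript(mrna.id, exons, cds)
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, transcripts))
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write GeneModels as minimal GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            spans = [s for t in gene.transcripts.values() for s in t.exons]
            gs, ge = min(s for s, _ in spans), max(e for _, e in spans)
            fh.write(f"{gene.chrom}\tmapkascade\tgene\t{gs + 1}\t{ge}\t.\t"
                     f"{gene.strand}\t.\tID={gene.gene_id}\n")
            for t in gene.transcripts.values():
                ts = min(s for s, _ in t.exons)
                te = max(e for _, e in t.exons)
                fh.write(f"{gene.chrom}\tmapkascade\tmRNA\t{ts + 1}\t{te}\t.\t"
                         f"{gene.strand}\t.\tID={t.transcript_id};Parent={gene.gene_id}\n")
                for s, e in t.exons:
                    fh.write(f"{gene.chrom}\tmapkascade\texon\t{s + 1}\t{e}\t.\t"
                             f"{gene.strand}\t.\tParent={t.transcript_id}\n")
                # CDS phase column: bases to skip to reach the next codon start
                prior = 0
                segs = t.cds if gene.strand == "+" else list(reversed(t.cds))
                for s, e in segs:
                    frame = (3 - prior % 3) % 3
                    fh.write(f"{gene.chrom}\tmapkascade\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{gene.strand}\t{frame}\tParent={t.transcript_id}\n")
                    prior += e - s


# ---------------------------------------------------- expression tables

def read_expression_table(path, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample metadata TSV.

    The first column of the matrix file is the gene id; the first column
    of the metadata file is the sample id.  Every sample column must be
    numeric and present in the metadata.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = [c for c in values.columns
                   if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric}")
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, samples=samples)


def write_expression_table(matrix: ExpressionMatrix, path, metadata_path) -> None:
    matrix.values.to_csv(path, sep="\t")
    matrix.samples.to_csv(metadata_path, sep="\t")
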