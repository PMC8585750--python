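"""Readers and writers for the standard formats at the pipeline boundary.

GFF3 goes through :mod:`gffutils`, FASTA through :mod:`Bio.SeqIO`, tabular
contracts (domain calls, homolog pairs, counts, sample sheets) through
:mod:`pandas`.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainCall, GeneModel, HomologPair

DOMAIN_COLUMNS = ["gene_id", "domain_type", "start", "end", "e_value", "cc_score", "source"]
PAIR_COLUMNS = ["gene_a", "gene_b", "identity", "aligned_length"]


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 annotation into :class:`GeneModel` records.

    Exons are taken from ``exon`` features of the first mRNA of each gene
    (or of the gene itself when no mRNA level is present).  A gene without
    exon features gets a single exon spanning its body.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted((e.start, e.end) for e in db.children(g, featuretype="exon"))
        if not exons:
            exons = [(g.start, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chromosome=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=tuple(exons),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS features (1-based closed, GFF3 version 3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chromosome}\tnbs_profiler\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\tnbs_profiler\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tnbs_profiler\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.chromosome}\tnbs_profiler\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain table

def read_domain_table(path: str | Path) -> list[DomainCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            DomainCall(
                gene_id=str(row.gene_id),
                domain_type=str(row.domain_type),
                start=int(row.start),
                end=int(row.end),
                e_value=None if pd.isna(row.e_value) else float(row.e_value),
                cc_score=None if pd.isna(row.cc_score) else float(row.cc_score),
                source=str(getattr(row, "source", "")),
            )
        )
    return calls


def write_domain_table(calls: Iterable[DomainCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.gene_id, c.domain_type, c.start, c.end, c.e_value, c.cc_score, c.source)
            for c in calls
        ],
        columns=DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Homolog pairs

def read_homolog_pairs(path: str | Path) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        HomologPair(str(r.gene_a), str(r.gene_b), float(r.identity), int(r.aligned_length))
        for r in df.itertuples(index=False)
    ]


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.gene_a, p.gene_b, p.identity, p.aligned_length) for p in pairs],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts / sample sheet

def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples integer count matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "tissue", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
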