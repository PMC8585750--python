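"""Chromosomal distribution: mapped/unmapped split and 250-kb cluster calling.

A cluster locus is a run of two or more NBS genes on one chromosome in which
consecutive genes are separated by at most the window size (250 kb by
default); genes joining no such run are singleton loci.  Chaining is
transitive and measured from the running end of the growing locus, which
makes the partition identical to merging every gene pair whose inter-gene
gap is within the window and taking connected components.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

from .models import ClusterLocus, GeneModel, UNPLACED

__all__ = ["split_mapped_unmapped", "call_clusters", "cluster_summary", "natural_key"]

DEFAULT_WINDOW_BP = 250_000


def natural_key(name: str) -> tuple:
    """Natural sort key: 'chr2' before 'chr10'."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name))


def split_mapped_unmapped(genes: Iterable[GeneModel]) -> tuple[list[GeneModel], list[GeneModel]]:
    """Separate genes on named chromosomes from those on unassembled contigs."""
    mapped, unmapped = [], []
    for g in genes:
        (unmapped if g.chromosome == UNPLACED else mapped).append(g)
    return mapped, unmapped


def call_clusters(
    mapped_genes: Sequence[GeneModel],
    window_bp: float = DEFAULT_WINDOW_BP,
) -> list[ClusterLocus]:
    """Partition mapped genes into cluster and singleton loci.

    Per chromosome, genes sorted by position are chained: a gene joins the
    current locus when the gap between its start and the locus' rightmost
    end so far (floored at 0 for overlaps) is at most ``window_bp``.
    Locus ids are 1-based, ordered by natural chromosome order then
    position.  Input order is irrelevant.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in mapped_genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    loci: list[ClusterLocus] = []
    locus_id = 0
    for chrom in sorted(by_chrom, key=natural_key):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        runs: list[list[GeneModel]] = []
        run_end = -math.inf
        for g in genes:
            gap = max(0, g.start - run_end)
            if runs and gap <= window_bp:
                runs[-1].append(g)
            else:
                runs.append([g])
            run_end = max(run_end, g.end)
        for run in runs:
            locus_id += 1
            loci.append(
                ClusterLocus(
                    locus_id=locus_id,
                    chromosome=chrom,
                    members=tuple(g.gene_id for g in run),
                    span=(min(g.start for g in run), max(g.end for g in run)),
                    kind="cluster" if len(run) >= 2 else "singleton",
                )
            )
    return loci


def cluster_summary(loci: Sequence[ClusterLocus]) -> dict:
    """Headline statistics: cluster/singleton counts, clustered fraction, mean size."""
    clusters = [l for l in loci if l.kind == "cluster"]
    singletons = [l for l in loci if l.kind == "singleton"]
    n_mapped = sum(len(l.members) for l in loci)
    n_clustered = sum(len(l.members) for l in clusters)
    per_chrom: dict[str, list[int]] = {}
    for l in loci:
        per_chrom.setdefault(l.chromosome, []).append(l.locus_id)
    return {
        "n_loci": len(loci),
        "n_clusters": len(clusters),
        "n_singletons": len(singletons),
        "n_mapped_genes": n_mapped,
        "n_clustered_genes": n_clustered,
        "clustered_pct": round(100.0 * n_clustered / n_mapped, 1) if n_mapped else 0.0,
        "mean_genes_per_cluster": round(n_clustered / len(clusters), 2) if clusters else 0.0,
        "no_clusters": not clusters,
        "loci_by_chromosome": per_chrom,
    }
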