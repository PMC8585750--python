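"""Candidate merging, NBS-domain verification and architecture classification.

An NBS-LRR survey starts from two permissive candidate searches (profile HMM
and protein homology), merges and deduplicates them, then keeps only genes
with a confidently detected NBS (NB-ARC) domain.  Verified genes are sorted
into three groups and nine subclasses by their domain architecture:

=========  =====================  =====
subclass   domains                group
=========  =====================  =====
CNL        CC, NBS, LRR           CNL
CN         CC, NBS                CNL
NL_CC      NBS, LRR               CNL
N_CC       NBS                    CNL
TNL        TIR, NBS, LRR          TNL
TN         TIR, NBS               TNL
NL_TIR     NBS, LRR               TNL
N_TIR      NBS                    TNL
RNL        RPW8, NBS, LRR         RNL
=========  =====================  =====

Genes carrying neither CC, TIR nor RPW8 (the NL/N architectures) cannot be
grouped by N-terminal evidence alone.  They are split by the terminal
residue of the kinase-2 motif — tryptophan (W) typifies non-TNL proteins and
aspartate (D) typifies TNLs — with the CNL group as the low-confidence
default when no kinase-2 evidence is available.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .models import ArchitectureLabel, DomainCall, Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "merge_candidates",
    "verify_nbs",
    "classify_architecture",
    "summarize_classification",
    "classify_genes",
]


def merge_candidates(list_a: Iterable[str], list_b: Iterable[str]) -> list[str]:
    """Union of two candidate gene-id lists, deduplicated and sorted.

    Gene ids are compared case-sensitively (GFF3 IDs are case-sensitive).
    """
    return sorted(set(list_a) | set(list_b))


def _calls_by_gene(domain_calls: Iterable[DomainCall]) -> dict[str, list[DomainCall]]:
    by_gene: dict[str, list[DomainCall]] = {}
    for call in domain_calls:
        by_gene.setdefault(call.gene_id, []).append(call)
    return by_gene


def verify_nbs(
    candidates: Iterable[str],
    domain_calls: Iterable[DomainCall],
    thresholds: Thresholds = Thresholds(),
) -> list[str]:
    """Keep candidates with at least one NBS call at e-value <= threshold.

    Candidates absent from the domain table are treated as having no NBS
    domain and dropped (with a warning), mirroring the elimination of genes
    without a conserved NBS domain.
    """
    by_gene = _calls_by_gene(domain_calls)
    verified = []
    for gene_id in sorted(set(candidates)):
        calls = by_gene.get(gene_id)
        if calls is None:
            logger.warning("candidate %s has no domain annotation; dropped", gene_id)
            continue
        if any(
            c.domain_type == "NBS" and c.e_value is not None and c.e_value <= thresholds.nbs_evalue_max
            for c in calls
        ):
            verified.append(gene_id)
    return verified


def classify_architecture(
    gene_id: str,
    domain_calls: Sequence[DomainCall],
    kinase2_residue: Optional[str] = None,
    thresholds: Thresholds = Thresholds(),
) -> ArchitectureLabel:
    """Assign one of the nine subclasses from a gene's domain calls.

    Precedence of N-terminal evidence is RPW8 > TIR > CC.  A CC domain
    counts as present only when its coiled-coil score reaches
    ``thresholds.cc_score_min``.  NL/N architectures are resolved by
    ``kinase2_residue`` (W -> CNL group, D -> TNL group, otherwise CNL with
    a low-confidence flag).
    """
    calls = [c for c in domain_calls if c.gene_id == gene_id]
    has_nbs = any(
        c.domain_type == "NBS" and c.e_value is not None and c.e_value <= thresholds.nbs_evalue_max
        for c in calls
    )
    if not has_nbs:
        raise ValueError(f"{gene_id}: no verified NBS domain; gene should not reach classification")

    has_tir = any(c.domain_type == "TIR" for c in calls)
    has_rpw8 = any(c.domain_type == "RPW8" for c in calls)
    has_lrr = any(c.domain_type == "LRR" for c in calls)
    has_cc = any(
        c.domain_type == "CC" and c.cc_score is not None and c.cc_score >= thresholds.cc_score_min
        for c in calls
    )

    if has_rpw8:
        if not has_lrr:
            logger.warning("%s: RPW8 without LRR; labelled RNL", gene_id)
        return ArchitectureLabel("RNL", "RNL")
    if has_tir:
        return ArchitectureLabel("TNL", "TNL" if has_lrr else "TN")
    if has_cc:
        return ArchitectureLabel("CNL", "CNL" if has_lrr else "CN")

    # NL / N architectures: kinase-2 terminal-residue tie-break.
    if kinase2_residue == "D":
        return ArchitectureLabel("TNL", "NL_TIR" if has_lrr else "N_TIR")
    if kinase2_residue == "W":
        return ArchitectureLabel("CNL", "NL_CC" if has_lrr else "N_CC")
    logger.info("%s: no N-terminal or kinase-2 evidence; defaulting to CNL group", gene_id)
    return ArchitectureLabel("CNL", "NL_CC" if has_lrr else "N_CC", low_confidence=True)


def classify_genes(
    verified: Iterable[str],
    domain_calls: Iterable[DomainCall],
    kinase2_residues: Optional[Mapping[str, str]] = None,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, ArchitectureLabel]:
    """Classify every verified gene; convenience wrapper over per-gene calls."""
    by_gene = _calls_by_gene(domain_calls)
    kinase2_residues = kinase2_residues or {}
    return {
        g: classify_architecture(g, by_gene.get(g, []), kinase2_residues.get(g), thresholds)
        for g in sorted(set(verified))
    }


def summarize_classification(
    labels: Mapping[str, ArchitectureLabel],
    n_annotated_genes: int,
) -> dict:
    """Counts per group/subclass and the family's share of the annotation.

    The proportion is reported as a percentage of all annotated genes,
    rounded to 2 decimals.
    """
    if n_annotated_genes <= 0:
        raise ValueError("n_annotated_genes must be positive")
    if n_annotated_genes < len(labels):
        raise ValueError("n_annotated_genes smaller than the number of classified genes")

    group_counts = Counter(lbl.group for lbl in labels.values())
    subclass_counts = Counter(lbl.subclass for lbl in labels.values())
    n_nbs = len(labels)
    return {
        "n_nbs": n_nbs,
        "n_annotated": n_annotated_genes,
        "proportion_pct": round(100.0 * n_nbs / n_annotated_genes, 2),
        "group_counts": dict(group_counts),
        "subclass_counts": dict(subclass_counts),
    }


def classification_table(labels: Mapping[str, ArchitectureLabel]) -> pd.DataFrame:
    """Flat gene/group/subclass table for TSV export."""
    rows = [
        (g, lbl.group, lbl.subclass, lbl.low_confidence)
        for g, lbl in sorted(labels.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "group", "subclass", "low_confidence"])
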