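"""Gene-structure statistics and cross-species correlations.

Covers exon-count and gene-length summaries per subfamily, the bivariate
(Pearson) correlations used throughout the survey — exon count vs gene
length within subfamilies, and NBS-gene count vs genome size across a
13-species census — and one-way ANOVA with Tukey HSD multiple comparisons
(compact letter display) for subfamily contrasts.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .models import GeneModel, SpeciesRecord, StructureRecord

__all__ = [
    "structure_from_gff",
    "pearson_r",
    "load_species_table",
    "species_correlation",
    "exon_length_correlation",
    "subfamily_comparison",
]


def structure_from_gff(
    genes: Iterable[GeneModel],
    groups: Optional[Mapping[str, str]] = None,
) -> list[StructureRecord]:
    """Exon count and genomic length per gene, with optional subfamily labels.

    Genes without exon features are treated as single-exon (the
    :mod:`~nbs_profiler.io` GFF3 reader already applies the same
    single-exon assumption).
    """
    groups = groups or {}
    records = []
    for g in genes:
        records.append(
            StructureRecord(
                gene_id=g.gene_id,
                exon_count=max(1, g.exon_count),
                gene_length_bp=g.length,
                group=groups.get(g.gene_id),
            )
        )
    return records


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def load_species_table(path: str | Path | None = None) -> list[SpeciesRecord]:
    """The packaged 13-species NBS census (counts per subfamily, genome size).

    Missing RNL entries ('-') are treated as zero.
    """
    if path is None:
        ref = resources.files("nbs_profiler").joinpath("data/table1_species.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        rnl = 0 if str(row.rnl).strip() == "-" else int(row.rnl)
        records.append(
            SpeciesRecord(
                species=str(row.species),
                cnl=int(row.cnl),
                tnl=int(row.tnl),
                rnl=rnl,
                predicted_proteins=int(row.predicted_proteins),
                genome_size_mb=float(row.genome_size_mb),
            )
        )
    return records


def species_correlation(
    records: Sequence[SpeciesRecord],
    exclude: Iterable[str] = (),
) -> tuple[float, float, int]:
    """Pearson correlation of genome size vs total NBS count across species."""
    exclude = set(exclude)
    kept = [r for r in records if r.species not in exclude]
    if len(kept) < 3:
        raise ValueError("need at least 3 species after exclusion")
    r, p = pearson_r([r.genome_size_mb for r in kept], [r.total_nbs for r in kept])
    return r, p, len(kept)


def exon_length_correlation(
    records: Sequence[StructureRecord],
    group: Optional[str] = None,
) -> tuple[float, float, int]:
    """Correlation of exon count vs gene length, optionally within one group."""
    kept = [r for r in records if group is None or r.group == group]
    if len(kept) < 3:
        raise ValueError("need at least 3 records in the selected group")
    r, p = pearson_r([r.exon_count for r in kept], [r.gene_length_bp for r in kept])
    return r, p, len(kept)


def _compact_letters(group_names: Sequence[str], means: Mapping[str, float],
                     not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: one letter per maximal clique of the
    'not significantly different' graph.  Groups sharing a letter are not
    significantly different.  Subfamily counts are small, so cliques are
    enumerated exhaustively.
    """
    from itertools import combinations

    names = list(group_names)
    cliques: list[frozenset] = []
    for size in range(len(names), 0, -1):
        for subset in combinations(names, size):
            fs = frozenset(subset)
            if any(fs <= c for c in cliques):
                continue
            if all(frozenset(pair) in not_different for pair in combinations(subset, 2)):
                cliques.append(fs)
    cliques.sort(key=lambda c: min(means[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, cover in zip(alphabet, cliques):
        for g in cover:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def subfamily_comparison(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    tukey: bool = True,
) -> dict:
    """One-way ANOVA across subfamilies with Tukey HSD multiple comparisons.

    Returns the ANOVA F and p, per-pair Tukey-adjusted p-values, and a
    compact letter display at the given alpha (groups sharing a letter are
    not significantly different).  ``tukey=False`` skips the post-hoc step
    (useful in large simulations where only the omnibus test matters).
    """
    names = sorted(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    f_stat, p_value = stats.f_oneway(*samples)

    means = {g: float(np.mean(groups[g])) for g in names}
    if not tukey:
        return {
            "anova_F": float(f_stat),
            "anova_p": float(p_value),
            "group_means": {g: round(means[g], 2) for g in names},
            "alpha": alpha,
        }

    values = np.concatenate(samples)
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations as _combos

    pair_order = list(_combos([str(g) for g in tukey.groupsunique], 2))
    pairwise: dict[tuple[str, str], float] = {}
    not_different: set[frozenset] = set()
    for (a, b), padj in zip(pair_order, tukey.pvalues):
        pairwise[(a, b)] = float(padj)
        if padj > alpha:
            not_different.add(frozenset((a, b)))

    return {
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "group_means": {g: round(means[g], 2) for g in names},
        "tukey_p": pairwise,
        "letters": _compact_letters(names, means, not_different),
        "alpha": alpha,
    }
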