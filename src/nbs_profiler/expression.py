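"""Expression profiling: FPKM, categorisation, tissue assignment, heatmap export.

The input boundary is a genes x samples fragment-count matrix with a sample
sheet (tissue x developmental stage) and per-gene effective lengths (summed
exon length).  FPKM is

    FPKM[g, s] = 1e9 * C[g, s] / (N[s] * L[g])

with C the count, N the per-sample mapped-fragment total and L the
effective length in bp.  Genes are categorised by their maximum FPKM across
samples: 0 = not detected, (0, 3) = very low, [3, 30] = low, > 30 =
intermediate/high.  The maximum is used because a single strongly expressed
sample is what marks a gene as intermediate/high in this survey.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "categorize_expression",
    "tissue_assignment",
    "tissue_means",
    "export_heatmap_matrix",
    "TISSUES",
    "STAGES",
]

TISSUES = ("rind", "flesh", "seed")
STAGES = ("young", "enlargement", "coloring", "mature")

#: Tie-break priority for tissue assignment (index = priority).
_TISSUE_PRIORITY = {t: i for i, t in enumerate(TISSUES)}


@dataclass
class ExpressionMatrix:
    """FPKM values with their sample sheet and provenance vectors."""

    fpkm: pd.DataFrame            # genes x samples
    samples: pd.DataFrame         # columns: sample, tissue, stage
    lengths: pd.Series            # per-gene effective length (bp)
    totals: pd.Series             # per-sample mapped-fragment totals

    def __post_init__(self) -> None:
        if list(self.fpkm.columns) != list(self.samples["sample"]):
            raise ValueError("FPKM columns and sample sheet disagree")
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.samples.loc[self.samples["tissue"] == tissue, "sample"])


def fpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, float] | pd.Series,
    samples: pd.DataFrame,
    totals: Optional[Mapping[str, float] | pd.Series] = None,
) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments.

    ``totals`` defaults to the within-matrix column sums; pass the true
    mapped-fragment totals when the matrix is a gene subset.
    """
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive effective length")
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series(totals, dtype=float).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive mapped-fragment total")

    values = 1e9 * counts.to_numpy(dtype=float) / np.outer(lengths.to_numpy(), totals.to_numpy())
    mat = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(fpkm=mat, samples=samples.reset_index(drop=True),
                            lengths=lengths, totals=totals)


def categorize_expression(
    matrix: ExpressionMatrix,
    low_band: tuple[float, float] = (3.0, 30.0),
    high_min: float = 30.0,
) -> pd.Series:
    """Per-gene category from the maximum FPKM across all samples."""
    lo, hi = low_band
    if not (0 < lo <= hi <= high_min):
        raise ValueError("thresholds must satisfy 0 < low <= high <= high_min")
    peak = matrix.fpkm.max(axis=1)

    def categorise(v: float) -> str:
        if v <= 0:
            return "not_detected"
        if v < lo:
            return "very_low"
        if v <= high_min:
            return "low"
        return "intermediate_high"

    return peak.map(categorise).rename("category")


def tissue_assignment(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Tissue with the highest mean FPKM per gene, plus per-tissue counts.

    Ties go to the earlier tissue in priority order (rind > flesh > seed)
    and are flagged.  Genes with no detectable expression are flagged as
    undetected and excluded from the per-tissue counts.
    """
    tissues = [t for t in TISSUES if (matrix.samples["tissue"] == t).any()]
    if not tissues:
        raise ValueError("sample sheet contains none of the known tissues")
    means = pd.DataFrame(
        {t: matrix.fpkm[matrix.samples_for(t)].mean(axis=1) for t in tissues}
    )
    rows = []
    for gene, row in means.iterrows():
        best = max(tissues, key=lambda t: (row[t], -_TISSUE_PRIORITY[t]))
        tied = sum(1 for t in tissues if row[t] == row[best]) > 1
        detected = matrix.fpkm.loc[gene].max() > 0
        rows.append((gene, best, tied, detected))
    table = pd.DataFrame(rows, columns=["gene_id", "tissue", "tied", "detected"]).set_index("gene_id")
    counts = (
        table.loc[table["detected"], "tissue"].value_counts().reindex(tissues, fill_value=0)
    )
    table.attrs["tissue_counts"] = counts.to_dict()
    return table


def tissue_means(matrix: ExpressionMatrix) -> dict[str, float]:
    """Grand mean FPKM per tissue (across all genes and stages), 1 decimal."""
    if matrix.fpkm.empty:
        raise ValueError("empty expression matrix")
    out = {}
    for t in TISSUES:
        cols = matrix.samples_for(t)
        if cols:
            out[t] = round(float(matrix.fpkm[cols].to_numpy().mean()), 1)
    return out


def export_heatmap_matrix(
    matrix: ExpressionMatrix,
    groups: Optional[Mapping[str, str]] = None,
    path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """log2(FPKM + 1) matrix with genes ordered by group then id.

    Suitable for heatmap rendering; written as TSV when ``path`` is given.
    """
    groups = groups or {}
    order = sorted(matrix.fpkm.index, key=lambda g: (groups.get(g, "~"), g))
    log = np.log2(matrix.fpkm.loc[order] + 1.0)
    if path is not None:
        log.to_csv(path, sep="\t")
    return log
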