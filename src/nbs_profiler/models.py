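"""Core domain types shared across the pipeline.

The types mirror the stages of an NBS-LRR (NB-ARC) resistance-gene survey:
gene models from a GFF3 annotation, per-gene domain evidence, the resulting
architecture label (three groups, nine subclasses), located NBS-domain
motifs, chromosomal cluster loci, Ka/Ks estimates and duplication-origin
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GeneModel",
    "DomainCall",
    "ArchitectureLabel",
    "Thresholds",
    "MotifHit",
    "MotifOrderCall",
    "ClusterLocus",
    "KaKsResult",
    "DuplicationCall",
    "HomologPair",
    "StructureRecord",
    "SpeciesRecord",
    "SUBCLASS_TO_GROUP",
    "GROUPS",
    "SUBCLASSES",
    "UNPLACED",
]

#: Chromosome value used for genes on unassembled contigs.
UNPLACED = "unplaced"

#: Subclass -> group mapping.  The nine subclasses are defined by which of
#: the N-terminal domains (CC, TIR, RPW8) and the C-terminal LRR are present;
#: ``NL_CC``/``N_CC`` and ``NL_TIR``/``N_TIR`` are NBS-LRR / bare-NBS genes
#: assigned to the CNL or TNL group respectively (see identify_classify).
SUBCLASS_TO_GROUP = {
    "CNL": "CNL",
    "CN": "CNL",
    "NL_CC": "CNL",
    "N_CC": "CNL",
    "TNL": "TNL",
    "TN": "TNL",
    "NL_TIR": "TNL",
    "N_TIR": "TNL",
    "RNL": "RNL",
}

GROUPS = ("CNL", "TNL", "RNL")
SUBCLASSES = tuple(SUBCLASS_TO_GROUP)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene (1-based, closed coordinates, as in GFF3)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene body")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class DomainCall:
    """Per-gene domain evidence from homology/HMM search or coiled-coil score.

    ``e_value`` applies to NBS/TIR/RPW8/LRR calls; ``cc_score`` (0..1) to CC
    calls, which come from a coiled-coil predictor rather than profile search.
    """

    gene_id: str
    domain_type: str  # NBS | TIR | CC | RPW8 | LRR
    start: int = 0
    end: int = 0
    e_value: Optional[float] = None
    cc_score: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.e_value is not None and self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.cc_score is not None and not (0.0 <= self.cc_score <= 1.0):
            raise ValueError("cc_score must be in [0, 1]")


@dataclass(frozen=True)
class ArchitectureLabel:
    """Subclass (one of nine) and the group it determines (CNL/TNL/RNL)."""

    group: str
    subclass: str
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASS_TO_GROUP:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if SUBCLASS_TO_GROUP[self.subclass] != self.group:
            raise ValueError(f"subclass {self.subclass} does not belong to group {self.group}")


@dataclass(frozen=True)
class Thresholds:
    """Evidence thresholds for NBS verification and classification.

    ``search_evalue_max`` documents the permissive cutoff of the upstream
    candidate searches; it is provenance metadata only (those searches are
    outside this package's boundary).
    """

    nbs_evalue_max: float = 1e-4
    cc_score_min: float = 0.5
    search_evalue_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nbs_evalue_max, self.cc_score_min, self.search_evalue_max) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    start: int  # 1-based protein coordinate
    match: str
    score: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("motif start must be >= 1")


@dataclass(frozen=True)
class MotifOrderCall:
    """Verdict on whether a gene's motif arrangement follows the canonical order."""

    verdict: str  # conserved | flanked_repeat | core_change | insufficient
    observed: tuple[str, ...]


@dataclass(frozen=True)
class ClusterLocus:
    locus_id: int
    chromosome: str
    members: tuple[str, ...]
    span: tuple[int, int]
    kind: str  # cluster | singleton

    def __post_init__(self) -> None:
        expected = "cluster" if len(self.members) >= 2 else "singleton"
        if self.kind != expected:
            raise ValueError(f"locus {self.locus_id}: kind {self.kind} inconsistent with {len(self.members)} members")


@dataclass(frozen=True)
class KaKsResult:
    """Nonsynonymous/synonymous substitution rates for one sequence pair.

    ``ka``/``ks``/``omega`` are ``None`` when undefined (no synonymous
    divergence, or Jukes-Cantor saturation).  Site and difference counts are
    retained so results can be audited against the counting method.
    """

    gene_a: str
    gene_b: str
    ka: Optional[float]
    ks: Optional[float]
    omega: Optional[float]
    selection_call: str  # positive | neutral | purifying | undefined
    n_sites: float = 0.0
    s_sites: float = 0.0
    n_diffs: float = 0.0
    s_diffs: float = 0.0
    codons: int = 0
    method: str = "NG86"


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    dup_type: str  # wgd_segmental | tandem | proximal | dispersed | singleton
    evidence: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    identity: float
    aligned_length: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a homolog pair must join two distinct genes")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")

    def key(self) -> tuple[str, str]:
        """Unordered pair key for deduplication."""
        return (self.gene_a, self.gene_b) if self.gene_a < self.gene_b else (self.gene_b, self.gene_a)


@dataclass(frozen=True)
class StructureRecord:
    gene_id: str
    exon_count: int
    gene_length_bp: int
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exon_count < 1 or self.gene_length_bp < 1:
            raise ValueError("exon_count and gene_length_bp must be >= 1")


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the cross-species NBS census (counts per subfamily)."""

    species: str
    cnl: int
    tnl: int
    rnl: int  # absent entries recorded as 0
    predicted_proteins: int
    genome_size_mb: float

    @property
    def total_nbs(self) -> int:
        return self.cnl + self.tnl + self.rnl
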