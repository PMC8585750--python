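"""Molecular evolution of the NBS family: Ka/Ks, selection and duplication.

Ka/Ks (omega) is estimated with the Nei-Gojobori (1986) counting method:
synonymous (S) and nonsynonymous (N) site totals come from the fraction of
one-step nucleotide changes per codon position that preserve the amino acid
(changes creating stop codons are disregarded), observed codon differences
are partitioned into synonymous and nonsynonymous counts by averaging
equally over all minimal substitution pathways between the two codons
(pathways through stop codons excluded), and the proportions are corrected
for multiple hits with the Jukes-Cantor formula

    K = -(3/4) * ln(1 - (4/3) * p).

omega = Ka/Ks < 1 indicates purifying selection, = 1 neutral evolution and
> 1 positive selection.

Duplication origins follow MCScanX-style decision rules re-implemented over
a per-chromosome gene-rank map: membership in a collinear block of
homologous gene pairs marks a whole-genome/segmental duplicate; otherwise a
homolog within the tandem rank bound on the same chromosome marks a tandem
duplicate, within the proximal bound a proximal duplicate, and any
remaining homology a dispersed duplicate.  Priority is
wgd_segmental > tandem > proximal > dispersed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .distribution import natural_key
from .models import HomologPair, KaKsResult, DuplicationCall

__all__ = [
    "NUCLEOTIDES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
    "kaks_ng86",
    "select_pairs",
    "subfamily_kaks_contrast",
    "detect_collinear_blocks",
    "classify_duplications",
    "CollinearBlock",
    "PairSelectionParams",
    "DuplicationParams",
]

NUCLEOTIDES = "ACGT"
_TABLE = standard_dna_table.forward_table
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE))


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return "*" if codon in STOP_CODONS else _TABLE[codon]


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (N = 3 - S).

    Per position, the synonymous fraction is computed over the one-step
    changes that do not create a stop codon.
    """
    aa = _TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _TABLE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    All minimal substitution pathways are weighted equally; pathways passing
    through a stop codon are excluded (when every pathway is blocked, all
    are used as a fallback).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if translate_codon(nxt) == translate_codon(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


# Precomputed lookups: per-codon synonymous sites and per-pair differences.
_SITES = {c: _codon_sites(c) for c in SENSE_CODONS}
_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    hit = _DIFFS.get(key)
    if hit is None:
        hit = _DIFFS[key] = _pair_differences(*key)
    return hit


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _split_codons(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def kaks_ng86(
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> KaKsResult:
    """Nei-Gojobori Ka, Ks and omega for one aligned codon pair.

    Sequences must be equal-length codon alignments; codons containing a
    gap ('-') or ambiguous base in either sequence are skipped pairwise.
    Internal stop codons are rejected.  When synonymous divergence is zero
    or either proportion is Jukes-Cantor saturated (p >= 3/4), the
    corresponding rate and omega are undefined.
    """
    codons_a = _split_codons(cds_a)
    codons_b = _split_codons(cds_b)
    if len(codons_a) != len(codons_b):
        raise ValueError("aligned sequences must have equal length")

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    compared = 0
    for ca, cb in zip(codons_a, codons_b):
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            continue  # gap or ambiguity: skip pairwise
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError("internal stop codon in coding sequence")
        compared += 1
        s_sites += (_SITES[ca] + _SITES[cb]) / 2.0
        d = _diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    n_sites = 3.0 * compared - s_sites

    ka = ks = omega = None
    call = "undefined"
    if compared:
        ps = sd / s_sites if s_sites > 0 else 0.0
        pn = nd / n_sites if n_sites > 0 else 0.0
        ks = _jukes_cantor(ps)
        ka = _jukes_cantor(pn)
        if ka is not None and ks is not None and ks > 0:
            omega = ka / ks
            call = "positive" if omega > 1 else ("purifying" if omega < 1 else "neutral")
        else:
            omega = None

    return KaKsResult(
        gene_a=gene_a,
        gene_b=gene_b,
        ka=ka,
        ks=ks,
        omega=omega,
        selection_call=call,
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=nd,
        s_diffs=sd,
        codons=compared,
    )


def align_codons(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Protein-guided codon alignment of two unaligned CDS.

    Translates both sequences, aligns the proteins with a global aligner
    (BLOSUM62, affine gaps) and maps the gap pattern back onto codons, so
    the result can be fed to :func:`kaks_ng86` directly.
    """
    from Bio.Align import PairwiseAligner, substitution_matrices

    prot_a = "".join(translate_codon(c) for c in _split_codons(cds_a))
    prot_b = "".join(translate_codon(c) for c in _split_codons(cds_b))
    if "*" in prot_a or "*" in prot_b:
        raise ValueError("internal stop codon in coding sequence")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a, prot_b)[0]
    # map the protein alignment back onto codons, with explicit gaps
    aligned_a: list[str] = []
    aligned_b: list[str] = []
    prev_a = prev_b = 0
    for (s_a, e_a), (s_b, e_b) in zip(*aln.aligned):
        gap_a = s_a - prev_a
        gap_b = s_b - prev_b
        aligned_a.append(cds_a[3 * prev_a : 3 * s_a] + "---" * gap_b)
        aligned_b.append("---" * gap_a + cds_b[3 * prev_b : 3 * s_b])
        aligned_a.append(cds_a[3 * s_a : 3 * e_a])
        aligned_b.append(cds_b[3 * s_b : 3 * e_b])
        prev_a, prev_b = e_a, e_b
    tail_a = len(prot_a) - prev_a
    tail_b = len(prot_b) - prev_b
    aligned_a.append(cds_a[3 * prev_a :] + "---" * tail_b)
    aligned_b.append("---" * tail_a + cds_b[3 * prev_b :])
    return "".join(aligned_a), "".join(aligned_b)


# ---------------------------------------------------------------------------
# Pair selection and subfamily contrast

@dataclass(frozen=True)
class PairSelectionParams:
    """Analyzable-pair window: near-identical paralog sets (e.g. the highly
    conserved RNL quartet) fall above the identity ceiling and are excluded,
    mirroring a lower divergence limit for ortholog analysis."""

    min_aligned_length: int = 100
    min_identity: float = 0.4
    max_identity: float = 0.99


def select_pairs(
    pairs: Iterable[HomologPair],
    classes: Mapping[str, object],
    params: PairSelectionParams = PairSelectionParams(),
) -> list[HomologPair]:
    """Homolog pairs within the identity/length window with both genes classified."""
    seen: set[tuple[str, str]] = set()
    kept: list[HomologPair] = []
    for p in pairs:
        if p.aligned_length < params.min_aligned_length:
            continue
        if not (params.min_identity <= p.identity <= params.max_identity):
            continue
        if p.gene_a not in classes or p.gene_b not in classes:
            continue
        key = p.key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    return kept


def subfamily_kaks_contrast(
    results_by_group: Mapping[str, Sequence[KaKsResult]],
) -> dict:
    """Mean omega per subfamily and a Welch two-sample test between groups.

    Undefined omegas are dropped; each group needs at least two defined
    values.  With more than two groups the test compares the first two in
    sorted order (the survey contrasts CNL vs TNL).
    """
    defined = {
        g: [r.omega for r in rs if r.omega is not None]
        for g, rs in results_by_group.items()
    }
    defined = {g: v for g, v in defined.items() if v}
    if len(defined) < 2 or any(len(v) < 2 for v in defined.values()):
        raise ValueError("need >= 2 groups with >= 2 defined omega values each")
    names = sorted(defined)
    t_stat, p = stats.ttest_ind(defined[names[0]], defined[names[1]], equal_var=False)
    return {
        "means": {g: round(float(np.mean(v)), 2) for g, v in defined.items()},
        "n": {g: len(v) for g, v in defined.items()},
        "welch_t": float(t_stat),
        "p_value": float(p),
        "compared": (names[0], names[1]),
    }


# ---------------------------------------------------------------------------
# Collinearity and duplication typing

@dataclass(frozen=True)
class CollinearBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    pairs: tuple[tuple[str, str], ...]  # (gene_on_a, gene_on_b) in chain order


@dataclass(frozen=True)
class DuplicationParams:
    tandem_max_rank: int = 2      # at most one intervening gene
    proximal_max_rank: int = 10
    min_block_size: int = 5
    max_rank_gap: int = 25


def detect_collinear_blocks(
    rank_map: Mapping[str, tuple[str, int]],
    pairs: Iterable[HomologPair],
    params: DuplicationParams = DuplicationParams(),
) -> list[CollinearBlock]:
    """Order-consistent chains of homologous gene pairs across two segments.

    A simplified collinearity search: anchors (homolog pairs with both
    genes ranked) are grouped by chromosome pair, sorted along the first
    chromosome, and chained greedily while both rank coordinates advance
    monotonically (one fixed direction per chain) with gaps at most
    ``max_rank_gap``.  Chains of at least ``min_block_size`` anchors are
    blocks.  Local duplicates — same-chromosome anchors within the proximal
    rank bound — are not collinearity evidence and are skipped.
    """
    anchors: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for p in pairs:
        if p.gene_a not in rank_map or p.gene_b not in rank_map:
            continue
        ca, ra = rank_map[p.gene_a]
        cb, rb = rank_map[p.gene_b]
        ga, gb = p.gene_a, p.gene_b
        if ca == cb and abs(ra - rb) <= params.proximal_max_rank:
            continue  # tandem/proximal repeat, not a collinearity anchor
        if (natural_key(cb), rb) < (natural_key(ca), ra):
            ca, ra, ga, cb, rb, gb = cb, rb, gb, ca, ra, ga
        anchors.setdefault((ca, cb), []).append((ra, rb, ga, gb))

    blocks: list[CollinearBlock] = []
    next_id = 1
    for (ca, cb), items in sorted(anchors.items()):
        items.sort()
        chains: list[dict] = []
        for ra, rb, ga, gb in items:
            placed = False
            for chain in chains:
                la, lb = chain["last"]
                da, db = ra - la, rb - lb
                if not (0 < da <= params.max_rank_gap):
                    continue
                direction = chain["dir"]
                if db == 0:
                    continue
                step_dir = 1 if db > 0 else -1
                if direction is not None and step_dir != direction:
                    continue
                if not (0 < abs(db) <= params.max_rank_gap):
                    continue
                chain["pairs"].append((ga, gb))
                chain["last"] = (ra, rb)
                chain["dir"] = step_dir
                placed = True
                break
            if not placed:
                chains.append({"pairs": [(ga, gb)], "last": (ra, rb), "dir": None})
        for chain in chains:
            if len(chain["pairs"]) >= params.min_block_size:
                blocks.append(
                    CollinearBlock(next_id, ca, cb, tuple(chain["pairs"]))
                )
                next_id += 1
    return blocks


def classify_duplications(
    nbs_genes: Iterable[str],
    rank_map: Mapping[str, tuple[str, int]],
    pairs: Iterable[HomologPair],
    blocks: Sequence[CollinearBlock],
    params: DuplicationParams = DuplicationParams(),
) -> dict[str, DuplicationCall]:
    """Assign one duplication origin per gene.

    Priority: wgd_segmental > tandem > proximal > dispersed; a gene with no
    homolog is a singleton.  Every queried gene must be present in the rank
    map.
    """
    pairs = list(pairs)
    partners: dict[str, list[str]] = {}
    for p in pairs:
        partners.setdefault(p.gene_a, []).append(p.gene_b)
        partners.setdefault(p.gene_b, []).append(p.gene_a)

    block_membership: dict[str, int] = {}
    for b in blocks:
        for ga, gb in b.pairs:
            block_membership.setdefault(ga, b.block_id)
            block_membership.setdefault(gb, b.block_id)

    calls: dict[str, DuplicationCall] = {}
    for gene in sorted(set(nbs_genes)):
        if gene not in rank_map:
            raise ValueError(f"{gene} missing from the gene rank map")
        chrom, rank = rank_map[gene]

        if gene in block_membership:
            calls[gene] = DuplicationCall(
                gene, "wgd_segmental", {"block_id": block_membership[gene]}
            )
            continue

        best_type = "singleton"
        evidence: dict = {}
        for partner in sorted(partners.get(gene, [])):
            if partner not in rank_map:
                continue
            pchrom, prank = rank_map[partner]
            if pchrom == chrom:
                dist = abs(rank - prank)
                if dist <= params.tandem_max_rank:
                    ptype = "tandem"
                elif dist <= params.proximal_max_rank:
                    ptype = "proximal"
                else:
                    ptype = "dispersed"
            else:
                dist = None
                ptype = "dispersed"
            order = {"tandem": 0, "proximal": 1, "dispersed": 2, "singleton": 3}
            if order[ptype] < order[best_type]:
                best_type = ptype
                evidence = {"partner": partner, "rank_distance": dist}
        calls[gene] = DuplicationCall(gene, best_type, evidence)
    return calls
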