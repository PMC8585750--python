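"""Synthetic genomes with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a small plant NBS-LRR
family embedded in an annotated genome:

* a configurable subclass composition (the nine CNL/TNL/RNL architectures),
  with matching noise-free domain-annotation calls;
* cluster geometry — planted multi-gene cluster loci whose internal gaps
  respect a chaining window, separated from all other loci by more than the
  window — plus singleton loci and genes on unassembled contigs;
* duplication families with known origins: tandem duplicates rank-adjacent,
  proximal duplicates within a bounded rank window, dispersed duplicates on
  other chromosomes, and whole-genome duplicates embedded in collinear runs
  of background anchor pairs;
* coding sequences per family evolved from a common ancestor under a
  controlled Ka/Ks ratio (simple Markov substitution with stop-codon
  rejection; motif codons are protected from amino-acid change so motif
  content stays analyzable);
* proteins carrying the canonical NBS motif library consensus in canonical
  order, with planted flanked-repeat and core-order-change exceptions and a
  planted kinase-2 terminal residue (W/D) per gene;
* negative-binomial read counts over 3 fruit tissues x 4 developmental
  stages with rind-elevated late-stage means and planted tissue preference.

Defaults reproduce the census structure of a 73-gene family in a 16
chromosome genome: 31/13/4/2 CNL-group, 5/1/10/3 TNL-group and 4 RNL
architectures; twelve clusters of sizes 7/6/4/4/4/3/3/2/2/2/2/2 (41 genes);
33 tandem, 29 dispersed, 9 proximal and 2 WGD duplicates; 9 genes on
unplaced contigs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .evolution import NUCLEOTIDES, STOP_CODONS, _TABLE, translate_codon
from .models import (
    DomainCall,
    GeneModel,
    HomologPair,
    SUBCLASS_TO_GROUP,
    UNPLACED,
)
from .motifs import CANONICAL_ORDER, MotifLibrary, load_default_library

__all__ = [
    "SimConfig",
    "ExprSpec",
    "GroundTruth",
    "SyntheticGenome",
    "CountSim",
    "generate_genome",
    "evolve_codon_pair",
    "generate_counts",
    "reverse_translate",
]


class InvalidConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration

_DEFAULT_SUBCLASS_COUNTS = {
    "CNL": 31, "CN": 13, "NL_CC": 4, "N_CC": 2,
    "TNL": 5, "TN": 1, "NL_TIR": 10, "N_TIR": 3,
    "RNL": 4,
}

_DEFAULT_CLUSTER_SPEC = (
    (7, 200_000), (6, 200_000),
    (4, 150_000), (4, 150_000), (4, 150_000),
    (3, 150_000), (3, 150_000),
    (2, 150_000), (2, 150_000), (2, 150_000), (2, 150_000), (2, 150_000),
)

# Planted exon-count multisets per group (used when the group size matches):
# 162 exons over 50 CNL-group genes, 69 over 19 TNL-group, 18 over 4 RNL.
_EXON_TEMPLATES = {
    "CNL": [1] * 9 + [2] * 27 + [3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 12, 14, 15],
    "TNL": [1] * 5 + [2] * 3 + [4, 4, 4, 4, 4, 5, 5, 6, 6, 6, 10],
    "RNL": [2, 4, 6, 6],
}


@dataclass(frozen=True)
class ExprSpec:
    """Negative-binomial expression model over tissue x stage conditions.

    ``base_mean_fpkm`` maps (tissue, stage) to the baseline true FPKM; the
    rind profile rises through the later stages.  A fraction of genes is
    silent, one or more planted genes are strongly expressed in late-stage
    rind, and every expressed gene has a preferred tissue whose samples are
    boosted by ``preference_boost``.
    """

    base_mean_fpkm: tuple[tuple[tuple[str, str], float], ...] = tuple(
        sorted(
            {
                **{("flesh", s): 1.5 for s in ("young", "enlargement", "coloring", "mature")},
                **{("seed", s): 1.4 for s in ("young", "enlargement", "coloring", "mature")},
                ("rind", "young"): 1.2,
                ("rind", "enlargement"): 2.0,
                ("rind", "coloring"): 2.6,
                ("rind", "mature"): 3.0,
            }.items()
        )
    )
    nb_size: float = 5.0                 # NB shape; variance = mu + mu^2 / nb_size
    preferred_fractions: tuple[tuple[str, float], ...] = (
        ("rind", 46 / 66), ("seed", 16 / 66), ("flesh", 4 / 66),
    )
    preference_boost: float = 2.5
    n_silent: int = 7
    n_high: int = 1
    high_fpkm: float = 50.0
    library_size: float = 2e7
    size_factor_sigma: float = 0.1
    gene_factor_sigma: float = 0.4

    def means(self) -> dict[tuple[str, str], float]:
        return dict(self.base_mean_fpkm)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic genome; a fixed seed gives
    byte-identical outputs."""

    seed: int = 0
    n_chromosomes: int = 16
    chrom_length_bp: int = 40_000_000
    n_nbs_genes: int = 73
    subclass_mix: tuple[tuple[str, float], ...] = tuple(
        sorted((k, v / 73) for k, v in _DEFAULT_SUBCLASS_COUNTS.items())
    )
    cluster_spec: tuple[tuple[int, int], ...] = _DEFAULT_CLUSTER_SPEC
    duplication_spec: tuple[tuple[str, int], ...] = (
        ("tandem", 33), ("dispersed", 29), ("proximal", 9), ("wgd", 2),
    )
    omega_by_group: tuple[tuple[str, float], ...] = (
        ("CNL", 0.31), ("TNL", 0.42), ("RNL", 0.31),
    )
    codon_length: int = 300
    expr_spec: ExprSpec = ExprSpec()
    n_unplaced: int = 9
    window_bp: int = 250_000
    pair_expected_subs: int = 60
    rnl_expected_subs: int = 2       # RNL families stay near-identical
    kinase2_w_ntnl: int = 48
    kinase2_d_tnl: int = 13
    motif_flanked_genes: int = 14
    motif_core_change_genes: int = 2
    motif_dropout: tuple[tuple[str, int], ...] = (("P-loop", 7), ("GLPL", 5))
    n_background_per_chrom: int = 12

    # -- derived views ------------------------------------------------
    def subclass_counts(self) -> dict[str, int]:
        return _largest_remainder(dict(self.subclass_mix), self.n_nbs_genes)

    def group_counts(self) -> dict[str, int]:
        counts = {"CNL": 0, "TNL": 0, "RNL": 0}
        for sub, n in self.subclass_counts().items():
            counts[SUBCLASS_TO_GROUP[sub]] += n
        return counts

    def dup_counts(self) -> dict[str, int]:
        base = {"tandem": 0, "dispersed": 0, "proximal": 0, "wgd": 0}
        base.update(dict(self.duplication_spec))
        return base

    def validate(self) -> None:
        mix_total = sum(v for _, v in self.subclass_mix)
        if abs(mix_total - 1.0) > 1e-9:
            raise InvalidConfigError(f"subclass_mix sums to {mix_total}, not 1")
        if any(v < 0 for _, v in self.subclass_mix):
            raise InvalidConfigError("subclass_mix proportions must be >= 0")
        if self.n_nbs_genes < 0 or self.n_chromosomes < 1:
            raise InvalidConfigError("counts must be non-negative")
        dup = self.dup_counts()
        if any(v < 0 for v in dup.values()):
            raise InvalidConfigError("duplication counts must be >= 0")
        if sum(dup.values()) > self.n_nbs_genes:
            raise InvalidConfigError("duplication_spec exceeds n_nbs_genes")
        if dup["wgd"] % 2:
            raise InvalidConfigError("wgd genes come in pairs; count must be even")
        for n, gap in self.cluster_spec:
            if n < 2:
                raise InvalidConfigError("cluster loci need >= 2 genes")
            if not (0 < gap <= self.window_bp):
                raise InvalidConfigError("cluster max_gap must be in (0, window_bp]")
        if sum(n for n, _ in self.cluster_spec) > self.n_nbs_genes:
            raise InvalidConfigError("cluster_spec requests more genes than n_nbs_genes")
        if self.n_unplaced < 0 or 2 * self.n_unplaced > dup["dispersed"]:
            # each unplaced gene consumes a placed dispersed partner
            raise InvalidConfigError("not enough dispersed genes to partner unplaced genes")
        if self.codon_length * 3 < 900:
            raise InvalidConfigError("codon_length must be >= 300 codons")
        if self.expr_spec.nb_size <= 0:
            raise InvalidConfigError("negative-binomial size (dispersion) must be positive")


@dataclass
class GroundTruth:
    """Planted truth covering every generated NBS gene exactly once."""

    subclass: dict[str, str]
    cluster_of: dict[str, Optional[int]]   # cluster index (0-based) or None
    duplication: dict[str, str]
    pair_omega: dict[tuple[str, str], float]
    kinase2_residue: dict[str, str]
    motif_verdict: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "subclass": self.subclass,
                "cluster_of": self.cluster_of,
                "duplication": self.duplication,
                "pair_omega": {f"{a}|{b}": w for (a, b), w in self.pair_omega.items()},
                "kinase2_residue": self.kinase2_residue,
                "motif_verdict": self.motif_verdict,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticGenome:
    config: SimConfig
    genes: list[GeneModel]               # NBS + background genes
    nbs_gene_ids: list[str]
    proteins: dict[str, str]             # NBS genes only
    cds: dict[str, str]
    domain_calls: list[DomainCall]
    homolog_pairs: list[HomologPair]
    truth: GroundTruth

    @property
    def nbs_genes(self) -> list[GeneModel]:
        wanted = set(self.nbs_gene_ids)
        return [g for g in self.genes if g.gene_id in wanted]

    def rank_map(self) -> dict[str, tuple[str, int]]:
        """(chromosome, rank) for every gene, ranked by start per chromosome."""
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        ranks: dict[str, tuple[str, int]] = {}
        for chrom, genes in by_chrom.items():
            for i, g in enumerate(sorted(genes, key=lambda x: (x.start, x.gene_id))):
                ranks[g.gene_id] = (chrom, i)
        return ranks

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_gff3(self.genes, outdir / "annotation.gff3")
        nio.write_fasta(self.proteins, outdir / "proteins.faa")
        nio.write_fasta(self.cds, outdir / "cds.fna")
        nio.write_domain_table(self.domain_calls, outdir / "domains.tsv")
        nio.write_homolog_pairs(self.homolog_pairs, outdir / "homolog_pairs.tsv")
        (outdir / "ground_truth.json").write_text(self.truth.to_json())


@dataclass
class CountSim:
    counts: pd.DataFrame
    samples: pd.DataFrame  # sample, tissue, stage, mapped_fragments
    truth: pd.DataFrame    # gene_id, preferred_tissue, role

    @property
    def totals(self) -> pd.Series:
        """True per-sample mapped-fragment totals (for FPKM)."""
        return self.samples.set_index("sample")["mapped_fragments"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "expression_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Small helpers

def _largest_remainder(weights: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    raw = {k: weights[k] * total for k in sorted(weights)}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    by_remainder = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.items():
    _AA_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_CODONS:
    _AA_CODONS[aa].sort()

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous reverse translation (never emits a stop codon)."""
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in protein)


def _family_sizes(n: int) -> list[int]:
    """Split n genes into homolog families of size 2 (and one 3 when odd)."""
    if n == 0:
        return []
    if n == 1:
        raise InvalidConfigError("a duplicate class needs at least 2 genes")
    if n % 2 == 0:
        return [2] * (n // 2)
    return [3] + [2] * ((n - 3) // 2)


def _pick_families(pool: Sequence[dict], target_genes: int) -> Optional[list[dict]]:
    """Choose families whose member counts sum exactly to ``target_genes``.

    Family sizes are 1-3, so a tiny exhaustive search over size
    multiplicities suffices.
    """
    if target_genes == 0:
        return []
    by_size: dict[int, list[dict]] = {1: [], 2: [], 3: []}
    for f in pool:
        by_size.setdefault(len(f["members"]), []).append(f)
    c1, c2, c3 = (len(by_size.get(s, [])) for s in (1, 2, 3))
    for x2 in range(min(c2, target_genes // 2), -1, -1):
        rem = target_genes - 2 * x2
        for x3 in range(min(c3, rem // 3), -1, -1):
            x1 = rem - 3 * x3
            if 0 <= x1 <= c1:
                return by_size[2][:x2] + by_size[3][:x3] + by_size[1][:x1]
    return None


def _solve_group_partition(sizes: Sequence[int], totals: Mapping[str, int]) -> Optional[dict[str, tuple[int, int, int]]]:
    """Assign family sizes (1/2/3) to groups to hit exact group totals.

    Returns per group (n_triples, n_pairs, n_singles) or None when
    infeasible.
    """
    c1 = sizes.count(1)
    c2 = sizes.count(2)
    c3 = sizes.count(3)
    names = sorted(totals, key=lambda g: -totals[g])

    def rec(i: int, r1: int, r2: int, r3: int, acc: dict) -> Optional[dict]:
        if i == len(names):
            return dict(acc) if (r1 == r2 == r3 == 0) else None
        t = totals[names[i]]
        for x3 in range(min(r3, t // 3), -1, -1):
            rem3 = t - 3 * x3
            for x2 in range(min(r2, rem3 // 2), -1, -1):
                x1 = rem3 - 2 * x2
                if x1 > r1:
                    continue
                acc[names[i]] = (x3, x2, x1)
                out = rec(i + 1, r1 - x1, r2 - x2, r3 - x3, acc)
                if out is not None:
                    return out
        return None

    return rec(0, c1, c2, c3, {})


# ---------------------------------------------------------------------------
# Codon-pair evolution

def evolve_codon_pair(
    ancestral_cds: str,
    omega: float,
    expected_subs: int,
    seed: int,
    frozen_codons: Sequence[int] = (),
) -> tuple[str, str]:
    """Evolve two descendants of one ancestor at a controlled Ka/Ks ratio.

    Substitutions are proposed uniformly over (codon, position, alternative
    base); proposals creating stop codons are rejected outright, and
    nonsynonymous/synonymous proposals are accepted with relative
    probabilities omega : 1 (normalised so the more likely class is always
    accepted).  ``expected_subs`` substitutions in total are split
    binomially between the two branches.  Codons listed in
    ``frozen_codons`` accept only synonymous change (used to keep planted
    motifs intact).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if expected_subs < 0:
        raise ValueError("expected_subs must be >= 0")
    codons = [ancestral_cds[i : i + 3].upper() for i in range(0, len(ancestral_cds), 3)]
    if len(ancestral_cds) % 3:
        raise ValueError("ancestral CDS length must be divisible by 3")
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestral CDS contains an internal stop codon")

    rng = np.random.default_rng(seed)
    n_a = int(rng.binomial(expected_subs, 0.5))
    frozen = frozenset(frozen_codons)
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)

    def branch(n_subs: int) -> list[str]:
        seq = list(codons)
        applied = 0
        while applied < n_subs:
            idx = int(rng.integers(len(seq)))
            pos = int(rng.integers(3))
            current = seq[idx]
            nt = NUCLEOTIDES[int(rng.integers(4))]
            if nt == current[pos]:
                continue
            mutant = current[:pos] + nt + current[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            synonymous = translate_codon(mutant) == translate_codon(current)
            if not synonymous and idx in frozen:
                continue
            accept_p = p_syn if synonymous else p_nonsyn
            if rng.random() < accept_p:
                seq[idx] = mutant
                applied += 1
        return seq

    a = "".join(branch(n_a))
    b = "".join(branch(expected_subs - n_a))
    return a, b


# ---------------------------------------------------------------------------
# Protein layout

_LINKER_GAP = 8  # residues between consecutive motifs


def _build_layout(
    library: MotifLibrary,
    codon_length: int,
    rng: np.random.Generator,
    verdict: str,
) -> tuple[str, dict[str, tuple[int, int]], tuple[int, int]]:
    """Protein of ``codon_length`` residues with motifs planted per verdict.

    Returns (protein, motif spans (0-based, end-exclusive) keyed by
    occurrence label, kinase-2 span).  Verdicts: 'conserved' plants the
    eight motifs in canonical order; 'flanked_repeat' adds a leading
    duplicate P-loop; 'core_change' swaps Kinase-2 and RNBS-B.
    """
    order = list(CANONICAL_ORDER)
    occurrences: list[tuple[str, str]] = [(name, name) for name in order]
    if verdict == "core_change":
        i, j = order.index("Kinase-2"), order.index("RNBS-B")
        occurrences[i], occurrences[j] = occurrences[j], occurrences[i]
    elif verdict == "flanked_repeat":
        occurrences = [("P-loop@flank", "P-loop")] + occurrences

    linker = lambda n: "".join(rng.choice(list(_AMINO_ACIDS), size=n))
    parts: list[str] = [linker(12)]
    spans: dict[str, tuple[int, int]] = {}
    pos = 12
    for label, name in occurrences:
        motif = library.get(name)
        spans[label] = (pos, pos + motif.width)
        parts.append(motif.consensus)
        pos += motif.width
        parts.append(linker(_LINKER_GAP))
        pos += _LINKER_GAP
    tail = codon_length - pos
    if tail < 0:
        raise InvalidConfigError("codon_length too short for the motif layout")
    parts.append(linker(tail))
    protein = "".join(parts)
    k2 = spans["Kinase-2"]
    return protein, spans, k2


def _set_codon_for_residue(cds: list[str], codon_idx: int, residue: str, rng: np.random.Generator) -> None:
    cds[codon_idx] = str(rng.choice(_AA_CODONS[residue]))


# ---------------------------------------------------------------------------
# Genome generation

def generate_genome(config: SimConfig) -> SyntheticGenome:
    """Generate a genome annotation, sequences, domain calls, homolog pairs
    and the matching ground truth.  Deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = load_default_library()

    n = config.n_nbs_genes
    gene_ids = [f"NBS{i + 1:03d}" for i in range(n)]
    dup = config.dup_counts()
    n_free = n - sum(dup.values())

    # --- homolog families ------------------------------------------------
    families: list[dict] = []  # {members, dup_type, group, omega, subs}
    remaining = list(gene_ids)

    def pop(k: int) -> list[str]:
        out = remaining[:k]
        del remaining[:k]
        return out

    for size in _family_sizes(dup["tandem"]):
        families.append({"members": pop(size), "dup_type": "tandem"})
    for size in _family_sizes(dup["proximal"]):
        families.append({"members": pop(size), "dup_type": "proximal"})
    for _ in range(dup["wgd"] // 2):
        families.append({"members": pop(2), "dup_type": "wgd_segmental"})
    # dispersed: unplaced genes each pair with a placed partner
    n_disp = dup["dispersed"]
    unplaced_ids: list[str] = []
    for _ in range(config.n_unplaced):
        a, b = pop(2)
        unplaced_ids.append(a)
        families.append({"members": [a, b], "dup_type": "dispersed", "unplaced": [a]})
        n_disp -= 2
    for size in _family_sizes(n_disp):
        families.append({"members": pop(size), "dup_type": "dispersed"})
    for gid in pop(n_free):
        families.append({"members": [gid], "dup_type": "singleton"})
    assert not remaining

    # --- groups and subclasses -------------------------------------------
    group_totals = config.group_counts()
    sizes = [len(f["members"]) for f in families]
    partition = _solve_group_partition(sizes, group_totals)
    if partition is None:
        raise InvalidConfigError(
            "cannot partition homolog families into the requested group totals"
        )
    by_size: dict[int, list[dict]] = {1: [], 2: [], 3: []}
    for f in families:
        by_size[len(f["members"])].append(f)
    for fams in by_size.values():
        rng.shuffle(fams)
    for grp in sorted(group_totals):
        x3, x2, x1 = partition[grp]
        for size, count in ((3, x3), (2, x2), (1, x1)):
            for _ in range(count):
                by_size[size].pop()["group"] = grp

    omega_map = dict(config.omega_by_group)
    for f in families:
        f["omega"] = omega_map.get(f["group"], 0.31)
        f["subs"] = config.rnl_expected_subs if f["group"] == "RNL" else config.pair_expected_subs

    subclass_counts = config.subclass_counts()
    subclass_of: dict[str, str] = {}
    for grp in ("CNL", "TNL", "RNL"):
        members = [g for f in families if f["group"] == grp for g in f["members"]]
        rng.shuffle(members)
        pool = [s for s in sorted(subclass_counts) if SUBCLASS_TO_GROUP[s] == grp]
        labels = [s for s in pool for _ in range(subclass_counts[s])]
        for gid, sub in zip(members, labels):
            subclass_of[gid] = sub

    # --- kinase-2 terminal residues --------------------------------------
    forced_w = {g for g, s in subclass_of.items() if s in ("NL_CC", "N_CC")}
    forced_d = {g for g, s in subclass_of.items() if s in ("NL_TIR", "N_TIR")}
    ntnl = [g for g, s in subclass_of.items() if SUBCLASS_TO_GROUP[s] in ("CNL", "RNL")]
    tnl = [g for g, s in subclass_of.items() if SUBCLASS_TO_GROUP[s] == "TNL"]
    if config.kinase2_w_ntnl < len(forced_w) or config.kinase2_w_ntnl > len(ntnl):
        raise InvalidConfigError("kinase2_w_ntnl incompatible with subclass mix")
    if config.kinase2_d_tnl < len(forced_d) or config.kinase2_d_tnl > len(tnl):
        raise InvalidConfigError("kinase2_d_tnl incompatible with subclass mix")
    kinase2: dict[str, str] = {g: "W" for g in forced_w}
    kinase2.update({g: "D" for g in forced_d})
    free_ntnl = sorted(set(ntnl) - forced_w)
    rng.shuffle(free_ntnl)
    need_w = config.kinase2_w_ntnl - len(forced_w)
    for i, g in enumerate(free_ntnl):
        kinase2[g] = "W" if i < need_w else "D"
    free_tnl = sorted(set(tnl) - forced_d)
    rng.shuffle(free_tnl)
    need_d = config.kinase2_d_tnl - len(forced_d)
    for i, g in enumerate(free_tnl):
        kinase2[g] = "D" if i < need_d else "W"

    # --- motif-order verdicts (assigned per family, exact gene totals) ----
    for f in families:
        f["verdict"] = "conserved"
    pool = list(families)
    rng.shuffle(pool)
    for verdict, target in (
        ("core_change", config.motif_core_change_genes),
        ("flanked_repeat", config.motif_flanked_genes),
    ):
        chosen = _pick_families(pool, target)
        if chosen is None:
            raise InvalidConfigError("could not place the requested motif-order exceptions")
        for f in chosen:
            f["verdict"] = verdict
            pool.remove(f)

    # --- sequences --------------------------------------------------------
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    pair_omega: dict[tuple[str, str], float] = {}
    homolog_pairs: list[HomologPair] = []

    for f in sorted(families, key=lambda f: f["members"][0]):
        layout_protein, spans, k2_span = _build_layout(
            library, config.codon_length, rng, f["verdict"]
        )
        ancestor = reverse_translate(layout_protein, rng)
        frozen = [i for (s, e) in spans.values() for i in range(s, e)]
        members = f["members"]
        descendants: list[str] = []
        for _gid in members:
            a, _ = evolve_codon_pair(
                ancestor, f["omega"], f["subs"], seed=int(rng.integers(2**31)),
                frozen_codons=frozen,
            )
            descendants.append(a)
        for gid, seq in zip(members, descendants):
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            _set_codon_for_residue(codons, k2_span[1] - 1, kinase2[gid], rng)
            cds[gid] = "".join(codons)
            proteins[gid] = "".join(translate_codon(c) for c in codons)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair_omega[(members[i], members[j])] = f["omega"]

    # --- motif dropout (conserved-layout genes only) ----------------------
    dropout_pool = [
        g
        for f in families
        if f["verdict"] == "conserved" and f["group"] != "RNL"
        for g in f["members"]
    ]
    rng.shuffle(dropout_pool)
    cursor = 0
    for motif_name, count in config.motif_dropout:
        motif = library.get(motif_name)
        for _ in range(count):
            if cursor >= len(dropout_pool):
                raise InvalidConfigError("not enough conserved genes for motif dropout")
            gid = dropout_pool[cursor]
            cursor += 1
            prot = proteins[gid]
            start = prot.find(motif.consensus)
            if start < 0:
                continue  # motif already degraded; nothing to remove
            replacement = "".join(rng.choice(list("ACEQ"), size=motif.width))
            new_prot = prot[:start] + replacement + prot[start + motif.width :]
            codons = [cds[gid][i : i + 3] for i in range(0, len(cds[gid]), 3)]
            for off, res in enumerate(replacement):
                _set_codon_for_residue(codons, start + off, res, rng)
            cds[gid] = "".join(codons)
            proteins[gid] = new_prot

    # homolog-pair identities from the final proteins
    for (a, b) in sorted(pair_omega):
        ident = float(np.mean([x == y for x, y in zip(proteins[a], proteins[b])]))
        homolog_pairs.append(HomologPair(a, b, round(ident, 4), config.codon_length))

    # --- exon structure ----------------------------------------------------
    exon_counts: dict[str, int] = {}
    for grp in ("CNL", "TNL", "RNL"):
        members = sorted(g for g, s in subclass_of.items() if SUBCLASS_TO_GROUP[s] == grp)
        template = _EXON_TEMPLATES.get(grp)
        if template is not None and len(template) == len(members):
            counts = list(template)
        else:
            cap = max(1, min(15, (config.codon_length * 3) // 60))
            counts = list(np.minimum(rng.geometric(0.35, size=len(members)), cap))
        rng.shuffle(counts)
        for gid, c in zip(members, counts):
            exon_counts[gid] = int(c)

    # --- placement ---------------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    units: list[dict] = []   # {kind, genes, chrom(optional), ...}

    tandem_fams = sorted(
        [f for f in families if f["dup_type"] == "tandem"],
        key=lambda f: -len(f["members"]),
    )
    cluster_bins = [
        {"capacity": size, "max_gap": gap, "genes": []}
        for size, gap in sorted(config.cluster_spec, key=lambda x: -x[0])
    ]
    tandem_overflow: list[dict] = []
    for fam in tandem_fams:
        size = len(fam["members"])
        target = next(
            (b for b in cluster_bins if b["capacity"] - len(b["genes"]) >= size), None
        )
        if target is None:
            # rank-adjacent but widely spaced: tandem without being clustered
            tandem_overflow.append(fam)
        else:
            target["genes"].extend(fam["members"])

    # cluster fillers: placed partners of unplaced genes first, then
    # singleton-type genes, then one member per dispersed family.
    filler_queue: list[tuple[str, Optional[dict]]] = []
    for f in families:
        if f["dup_type"] == "dispersed" and f.get("unplaced"):
            placed = [g for g in f["members"] if g not in f["unplaced"]]
            filler_queue.extend((g, None) for g in placed)
    for f in families:
        if f["dup_type"] == "singleton":
            filler_queue.extend((g, None) for g in f["members"])
    for f in families:
        if f["dup_type"] == "dispersed" and not f.get("unplaced"):
            filler_queue.append((f["members"][0], f))

    used_as_filler: set[str] = set()
    qi = 0
    for b in cluster_bins:
        while len(b["genes"]) < b["capacity"]:
            if qi >= len(filler_queue):
                raise InvalidConfigError("not enough geometry-free genes to fill clusters")
            gid, fam = filler_queue[qi]
            qi += 1
            b["genes"].append(gid)
            used_as_filler.add(gid)
            if fam is not None:
                fam["filler_gene"] = gid

    for idx, b in enumerate(cluster_bins):
        units.append({"kind": "cluster", "genes": b["genes"], "max_gap": b["max_gap"],
                      "cluster_index": idx})

    for fam in tandem_overflow:
        units.append({"kind": "tandem_spread", "genes": list(fam["members"])})

    for f in families:
        if f["dup_type"] == "proximal":
            units.append({"kind": "proximal", "genes": list(f["members"])})

    wgd_units: list[tuple[dict, dict]] = []
    for f in families:
        if f["dup_type"] == "wgd_segmental":
            g1, g2 = f["members"]
            u1 = {"kind": "wgd_run", "genes": [g1], "anchor_tag": g1}
            u2 = {"kind": "wgd_run", "genes": [g2], "anchor_tag": g2, "mirror_of": g1}
            wgd_units.append((u1, u2))

    single_genes = [
        gid
        for f in families
        for gid in f["members"]
        if f["dup_type"] in ("dispersed", "singleton")
        and gid not in used_as_filler
        and gid not in unplaced_ids
    ]

    # chromosome assignment: wgd mirrors first (distinct chroms), then big
    # units round-robin over a shuffled chromosome list.
    order = list(chroms)
    rng.shuffle(order)
    assignments: list[tuple[dict, str]] = []
    ci = 0
    for u1, u2 in wgd_units:
        c1 = order[ci % len(order)]
        c2 = order[(ci + 1) % len(order)]
        ci += 2
        if c1 == c2:
            raise InvalidConfigError("need >= 2 chromosomes for wgd pairs")
        assignments.append((u1, c1))
        assignments.append((u2, c2))
    big_units = [u for u in units if u["kind"] in ("cluster", "proximal", "tandem_spread")]
    rng.shuffle(big_units)
    for u in big_units:
        assignments.append((u, order[ci % len(order)]))
        ci += 1

    chrom_of_gene: dict[str, str] = {}
    for u, c in assignments:
        for g in u["genes"]:
            chrom_of_gene[g] = c

    # dispersed singles: keep every family spread over distinct chromosomes.
    single_units: list[tuple[dict, str]] = []
    fam_of: dict[str, dict] = {g: f for f in families for g in f["members"]}
    for gid in sorted(single_genes):
        fam = fam_of[gid]
        taken = {chrom_of_gene[m] for m in fam["members"] if m in chrom_of_gene}
        options = [c for c in chroms if c not in taken]
        if not options:
            raise InvalidConfigError("not enough chromosomes to spread a dispersed family")
        c = options[int(rng.integers(len(options)))]
        chrom_of_gene[gid] = c
        single_units.append(({"kind": "single", "genes": [gid]}, c))

    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for u, c in assignments + single_units:
        per_chrom[c].append(u)

    # --- lay out coordinates ----------------------------------------------
    genes_out: list[GeneModel] = []
    background_counter = 0

    def new_background(chrom: str, start: int, rng: np.random.Generator) -> GeneModel:
        nonlocal background_counter
        background_counter += 1
        length = int(rng.integers(1_000, 5_000))
        return GeneModel(
            gene_id=f"BG{background_counter:04d}",
            chromosome=chrom,
            start=start,
            end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
            exons=((start, start + length - 1),),
        )

    def nbs_gene(gid: str, chrom: str, start: int) -> GeneModel:
        k = exon_counts[gid]
        exonic = config.codon_length * 3
        lengths = np.full(k, exonic // k)
        lengths[: exonic % k] += 1
        introns = rng.integers(200, 4_000, size=max(0, k - 1))
        exons = []
        pos = start
        for i in range(k):
            exons.append((pos, pos + int(lengths[i]) - 1))
            pos = exons[-1][1] + 1
            if i < k - 1:
                pos += int(introns[i])
        end = exons[-1][1]
        return GeneModel(
            gene_id=gid, chromosome=chrom, start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-", exons=tuple(exons),
        )

    anchor_runs: dict[str, list[str]] = {}  # wgd gene -> ordered anchor ids
    window = config.window_bp

    for chrom in chroms:
        chrom_units = per_chrom[chrom]
        rng.shuffle(chrom_units)
        pos = int(rng.integers(200_000, 600_000))
        gap_boundaries: list[tuple[int, int]] = []
        last_end = 0
        for u in chrom_units:
            if last_end:
                gap_boundaries.append((last_end, pos))
            if u["kind"] == "cluster":
                for i, gid in enumerate(u["genes"]):
                    g = nbs_gene(gid, chrom, pos)
                    genes_out.append(g)
                    gap = int(rng.integers(2_000, max(2_001, u["max_gap"])))
                    pos = g.end + 1 + gap
                pos = genes_out[-1].end + 1
            elif u["kind"] == "tandem_spread":
                for i, gid in enumerate(u["genes"]):
                    g = nbs_gene(gid, chrom, pos)
                    genes_out.append(g)
                    pos = g.end + 1 + int(rng.integers(window + 20_000, window + 120_000))
                pos = genes_out[-1].end + 1
            elif u["kind"] == "proximal":
                for i, gid in enumerate(u["genes"]):
                    g = nbs_gene(gid, chrom, pos)
                    genes_out.append(g)
                    if i < len(u["genes"]) - 1:
                        gap = int(rng.integers(window + 20_000, window + 80_000))
                        # sprinkle intervening background genes (rank spacing)
                        n_between = 4
                        step = gap // (n_between + 1)
                        for b in range(n_between):
                            bstart = g.end + 1 + (b + 1) * step + int(rng.integers(0, 5_000))
                            genes_out.append(new_background(chrom, bstart, rng))
                        pos = g.end + 1 + gap
                    else:
                        pos = g.end + 1
            elif u["kind"] == "wgd_run":
                tag = u["anchor_tag"]
                anchors: list[str] = []
                slots = 7  # 6 anchors + the NBS gene in the middle
                gene_slot = 3
                for s in range(slots):
                    if s == gene_slot:
                        g = nbs_gene(u["genes"][0], chrom, pos)
                        genes_out.append(g)
                        pos = g.end + 1 + int(rng.integers(20_000, 80_000))
                    else:
                        bg = new_background(chrom, pos, rng)
                        genes_out.append(bg)
                        anchors.append(bg.gene_id)
                        pos = bg.end + 1 + int(rng.integers(20_000, 80_000))
                anchor_runs[tag] = anchors
            else:  # single
                g = nbs_gene(u["genes"][0], chrom, pos)
                genes_out.append(g)
                pos = g.end + 1
            last_end = pos
            pos += int(rng.integers(window + 50_000, window + 650_000))
        # background fillers in inter-unit gaps (never inside a unit)
        for _ in range(config.n_background_per_chrom):
            if not gap_boundaries:
                break
            lo, hi = gap_boundaries[int(rng.integers(len(gap_boundaries)))]
            if hi - lo < 120_000:
                continue
            bstart = int(rng.integers(lo + 50_000, hi - 60_000))
            genes_out.append(new_background(chrom, bstart, rng))

    # unplaced contigs
    pos = 1_000
    for gid in unplaced_ids:
        g = nbs_gene(gid, UNPLACED, pos)
        genes_out.append(g)
        pos = g.end + 1 + 100_000

    # wgd anchor homology (mirrored runs, same order)
    for f in families:
        if f["dup_type"] == "wgd_segmental":
            g1, g2 = f["members"]
            for a1, a2 in zip(anchor_runs[g1], anchor_runs[g2]):
                homolog_pairs.append(
                    HomologPair(a1, a2, round(float(rng.uniform(0.5, 0.9)), 4), 200)
                )

    # --- domain calls -------------------------------------------------------
    domain_calls: list[DomainCall] = []
    has_lrr = {"CNL", "NL_CC", "TNL", "NL_TIR", "RNL"}
    for gid in gene_ids:
        sub = subclass_of[gid]
        L = config.codon_length
        e_nbs = 10.0 ** float(rng.uniform(-30, -6))
        domain_calls.append(DomainCall(gid, "NBS", 60, 230, e_value=e_nbs, source="sim"))
        if sub in ("CNL", "CN"):
            cc = float(rng.uniform(0.6, 0.95))
            domain_calls.append(DomainCall(gid, "CC", 5, 40, cc_score=round(cc, 3), source="sim"))
        if sub in ("TNL", "TN"):
            e = 10.0 ** float(rng.uniform(-20, -6))
            domain_calls.append(DomainCall(gid, "TIR", 5, 55, e_value=e, source="sim"))
        if sub == "RNL":
            e = 10.0 ** float(rng.uniform(-20, -6))
            domain_calls.append(DomainCall(gid, "RPW8", 5, 50, e_value=e, source="sim"))
        if sub in has_lrr:
            e = 10.0 ** float(rng.uniform(-15, -5))
            domain_calls.append(DomainCall(gid, "LRR", 240, L - 5, e_value=e, source="sim"))

    # --- ground truth -------------------------------------------------------
    cluster_of: dict[str, Optional[int]] = {g: None for g in gene_ids}
    for u in units:
        if u["kind"] == "cluster":
            for g in u["genes"]:
                cluster_of[g] = u["cluster_index"]
    duplication = {g: fam_of[g]["dup_type"] for g in gene_ids}
    motif_verdict = {g: fam_of[g]["verdict"] for g in gene_ids}

    truth = GroundTruth(
        subclass=dict(sorted(subclass_of.items())),
        cluster_of=dict(sorted(cluster_of.items())),
        duplication=dict(sorted(duplication.items())),
        pair_omega=pair_omega,
        kinase2_residue=dict(sorted(kinase2.items())),
        motif_verdict=dict(sorted(motif_verdict.items())),
    )
    genes_out.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return SyntheticGenome(
        config=config,
        genes=genes_out,
        nbs_gene_ids=list(gene_ids),
        proteins=dict(sorted(proteins.items())),
        cds=dict(sorted(cds.items())),
        domain_calls=domain_calls,
        homolog_pairs=homolog_pairs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Counts

def generate_counts(
    config: SimConfig,
    gene_lengths: Mapping[str, float],
    rnl_genes: Sequence[str] = (),
) -> CountSim:
    """Negative-binomial counts over 3 tissues x 4 stages with planted truth.

    ``rnl_genes`` (if given) are preferred when picking the planted
    high-expression gene, mirroring a strongly expressed helper-class gene.
    """
    spec = config.expr_spec
    if spec.nb_size <= 0:
        raise ValueError("negative-binomial size must be positive")
    rng = np.random.default_rng([config.seed, 7])
    genes = sorted(gene_lengths)
    if spec.n_silent + spec.n_high > len(genes):
        raise ValueError("expr_spec silent + high genes exceed gene count")

    from .expression import STAGES, TISSUES

    samples = pd.DataFrame(
        [(f"{t}_{s}", t, s) for t in TISSUES for s in STAGES],
        columns=["sample", "tissue", "stage"],
    )
    means = spec.means()

    shuffled = list(genes)
    rng.shuffle(shuffled)
    silent = set(shuffled[: spec.n_silent])
    expressed = [g for g in shuffled if g not in silent]
    high_pool = [g for g in rnl_genes if g in expressed] or expressed
    high = set(high_pool[: spec.n_high])

    frac = dict(spec.preferred_fractions)
    pref_counts = _largest_remainder(frac, len(expressed))
    preferred: dict[str, str] = {}
    cursor = 0
    ordered = [g for g in expressed if g not in high] + [g for g in expressed if g in high]
    # planted high genes prefer rind
    for g in high:
        preferred[g] = "rind"
        pref_counts["rind"] = max(0, pref_counts.get("rind", 0) - 1)
    rest = [g for g in ordered if g not in preferred]
    labels = [t for t in sorted(pref_counts) for _ in range(pref_counts[t])]
    for g, t in zip(rest, labels):
        preferred[g] = t
    for g in rest[len(labels):]:
        preferred[g] = "rind"

    gene_factor = {
        g: float(rng.lognormal(0.0, spec.gene_factor_sigma)) for g in genes
    }
    size_factor = {
        s: float(rng.lognormal(0.0, spec.size_factor_sigma)) for s in samples["sample"]
    }
    samples = samples.assign(
        mapped_fragments=[spec.library_size * size_factor[s] for s in samples["sample"]]
    )

    matrix = np.zeros((len(genes), len(samples)), dtype=np.int64)
    truth_rows = []
    late = {"enlargement", "coloring", "mature"}
    sample_meta = list(zip(samples["sample"], samples["tissue"], samples["stage"]))
    for gi, g in enumerate(genes):
        for si, (sample, tissue, stage) in enumerate(sample_meta):
            if g in silent:
                continue
            fpkm_true = means.get((tissue, stage), 0.0)
            if tissue == preferred[g]:
                fpkm_true *= spec.preference_boost
            if g in high and tissue == "rind" and stage in late:
                fpkm_true = spec.high_fpkm
            fpkm_true *= gene_factor[g]
            n_frag = spec.library_size * size_factor[sample]
            mu = fpkm_true * n_frag * gene_lengths[g] / 1e9
            if mu <= 0:
                continue
            p = spec.nb_size / (spec.nb_size + mu)
            matrix[gi, si] = rng.negative_binomial(spec.nb_size, p)
        truth_rows.append(
            (
                g,
                preferred.get(g, ""),
                "silent" if g in silent else ("high" if g in high else "background"),
            )
        )

    counts = pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"),
                          columns=list(samples["sample"]))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "preferred_tissue", "role"])
    return CountSim(counts=counts, samples=samples, truth=truth)
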