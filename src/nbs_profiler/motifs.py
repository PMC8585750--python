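"""Conserved NBS-domain motif scanning and motif-order analysis.

The NB-ARC domain of plant resistance proteins carries eight short motifs in
a canonical N-to-C order: P-loop, RNBS-A, kinase-2, RNBS-B, RNBS-C, GLPL,
RNBS-D and MHDL.  This module locates them with a curated library of
position-specific residue-class patterns (a deliberate, configurable
replacement for de-novo discovery: the downstream analyses — order
conservation and the kinase-2 terminal residue — depend only on where the
motifs sit, not on rediscovering them), judges whether a protein keeps the
canonical motif order, and reads off the last residue of the kinase-2 motif,
which discriminates TNL (aspartate, D) from non-TNL (tryptophan, W)
proteins.

Scoring is +1 per position whose residue falls in the pattern's residue
class; a window is a hit when its score reaches the motif's minimum score
(80% of the width by default).  Overlapping candidate hits are resolved
highest-score-first, ties broken leftmost, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .models import MotifHit, MotifOrderCall

__all__ = [
    "CANONICAL_ORDER",
    "Motif",
    "MotifLibrary",
    "load_default_library",
    "scan_motifs",
    "classify_motif_order",
    "kinase2_terminal_residue",
    "kinase2_frequency_table",
]

CANONICAL_ORDER = (
    "P-loop",
    "RNBS-A",
    "Kinase-2",
    "RNBS-B",
    "RNBS-C",
    "GLPL",
    "RNBS-D",
    "MHDL",
)

_MIN_WIDTH, _MAX_WIDTH = 6, 50


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: tuple[str, ...]  # one residue-class string per position
    min_score: int

    def __post_init__(self) -> None:
        if not (_MIN_WIDTH <= len(self.pattern) <= _MAX_WIDTH):
            raise ValueError(f"{self.name}: width {len(self.pattern)} outside [{_MIN_WIDTH}, {_MAX_WIDTH}]")
        if not (0 < self.min_score <= len(self.pattern)):
            raise ValueError(f"{self.name}: min_score must be in (0, width]")

    @property
    def width(self) -> int:
        return len(self.pattern)

    @property
    def consensus(self) -> str:
        return "".join(cls[0] for cls in self.pattern)

    def score(self, window: str) -> int:
        return sum(1 for res, cls in zip(window, self.pattern) if res in cls)


@dataclass(frozen=True)
class MotifLibrary:
    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate motif names in library")

    def __iter__(self):
        return iter(self.motifs)

    def get(self, name: str) -> Motif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifLibrary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "MotifLibrary":
        motifs = []
        for entry in raw["motifs"]:
            pattern = tuple(str(p) for p in entry["pattern"])
            default_min = max(1, -(-len(pattern) * 4 // 5))  # ceil(0.8 * width)
            motifs.append(Motif(entry["name"], pattern, int(entry.get("min_score", default_min))))
        return cls(tuple(motifs))


def load_default_library() -> MotifLibrary:
    """The packaged NBS motif library (canonical eight motifs)."""
    ref = resources.files("nbs_profiler").joinpath("data/motif_library.yaml")
    with resources.as_file(ref) as path:
        return MotifLibrary.from_yaml(path)


def scan_motifs(
    protein: str,
    library: Optional[MotifLibrary] = None,
    gene_id: str = "",
) -> list[MotifHit]:
    """All non-overlapping motif hits above threshold, in position order.

    Candidate windows for every motif are pooled, then accepted greedily by
    descending score (ties: leftmost start, then library order), skipping
    windows that overlap an already accepted hit.
    """
    if library is None:
        library = load_default_library()
    if not protein:
        return []

    candidates: list[tuple[int, int, int, int, str]] = []  # (-score, start0, lib_idx, width, name)
    for idx, motif in enumerate(library):
        w = motif.width
        for start0 in range(0, len(protein) - w + 1):
            s = motif.score(protein[start0 : start0 + w])
            if s >= motif.min_score:
                candidates.append((-s, start0, idx, w, motif.name))

    candidates.sort()
    occupied: list[tuple[int, int]] = []  # accepted [start0, end0) intervals
    accepted: list[MotifHit] = []
    for neg_score, start0, _idx, w, name in candidates:
        end0 = start0 + w
        if any(start0 < oe and os_ < end0 for os_, oe in occupied):
            continue
        occupied.append((start0, end0))
        accepted.append(
            MotifHit(gene_id=gene_id, motif=name, start=start0 + 1,
                     match=protein[start0:end0], score=-neg_score)
        )
    accepted.sort(key=lambda h: h.start)
    return accepted


def _is_canonical_subsequence(names: Sequence[str], order: Sequence[str] = CANONICAL_ORDER) -> bool:
    """True when ``names`` are distinct and appear in canonical relative order."""
    if len(set(names)) != len(names):
        return False
    pos = {n: i for i, n in enumerate(order)}
    ranks = [pos.get(n) for n in names]
    if any(r is None for r in ranks):
        return False
    return all(a < b for a, b in zip(ranks, ranks[1:]))


def classify_motif_order(hits: Sequence[MotifHit]) -> MotifOrderCall:
    """Judge the motif arrangement of one protein.

    * ``conserved`` — the observed motif names are distinct and form a
      subsequence of the canonical order.
    * ``flanked_repeat`` — a maximal contiguous core in canonical order
      exists and every occurrence outside it repeats a motif already in the
      core (repeated motifs flanking an intact core).
    * ``core_change`` — otherwise: the core order itself deviates.
    * ``insufficient`` — fewer than two distinct motifs found.
    """
    observed = tuple(h.motif for h in sorted(hits, key=lambda h: h.start))
    if len(set(observed)) < 2:
        return MotifOrderCall("insufficient", observed)
    if _is_canonical_subsequence(observed):
        return MotifOrderCall("conserved", observed)

    # Longest contiguous run that is a canonical-order subsequence (leftmost
    # on ties) serves as the core.
    best: tuple[int, int] = (0, 1)  # (start, length)
    n = len(observed)
    for i in range(n):
        for j in range(i + best[1], n):  # only runs longer than current best
            if _is_canonical_subsequence(observed[i : j + 1]):
                if j - i + 1 > best[1]:
                    best = (i, j - i + 1)
            else:
                break
    core_start, core_len = best
    core = set(observed[core_start : core_start + core_len])
    extras = list(observed[:core_start]) + list(observed[core_start + core_len :])
    if all(e in core for e in extras):
        return MotifOrderCall("flanked_repeat", observed)
    return MotifOrderCall("core_change", observed)


def kinase2_terminal_residue(hits: Sequence[MotifHit]) -> Optional[str]:
    """Last residue of the best-scoring kinase-2 hit, or None without a hit."""
    k2 = [h for h in hits if h.motif == "Kinase-2"]
    if not k2:
        return None
    best = min(k2, key=lambda h: (-h.score, h.start))
    return best.match[-1]


def kinase2_frequency_table(
    groups: Mapping[str, str],
    residues: Mapping[str, Optional[str]],
    ntnl: Iterable[str] = ("CNL", "RNL"),
) -> dict:
    """Terminal-residue counts and percentages per TNL / non-TNL group.

    Percentages use the full group size as denominator (genes without a
    kinase-2 hit count against conservation), rounded to 1 decimal.
    """
    ntnl = set(ntnl)
    table: dict = {}
    for side, members in (
        ("nTNL", [g for g, grp in groups.items() if grp in ntnl]),
        ("TNL", [g for g, grp in groups.items() if grp == "TNL"]),
    ):
        counts: dict[str, int] = {}
        for g in members:
            res = residues.get(g)
            key = res if res is not None else "none"
            counts[key] = counts.get(key, 0) + 1
        n = len(members)
        table[side] = {
            "n": n,
            "counts": dict(sorted(counts.items())),
            "percentages": {
                k: round(100.0 * v / n, 1) for k, v in sorted(counts.items())
            } if n else {},
        }
    return table
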