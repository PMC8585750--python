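"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the quantities from first principles, by
exhaustive enumeration, without reusing the package's counting code.
"""

from __future__ import annotations

from Bio.Seq import Seq

NUCS = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    """Synonymous site count of a sense codon (stop changes disregarded)."""
    aa = _aa(codon)
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _aa(alt) == "*":
                continue
            valid += 1
            if _aa(alt) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def pair_diff_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by exhaustive pathway walking.

    Depth-first enumeration of every order in which the differing positions
    can be substituted; pathways passing through a stop codon are dropped
    (unless all are, in which case all count).  Each surviving pathway has
    equal weight.
    """
    diff = frozenset(i for i in range(3) if c1[i] != c2[i])
    paths: list[tuple[int, int, bool]] = []

    def walk(cur: str, remaining: frozenset, sd: int, nd: int, stopped: bool) -> None:
        if not remaining:
            paths.append((sd, nd, stopped))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = _aa(nxt) == _aa(cur)
            walk(nxt, remaining - {pos}, sd + syn, nd + (not syn),
                 stopped or _aa(nxt) == "*")

    walk(c1, diff, 0, 0, False)
    ok = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in ok) / len(ok), sum(p[1] for p in ok) / len(ok))


def cluster_oracle(intervals: dict[str, tuple[int, int]], window: float) -> list[frozenset]:
    """Connected components merging every gene pair with inter-gene gap <= window.

    ``intervals`` maps gene id -> (start, end) on one chromosome.  The gap
    between two genes is the bases between them (0 when they touch or
    overlap).
    """
    ids = sorted(intervals)
    parent = {g: g for g in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            (s1, e1), (s2, e2) = intervals[a], intervals[b]
            gap = max(0, max(s1, s2) - min(e1, e2))
            if gap <= window:
                union(a, b)
    comps: dict[str, set] = {}
    for g in ids:
        comps.setdefault(find(g), set()).add(g)
    return sorted((frozenset(c) for c in comps.values()), key=lambda c: sorted(c))
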