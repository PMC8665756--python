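"""Independent brute-force oracles used to audit the package.

Everything here works on plain strings and frozensets of taxon indices —
deliberately none of the 2-bit / bit-vector machinery of the package under
test.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations, product

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canonical_str(s: str) -> str:
    # lexicographic A<C<G<T order coincides with the 2-bit numeric order
    rc = revcomp(s)
    return s if s <= rc else rc


def genome_kmer_set(records: list[str], k: int) -> set[str]:
    """All canonical k-mers of a genome given as a list of record strings."""
    out: set[str] = set()
    for seq in records:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if all(c in "ACGT" for c in window):
                out.add(canonical_str(window))
    return out


def oracle_split_table(
    genomes: list[list[str]], k: int
) -> tuple[dict[frozenset[int], tuple[int, int]], int]:
    """Split -> (count_side, count_comp) by exhaustive set operations.

    Returns the table keyed by the canonical side (smaller subset; ties keep
    the side containing taxon 0) and the number of k-mers present in every
    genome (which separate nothing).
    """
    n = len(genomes)
    sets = [genome_kmer_set(records, k) for records in genomes]
    universe: set[str] = set().union(*sets) if sets else set()
    full = frozenset(range(n))
    pattern_counts: Counter[frozenset[int]] = Counter(
        frozenset(i for i in range(n) if kmer in sets[i]) for kmer in universe
    )
    n_ubiquitous = pattern_counts.pop(full, 0)
    table: dict[frozenset[int], list[int]] = {}
    for pattern, count in pattern_counts.items():
        comp = full - pattern
        if len(pattern) < len(comp) or (len(pattern) == len(comp) and 0 in pattern):
            side, slot = pattern, 0
        else:
            side, slot = comp, 1
        table.setdefault(side, [0, 0])[slot] += count
    return {side: (c[0], c[1]) for side, c in table.items()}, n_ubiquitous


def oracle_expand_iupac(window: str, codes: dict[str, str]) -> list[str]:
    """Cartesian expansion by explicit product enumeration (no cap)."""
    if any(ch not in codes for ch in window):
        return []
    return ["".join(p) for p in product(*(codes[ch] for ch in window))]


def oracle_compatible(a: frozenset[int], b: frozenset[int], n: int) -> bool:
    full = frozenset(range(n))
    return any(
        not (x & y) for x in (a, full - a) for y in (b, full - b)
    )


def oracle_weak_triple(
    a: frozenset[int], b: frozenset[int], c: frozenset[int], n: int
) -> bool:
    """All-8-orientations weak-compatibility check on frozensets."""
    full = frozenset(range(n))
    for a1 in (a, full - a):
        b1 = full - a1
        for a2 in (b, full - b):
            b2 = full - a2
            for a3 in (c, full - c):
                b3 = full - a3
                if (a1 & a2 & a3) and (a1 & b2 & b3) and (b1 & a2 & b3) and (b1 & b2 & a3):
                    return False
    return True


def audit_pairwise_compatible(sides: list[frozenset[int]], n: int) -> bool:
    return all(oracle_compatible(a, b, n) for a, b in combinations(sides, 2))


def audit_weakly_compatible(sides: list[frozenset[int]], n: int) -> bool:
    return all(
        oracle_weak_triple(a, b, c, n) for a, b, c in combinations(sides, 3)
    )


def sides_as_sets(system) -> list[frozenset[int]]:
    """Canonical sides of a package SplitSystem as frozensets of indices."""
    return [frozenset(ws.split.indices()) for ws in system.splits]
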