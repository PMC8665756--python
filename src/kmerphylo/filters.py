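"""Split-system filters: top-x, greedy tree, two greedy trees, weakly compatible.

All filters scan the system in its total sort order (weight descending,
side-bit-vector tiebreak), so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

from kmerphylo.splits import Split, SplitSystem, WeightedSplit

FilterMode = Literal["none", "topx", "strict", "2tree", "weakly"]


@dataclass(frozen=True)
class FilterConfig:
    mode: FilterMode = "none"
    x: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "topx" and (self.x is None or self.x < 0):
            raise ValueError("topx filter requires x >= 0")
        if self.mode != "topx" and self.x is not None:
            raise ValueError("x is only meaningful for the topx filter")


def compatible(s1: Split, s2: Split) -> bool:
    """Two splits A|B, C|D are compatible iff one of the four side
    intersections A∩C, A∩D, B∩C, B∩D is empty."""
    full = s1.full_mask
    a, c = s1.side, s2.side
    b, d = a ^ full, c ^ full
    return not (a & c) or not (a & d) or not (b & c) or not (b & d)


def weakly_compatible_triple(s1: Split, s2: Split, s3: Split) -> bool:
    """Weak-compatibility check for a triple of splits.

    For every orientation (A1, A2, A3) of the three splits' sides, at least one
    of A1∩A2∩A3, A1∩B2∩B3, B1∩A2∩B3, B1∩B2∩A3 must be empty.  All 8
    orientations are checked (4 are redundant by complement symmetry; the loop
    is cheap).
    """
    full = s1.full_mask
    for a1 in (s1.side, s1.side ^ full):
        b1 = a1 ^ full
        for a2 in (s2.side, s2.side ^ full):
            b2 = a2 ^ full
            for a3 in (s3.side, s3.side ^ full):
                b3 = a3 ^ full
                if (a1 & a2 & a3) and (a1 & b2 & b3) and (b1 & a2 & b3) and (b1 & b2 & a3):
                    return False
    return True


def filter_topx(system: SplitSystem, x: int) -> SplitSystem:
    """Keep the x highest-weighting splits (all of them if x exceeds the size)."""
    if x < 0:
        raise ValueError("x must be >= 0")
    return system.with_splits(system.splits[:x])


def filter_strict(system: SplitSystem) -> SplitSystem:
    """Greedily extract a pairwise-compatible (tree) subset in sort order."""
    kept: list[WeightedSplit] = []
    for ws in system.splits:
        if all(compatible(ws.split, other.split) for other in kept):
            kept.append(ws)
    return system.with_splits(kept)


def filter_2tree(system: SplitSystem) -> SplitSystem:
    """Greedily fill two pairwise-compatible bins; return their union.

    A split goes to the second bin only after the first bin rejects it; bins
    are never rebalanced.  The union is returned in system order (each bin is
    itself pairwise compatible).
    """
    tree1: list[WeightedSplit] = []
    tree2: list[WeightedSplit] = []
    kept: list[WeightedSplit] = []
    for ws in system.splits:
        if all(compatible(ws.split, other.split) for other in tree1):
            tree1.append(ws)
            kept.append(ws)
        elif all(compatible(ws.split, other.split) for other in tree2):
            tree2.append(ws)
            kept.append(ws)
    return system.with_splits(kept)


def two_tree_bins(system: SplitSystem) -> tuple[list[WeightedSplit], list[WeightedSplit]]:
    """The two bins the 2-tree filter would build (for auditing/logging)."""
    tree1: list[WeightedSplit] = []
    tree2: list[WeightedSplit] = []
    for ws in system.splits:
        if all(compatible(ws.split, other.split) for other in tree1):
            tree1.append(ws)
        elif all(compatible(ws.split, other.split) for other in tree2):
            tree2.append(ws)
    return tree1, tree2


def filter_weakly(system: SplitSystem) -> SplitSystem:
    """Greedily extract a weakly compatible subset in sort order.

    A candidate is kept iff every triple it forms with two already-kept splits
    passes :func:`weakly_compatible_triple`; with fewer than two kept splits it
    is always kept.  The kept set is weakly compatible by induction.
    """
    kept: list[WeightedSplit] = []
    for ws in system.splits:
        ok = all(
            weakly_compatible_triple(ws.split, a.split, b.split)
            for a, b in combinations(kept, 2)
        )
        if ok:
            kept.append(ws)
    return system.with_splits(kept)


def apply_filter(system: SplitSystem, config: FilterConfig) -> SplitSystem:
    if config.mode == "none":
        return system
    if config.mode == "topx":
        assert config.x is not None
        return filter_topx(system, config.x)
    if config.mode == "strict":
        return filter_strict(system)
    if config.mode == "2tree":
        return filter_2tree(system)
    if config.mode == "weakly":
        return filter_weakly(system)
    raise ValueError(f"unknown filter mode {config.mode!r}")
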