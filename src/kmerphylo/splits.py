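"""Splits: collapse presence/absence patterns into weighted bipartitions.

Second stage of the pipeline: the color table is scanned once, k-mers sharing
a pattern are counted, each pattern is merged with its complement into one
canonical split, and the two counts are combined into a weight (geometric
mean, by default with +1 pseudocounts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

from kmerphylo.kmers import ColorTable
from kmerphylo.seqio import TaxonTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Split:
    """Canonical bipartition of n taxa, stored as the bit vector of one side.

    Canonical form: ``side`` is the smaller of the two subsets; on a tie
    (|side| == n/2) the side containing taxon index 0 is kept.
    """

    side: int
    n: int

    @property
    def size(self) -> int:
        return self.side.bit_count()

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    @property
    def complement(self) -> int:
        return self.side ^ self.full_mask

    @property
    def is_trivial(self) -> bool:
        return self.size == 1 or self.size == self.n - 1

    def indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n) if self.side >> i & 1)

    def names(self, taxa: TaxonTable) -> tuple[str, ...]:
        return tuple(taxa.names[i] for i in self.indices())


class SplitCounts(NamedTuple):
    count_side: int
    count_comp: int


@dataclass(frozen=True)
class WeightedSplit:
    split: Split
    counts: SplitCounts
    weight: float


@dataclass(frozen=True)
class SplitSystem:
    """Splits over one taxon table, sorted by weight descending.

    Ties are broken by the side bit vector (ascending integer value) so output
    files are byte-reproducible.
    """

    taxa: TaxonTable
    splits: tuple[WeightedSplit, ...]

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def with_splits(self, splits: Iterable[WeightedSplit]) -> "SplitSystem":
        return replace(self, splits=tuple(splits))

    def sides(self) -> set[int]:
        return {ws.split.side for ws in self.splits}


def canonical_side(pattern: int, n: int) -> int:
    """The canonical side mask of the bipartition separating ``pattern``."""
    full = (1 << n) - 1
    comp = pattern ^ full
    pc, cc = pattern.bit_count(), comp.bit_count()
    if pc < cc:
        return pattern
    if cc < pc:
        return comp
    return pattern if pattern & 1 else comp


def sort_key(ws: WeightedSplit) -> tuple[float, int]:
    return (-ws.weight, ws.split.side)


def aggregate_splits(table: ColorTable) -> tuple[dict[Split, SplitCounts], int]:
    """Group k-mers by pattern and merge complementary patterns into splits.

    Returns the mapping split -> (count_side, count_comp) and the number of
    all-ones k-mers (present in every file) that were discarded: a k-mer shared
    by all genomes separates nothing.
    """
    n = table.n
    full = (1 << n) - 1
    pattern_counts: dict[int, int] = {}
    for pattern in table.patterns.values():
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    n_ubiquitous = pattern_counts.pop(full, 0)
    result: dict[Split, SplitCounts] = {}
    for pattern, count in pattern_counts.items():
        side = canonical_side(pattern, n)
        split = Split(side=side, n=n)
        prev = result.get(split, SplitCounts(0, 0))
        if pattern == side:
            result[split] = SplitCounts(prev.count_side + count, prev.count_comp)
        else:
            result[split] = SplitCounts(prev.count_side, prev.count_comp + count)
    if n_ubiquitous:
        logger.info("discarded %d k-mers present in all %d files", n_ubiquitous, n)
    return result, n_ubiquitous


def split_weight(counts: SplitCounts, pseudocount: bool = True) -> float:
    """Geometric mean of the two complementary pattern counts.

    With ``pseudocount`` (the default) one is added to each count first.
    """
    c1, c2 = counts
    if pseudocount:
        c1, c2 = c1 + 1, c2 + 1
    return math.sqrt(c1 * c2)


def build_split_system(
    table: ColorTable,
    taxa: TaxonTable,
    pseudocount: bool = True,
) -> SplitSystem:
    """Aggregate patterns, weight each split and sort deterministically.

    Trivial splits (single taxon vs rest) are included like any other split.
    """
    if table.n != taxa.n:
        raise ValueError("color table and taxon table disagree on taxon count")
    counts, _ = aggregate_splits(table)
    weighted = [
        WeightedSplit(split=split, counts=c, weight=split_weight(c, pseudocount))
        for split, c in counts.items()
    ]
    weighted.sort(key=sort_key)
    return SplitSystem(taxa=taxa, splits=tuple(weighted))
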