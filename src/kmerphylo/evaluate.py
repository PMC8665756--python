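"""Precision/recall of a called split set against a reference tree.

Precision: called splits also in the reference tree / all called splits.
Recall: reference splits also in the call set / all reference splits.
Trivial splits (separating single leaves) are excluded from both sides, and
weights play no role: only the bipartition identity counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from kmerphylo.splits import SplitSystem
from kmerphylo.tree import TreeNode, tree_to_splits

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitComparison:
    n_called_nontrivial: int
    n_ref_nontrivial: int
    n_intersection: int
    precision: float
    recall: float

    def as_tsv(self) -> str:
        header = "called_nontrivial\tref_nontrivial\tintersection\tprecision\trecall"
        row = (
            f"{self.n_called_nontrivial}\t{self.n_ref_nontrivial}\t"
            f"{self.n_intersection}\t{self.precision:.6g}\t{self.recall:.6g}"
        )
        return header + "\n" + row + "\n"


def _nontrivial_sides(system: SplitSystem) -> set[int]:
    return {ws.split.side for ws in system.splits if not ws.split.is_trivial}


def compare_split_systems(called: SplitSystem, reference: SplitSystem) -> SplitComparison:
    if called.taxa.names != reference.taxa.names:
        raise ValueError("called and reference split systems use different taxon sets")
    called_sides = _nontrivial_sides(called)
    ref_sides = _nontrivial_sides(reference)
    both = called_sides & ref_sides
    if not called_sides or not ref_sides:
        logger.warning("degenerate comparison: a side has no nontrivial splits")
    precision = len(both) / len(called_sides) if called_sides else 0.0
    recall = len(both) / len(ref_sides) if ref_sides else 0.0
    return SplitComparison(
        n_called_nontrivial=len(called_sides),
        n_ref_nontrivial=len(ref_sides),
        n_intersection=len(both),
        precision=precision,
        recall=recall,
    )


def compare_splits(called: SplitSystem, reference: TreeNode) -> SplitComparison:
    """Compare a called split system against a reference tree."""
    ref_labels = sorted(reference.leaf_labels())
    if ref_labels != sorted(called.taxa.names):
        raise ValueError(
            "taxon sets differ between call set and reference tree: "
            f"{sorted(set(called.taxa.names) ^ set(ref_labels))}"
        )
    ref_system = tree_to_splits(reference, called.taxa)
    return compare_split_systems(called, ref_system)
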