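from __future__ import annotations

import random

import pytest

from kmerphylo.seqio import TaxonTable, load_taxon_table
from kmerphylo.splits import Split, SplitCounts, SplitSystem, WeightedSplit, canonical_side, sort_key


@pytest.fixture
def make_dataset(tmp_path):
    """Write FASTA files + input list for genomes given as lists of record strings."""

    def _make(genomes: list[list[str]], names: list[str] | None = None) -> str:
        if names is None:
            names = [f"g{i}" for i in range(len(genomes))]
        list_path = tmp_path / "list.txt"
        lines = []
        for name, records in zip(names, genomes):
            fasta = tmp_path / f"{name}.fa"
            with open(fasta, "w") as fh:
                for j, seq in enumerate(records):
                    fh.write(f">{name}_r{j}\n{seq}\n")
            lines.append(str(fasta))
        list_path.write_text("\n".join(lines) + "\n")
        return str(list_path)

    return _make


def taxa_for(n: int, names: list[str] | None = None) -> TaxonTable:
    if names is None:
        names = [f"g{i}" for i in range(n)]
    return TaxonTable(names=tuple(names), paths=tuple("" for _ in names))


def make_system(taxa: TaxonTable, side_weights: dict[int, float]) -> SplitSystem:
    """SplitSystem from {canonical side mask: weight}; counts are zeros."""
    weighted = [
        WeightedSplit(split=Split(side=side, n=taxa.n), counts=SplitCounts(0, 0), weight=w)
        for side, w in side_weights.items()
    ]
    weighted.sort(key=sort_key)
    return SplitSystem(taxa=taxa, splits=tuple(weighted))


def random_compatible_sides(rng: random.Random, n: int) -> dict[int, float]:
    """Random tree-like split set: canonical side mask -> distinct random weight.

    Built by recursive random bipartition of the taxon set (a laminar family),
    including all trivial splits.
    """
    sides: set[int] = set()

    def partition(indices: list[int]) -> None:
        if len(indices) <= 1:
            return
        cut = rng.randint(1, len(indices) - 1)
        shuffled = indices[:]
        rng.shuffle(shuffled)
        left, right = shuffled[:cut], shuffled[cut:]
        for part in (left, right):
            mask = 0
            for i in part:
                mask |= 1 << i
            sides.add(canonical_side(mask, n))
            partition(part)

    partition(list(range(n)))
    for i in range(n):
        sides.add(canonical_side(1 << i, n))
    return {side: round(rng.uniform(0.5, 10.0), 4) for side in sorted(sides)}


def random_genomes(rng: random.Random, n: int, max_len: int) -> list[list[str]]:
    genomes = []
    for _ in range(n):
        n_records = rng.randint(1, 2)
        genomes.append(
            [
                "".join(rng.choice("ACGT") for _ in range(rng.randint(1, max_len)))
                for _ in range(n_records)
            ]
        )
    return genomes


@pytest.fixture
def load_table(make_dataset):
    def _load(genomes, names=None):
        return load_taxon_table(make_dataset(genomes, names))

    return _load
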