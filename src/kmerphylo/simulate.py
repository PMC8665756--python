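"""Synthetic datasets with known ground truth.

Generates a random binary phylogeny, evolves sequences along it under a
Jukes-Cantor-like site substitution model (each site substituted with a fixed
per-edge probability, uniform over the three alternative bases), writes one
FASTA file per leaf plus the input list and the true tree, and can corrupt
sequences with IUPAC ``N`` characters at random positions.  Everything is
bit-reproducible given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from kmerphylo.tree import TreeNode, write_newick

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 20
    seq_length: int = 10_000
    substitution_prob_per_edge: float = 0.01
    n_prob: float = 0.0
    seed: int = 0
    k: int = 21

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not 0.0 <= self.substitution_prob_per_edge < 1.0:
            raise ValueError("substitution_prob_per_edge must be in [0, 1)")
        if not 0.0 <= self.n_prob <= 1.0:
            raise ValueError("n_prob must be in [0, 1]")


@dataclass(frozen=True)
class Dataset:
    """Paths written by :func:`generate_dataset`."""

    directory: str
    list_path: str
    tree_path: str
    fasta_paths: tuple[str, ...] = field(default_factory=tuple)


def simulate_tree(config: SimulationConfig) -> TreeNode:
    """Random binary tree over ``t000..`` leaves by sequential random joins."""
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_taxa - 1)))
    pool: list[TreeNode] = [
        TreeNode(label=f"t{i:0{width}d}", branch_length=1.0)
        for i in range(config.n_taxa)
    ]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        right = pool.pop(int(j))
        left = pool.pop(int(i))
        pool.append(TreeNode(branch_length=1.0, children=[left, right]))
    root = pool[0]
    root.branch_length = 0.0
    return root


def _mutate(parent: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    child = parent.copy()
    hit = np.flatnonzero(rng.random(parent.shape[0]) < prob)
    if hit.size:
        child[hit] = (child[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return child


def evolve_sequences(tree: TreeNode, config: SimulationConfig, out_dir: str) -> Dataset:
    """Evolve a random root sequence down the tree and write one FASTA per leaf.

    Also writes ``list.txt`` (the pipeline input list, leaf order) and
    ``true.nwk`` (the generating tree).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    root_seq = rng.integers(0, 4, size=config.seq_length)
    fasta_paths: list[str] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            path = os.path.join(out_dir, f"{node.label}.fa")
            with open(path, "w") as fh:
                fh.write(f">{node.label}\n")
                fh.write(_BASES[seq].tobytes().decode() + "\n")
            fasta_paths.append(path)
            return
        for child in node.children:
            descend(child, _mutate(seq, config.substitution_prob_per_edge, rng))

    descend(tree, root_seq)
    list_path = os.path.join(out_dir, "list.txt")
    with open(list_path, "w") as fh:
        for path in fasta_paths:
            fh.write(path + "\n")
    tree_path = os.path.join(out_dir, "true.nwk")
    write_newick(tree, tree_path)
    return Dataset(
        directory=out_dir,
        list_path=list_path,
        tree_path=tree_path,
        fasta_paths=tuple(fasta_paths),
    )


def corrupt_with_iupac(fasta_in: str, n_prob: float, seed: int, fasta_out: str) -> str:
    """Replace each base by ``N`` independently with probability ``n_prob``."""
    rng = np.random.default_rng(seed)
    with open(fasta_in) as src, open(fasta_out, "w") as dst:
        for line in src:
            if line.startswith(">") or not line.strip():
                dst.write(line)
                continue
            seq = line.rstrip("\n")
            chars = np.frombuffer(seq.encode(), dtype="S1").copy()
            chars[rng.random(len(seq)) < n_prob] = b"N"
            dst.write(chars.tobytes().decode() + "\n")
    return fasta_out


def generate_dataset(config: SimulationConfig, out_dir: str) -> Dataset:
    """Full fixture: simulate a tree, evolve sequences, optionally add N's."""
    tree = simulate_tree(config)
    dataset = evolve_sequences(tree, config, out_dir)
    if config.n_prob > 0:
        for i, path in enumerate(dataset.fasta_paths):
            tmp = path + ".tmp"
            corrupt_with_iupac(path, config.n_prob, config.seed + 1000 + i, tmp)
            os.replace(tmp, path)
    return dataset
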