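"""Canonical k-mer extraction with IUPAC ambiguity expansion.

k-mers are encoded as unsigned integers, 2 bits per base (A=00, C=01, G=10,
T=11, most-significant pair = first base).  Each k-mer maps to a
presence/absence pattern: an integer bit vector whose bit i is set iff the
k-mer occurs in the i-th input file.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from kmerphylo.seqio import TaxonTable, read_sequences

logger = logging.getLogger(__name__)

BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = "ACGT"

#: IUPAC nucleotide codes mapped to the plain bases they stand for.
IUPAC_CODES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

DEFAULT_IUPAC_CAP = 64


def encode(kmer: str) -> int:
    """2-bit encode a plain-base k-mer (first base in the most significant pair)."""
    code = 0
    try:
        for base in kmer:
            code = (code << 2) | BASE_TO_CODE[base]
    except KeyError:
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}") from None
    return code


def decode(code: int, k: int) -> str:
    bases = []
    for shift in range(2 * (k - 1), -1, -2):
        bases.append(CODE_TO_BASE[(code >> shift) & 3])
    return "".join(bases)


def reverse_complement(code: int, k: int) -> int:
    """Reverse complement under the 2-bit encoding (complement = XOR 0b11)."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((code & 3) ^ 3)
        code >>= 2
    return rc


def canonical(code: int, k: int) -> int:
    """The numerically smaller of a k-mer code and its reverse complement."""
    rc = reverse_complement(code, k)
    return code if code <= rc else rc


def expand_iupac(window: str, cap: int = DEFAULT_IUPAC_CAP) -> list[str]:
    """Expand every IUPAC ambiguity code in ``window`` to all plain-base strings.

    Returns the Cartesian product over positions.  Returns an empty list if the
    window contains any character outside the IUPAC nucleotide alphabet, or if
    the number of expansions would exceed ``cap``.
    """
    choices: list[str] = []
    total = 1
    for ch in window:
        bases = IUPAC_CODES.get(ch)
        if bases is None:
            return []
        total *= len(bases)
        if total > cap:
            return []
        choices.append(bases)
    if total == 1:
        return [window]
    return ["".join(combo) for combo in itertools.product(*choices)]


@dataclass
class ColorTable:
    """First hash table: canonical k-mer code -> presence/absence pattern.

    ``patterns`` maps the 2-bit k-mer code to an integer whose bit i is set iff
    the k-mer was observed in input file i.  No stored pattern is zero.
    """

    patterns: dict[int, int]
    k: int
    n: int
    n_skipped_windows: int = 0
    stats: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patterns)


def build_color_table(
    taxa: TaxonTable,
    k: int,
    iupac_cap: int = DEFAULT_IUPAC_CAP,
) -> ColorTable:
    """Slide a window of length k over every record of every input file.

    Every expanded, canonicalized k-mer gets bit i set in its pattern when seen
    in file i; multiplicity within a file is irrelevant.  Windows never span
    record boundaries.  Windows containing non-IUPAC characters, or whose IUPAC
    expansion exceeds ``iupac_cap``, are skipped and counted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    patterns: dict[int, int] = {}
    skipped = 0
    n_windows = 0
    mask = (1 << (2 * k)) - 1
    base_codes = BASE_TO_CODE
    for taxon_index in range(taxa.n):
        bit = 1 << taxon_index
        for record in read_sequences(taxa.paths[taxon_index], taxon_index):
            seq = record.sequence
            if len(seq) < k:
                continue
            code = 0
            last_bad = -1  # most recent position holding a non-ACGT character
            for pos, ch in enumerate(seq):
                b = base_codes.get(ch)
                if b is None:
                    last_bad = pos
                    code = (code << 2) & mask
                else:
                    code = ((code << 2) | b) & mask
                start = pos - k + 1
                if start < 0:
                    continue
                n_windows += 1
                if last_bad < start:
                    c = canonical(code, k)
                    patterns[c] = patterns.get(c, 0) | bit
                else:
                    expansions = expand_iupac(seq[start : pos + 1], iupac_cap)
                    if not expansions:
                        skipped += 1
                        continue
                    for word in expansions:
                        c = canonical(encode(word), k)
                        patterns[c] = patterns.get(c, 0) | bit
    if n_windows == 0:
        logger.warning("no window of length k=%d fit any sequence; table is empty", k)
    if skipped:
        logger.info("skipped %d windows (invalid characters or expansion cap)", skipped)
    return ColorTable(
        patterns=patterns,
        k=k,
        n=taxa.n,
        n_skipped_windows=skipped,
        stats={"n_windows": n_windows},
    )
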