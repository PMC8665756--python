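"""Genome sequence input: list files, FASTA/FASTQ records, gzip handling.

One input file corresponds to one taxon ("color"); all records in a file share
the taxon index.  Sequences are uppercased and RNA ``U`` is mapped to ``T``.
Characters outside the IUPAC nucleotide alphabet are preserved as-is; the
k-mer layer invalidates windows containing them.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"

# uppercase + U->T in one pass
_NORMALIZE = str.maketrans(
    "abcdefghijklmnopqrstuvwxyzU",
    "ABCDEFGHIJKLMNOPQRSTTVWXYZT",
)


@dataclass(frozen=True)
class TaxonTable:
    """Ordered table of taxa: position i is the i-th input file (bit i in patterns)."""

    names: tuple[str, ...]
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.paths):
            raise ValueError("names and paths must have equal length")
        if len(self.names) < 1:
            raise ValueError("taxon table must contain at least one taxon")
        if any(not name for name in self.names):
            raise ValueError("taxon labels must be non-empty")
        if len(set(self.names)) != len(self.names):
            seen: dict[str, int] = {}
            for i, name in enumerate(self.names):
                if name in seen:
                    raise ValueError(
                        f"duplicate taxon {name!r} (entries {seen[name] + 1} and {i + 1})"
                    )
                seen[name] = i

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence from one input file, already normalized (uppercase, U->T)."""

    taxon_index: int
    sequence: str


def default_label(path: str) -> str:
    """Basename with every extension stripped: ``dir/g1.fa.gz`` -> ``g1``."""
    base = os.path.basename(path)
    return base.split(".", 1)[0]


def load_taxon_table(list_path: str) -> TaxonTable:
    """Parse a plain-text list of genome files into a :class:`TaxonTable`.

    One path per line, optionally ``path<TAB>label``; ``#`` starts a comment
    line; blank lines are ignored.  Line order fixes the taxon indices used in
    all presence/absence patterns downstream.
    """
    if not os.path.exists(list_path):
        raise FileNotFoundError(f"input list not found: {list_path}")
    names: list[str] = []
    paths: list[str] = []
    lines_by_name: dict[str, int] = {}
    with open(list_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                path, label = line.split("\t", 1)
                path, label = path.strip(), label.strip()
            else:
                path, label = line, default_label(line)
            if not label:
                raise ValueError(f"{list_path}:{lineno}: empty taxon label")
            if label in lines_by_name:
                raise ValueError(
                    f"duplicate taxon {label!r}: lines {lines_by_name[label]} and "
                    f"{lineno} of {list_path}"
                )
            lines_by_name[label] = lineno
            names.append(label)
            paths.append(path)
    if not names:
        raise ValueError(f"input list is empty: {list_path}")
    return TaxonTable(names=tuple(names), paths=tuple(paths))


def _open_text(path: str) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(handle: IO[str]) -> str | None:
    """Return 'fasta' or 'fastq' from the first record character; None if empty."""
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            return None
        if line.strip():
            handle.seek(pos)
            break
    first = line.lstrip()[0]
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"unrecognized sequence format (first record char {first!r})")


def read_sequences(path: str, taxon_index: int) -> Iterator[SequenceRecord]:
    """Yield every record of a FASTA/FASTQ file (plain or gzipped).

    FASTQ quality strings are discarded.  All records carry ``taxon_index``
    (one color per file).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"sequence file not found: {path}")
    with _open_text(path) as handle:
        try:
            fmt = _sniff_format(handle)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        if fmt is None:
            logger.warning("empty sequence file: %s", path)
            return
        n_records = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                n_records += 1
                yield SequenceRecord(
                    taxon_index=taxon_index,
                    sequence=str(record.seq).translate(_NORMALIZE),
                )
        except ValueError as exc:
            raise ValueError(f"{path}: record {n_records + 1}: {exc}") from None
        if n_records == 0:
            logger.warning("no records parsed from %s", path)
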