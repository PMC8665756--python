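"""Serialization of split systems: tab-separated split lists and NEXUS splits.

The TSV lists, per line, the split weight followed by the taxon names of the
canonical (smaller) side; the complement is implied by the taxon table.  The
NEXUS output carries minimal TAXA and SPLITS blocks consumable by common
split-network viewers.
"""

from __future__ import annotations

import re

from kmerphylo.seqio import TaxonTable
from kmerphylo.splits import (
    Split,
    SplitCounts,
    SplitSystem,
    WeightedSplit,
    sort_key,
)

WEIGHT_FORMAT = "%.6g"


def write_splits_tsv(system: SplitSystem, out: str) -> None:
    """One line per split: weight, then the canonical side's taxon names, tab-separated."""
    with open(out, "w") as fh:
        for ws in system.splits:
            names = ws.split.names(system.taxa)
            fh.write("\t".join([WEIGHT_FORMAT % ws.weight, *names]) + "\n")


def read_splits_tsv(path: str, taxa: TaxonTable) -> SplitSystem:
    """Inverse of :func:`write_splits_tsv` up to float formatting.

    Counts are not stored in the TSV and come back as zeros.
    """
    index = {name: i for i, name in enumerate(taxa.names)}
    weighted: list[WeightedSplit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected weight and at least one taxon")
            try:
                weight = float(fields[0])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad weight {fields[0]!r}") from None
            side = 0
            for name in fields[1:]:
                if name not in index:
                    raise ValueError(f"{path}:{lineno}: unknown taxon {name!r}")
                side |= 1 << index[name]
            weighted.append(
                WeightedSplit(
                    split=Split(side=side, n=taxa.n),
                    counts=SplitCounts(0, 0),
                    weight=weight,
                )
            )
    weighted.sort(key=sort_key)
    return SplitSystem(taxa=taxa, splits=tuple(weighted))


def _nexus_label(name: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_.+-]+", name):
        return name
    return "'" + name.replace("'", "''") + "'"


def write_nexus_splits(system: SplitSystem, out: str) -> None:
    """Minimal NEXUS file with TAXA and SPLITS blocks (1-based taxon indices)."""
    taxa = system.taxa
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={taxa.n};", "TAXLABELS"]
    for i, name in enumerate(taxa.names, start=1):
        lines.append(f"[{i}] {_nexus_label(name)}")
    lines.append(";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN SPLITS;")
    lines.append(f"DIMENSIONS NTAX={taxa.n} NSPLITS={len(system.splits)};")
    lines.append("FORMAT LABELS=NO WEIGHTS=YES;")
    lines.append("MATRIX")
    for row, ws in enumerate(system.splits, start=1):
        ids = " ".join(str(i + 1) for i in ws.split.indices())
        lines.append(f"[{row}] {WEIGHT_FORMAT % ws.weight} {ids},")
    lines.append(";")
    lines.append("END;")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_nexus_splits(path: str) -> SplitSystem:
    """Read back the NEXUS dialect written by :func:`write_nexus_splits`."""
    with open(path) as fh:
        text = fh.read()
    taxa_match = re.search(
        r"BEGIN TAXA;.*?TAXLABELS(.*?);\s*END;", text, re.S | re.I
    )
    if taxa_match is None:
        raise ValueError(f"{path}: no TAXA block")
    names: list[str] = []
    for line in taxa_match.group(1).strip().splitlines():
        line = re.sub(r"^\[\d+\]\s*", "", line.strip())
        if not line:
            continue
        if line.startswith("'"):
            names.append(line[1:-1].replace("''", "'"))
        else:
            names.append(line)
    taxa = TaxonTable(names=tuple(names), paths=tuple("" for _ in names))
    matrix_match = re.search(r"MATRIX(.*?);\s*END;", text, re.S | re.I)
    if matrix_match is None:
        raise ValueError(f"{path}: no SPLITS MATRIX")
    weighted: list[WeightedSplit] = []
    for line in matrix_match.group(1).strip().splitlines():
        line = re.sub(r"^\[\d+\]\s*", "", line.strip()).rstrip(",")
        if not line:
            continue
        fields = line.split()
        weight = float(fields[0])
        side = 0
        for token in fields[1:]:
            side |= 1 << (int(token) - 1)
        weighted.append(
            WeightedSplit(
                split=Split(side=side, n=taxa.n),
                counts=SplitCounts(0, 0),
                weight=weight,
            )
        )
    weighted.sort(key=sort_key)
    return SplitSystem(taxa=taxa, splits=tuple(weighted))
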