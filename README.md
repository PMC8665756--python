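# kmerphylo

Alignment-free, whole-genome phylogeny estimation from k-mer presence/absence
patterns.

Given one FASTA/FASTQ file per genome (assemblies, contigs or raw reads;
optionally gzipped), the pipeline:

1. extracts canonical k-mers (2-bit encoded; IUPAC ambiguity codes are
   expanded to all matching DNA bases, up to a configurable cap) and records,
   per k-mer, the set of input files it occurs in;
2. merges each presence/absence pattern with its complementary pattern into a
   phylogenetic split, counting the k-mers on both sides;
3. weights each split by the geometric mean of the two counts (by default
   with +1 pseudocounts);
4. optionally filters the split system: the `x` highest-weighting splits, a
   greedy pairwise-compatible subset (`strict`, a tree), two such subsets
   (`2tree`), or a greedy weakly compatible subset (`weakly`, a split
   network);
5. writes a tab-separated split table, a NEXUS SPLITS file for split-network
   viewers, and — when the filtered set is pairwise compatible — a Newick
   tree.

A simulator with known ground truth and a precision/recall evaluator against
a reference tree are included.

## CLI

```sh
# synthetic dataset with a known true tree
kmerphylo simulate -d data/ --n-taxa 20 --seq-length 10000 --sub-prob 0.01 --seed 1

# full pipeline: splits TSV + NEXUS network + strict-filtered Newick tree
kmerphylo run -i data/list.txt -o splits.tsv -k 21 \
    --nexus splits.nex --filter strict --newick tree.nwk

# precision/recall of the called splits against the true tree
kmerphylo compare -s splits.tsv -r data/true.nwk -i data/list.txt
```

`kmerphylo run` flags: `-i/--input` (list of genome files, one path per line,
optional `path<TAB>label`, `#` comments), `-k/--kmer` (default 31),
`-o/--output` (TSV), `--nexus`, `--newick`, `--filter
{none,strict,2tree,weakly}`, `-t/--top` (truncate after filtering),
`--no-pseudo`, `--iupac-cap` (default 64; windows whose expansion exceeds the
cap are skipped — `--iupac-cap 1` skips every ambiguous window), `--verbose`.

Split TSV format: one split per line — weight (6 significant digits), then
the taxon names of the smaller side, tab-separated, ordered by weight
descending (ties broken by the side bit vector, so output is
byte-reproducible).

## Layout

- `src/kmerphylo/seqio.py` — input list, FASTA/FASTQ/gzip reading
- `src/kmerphylo/kmers.py` — 2-bit encoding, canonical k-mers, IUPAC
  expansion, k-mer → presence-pattern table
- `src/kmerphylo/splits.py` — pattern aggregation, split weights, split system
- `src/kmerphylo/filters.py` — top-x / strict / 2tree / weakly filters
- `src/kmerphylo/tree.py` — compatible splits ↔ rooted tree, Newick
- `src/kmerphylo/writers.py` — TSV and NEXUS serialization
- `src/kmerphylo/evaluate.py` — precision/recall vs a reference tree
- `src/kmerphylo/simulate.py` — synthetic genomes from a random tree
- `src/kmerphylo/cli.py` — `kmerphylo` entry point
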