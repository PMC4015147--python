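# kfmindex

A succinct, FM-index-like representation of the order-(k−1) de Bruijn
subgraph induced by the k-mers of a read set.  Each vertex (a distinct
(k−1)-mer, lexicographically ordered) is stored as σ in-edge flag bits plus
one group-end flag — 5 bits per vertex for DNA — and a sparse,
delta-compressed previous-position table (≈0.5–1.5 extra bits per vertex,
depending on the stride q) makes the graph walkable: backward search,
k-mer membership, and vertex-string reconstruction all work without ever
storing the k-mers themselves.

Provided operations:

* **construction** from strings or FASTA/FASTQ reads — sorted integer
  edge-word encoding, with optional partitioning and pairwise merging for
  streams that do not fit in memory;
* **queries** — prefix intervals, path membership for strings of any
  length ≥ k, previous-position map ρ and its inverse, vertex-string
  reconstruction;
* **merge** of two indexes into the union of their k-mer sets using three
  transient bit arrays (3·n_A + 2·n_B bits);
* **prune** of superfluous sentinel-padded ("final-completing") vertices;
* **pre-assembly** — degree classification and extraction of uniquely
  determined paths (unitigs);
* **simulate** — a diploid genome/read simulator for reproducible
  end-to-end benchmarks;
* a binary **KFMI** serialization format whose size matches the analytic
  per-vertex memory estimate.

## CLI

```sh
kfm simulate --length 1000000 --snp-rate 0.001 --reads 300000 \
             --read-length 100 --error-rate 0 --seed 1 -o reads.fa
kfm build reads.fa -k 23 -q 32 -o idx.kfm       # RC-augmented, pruned
kfm query idx.kfm ACGTACGTACGTACGTACGTACG        # per-k-mer true/false
kfm stats idx.kfm
kfm assemble idx.kfm -o unitigs.fa
kfm merge a.kfm b.kfm -o union.kfm
kfm prune union.kfm -o pruned.kfm
```

`kfm build` accepts FASTA or FASTQ; FASTQ reads are split at bases with
Phred quality below `--quality` (default 30) and at non-ACGT symbols.

## Python API sketch

```python
import kfmindex as kfm

idx = kfm.build(["ACG", "CGT", "CGA"], kfm.BuildConfig(k=3))
idx.contains_path("ACGA")          # (True, vertex index of the (k-1)-prefix)
idx.prefix_interval("CG")          # half-open [alpha, beta) of vertex indices
idx.vertex_string(4)               # reconstructs "GA"
paths = kfm.extract_paths(idx)     # unitigs
```

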