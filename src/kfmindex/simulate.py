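"""Synthetic diploid genomes and shotgun reads.

Generates a pair of random DNA haplotypes differing by independent
substitutions at a fixed rate (simulated SNPs), then uniform random
fixed-length reads drawn from either haplotype with independent
substitution errors.  Defaults reproduce the reference benchmark: two 1 Mnt
haplotypes at 0.1% divergence, 300 k reads of 100 nt, error rates 0, 0.1%
or 1%.  Reads are emitted on the forward strand only; reverse complements
are added at indexing time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import DNA

__all__ = ["SimulationConfig", "simulate_diploid", "simulate_reads",
           "decode_reads", "write_reads"]


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    snp_rate: float = 0.001
    n_reads: int = 300_000
    read_length: int = 100
    error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.snp_rate <= 1.0 or not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Independently replace bases at ``rate`` with a uniform different base."""
    out = seq.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64)
    hit = np.flatnonzero(rng.random(seq.shape) < rate)
    shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
    out.reshape(-1)[hit] = (out.reshape(-1)[hit] + shift) % 4
    return out, hit


def simulate_diploid(config: SimulationConfig,
                     rng: np.random.Generator | None = None):
    """A random haplotype pair plus the positions where they differ.

    Returns ``(haplotype1, haplotype2, snp_positions)``; haplotypes are
    uint8 code arrays over A=0 < C=1 < G=2 < T=3.  Deterministic for a
    fixed ``rng_seed``.
    """
    if rng is None:
        rng = np.random.default_rng([0, config.rng_seed])
    h1 = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    h2, snps = _substitute(h1, config.snp_rate, rng)
    return h1, h2, snps


def simulate_reads(haplotypes, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random forward-strand reads with substitution errors.

    Each read picks a haplotype uniformly, a uniform start position, and
    substitutes bases independently at ``error_rate``.  Returns an
    ``(n_reads, read_length)`` uint8 code matrix.
    """
    if rng is None:
        rng = np.random.default_rng([1, config.rng_seed])
    h = np.stack(haplotypes)
    which = rng.integers(0, h.shape[0], size=config.n_reads)
    starts = rng.integers(0, config.genome_length - config.read_length + 1,
                          size=config.n_reads)
    reads = h[which[:, None], starts[:, None] + np.arange(config.read_length)[None, :]]
    reads, _ = _substitute(reads, config.error_rate, rng)
    return reads


def decode_reads(reads: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(lut[row]).decode("ascii") for row in np.atleast_2d(reads)]


def write_reads(reads: np.ndarray, path: str, fastq: bool = False,
                quality: str = "I") -> None:
    """Write reads as FASTA, or FASTQ with a constant quality score."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for i, row in enumerate(np.atleast_2d(reads)):
            seq = bytes(lut[row]).decode("ascii")
            if fastq:
                fh.write(f"@read_{i}\n{seq}\n+\n{quality * len(seq)}\n")
            else:
                fh.write(f">read_{i}\n{seq}\n")
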