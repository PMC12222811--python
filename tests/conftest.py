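"""Shared fixtures: tiny genomes and read sets built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from pcnkit.io import GenomeRef, ReadRecord, Replicon
from pcnkit.simulate import SharedElement, SimConfig, simulate_genome, simulate_reads


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def shared_element_genome():
    """Chromosome (20 kb) and plasmid (5 kb) sharing one 2 kb element."""
    cfg = SimConfig(
        chromosome_length=20_000,
        plasmids=[(5_000, 3.0)],
        shared_elements=[SharedElement(length=2_000, carriers=(0, 1))],
        read_length=100,
        total_reads=2_000,
        seed=11,
    )
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture
def simple_two_replicon():
    """Two unrelated random replicons, no shared sequence."""
    r = np.random.default_rng(5)
    chrom = Replicon(id="chr", sequence=random_seq(r, 30_000), role="chromosome")
    plas = Replicon(
        id="p1", sequence=random_seq(r, 6_000), role="plasmid", description="p1 plasmid"
    )
    return GenomeRef(replicons=(chrom, plas), genome_id="toy")


def reads_from(seq: str, rng: np.random.Generator, n: int, length: int, prefix: str):
    starts = rng.integers(0, len(seq) - length + 1, n)
    strands = rng.integers(0, 2, n)
    out = []
    for i, (s, st) in enumerate(zip(starts, strands)):
        frag = seq[s : s + length]
        if st:
            frag = revcomp(frag)
        out.append(ReadRecord(id=f"{prefix}{i}", sequence=frag))
    return out
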