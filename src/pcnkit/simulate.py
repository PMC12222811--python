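"""Ground-truth read simulator.

Generates multi-replicon genomes with known copy numbers and planted
shared mobile elements, then samples reads whose abundance is
proportional to DNA mass (copy number x length) — the data-generating
assumption behind coverage-ratio copy-number estimation.  Every
stochastic choice flows from one explicit RNG, so a seed fully
determines the output.

The error model is substitution-only: a substituted base breaks the
k-mers covering it, which is exactly the mechanism by which erroneous
reads fail to pseudoalign and drop out of the analysis.  Indels, quality
profiles, GC bias and insert-size structure are deliberately absent (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import CHROMOSOME, PLASMID, GenomeRef, ReadRecord, Replicon

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SharedElement:
    """A mobile element planted verbatim into several replicons."""

    length: int
    carriers: tuple[int, ...]  # replicon indices (0 = chromosome)
    copies_per_carrier: int = 1


@dataclass
class SimConfig:
    """Study conditions for one simulated genome + read set.

    ``plasmids`` is a list of ``(length_bp, true_pcn)`` pairs; copy
    numbers below 1 are allowed (e.g. 0.5 models two plasmid copies in a
    cell with four chromosome copies).  ``total_reads`` reads of length
    ``read_length`` are sampled with per-replicon probability
    proportional to ``true_pcn x length``, uniform start and strand, and
    i.i.d. substitutions at ``substitution_rate``.
    """

    chromosome_length: int
    plasmids: list[tuple[int, float]] = field(default_factory=list)
    shared_elements: list[SharedElement] = field(default_factory=list)
    read_length: int = 150
    total_reads: int = 10_000
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = [self.chromosome_length] + [int(l) for l, _ in self.plasmids]
        if min(lengths) < self.read_length:
            raise ValueError("read_length must not exceed the shortest replicon")
        for _, pcn in self.plasmids:
            if not pcn > 0:
                raise ValueError("plasmid true_pcn must be > 0")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        for el in self.shared_elements:
            for c in el.carriers:
                if not (0 <= c < len(lengths)):
                    raise ValueError(f"element carrier index {c} out of range")
                if el.length * el.copies_per_carrier >= lengths[c]:
                    raise ValueError(
                        "shared element does not fit inside carrier "
                        f"replicon {c}"
                    )

    @property
    def replicon_lengths(self) -> list[int]:
        return [self.chromosome_length] + [int(l) for l, _ in self.plasmids]

    @property
    def true_pcn(self) -> np.ndarray:
        return np.array([1.0] + [float(p) for _, p in self.plasmids])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        elements = [
            SharedElement(
                length=int(e["length"]),
                carriers=tuple(int(c) for c in e["carriers"]),
                copies_per_carrier=int(e.get("copies_per_carrier", 1)),
            )
            for e in raw.get("shared_elements", [])
        ]
        return cls(
            chromosome_length=int(raw["chromosome_length"]),
            plasmids=[(int(l), float(p)) for l, p in raw.get("plasmids", [])],
            shared_elements=elements,
            read_length=int(raw.get("read_length", 150)),
            total_reads=int(raw.get("total_reads", 10_000)),
            substitution_rate=float(raw.get("substitution_rate", 0.0)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class SimTruth:
    """Everything the estimator is not allowed to see.

    ``read_sources`` is filled by :func:`simulate_reads`: one
    ``(replicon_index, start, strand)`` triple per read, in read order.
    """

    mass_fractions: np.ndarray
    element_coords: dict[int, list[tuple[int, int, int]]]  # elem -> [(rep, start, end)]
    true_pcn: np.ndarray | None = None
    read_sources: list[tuple[int, int, int]] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeRef, SimTruth]:
    """Generate the reference genome with planted shared elements.

    Backbones are i.i.d.-uniform random sequences; each shared element is
    a single random sequence spliced verbatim into every carrier at
    uniform, non-overlapping insertion points, ``copies_per_carrier``
    times, keeping each replicon at its configured final length.
    Deterministic given ``config.seed`` (or the supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = config.replicon_lengths
    n = len(lengths)

    element_seqs = [
        _random_sequence(rng, el.length) for el in config.shared_elements
    ]
    # planned insertions per carrier: list of element ids
    plan: list[list[int]] = [[] for _ in range(n)]
    for ei, el in enumerate(config.shared_elements):
        for c in el.carriers:
            plan[c].extend([ei] * el.copies_per_carrier)

    replicons: list[Replicon] = []
    coords: dict[int, list[tuple[int, int, int]]] = {
        ei: [] for ei in range(len(config.shared_elements))
    }
    for j in range(n):
        insert_total = sum(len(element_seqs[ei]) for ei in plan[j])
        backbone_len = lengths[j] - insert_total
        if backbone_len <= 0:
            raise ValueError(f"elements do not fit into replicon {j}")
        backbone = _random_sequence(rng, backbone_len)
        # distinct uniform cut points keep the copies non-overlapping
        cuts = np.sort(rng.choice(backbone_len + 1, size=len(plan[j]), replace=False))
        order = rng.permutation(len(plan[j]))
        pieces: list[np.ndarray] = []
        prev = 0
        offset = 0
        for cut, oi in zip(cuts, order):
            ei = plan[j][oi]
            pieces.append(backbone[prev:cut])
            start = cut + offset
            pieces.append(element_seqs[ei])
            coords[ei].append((j, int(start), int(start + len(element_seqs[ei]))))
            offset += len(element_seqs[ei])
            prev = cut
        pieces.append(backbone[prev:])
        seq = np.concatenate(pieces) if pieces else backbone
        role = CHROMOSOME if j == 0 else PLASMID
        rid = "chromosome" if j == 0 else f"plasmid_{j}"
        desc = rid if j == 0 else f"{rid} plasmid"
        replicons.append(
            Replicon(id=rid, sequence=_to_str(seq), role=role, description=desc)
        )

    pcn = config.true_pcn
    mass = pcn * np.array(lengths, dtype=float)
    genome = GenomeRef(replicons=tuple(replicons), genome_id="sim")
    # GenomeRef orders replicons by descending length; remap truth from
    # construction order to genome order via replicon ids
    pos = {rep.id: i for i, rep in enumerate(genome.replicons)}
    perm = [pos[r.id] for r in replicons]
    mass_g = np.empty(n)
    pcn_g = np.empty(n)
    for cfg_i, gen_i in enumerate(perm):
        mass_g[gen_i] = mass[cfg_i]
        pcn_g[gen_i] = pcn[cfg_i]
    coords_g = {
        ei: [(perm[j], s, e) for j, s, e in lst] for ei, lst in coords.items()
    }
    truth = SimTruth(
        mass_fractions=mass_g / mass_g.sum(),
        element_coords=coords_g,
        true_pcn=pcn_g,
    )
    return genome, truth


_COMP_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_reads(
    genome: GenomeRef,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], SimTruth]:
    """Sample reads proportional to DNA mass; record per-read truth.

    Read count per replicon is multinomial over the mass fractions; start
    positions uniform over valid windows; strand uniform; substitutions
    i.i.d. at ``config.substitution_rate`` replacing a base with a
    uniformly chosen *different* base.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    n = genome.n_replicons
    counts = rng.multinomial(config.total_reads, truth.mass_fractions)
    seqs = [np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8) for r in genome.replicons]

    reads: list[ReadRecord] = []
    sources: list[tuple[int, int, int]] = []
    ridx = 0
    for j in range(n):
        if counts[j] == 0:
            continue
        starts = rng.integers(0, len(seqs[j]) - rl + 1, size=counts[j])
        strands = rng.integers(0, 2, size=counts[j])
        for s, st in zip(starts, strands):
            frag = seqs[j][s : s + rl].copy()
            if st == 1:
                # reverse complement in encoded space: A<->T, C<->G
                frag = frag[::-1]
                frag = np.frombuffer(
                    frag.tobytes().translate(_COMP_TABLE), dtype=np.uint8
                )
            if config.substitution_rate > 0:
                hit = np.nonzero(rng.random(rl) < config.substitution_rate)[0]
                if hit.size:
                    frag = frag.copy()
                    # shift by 1-3 positions in base order => always a different base
                    cur = _ENC_LOOKUP[frag[hit]]
                    new = (cur + rng.integers(1, 4, size=hit.size)) % 4
                    frag[hit] = _BASES[new]
            reads.append(
                ReadRecord(id=f"r{ridx:08d}", sequence=_to_str(frag), mate="single")
            )
            sources.append((j, int(s), int(st)))
            ridx += 1
    truth.read_sources = sources
    return reads, truth


_ENC_LOOKUP = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC_LOOKUP[_b] = _i


def write_reads_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(truth: SimTruth, genome: GenomeRef, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_index\treplicon_id\tstart\tstrand\n")
        for i, (j, s, st) in enumerate(truth.read_sources):
            fh.write(f"{i}\t{genome.replicons[j].id}\t{s}\t{'-' if st else '+'}\n")
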