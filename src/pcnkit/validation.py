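"""Reference scenarios for validating the estimator end to end.

These functions pin down the study conditions used to check the
pipeline against ground truth: the textbook one-chromosome/one-plasmid
worked example, and a copy-number recovery experiment spanning the
biologically relevant range (multicopy small plasmids down to
sub-chromosomal copy numbers) with a shared mobile element forcing the
EM to do real work.  Both the test suite and the reproduction script
drive their checks through here so they measure the same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReadRecord
from .pira import PCNResults, PlasmidCopyNumberModel
from .simulate import SharedElement, SimConfig, simulate_genome, simulate_reads

#: copy numbers exercised by the recovery experiment
RECOVERY_PCNS = (0.5, 1.0, 2.0, 5.0, 20.0, 100.0)

#: plasmid length per copy number — sized so that at 30x chromosome
#: depth the plasmid collects enough reads (>= ~2000 at the lowest copy
#: number) for binomial sampling error to sit well inside a 5% band,
#: while high-copy plasmids stay small enough to keep read totals modest
RECOVERY_PLASMID_LENGTHS = {0.5: 30_000, 1.0: 30_000, 2.0: 10_000, 5.0: 10_000, 20.0: 5_000, 100.0: 3_000}

RECOVERY_CHROMOSOME = 50_000
RECOVERY_READ_LENGTH = 150
RECOVERY_DEPTH = 30  # x chromosome
RECOVERY_ELEMENT = SharedElement(length=2_000, carriers=(0, 1), copies_per_carrier=1)


def fig1a_case(seed: int = 0) -> PCNResults:
    """One chromosome (100 kb) + one plasmid (10 kb) at copy number 3.

    Error-free reads at *exact* proportional counts — 10,000 chromosome
    reads and 3,000 plasmid reads, matching the 100 kb : 30 kb DNA mass
    ratio — so the coverage-ratio estimate is exactly 3 and, with no
    shared sequence, the EM is a no-op.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        chromosome_length=100_000,
        plasmids=[(10_000, 3.0)],
        read_length=150,
        total_reads=13_000,
        seed=seed,
    )
    genome, _ = simulate_genome(cfg, rng)
    counts = {0: 10_000, 1: 3_000}  # exact mass-proportional counts
    reads: list[ReadRecord] = []
    i = 0
    for j, c in counts.items():
        seq = genome.replicons[j].sequence
        starts = rng.integers(0, len(seq) - cfg.read_length + 1, size=c)
        for s in starts:
            reads.append(ReadRecord(id=f"r{i}", sequence=seq[s : s + cfg.read_length]))
            i += 1
    return PlasmidCopyNumberModel(genome, reads).fit(min_reads=0)


def recovery_config(true_pcn: float, seed: int, with_element: bool = True) -> SimConfig:
    """Study conditions for one recovery replicate at a given copy number."""
    plasmid_len = RECOVERY_PLASMID_LENGTHS[true_pcn]
    chrom_reads = RECOVERY_DEPTH * RECOVERY_CHROMOSOME // RECOVERY_READ_LENGTH
    total_mass = RECOVERY_CHROMOSOME + true_pcn * plasmid_len
    total_reads = int(round(chrom_reads * total_mass / RECOVERY_CHROMOSOME))
    return SimConfig(
        chromosome_length=RECOVERY_CHROMOSOME,
        plasmids=[(plasmid_len, true_pcn)],
        shared_elements=[RECOVERY_ELEMENT] if with_element else [],
        read_length=RECOVERY_READ_LENGTH,
        total_reads=total_reads,
        substitution_rate=0.0,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    true_pcn: float
    estimate: float
    direct: float
    rel_err: float
    seed: int


def run_recovery_replicate(true_pcn: float, seed: int, with_element: bool = True) -> RecoveryResult:
    cfg = recovery_config(true_pcn, seed, with_element=with_element)
    genome, truth = simulate_genome(cfg)
    reads, truth = simulate_reads(genome, truth, cfg)
    res = PlasmidCopyNumberModel(genome, reads).fit(min_reads=0)
    est = res.estimates.set_index("replicon_id")
    pira = float(est.loc["plasmid_1", "pcn_pira"])
    direct = float(est.loc["plasmid_1", "pcn_direct"])
    return RecoveryResult(
        true_pcn=true_pcn,
        estimate=pira,
        direct=direct,
        rel_err=abs(pira - true_pcn) / true_pcn,
        seed=seed,
    )


def recovery_replicates(seed: int, n_replicates: int = 40) -> list[RecoveryResult]:
    """Run the full recovery experiment: replicates cycle over RECOVERY_PCNS."""
    out = []
    for i in range(n_replicates):
        pcn = RECOVERY_PCNS[i % len(RECOVERY_PCNS)]
        out.append(run_recovery_replicate(pcn, seed=seed * 100_003 + i))
    return out
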