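"""Copy-number estimation: direct coverage ratio and the PIRA EM.

The copy number of replicon *j* relative to the longest chromosome is
estimated from read-count coverage,

    pi_j = (R_j / L_j) / (R_1 / L_1),

where ``R_j`` is the number of reads mapping to replicon *j* and ``L_j``
its length; read length cancels in the ratio.  Multireads — reads
compatible with several replicons — are then allocated by probabilistic
iterative read assignment (PIRA), an EM algorithm for multinomial read
counts:

* **E-step**: given copy numbers ``pi``, multiread *j* is assigned to
  replicon *k* with responsibility
  ``L_jk = M_jk pi_k / sum_k' M_jk' pi_k'``, where ``M_jk`` counts the
  read's distinct alignment locations on replicon *k*;
* **M-step**: ``pi_k <- (R_k + sum_j L_jk) / L_k``, renormalized so the
  reference chromosome has copy number exactly 1.

Iteration stops when the L1 norm of the change in ``pi`` falls below
``tol`` (default 1e-6).  The observed-data log-likelihood is

    ll(pi) = sum_k R_k log(pi_k L_k / S) + sum_j log(sum_k M_jk pi_k / S),

with ``S = sum_k pi_k L_k`` the total DNA mass; it is non-decreasing
along the iteration (the EM guarantee) and is traced at every step.

``PlasmidCopyNumberModel`` wraps the whole pipeline (index, classify,
locate, promote, EM, filters) behind a model/results interface;
``fit()`` returns a :class:`PCNResults` with the per-replicon table and a
``summary()`` view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .index import DEFAULT_K, DEFAULT_TAU, AssignmentSummary, build_index, classify_reads
from .io import CHROMOSOME, GenomeRef, ReadRecord, load_genome, load_reads
from .matcher import DEFAULT_TAU_LOC, MatchMatrix, build_match_rows, promote_unique

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000
DEFAULT_MIN_READS = 10_000


@dataclass
class PCNVector:
    """Copy-number vector pi with the replicon lengths it refers to.

    ``values[0]`` is the reference chromosome and is exactly 1.
    """

    values: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.values.shape != self.lengths.shape:
            raise ValueError("values and lengths must have the same shape")
        if self.values[0] != 1.0:
            raise ValueError("reference copy number must be exactly 1")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("copy numbers must be finite and non-negative")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PiraTrace:
    """Per-iteration diagnostics of one EM run."""

    iterations: int
    pi_history: list[np.ndarray]
    log_likelihoods: list[float]
    converged: bool


def direct_pcn(R: Sequence[int] | np.ndarray, lengths: Sequence[int] | np.ndarray) -> PCNVector:
    """Direct copy-number estimate from per-replicon read counts.

    ``pi_j = (R_j L_1) / (R_1 L_j)`` — algebraically the coverage ratio
    ``(R_j/L_j)/(R_1/L_1)``, computed in a single expression so integer
    inputs give machine-exact ratios.
    """
    R = np.asarray(R, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("replicon lengths must be positive")
    if R[0] <= 0:
        raise ValueError("no chromosomal coverage: zero reads on the reference")
    values = (R.astype(float) * float(lengths[0])) / (float(R[0]) * lengths.astype(float))
    return PCNVector(values=values, lengths=lengths)


def log_likelihood(pi: PCNVector, R: np.ndarray, M: np.ndarray | MatchMatrix) -> float:
    """Observed-data multinomial log-likelihood (constant terms dropped)."""
    rows = M.rows if isinstance(M, MatchMatrix) else np.asarray(M, dtype=float)
    R = np.asarray(R, dtype=float)
    v, L = pi.values, pi.lengths.astype(float)
    S = float(np.sum(v * L))
    mass = v * L / S
    ll = 0.0
    for k in range(v.size):
        if R[k] > 0:
            if mass[k] <= 0:
                return -np.inf
            ll += R[k] * np.log(mass[k])
    if rows.size:
        per_read = rows @ v / S
        if (per_read <= 0).any():
            return -np.inf
        ll += float(np.log(per_read).sum())
    return ll


def pira_estimate(
    pi0: PCNVector,
    M: MatchMatrix | np.ndarray,
    R: Sequence[int] | np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[PCNVector, PiraTrace]:
    """Run the PIRA EM from initial estimate ``pi0``.

    Returns the converged copy-number vector and the full trace.  With an
    empty match matrix this is a no-op (0 iterations).  Non-convergence at
    ``max_iter`` is flagged on the trace and warned about, never silent.
    """
    rows = M.rows if isinstance(M, MatchMatrix) else np.asarray(M, dtype=np.int64)
    rows = rows.reshape(-1, pi0.n).astype(float)
    R = np.asarray(R, dtype=float)
    lengths = pi0.lengths.astype(float)
    pi = pi0.values.copy()

    trace = PiraTrace(
        iterations=0,
        pi_history=[pi.copy()],
        log_likelihoods=[log_likelihood(pi0, R, rows)],
        converged=True,
    )
    if rows.shape[0] == 0:
        return pi0, trace

    if (rows.sum(axis=1) == 0).any():
        raise ValueError("match matrix contains an all-zero row")

    converged = False
    for _ in range(max_iter):
        weighted = rows * pi  # E-step: M weighted by current copy numbers
        resp = weighted / weighted.sum(axis=1, keepdims=True)
        R_D = resp.sum(axis=0)  # multiread vector: probabilistic allocation
        new = (R + R_D) / lengths
        new = new / new[0]  # pin the reference chromosome at 1
        delta = float(np.abs(new - pi).sum())
        pi = new
        trace.iterations += 1
        trace.pi_history.append(pi.copy())
        trace.log_likelihoods.append(
            log_likelihood(PCNVector(pi, pi0.lengths), R, rows)
        )
        if delta < tol:
            converged = True
            break
    trace.converged = converged
    if not converged:
        warnings.warn(
            f"PIRA did not converge within {max_iter} iterations "
            f"(last L1 change {delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PCNVector(values=pi, lengths=pi0.lengths), trace


def expected_allocation(pi: PCNVector, M: MatchMatrix | np.ndarray) -> np.ndarray:
    """Expected multiread counts per replicon at copy numbers ``pi``."""
    rows = M.rows if isinstance(M, MatchMatrix) else np.asarray(M, dtype=float)
    rows = rows.reshape(-1, pi.n).astype(float)
    if rows.shape[0] == 0:
        return np.zeros(pi.n)
    weighted = rows * pi.values
    return (weighted / weighted.sum(axis=1, keepdims=True)).sum(axis=0)


def filter_estimates(
    pi: PCNVector,
    mapped_reads: Sequence[int] | np.ndarray,
    roles: Sequence[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[dict[int, float], list[dict]]:
    """Drop plasmid estimates with fewer than ``min_reads`` mapped reads.

    The rule is strictly less-than: a plasmid with exactly ``min_reads``
    reads is kept.  Chromosomes are never dropped.  Returns the kept
    estimates keyed by replicon index and a report of removals.
    """
    mapped = np.asarray(mapped_reads, dtype=np.int64)
    if roles is None:
        roles = [CHROMOSOME] + ["plasmid"] * (pi.n - 1)
    kept: dict[int, float] = {}
    report: list[dict] = []
    for j in range(pi.n):
        if roles[j] != CHROMOSOME and mapped[j] < min_reads:
            report.append(
                {
                    "replicon_index": j,
                    "mapped_reads": int(mapped[j]),
                    "reason": f"fewer_than_{min_reads}_mapped_reads",
                }
            )
        else:
            kept[j] = float(pi.values[j])
    return kept, report


@dataclass
class PCNResults:
    """Fitted copy numbers with per-replicon diagnostics.

    ``estimates`` is a DataFrame with one row per replicon:
    ``genome_id, replicon_id, role, length_bp, uniread_count,
    multiread_alloc, mapped_reads, pcn_direct, pcn_pira, kept,
    converged, iterations``.
    """

    model: "PlasmidCopyNumberModel"
    pcn: PCNVector
    pcn_direct: PCNVector
    trace: PiraTrace
    estimates: pd.DataFrame
    filter_report: list[dict]
    summary_counts: dict

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def iterations(self) -> int:
        return self.trace.iterations

    def summary(self) -> str:
        g = self.model.genome
        lines = [
            "Plasmid copy number estimates (PIRA)",
            "=" * 72,
            f"genome: {g.genome_id}   replicons: {g.n_replicons}   "
            f"reads: {self.summary_counts['n_total']}",
            f"unireads: {self.summary_counts['n_uniread']}   "
            f"multireads (true): {self.summary_counts['n_multiread']}   "
            f"unmapped: {self.summary_counts['n_unmapped']}",
            f"EM iterations: {self.iterations}   converged: {self.converged}",
            "-" * 72,
        ]
        cols = ["replicon_id", "role", "length_bp", "mapped_reads", "pcn_direct", "pcn_pira", "kept"]
        lines.append(
            self.estimates[cols].to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        lines.append("=" * 72)
        return "\n".join(lines)


class PlasmidCopyNumberModel:
    """Copy-number model for one genome and one read set.

    Parameters
    ----------
    genome
        The multi-replicon reference (longest chromosome = copy number 1).
    reads
        Iterable of :class:`~pcnkit.io.ReadRecord`; consumed once at fit
        time.
    k
        k-mer size of the pseudoalignment index (odd, <= 31).
    tau
        Color-support fraction for the empty-intersection fallback.
    tau_loc
        Location-support fraction of the multiread locator.

    Examples
    --------
    >>> model = PlasmidCopyNumberModel.from_files("ref.fa", ["r1.fq"])
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        genome: GenomeRef,
        reads: Iterable[ReadRecord],
        k: int = DEFAULT_K,
        tau: float = DEFAULT_TAU,
        tau_loc: float = DEFAULT_TAU_LOC,
    ) -> None:
        self.genome = genome
        self.reads = reads
        self.k = k
        self.tau = tau
        self.tau_loc = tau_loc

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        fastq_paths: Sequence[str | Path],
        metadata: str | Path | dict | None = None,
        **kwargs,
    ) -> "PlasmidCopyNumberModel":
        genome = load_genome(fasta_path, metadata=metadata)
        return cls(genome, load_reads(fastq_paths), **kwargs)

    def fit(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        min_reads: int = DEFAULT_MIN_READS,
    ) -> PCNResults:
        """Run the full pipeline and return fitted results."""
        genome = self.genome
        index = build_index(genome, k=self.k)
        summary = classify_reads(index, self.reads, tau=self.tau)
        raw_rows = build_match_rows(index, summary.multireads, tau_loc=self.tau_loc)
        promoted, M = promote_unique(summary, raw_rows)

        lengths = np.array(genome.lengths, dtype=np.int64)
        pi0 = direct_pcn(promoted.R, lengths)
        pi, trace = pira_estimate(pi0, M, promoted.R, tol=tol, max_iter=max_iter)

        alloc = expected_allocation(pi, M)
        # banker's rounding of the expected allocation for the read filter
        mapped = promoted.R + np.round(alloc).astype(np.int64)
        roles = [r.role for r in genome.replicons]
        kept, report = filter_estimates(pi, mapped, roles=roles, min_reads=min_reads)

        est = pd.DataFrame(
            {
                "genome_id": genome.genome_id,
                "replicon_id": [r.id for r in genome.replicons],
                "role": roles,
                "length_bp": lengths,
                "uniread_count": promoted.R,
                "multiread_alloc": alloc,
                "mapped_reads": mapped,
                "pcn_direct": pi0.values,
                "pcn_pira": pi.values,
                "kept": [j in kept for j in range(genome.n_replicons)],
                "converged": trace.converged,
                "iterations": trace.iterations,
            }
        )
        counts = {
            "n_total": summary.n_total,
            "n_uniread": int(promoted.R.sum()),
            "n_multiread": M.m,
            "n_unmapped": promoted.n_unmapped,
        }
        return PCNResults(
            model=self,
            pcn=pi,
            pcn_direct=pi0,
            trace=trace,
            estimates=est,
            filter_report=report,
            summary_counts=counts,
        )
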