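"""Colored k-mer index and pseudoalignment.

Pseudoalignment assigns each read to the *set* of replicons compatible
with its k-mer content, without base-level alignment.  Every canonical
k-mer of every replicon is stored with its color set (the replicons it
occurs on) and its occurrence positions; a read is then classified as

* **unmapped** — none of its k-mers hit the index (this is how erroneous
  reads and adapter artifacts drop out of the analysis);
* **uniread** — its k-mers are jointly compatible with exactly one
  replicon;
* **multiread** — compatible with two or more replicons, the signature of
  a mobile element (e.g. a transposon) shared between a chromosome and a
  plasmid.

The assignment rule is the intersection of the color sets of all hit
k-mers; if the intersection is empty (chimeric or junction-spanning
artifacts), we fall back to the union of colors supported by at least a
fraction ``tau`` of the hit k-mers.

Implementation notes: k-mers are packed 2 bits/base into uint64 codes
(so k <= 31), canonicalized as min(code, revcomp code), and stored in a
sorted array with one uint64 color *bitmask* per distinct k-mer (hence at
most 64 replicons per genome — ample for any prokaryote).  k-mers
containing N are never indexed or queried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io import GenomeRef, ReadRecord

DEFAULT_K = 31
DEFAULT_TAU = 0.8
# a read counts as mapped only if this fraction of its valid k-mers hit
# the index; reads riddled with errors keep a stray intact k-mer or two
# and must still be omitted from the analysis
DEFAULT_MIN_HIT_FRACTION = 0.4

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit-packed codes of all k-windows (N treated as 0; mask separately)."""
    m = arr.size - k + 1
    a = np.where(arr < 4, arr, 0).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes |= a[j : j + m] << np.uint64(2 * (k - 1 - j))
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes of a uint8-encoded sequence.

    Returns ``(codes, is_forward, valid)`` over all ``len(arr)-k+1``
    windows: the canonical (strand-collapsed) code, whether the canonical
    form is the forward-strand k-mer, and whether the window is free of N.
    """
    if arr.size < k:
        empty = np.empty(0)
        return empty.astype(np.uint64), empty.astype(bool), empty.astype(bool)
    fwd = _window_codes(arr, k)
    comp = np.where(arr < 4, 3 - arr, 4).astype(np.uint8)
    rc = _window_codes(comp[::-1], k)[::-1]
    canon = np.minimum(fwd, rc)
    is_forward = fwd <= rc
    n_counts = np.concatenate(([0], np.cumsum(arr == 4)))
    valid = (n_counts[k:] - n_counts[:-k]) == 0
    return canon, is_forward, valid


@dataclass
class ColoredKmerIndex:
    """Sorted canonical k-mer codes with color bitmasks and occurrences.

    ``codes`` is sorted ascending; ``masks[i]`` has bit ``j`` set iff
    k-mer ``codes[i]`` occurs on replicon ``j``.  Occurrences of k-mer
    ``i`` live in ``occ_rep/occ_pos/occ_strand[occ_offsets[i]:occ_offsets[i+1]]``;
    ``occ_strand`` is 1 where the reference k-mer equals its canonical
    form, 0 where the canonical form is the reverse complement.
    """

    k: int
    replicon_ids: tuple[str, ...]
    replicon_lengths: np.ndarray
    codes: np.ndarray
    masks: np.ndarray
    occ_offsets: np.ndarray
    occ_rep: np.ndarray
    occ_pos: np.ndarray
    occ_strand: np.ndarray

    @property
    def n_replicons(self) -> int:
        return len(self.replicon_ids)

    @property
    def n_kmers(self) -> int:
        return self.codes.size

    @property
    def n_positions(self) -> int:
        return self.occ_rep.size

    def lookup(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Index of each query code in ``codes`` and a found mask."""
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, self.codes.size - 1) if self.codes.size else idx
        found = (idx < self.codes.size) & (
            self.codes[idx_c] == query if self.codes.size else False
        )
        return idx_c, found


def build_index(genome: GenomeRef, k: int = DEFAULT_K) -> ColoredKmerIndex:
    """Build the colored k-mer index over all replicons of a genome.

    ``k`` must be odd (so no k-mer is its own reverse complement) and at
    most 31 (2-bit packing into 64-bit codes).  Deterministic for a given
    genome and k.
    """
    if k % 2 == 0 or not (3 <= k <= 31):
        raise ValueError(f"k must be odd and in [3, 31], got {k}")
    if genome.n_replicons > 64:
        raise ValueError("at most 64 replicons per genome are supported")
    for rep in genome.replicons:
        if rep.length < k:
            raise ValueError(f"replicon {rep.id!r} is shorter than k={k}")

    codes_parts, rep_parts, pos_parts, strand_parts = [], [], [], []
    for j, rep in enumerate(genome.replicons):
        arr = encode_sequence(rep.sequence)
        canon, is_fwd, valid = canonical_codes(arr, k)
        pos = np.nonzero(valid)[0]
        codes_parts.append(canon[pos])
        rep_parts.append(np.full(pos.size, j, dtype=np.int16))
        pos_parts.append(pos.astype(np.int64))
        strand_parts.append(is_fwd[pos].astype(np.int8))

    all_codes = np.concatenate(codes_parts)
    all_rep = np.concatenate(rep_parts)
    all_pos = np.concatenate(pos_parts)
    all_strand = np.concatenate(strand_parts)

    order = np.argsort(all_codes, kind="stable")
    sc, sr, sp, ss = all_codes[order], all_rep[order], all_pos[order], all_strand[order]

    if sc.size == 0:
        raise ValueError("no indexable k-mers (all windows contain N?)")
    starts = np.concatenate(([0], np.nonzero(sc[1:] != sc[:-1])[0] + 1))
    codes_u = sc[starts]
    occ_offsets = np.concatenate((starts, [sc.size])).astype(np.int64)
    occ_masks = (np.uint64(1) << sr.astype(np.uint64))
    masks_u = np.bitwise_or.reduceat(occ_masks, starts)

    return ColoredKmerIndex(
        k=k,
        replicon_ids=tuple(r.id for r in genome.replicons),
        replicon_lengths=np.array(genome.lengths, dtype=np.int64),
        codes=codes_u,
        masks=masks_u,
        occ_offsets=occ_offsets,
        occ_rep=sr,
        occ_pos=sp,
        occ_strand=ss,
    )


UNMAPPED = "unmapped"
UNIREAD = "uniread"
MULTIREAD = "multiread"


@dataclass(frozen=True)
class ReadAssignment:
    """Pseudoalignment outcome for one read."""

    read_id: str
    status: str
    replicon_set: frozenset[int]

    def __post_init__(self) -> None:
        n = len(self.replicon_set)
        ok = (
            (self.status == UNMAPPED and n == 0)
            or (self.status == UNIREAD and n == 1)
            or (self.status == MULTIREAD and n >= 2)
        )
        if not ok:
            raise ValueError(
                f"status {self.status!r} inconsistent with replicon set of size {n}"
            )


def _bits_to_set(mask: int) -> frozenset[int]:
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return frozenset(out)


def _assign(
    index: ColoredKmerIndex,
    seq: str,
    tau: float,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
) -> frozenset[int]:
    """Replicon set for one read sequence (empty set = unmapped)."""
    arr = encode_sequence(seq)
    canon, _is_fwd, valid = canonical_codes(arr, index.k)
    q = canon[valid]
    if q.size == 0:
        return frozenset()
    idx, found = index.lookup(q)
    if found.sum() < max(1, min_hit_fraction * q.size):
        return frozenset()
    hits = index.masks[idx[found]]
    inter = int(np.bitwise_and.reduce(hits))
    if inter:
        return _bits_to_set(inter)
    # empty intersection: junction/chimeric fallback — union of colors
    # supported by >= tau of the hit k-mers
    n_hits = hits.size
    union = int(np.bitwise_or.reduce(hits))
    sel = 0
    j = 0
    u = union
    while u:
        if u & 1:
            support = int(((hits >> np.uint64(j)) & np.uint64(1)).sum())
            if support >= tau * n_hits:
                sel |= 1 << j
        u >>= 1
        j += 1
    return _bits_to_set(sel)


def pseudoalign_read(
    index: ColoredKmerIndex,
    read: ReadRecord,
    tau: float = DEFAULT_TAU,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
) -> ReadAssignment:
    """Classify one read as unmapped, uniread, or multiread."""
    reps = _assign(index, read.sequence, tau, min_hit_fraction)
    if not reps:
        status = UNMAPPED
    elif len(reps) == 1:
        status = UNIREAD
    else:
        status = MULTIREAD
    return ReadAssignment(read_id=read.id, status=status, replicon_set=reps)


@dataclass
class AssignmentSummary:
    """Aggregate pseudoalignment outcome over a read set.

    ``R[j]`` counts unireads on replicon ``j`` (the initialization counts
    of the copy-number estimate); multireads are retained verbatim for the
    matching stage.  Invariant: ``R.sum() + len(multireads) + n_unmapped
    == n_total``.
    """

    R: np.ndarray
    multireads: list[ReadRecord] = field(default_factory=list)
    n_unmapped: int = 0
    n_total: int = 0

    def check(self) -> None:
        if int(self.R.sum()) + len(self.multireads) + self.n_unmapped != self.n_total:
            raise AssertionError("read-count conservation violated")


_ALL_ONES = np.uint64(0xFFFFFFFFFFFFFFFF)
_BATCH_SIZE = 4096


def _classify_batch(
    index: ColoredKmerIndex,
    batch: list[ReadRecord],
    tau: float,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
) -> list[frozenset[int]]:
    """Vectorized pseudoalignment of a batch of reads.

    Reads are concatenated with ``k-1`` N separators, so invalid windows
    are exactly the read-spanning ones; one code/lookup pass serves the
    whole batch, and per-read color intersections come from segmented
    ``reduceat`` reductions.  Equivalent to mapping
    :func:`pseudoalign_read` over the batch.
    """
    k = index.k
    sep = "N" * (k - 1)
    # trailing separator guarantees every read owns a non-empty window
    # segment even when shorter than k
    arr = encode_sequence(sep.join(r.sequence for r in batch) + sep)
    canon, _is_fwd, valid = canonical_codes(arr, k)

    # window-index offset of each read's first window
    lens = np.fromiter((len(r.sequence) for r in batch), dtype=np.int64, count=len(batch))
    starts = np.concatenate(([0], np.cumsum(lens + (k - 1))[:-1]))

    idx, found = index.lookup(canon)
    found &= valid
    masks_and = np.where(found, index.masks[idx], _ALL_ONES)
    masks_or = np.where(found, index.masks[idx], np.uint64(0))

    inter = np.bitwise_and.reduceat(masks_and, starts)
    union = np.bitwise_or.reduceat(masks_or, starts)
    n_found = np.add.reduceat(found.astype(np.int64), starts)
    n_valid = np.add.reduceat(valid.astype(np.int64), starts)
    # a read shorter than k has no windows of its own (only separator
    # windows land in its segment), so force those to unmapped
    n_found[lens < k] = 0

    out: list[frozenset[int]] = []
    for i in range(len(batch)):
        if n_found[i] < max(1, min_hit_fraction * n_valid[i]):
            out.append(frozenset())
        elif inter[i] != 0:
            out.append(_bits_to_set(int(inter[i])))
        else:
            # rare junction/chimera fallback: per-color support count
            s = starts[i]
            e = starts[i + 1] if i + 1 < len(batch) else masks_and.size
            hits = masks_or[s:e]
            hits = hits[hits != 0]
            sel = 0
            u = int(union[i])
            j = 0
            while u:
                if u & 1:
                    support = int(((hits >> np.uint64(j)) & np.uint64(1)).sum())
                    if support >= tau * hits.size:
                        sel |= 1 << j
                u >>= 1
                j += 1
            out.append(_bits_to_set(sel))
    return out


def classify_reads(
    index: ColoredKmerIndex,
    reads: Iterable[ReadRecord],
    tau: float = DEFAULT_TAU,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
    per_read: list | None = None,
) -> AssignmentSummary:
    """Pseudoalign a read stream and accumulate uniread counts.

    Pass ``per_read=[]`` to additionally collect every ReadAssignment
    (used by the per-read TSV output of the CLI).
    """
    R = np.zeros(index.n_replicons, dtype=np.int64)
    summary = AssignmentSummary(R=R)

    def handle(read: ReadRecord, reps: frozenset[int]) -> None:
        summary.n_total += 1
        if not reps:
            summary.n_unmapped += 1
            status = UNMAPPED
        elif len(reps) == 1:
            R[next(iter(reps))] += 1
            status = UNIREAD
        else:
            summary.multireads.append(read)
            status = MULTIREAD
        if per_read is not None:
            per_read.append(ReadAssignment(read.id, status, reps))

    batch: list[ReadRecord] = []
    for read in reads:
        batch.append(read)
        if len(batch) >= _BATCH_SIZE:
            for r, reps in zip(batch, _classify_batch(index, batch, tau, min_hit_fraction)):
                handle(r, reps)
            batch = []
    if batch:
        for r, reps in zip(batch, _classify_batch(index, batch, tau, min_hit_fraction)):
            handle(r, reps)
    summary.check()
    return summary
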