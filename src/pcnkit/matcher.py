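"""Multiread re-mapping and the match matrix.

Pseudoalignment tells us *which replicons* a multiread is compatible
with; the EM allocation additionally needs *how many distinct places* on
each replicon the read could have come from (a transposon present twice
on the chromosome and once on a plasmid should pull reads toward the
chromosome 2:1 at equal copy number).  This module recovers that count
with a seed-and-cluster procedure over the k-mer occurrence positions
already held in the index:

1. each k-mer hit at read offset ``o`` and reference position ``p``
   implies a candidate read start (``p - o`` for a forward-orientation
   hit, ``p - (L - k - o)`` for reverse);
2. implied starts on one replicon are clustered greedily — two locations
   are distinct when their implied starts differ by at least the read
   length;
3. a cluster supported by at least a fraction ``tau_loc`` of the read's
   k-mers counts as one alignment location.

Multireads whose total location count is exactly 1 are *promoted* to
unireads (they were ambiguous only at replicon-set level, not at
location level); reads with zero locations are reclassified unmapped.
The surviving rows form the match matrix **M** consumed by the EM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .index import AssignmentSummary, ColoredKmerIndex, canonical_codes, encode_sequence
from .io import GenomeRef, ReadRecord

DEFAULT_TAU_LOC = 0.5


@dataclass
class MatchMatrix:
    """m* x n matrix of distinct alignment locations per true multiread.

    Row ``i`` gives, for multiread ``row_read_ids[i]``, the number of
    distinct candidate locations on each replicon.  Every retained row
    describes a true multiread: >= 2 locations in total.
    """

    rows: np.ndarray  # (m*, n) int64
    row_read_ids: list[str]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 2:
            self.rows = self.rows.reshape(0, 0) if self.rows.size == 0 else self.rows
        if self.rows.size and (self.rows < 0).any():
            raise ValueError("match matrix entries must be non-negative")
        if self.rows.size and (self.rows.sum(axis=1) == 0).any():
            raise ValueError("match matrix must not contain all-zero rows")

    @property
    def m(self) -> int:
        return self.rows.shape[0]

    def to_tsv(self, path: str | Path, replicon_ids: Sequence[str]) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\t" + "\t".join(replicon_ids) + "\n")
            for rid, row in zip(self.row_read_ids, self.rows):
                fh.write(rid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def locate_matches(
    index: ColoredKmerIndex,
    genome: GenomeRef | None,
    read: ReadRecord,
    tau_loc: float = DEFAULT_TAU_LOC,
    merge_window: int | None = None,
) -> np.ndarray:
    """Count distinct candidate alignment locations of a read per replicon.

    Returns one integer row of the match matrix.  ``genome`` is accepted
    for interface symmetry but the index alone carries the occurrence
    positions.  ``merge_window`` defaults to the read length.
    """
    k = index.k
    L = len(read.sequence)
    n = index.n_replicons
    row = np.zeros(n, dtype=np.int64)
    if L < k:
        return row
    arr = encode_sequence(read.sequence)
    canon, is_fwd, valid = canonical_codes(arr, k)
    offsets = np.nonzero(valid)[0]
    n_kmers = offsets.size
    if n_kmers == 0:
        return row
    window = merge_window if merge_window is not None else L

    # gather (replicon, implied read start, read offset) triples for all
    # occurrences of all hit k-mers in one flat range expansion
    idx, found = index.lookup(canon[offsets])
    hit = np.nonzero(found)[0]
    if hit.size == 0:
        return row
    o_hit = offsets[hit]
    i_hit = idx[hit]
    occ_s = index.occ_offsets[i_hit]
    occ_e = index.occ_offsets[i_hit + 1]
    counts = occ_e - occ_s
    total = int(counts.sum())
    if total == 0:
        return row
    # flat[j] = occ_s[g] + within-group offset, for group g of element j
    group = np.repeat(np.arange(hit.size), counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    flat = occ_s[group] + within

    reps = index.occ_rep[flat].astype(np.int64)
    pos = index.occ_pos[flat]
    same = index.occ_strand[flat] == is_fwd[o_hit][group].astype(np.int8)
    offs = o_hit[group]
    starts = np.where(same, pos - offs, pos - (L - k - offs))
    min_support = tau_loc * n_kmers

    order = np.lexsort((starts, reps))
    reps_s, starts_s, offs_s = reps[order], starts[order], offs[order]
    bounds = np.concatenate(
        ([0], np.nonzero(reps_s[1:] != reps_s[:-1])[0] + 1, [reps_s.size])
    )
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        j = int(reps_s[b0])
        st = starts_s[b0:b1]
        of = offs_s[b0:b1]
        # greedy clustering: a new location opens when the implied start
        # moves >= window past the cluster anchor
        anchor = st[0]
        support: set[int] = set()
        count = 0
        for s_i, o_i in zip(st.tolist(), of.tolist()):
            if s_i - anchor >= window:
                if len(support) >= min_support:
                    count += 1
                anchor = s_i
                support = set()
            support.add(o_i)
        if len(support) >= min_support:
            count += 1
        row[j] = count
    return row


def build_match_rows(
    index: ColoredKmerIndex,
    multireads: Sequence[ReadRecord],
    tau_loc: float = DEFAULT_TAU_LOC,
) -> np.ndarray:
    """Stack locate_matches rows for a batch of multireads."""
    n = index.n_replicons
    if not multireads:
        return np.zeros((0, n), dtype=np.int64)
    return np.vstack(
        [locate_matches(index, None, r, tau_loc=tau_loc) for r in multireads]
    )


def promote_unique(
    summary: AssignmentSummary, rows: np.ndarray
) -> tuple[AssignmentSummary, MatchMatrix]:
    """Promote unique-location multireads to unireads; build M.

    Rows summing to exactly 1 move their read into the uniread counts of
    the matching replicon; rows summing to 0 (the locator found nothing)
    are reclassified unmapped; the rest form the match matrix.  Read-count
    conservation holds through the promotion.
    """
    rows = np.asarray(rows, dtype=np.int64)
    if rows.shape[0] != len(summary.multireads):
        raise ValueError("one row per multiread required")
    R = summary.R.copy()
    kept_rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    kept_reads: list[ReadRecord] = []
    n_unmapped = summary.n_unmapped
    for read, row in zip(summary.multireads, rows):
        total = int(row.sum())
        if total == 0:
            n_unmapped += 1
        elif total == 1:
            R[int(np.nonzero(row)[0][0])] += 1
        else:
            kept_rows.append(row)
            kept_ids.append(read.id)
            kept_reads.append(read)
    matrix = MatchMatrix(
        rows=np.array(kept_rows, dtype=np.int64).reshape(len(kept_rows), R.size),
        row_read_ids=kept_ids,
    )
    updated = AssignmentSummary(
        R=R, multireads=kept_reads, n_unmapped=n_unmapped, n_total=summary.n_total
    )
    updated.check()
    return updated, matrix
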