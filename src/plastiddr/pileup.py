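"""Per-site base counts from mapped reads.

C-to-U editing is defined on the transcript, so counts can be queried on a
feature's coding strand: for a minus-strand gene the read bases are
complemented before tallying into the A/C/G/T columns.
"""

from __future__ import annotations

import os

import numpy as np
import pysam

from .records import PlastomeRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G


class BaseCounts:
    """A 4 x genome-length table of read base counts (rows A, C, G, T)."""

    def __init__(self, genome_length: int, counts: np.ndarray | None = None):
        self.genome_length = genome_length
        self.counts = (
            counts if counts is not None else np.zeros((4, genome_length), dtype=np.int64)
        )

    def add(self, pos: int, base: str) -> None:
        i = _BASE_INDEX.get(base)
        if i is not None:
            self.counts[i, pos % self.genome_length] += 1

    def depth(self, pos: int) -> int:
        return int(self.counts[:, pos % self.genome_length].sum())

    def at(self, pos: int, strand: str = "+") -> dict[str, int]:
        """Counts at ``pos``, reported on the given strand."""
        col = self.counts[:, pos % self.genome_length]
        if strand == "-":
            col = col[_COMPLEMENT_INDEX]
        return {b: int(col[i]) for i, b in enumerate(BASES)}

    @property
    def total_reads_placed(self) -> int:
        return int(self.counts.sum())


def read_alignments(
    path: str | os.PathLike, record: PlastomeRecord
) -> BaseCounts:
    """Tally per-site base counts from a SAM/BAM file mapped to ``record``.

    The reference name and length in the header must match the record.
    Works on plain-text SAM as well as BAM; no index is required.
    """
    counts = BaseCounts(record.length)
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        refs = dict(zip(af.references, af.lengths))
        if refs:
            if record.id not in refs:
                raise ValueError(
                    f"alignment references {list(refs)} do not include record "
                    f"{record.id}"
                )
            if refs[record.id] != record.length:
                raise ValueError(
                    f"reference length {refs[record.id]} != record length "
                    f"{record.length} for {record.id}"
                )
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            seq = aln.query_sequence.upper()
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                counts.add(rpos, seq[qpos])
    return counts
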