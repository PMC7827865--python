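"""Arithmetic on intervals of a circular genome.

All coordinates are 0-based, half-open. An interval may cross the
replication origin, in which case ``start > end`` and ``wraps`` is true;
its length is then ``genome_length - start + end``. The full circle is not
representable (length must be strictly positive and < genome length for a
wrapping interval).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CircularInterval:
    """Half-open interval ``[start, end)`` on a circle.

    ``start == end`` is rejected: an interval is never empty, and the full
    circle has no canonical representation as a single interval.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        n = (self.end - self.start) % genome_length
        if n == 0:
            raise ValueError(f"zero-length interval {self!r}")
        return n

    def unrolled(self, genome_length: int) -> tuple[int, int]:
        """(start, end) with end possibly beyond genome_length."""
        return self.start, self.start + self.length(genome_length)

    def contains(self, pos: int, genome_length: int) -> bool:
        return (pos - self.start) % genome_length < self.length(genome_length)

    def positions(self, genome_length: int):
        """Iterate genomic positions in 5'->3' order along the circle."""
        s = self.start
        for i in range(self.length(genome_length)):
            yield (s + i) % genome_length

    def shifted(self, offset: int, genome_length: int) -> "CircularInterval":
        """The same arc after rotating the genome left by ``offset``."""
        n = self.length(genome_length)
        s = (self.start - offset) % genome_length
        e = (s + n) % genome_length
        return CircularInterval(s, e)

    def overlaps(self, other: "CircularInterval", genome_length: int) -> bool:
        a0, a1 = self.unrolled(genome_length)
        b0, b1 = other.unrolled(genome_length)
        for da in (0, genome_length):
            for db in (0, genome_length):
                if a0 + da < b1 + db and b0 + db < a1 + da:
                    return True
        return False


def slice_circular(seq: str, iv: CircularInterval) -> str:
    """Extract the bases of ``iv`` from a circular sequence."""
    L = len(seq)
    if iv.wraps:
        return seq[iv.start :] + seq[: iv.end]
    return seq[iv.start : iv.end]
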