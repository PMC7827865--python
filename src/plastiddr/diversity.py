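"""Pairwise SNP/InDel counting between closely related plastomes.

Two genomes (pre-rotated to a comparable origin, e.g. the canonical LSC
start) are aligned by chaining unique shared 31-mers into the longest
collinear chain; the short regions between anchors are closed with a
gapped global alignment. SNPs are aligned columns with two distinct
unambiguous bases; an InDel *event* is one maximal run of gap columns
regardless of its length (the counting dialect is stated in output
headers). Columns involving N are excluded from every tally.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio import Align

DEFAULT_ANCHOR_K = 31
MAX_GAP_CLOSE = 20_000
MIN_CHAIN_COVERAGE = 0.50

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2


class NotCollinearError(ValueError):
    pass


@dataclass
class CollinearAlignment:
    idA: str
    idB: str
    gappedA: str
    gappedB: str
    aligned_fraction: float
    unaligned_bp: int = 0


@dataclass
class PairwiseVariants:
    idA: str
    idB: str
    snp_count: int
    indel_event_count: int
    indel_bp: int
    aligned_fraction: float
    snp_positions: list[int] = field(default_factory=list, repr=False)
    indel_events: list[tuple[int, int, str]] = field(default_factory=list, repr=False)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    index: dict[str, int] = {}
    multi: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in multi:
            continue
        if km in index:
            del index[km]
            multi.add(km)
        else:
            index[km] = i
    return index


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain increasing in both coordinates (pairs sorted by posA)."""
    tails: list[int] = []  # posB of smallest tail per length
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, b) in enumerate(pairs):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    return chain[::-1]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    # a gap of length g costs GAP_OPEN + g * GAP_EXTEND
    a.open_gap_score = GAP_OPEN + GAP_EXTEND
    a.extend_gap_score = GAP_EXTEND
    return a


_DIRECT_CELLS = 1_000_000  # DP size below which we align without anchoring
_FALLBACK_CELLS = 25_000_000  # absolute DP ceiling for unanchorable segments


def _align_pair(
    a: str, b: str, aligner: Align.PairwiseAligner, k: int, max_gap: int
) -> tuple[str, str] | None:
    """Align one inter-anchor segment pair; None when it must stay unaligned.

    Repeat copies carry no genome-wide unique k-mers, so large segments
    are re-anchored with k-mers unique *within the segment* and closed
    recursively; only segments that resist anchoring fall back to a
    bounded direct DP or are reported unaligned.
    """
    if a == b:
        return a, b
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    if len(a) * len(b) <= _DIRECT_CELLS:
        aln = aligner.align(a, b)[0]
        return str(aln[0]), str(aln[1])
    ixa = _unique_kmers(a, k)
    ixb = _unique_kmers(b, k)
    shared = sorted((pa, ixb[km]) for km, pa in ixa.items() if km in ixb)
    chain = _lis_chain(shared) if shared else []
    if not chain:
        if max(len(a), len(b)) > max_gap or len(a) * len(b) > _FALLBACK_CELLS:
            return None
        aln = aligner.align(a, b)[0]
        return str(aln[0]), str(aln[1])
    pa_parts: list[str] = []
    pb_parts: list[str] = []
    ca = cb = 0
    for pa, pb in chain:
        if pa < ca or pb < cb:
            continue
        sub = _align_pair(a[ca:pa], b[cb:pb], aligner, k, max_gap)
        if sub is None:
            return None
        pa_parts.append(sub[0])
        pb_parts.append(sub[1])
        pa_parts.append(a[pa : pa + k])
        pb_parts.append(b[pb : pb + k])
        ca, cb = pa + k, pb + k
    sub = _align_pair(a[ca:], b[cb:], aligner, k, max_gap)
    if sub is None:
        return None
    pa_parts.append(sub[0])
    pb_parts.append(sub[1])
    return "".join(pa_parts), "".join(pb_parts)


def collinear_align(
    seqA: str,
    seqB: str,
    idA: str = "A",
    idB: str = "B",
    k: int = DEFAULT_ANCHOR_K,
    max_gap: int = MAX_GAP_CLOSE,
) -> CollinearAlignment:
    """Anchor-chained global alignment of two near-identical genomes.

    Raises :class:`NotCollinearError` when the anchor chain covers less
    than half of either sequence — the genomes then differ by
    rearrangement, not point variation, and gene-order comparison is the
    right tool.
    """
    seqA, seqB = seqA.upper(), seqB.upper()
    ixA = _unique_kmers(seqA, k)
    ixB = _unique_kmers(seqB, k)
    shared = sorted(
        (posA, ixB[km]) for km, posA in ixA.items() if km in ixB
    )
    if not shared:
        raise NotCollinearError(
            "no shared unique anchors; sequences not collinear; "
            "run compare-order first"
        )
    chain = _lis_chain(shared)
    covA = chain[-1][0] + k - chain[0][0]
    covB = chain[-1][1] + k - chain[0][1]
    if covA < MIN_CHAIN_COVERAGE * len(seqA) or covB < MIN_CHAIN_COVERAGE * len(seqB):
        raise NotCollinearError(
            f"anchor chain covers only {covA}/{len(seqA)} and {covB}/{len(seqB)} "
            "bases; sequences not collinear; run compare-order first"
        )

    aligner = _aligner()
    partsA: list[str] = []
    partsB: list[str] = []
    unaligned = 0

    def close_gap(a_seg: str, b_seg: str) -> None:
        nonlocal unaligned
        pair = _align_pair(a_seg, b_seg, aligner, k, max_gap)
        if pair is None:
            unaligned += len(a_seg)  # reported unaligned, excluded from counts
        else:
            partsA.append(pair[0])
            partsB.append(pair[1])

    ca, cb = 0, 0
    for a, b in chain:
        if a < ca or b < cb:
            continue  # anchor overlapping the previous one on one side only
        close_gap(seqA[ca:a], seqB[cb:b])
        partsA.append(seqA[a : a + k])
        partsB.append(seqB[b : b + k])
        ca, cb = a + k, b + k
    close_gap(seqA[ca:], seqB[cb:])

    gA, gB = "".join(partsA), "".join(partsB)
    aligned_fraction = (len(seqA) - unaligned) / len(seqA)
    return CollinearAlignment(idA, idB, gA, gB, aligned_fraction, unaligned)


def count_variants(alignment: CollinearAlignment) -> PairwiseVariants:
    """Tally SNPs and InDel events from a collinear alignment.

    One InDel event is one maximal contiguous gap run; its length in
    bases accumulates into ``indel_bp``.
    """
    gA, gB = alignment.gappedA, alignment.gappedB
    snps: list[int] = []
    events: list[tuple[int, int, str]] = []
    posA = 0
    in_gap = False
    gap_len = 0
    gap_kind = ""
    gap_start = 0
    for ca, cb in zip(gA, gB):
        if "N" in (ca, cb):
            posA += ca != "-"
            continue
        if ca == "-" or cb == "-":
            kind = "del_in_A" if ca == "-" else "del_in_B"
            if in_gap and kind == gap_kind:
                gap_len += 1
            else:
                if in_gap:
                    events.append((gap_start, gap_len, gap_kind))
                in_gap, gap_len, gap_kind, gap_start = True, 1, kind, posA
            posA += ca != "-"
            continue
        if in_gap:
            events.append((gap_start, gap_len, gap_kind))
            in_gap = False
        if ca != cb:
            snps.append(posA)
        posA += 1
    if in_gap:
        events.append((gap_start, gap_len, gap_kind))
    return PairwiseVariants(
        idA=alignment.idA,
        idB=alignment.idB,
        snp_count=len(snps),
        indel_event_count=len(events),
        indel_bp=sum(n for _, n, _ in events),
        aligned_fraction=alignment.aligned_fraction,
        snp_positions=snps,
        indel_events=events,
    )


def pairwise_variants(
    seqA: str, seqB: str, idA: str = "A", idB: str = "B", **kwargs
) -> PairwiseVariants:
    return count_variants(collinear_align(seqA, seqB, idA, idB, **kwargs))
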