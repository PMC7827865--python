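"""Inversion modelling on circular gene orders.

Selaginella plastome architectures are explained by block inversions that
each span part of a single-copy region plus one repeat copy: the first
inversion turned the ancestral IR pair into a DR pair, and later lineage-
specific inversions turned DR_B back into IR_B. This module applies a
named inversion to an annotated genome and, given two gene orders, infers
the single inversion separating them (the model is deliberately restricted
to one event; multi-inversion sorting is out of scope and is reported as
an explicit failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .intervals import CircularInterval
from .records import PSEUDOGENE, GeneFeature, PlastomeRecord, revcomp, rotate


@dataclass(frozen=True)
class InversionEvent:
    span: CircularInterval
    left_flank: str = ""
    right_flank: str = ""


@dataclass
class GeneOrderMap:
    """Circular list of (gene, strand) derived from an annotated record."""

    genes: list[tuple[str, str]]
    source_id: str = ""
    spans: list[CircularInterval] = field(default_factory=list)

    @classmethod
    def from_record(cls, record: PlastomeRecord) -> "GeneOrderMap":
        feats = sorted(record.features, key=lambda f: f.exons[0].start)
        return cls(
            genes=[(f.name, f.strand) for f in feats],
            source_id=record.id,
            spans=[f.span(record.length) for f in feats],
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class InversionCall:
    """Result of single-inversion inference."""

    found: bool
    identical: bool = False
    segment: list[tuple[str, str]] = field(default_factory=list)
    left_flank: str = ""
    right_flank: str = ""
    span: CircularInterval | None = None
    breakpoints: int = 0

    @property
    def event(self) -> InversionEvent | None:
        if not self.found or self.span is None:
            return None
        return InversionEvent(self.span, self.left_flank, self.right_flank)


def apply_inversion(
    record: PlastomeRecord, event: InversionEvent, allow_split: bool = False
) -> PlastomeRecord:
    """Reverse-complement the spanned block of a circular genome in place.

    Features inside the span get mirrored coordinates and flipped strands;
    features outside are untouched; the genome length is preserved, and
    applying the same event twice restores the original record byte for
    byte. A span boundary falling inside an intact feature is an error
    unless ``allow_split`` is set, in which case the feature is clipped
    into pseudogene fragments.
    """
    L = record.length
    span_len = event.span.length(L)
    rot = rotate(record, event.span.start)  # span now occupies [0, span_len)

    # classify each feature; transformed features keep their list position
    # so that applying the same event twice restores the record exactly
    placed: list[tuple[str, GeneFeature]] = []
    for f in rot.features:
        statuses = []
        for e in f.exons:
            if e.wraps:
                statuses.append("split")
            elif e.end <= span_len:
                statuses.append("in")
            elif e.start >= span_len:
                statuses.append("out")
            else:
                statuses.append("split")
        if all(s == "in" for s in statuses):
            placed.append(("in", f))
        elif all(s == "out" for s in statuses):
            placed.append(("out", f))
        else:
            if not allow_split:
                raise ValueError(
                    f"inversion span splits feature {f.name}; "
                    "pass allow_split=True to clip it into pseudogene fragments"
                )
            inside_ex, outside_ex = [], []
            for e in f.exons:
                s, ue = e.unrolled(L)
                pieces = [(s, min(ue, L))] if not e.wraps else [(s, L), (0, e.end)]
                for ps, pe in pieces:
                    if ps < span_len:
                        inside_ex.append(CircularInterval(ps, min(pe, span_len)))
                    if pe > span_len:
                        outside_ex.append(CircularInterval(max(ps, span_len), pe))
            if inside_ex:
                placed.append(("in", replace(f, exons=inside_ex, status=PSEUDOGENE)))
            if outside_ex:
                placed.append(("out", replace(f, exons=outside_ex, status=PSEUDOGENE)))

    new_seq = revcomp(rot.seq[:span_len]) + rot.seq[span_len:]
    new_features: list[GeneFeature] = []
    for where, f in placed:
        if where == "in":
            exons = [
                CircularInterval(span_len - e.end, span_len - e.start)
                for e in f.exons
            ]
            new_features.append(
                replace(f, strand="-" if f.strand == "+" else "+", exons=exons)
            )
        else:
            new_features.append(f)
    flipped = replace(rot, seq=new_seq, features=new_features)
    return rotate(flipped, -event.span.start)


def event_between_genes(
    record: PlastomeRecord, from_gene: str, to_gene: str
) -> InversionEvent:
    """Span from the start of ``from_gene`` to the end of ``to_gene``."""
    starts = record.features_named(from_gene)
    ends = record.features_named(to_gene)
    if not starts or not ends:
        missing = from_gene if not starts else to_gene
        raise ValueError(f"gene {missing} not found on {record.id}")
    L = record.length
    a = starts[0].span(L)
    b = ends[0].span(L)
    return InversionEvent(CircularInterval(a.start, b.end), from_gene, to_gene)


def _shared_unique(mapA: GeneOrderMap, mapB: GeneOrderMap):
    from collections import Counter

    ca = Counter(n for n, _ in mapA.genes)
    cb = Counter(n for n, _ in mapB.genes)
    keep = {n for n in ca if ca[n] == 1 and cb.get(n) == 1}
    idxA = [i for i, (n, _) in enumerate(mapA.genes) if n in keep]
    idxB = [i for i, (n, _) in enumerate(mapB.genes) if n in keep]
    return idxA, idxB


def _flip(seg: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(n, "-" if s == "+" else "+") for n, s in reversed(seg)]


def infer_inversion(mapA: GeneOrderMap, mapB: GeneOrderMap) -> InversionCall:
    """Find the single inversion transforming ``mapA`` into ``mapB``.

    Comparison is restricted to genes present exactly once in both maps
    (gene loss is a content question, not a rearrangement one). All
    rotations of mapB and both reading directions are tried; a candidate
    exists when the mismatching genes form one contiguous circular block
    whose strand-flipped reversal matches. Ties are broken by shortest
    span. When no single inversion explains the difference the call
    reports the minimal breakpoint-block count instead.
    """
    idxA, idxB = _shared_unique(mapA, mapB)
    if len(idxA) < 3:
        raise ValueError("maps share fewer than 3 uniquely named genes")
    A = [mapA.genes[i] for i in idxA]
    spansA = [mapA.spans[i] for i in idxA] if mapA.spans else []
    B0 = [mapB.genes[i] for i in idxB]
    n = len(A)

    best: InversionCall | None = None
    min_blocks = n + 1
    for flipped_reading, reading in ((False, B0), (True, _flip(B0))):
        for r in range(n):
            B = reading[r:] + reading[:r]
            mism = [i for i in range(n) if A[i] != B[i]]
            if not mism:
                return InversionCall(found=False, identical=True)
            # contiguous circular block? count maximal blocks
            in_m = [i in set(mism) for i in range(n)]
            blocks = sum(
                1 for i in range(n) if in_m[i] and not in_m[(i - 1) % n]
            )
            if blocks == 0:
                # every gene mismatches; a whole-circle reversal is just the
                # flipped reading, so this rotation is uninformative
                continue
            if not flipped_reading:
                # the reported breakpoint count uses the forward reading;
                # flipped-reading block counts are not comparable
                min_blocks = min(min_blocks, blocks)
            if blocks != 1:
                continue
            # block start = first mismatch whose predecessor matches
            i0 = next(i for i in mism if not in_m[(i - 1) % n])
            m = len(mism)
            seg_idx = [(i0 + t) % n for t in range(m)]
            segA = [A[i] for i in seg_idx]
            segB = [B[i] for i in seg_idx]
            if _flip(segA) != segB:
                continue
            left = A[(i0 - 1) % n][0]
            right = A[(i0 + m) % n][0]
            span = None
            if spansA:
                span = CircularInterval(
                    spansA[seg_idx[0]].start, spansA[seg_idx[-1]].end
                )
            cand = InversionCall(
                found=True,
                segment=segA,
                left_flank=left,
                right_flank=right,
                span=span,
                breakpoints=1,
            )
            if best is None or len(cand.segment) < len(best.segment):
                best = cand
    if best is not None:
        return best
    return InversionCall(found=False, identical=False, breakpoints=min_blocks)
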