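"""Annotated circular plastome records.

A :class:`PlastomeRecord` holds the sequence of one plastid genome together
with its gene features. Coordinates are 0-based half-open throughout;
1-based GenBank coordinates exist only at the I/O boundary
(:mod:`plastiddr.genbank_io`). A feature crossing the replication origin is
stored as a single wrapping exon, which keeps intron counts meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .intervals import CircularInterval, slice_circular

PROTEIN = "protein"
TRNA = "tRNA"
RRNA = "rRNA"
CATEGORIES = (PROTEIN, TRNA, RRNA)

INTACT = "intact"
PSEUDOGENE = "pseudogene"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One gene on a plastome.

    ``exons`` are listed in transcription (5'->3' on the coding strand)
    order: for a minus-strand gene the first exon is the one with the
    highest genomic coordinate. ``codon_offset`` is the number of leading
    bases to trim before the first complete codon (GenBank /codon_start
    minus one).
    """

    name: str
    category: str
    strand: str
    exons: list[CircularInterval]
    status: str = INTACT
    codon_offset: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name} has no exons")
        if self.codon_offset not in (0, 1, 2):
            raise ValueError(f"codon_offset must be 0/1/2, got {self.codon_offset}")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def genomic_start(self, genome_length: int) -> int:
        """Smallest genomic start among exons (for sorting/display)."""
        return min(e.start for e in self.exons)

    def spliced_length(self, genome_length: int) -> int:
        return sum(e.length(genome_length) for e in self.exons)

    def span(self, genome_length: int) -> CircularInterval:
        """The genomic footprint from first to last exon, introns included."""
        if self.strand == "+":
            first, last = self.exons[0], self.exons[-1]
        else:
            first, last = self.exons[-1], self.exons[0]
        return CircularInterval(first.start, last.end)


@dataclass
class PlastomeRecord:
    id: str
    species: str
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {self.id}: ambiguity codes other than N are not "
                f"supported (found {sorted(bad)}); resolve them upstream"
            )
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        L = self.length
        for f in self.features:
            for e in f.exons:
                if e.start >= L or e.end > L:
                    raise ValueError(
                        f"record {self.id}: exon {e} of {f.name} outside genome "
                        f"of length {L}"
                    )
                e.length(L)  # raises on zero length

    def features_named(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]

    def gc_percent(self) -> float:
        """GC over the whole circle; N excluded from the denominator."""
        gc = self.seq.count("G") + self.seq.count("C")
        acgt = len(self.seq) - self.seq.count("N")
        return 100.0 * gc / acgt


def extract_cds(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature.

    Exons are concatenated in transcription order, reverse-complemented for
    minus-strand genes, and the first ``codon_offset`` bases are trimmed,
    so the first three characters of the result are the start codon.
    """
    L = record.length
    parts = []
    for e in feature.exons:
        if e.start >= L or e.end > L:
            raise ValueError(f"exon {e} of {feature.name} outside genome")
        s = slice_circular(record.seq, e)
        parts.append(revcomp(s) if feature.strand == "-" else s)
    return "".join(parts)[feature.codon_offset :]


def cds_index_to_genomic(
    record: PlastomeRecord, feature: GeneFeature, index: int
) -> int:
    """Genomic coordinate of base ``index`` of the (offset-trimmed) CDS."""
    L = record.length
    index += feature.codon_offset
    for e in feature.exons:
        n = e.length(L)
        if index < n:
            if feature.strand == "+":
                return (e.start + index) % L
            # minus strand: transcription runs from the exon's genomic end
            return (e.end - 1 - index) % L
        index -= n
    raise IndexError(f"CDS index beyond spliced length of {feature.name}")


def rotate(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular genome left by ``offset`` bases.

    Gene content and every downstream summary statistic are unchanged;
    only coordinates move.
    """
    if not record.circular:
        raise ValueError(f"record {record.id} is linear; cannot rotate")
    L = record.length
    offset %= L
    new_seq = record.seq[offset:] + record.seq[:offset]
    new_features = [
        replace(f, exons=[e.shifted(offset, L) for e in f.exons])
        for f in record.features
    ]
    return replace(record, seq=new_seq, features=new_features)


def reverse_complement_record(record: PlastomeRecord) -> PlastomeRecord:
    """The same molecule read from the other strand."""
    L = record.length
    new_features = []
    for f in record.features:
        exons = []
        for e in f.exons:
            s, ue = e.unrolled(L)
            ns = (L - ue) % L
            ne = (L - s) % L
            exons.append(CircularInterval(ns, ne))
        new_features.append(
            replace(f, strand="-" if f.strand == "+" else "+", exons=exons)
        )
    return replace(record, seq=revcomp(record.seq), features=new_features)
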