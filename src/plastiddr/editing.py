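"""C-to-U RNA editing survey at start and stop codons.

Selaginella plastid genes frequently encode ACG where the transcript needs
an AUG start, and CAA/CAG/CGA where it needs a stop; C-to-U editing
restores the canonical codon post-transcriptionally. The survey classifies
the first and last codon of every intact protein gene as normal, abnormal
(editable to canonical by a single C-to-U event) or other, and pileups of
mapped mRNA reads confirm editing: the genomically-C position shows T in
edited reads.

The edited C within an abnormal codon is fixed by the chemistry:
ACG -> AUG edits the middle base (codon position 2); CAA/CAG/CGA -> stop
edits the first base (codon position 1).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .pileup import BaseCounts
from .records import INTACT, PROTEIN, PlastomeRecord, cds_index_to_genomic, extract_cds

START, STOP = "start", "stop"
NORMAL, ABNORMAL, OTHER = "normal", "abnormal", "other"

NORMAL_STOPS = {"TAA", "TAG", "TGA"}
ABNORMAL_STOPS = {"CAA", "CAG", "CGA"}

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_RATIO = 0.10


def classify_codon(codon: str, kind: str) -> str:
    if kind == START:
        if codon == "ATG":
            return NORMAL
        if codon == "ACG":
            return ABNORMAL
        return OTHER
    if codon in NORMAL_STOPS:
        return NORMAL
    if codon in ABNORMAL_STOPS:
        return ABNORMAL
    return OTHER


@dataclass(frozen=True)
class CodonClassification:
    species: str
    gene: str
    position_kind: str  # start / stop
    codon: str
    klass: str  # normal / abnormal / other


@dataclass
class SpeciesEditingSummary:
    species: str
    n_genes: int
    percents: dict[str, dict[str, float]] = field(default_factory=dict)

    def percent(self, kind: str, klass: str) -> float:
        return self.percents.get(kind, {}).get(klass, 0.0)


def survey_codons(
    record: PlastomeRecord, include_pseudogenes: bool = False
) -> tuple[list[CodonClassification], SpeciesEditingSummary]:
    """Classify the first and last codon of every surveyed protein gene.

    Pseudogenes are excluded by default (their frames are unreliable);
    repeat-duplicated copies of a gene are surveyed once. Genes whose CDS
    is shorter than 6 nt are skipped with a warning.
    """
    seen: set[str] = set()
    classifications: list[CodonClassification] = []
    for f in record.features:
        if f.category != PROTEIN:
            continue
        if f.status != INTACT and not include_pseudogenes:
            continue
        if f.name in seen:
            continue
        seen.add(f.name)
        cds = extract_cds(record, f)
        if len(cds) < 6:
            warnings.warn(f"{record.id}: CDS of {f.name} shorter than 6 nt; skipped")
            continue
        tail_start = len(cds) - 3 - (len(cds) % 3)
        for kind, codon in ((START, cds[:3]), (STOP, cds[tail_start : tail_start + 3])):
            classifications.append(
                CodonClassification(
                    record.species, f.name, kind, codon, classify_codon(codon, kind)
                )
            )
    summary = SpeciesEditingSummary(record.species, len(seen))
    for kind in (START, STOP):
        tally = Counter(
            c.klass for c in classifications if c.position_kind == kind
        )
        total = sum(tally.values())
        summary.percents[kind] = {
            klass: round(100.0 * tally.get(klass, 0) / total, 2) if total else 0.0
            for klass in (ABNORMAL, NORMAL, OTHER)
        }
    return classifications, summary


@dataclass
class EditingCall:
    gene: str
    position_kind: str
    genomic_pos: int
    depth: int
    c_count: int
    t_count: int
    edit_ratio: float
    confirmed: bool
    reason: str = ""


def edited_c_cds_index(codon_start_index: int, kind: str) -> int:
    """CDS index of the C a single C-to-U event must edit."""
    return codon_start_index + (1 if kind == START else 0)


def confirm_editing(
    record: PlastomeRecord,
    classifications: list[CodonClassification],
    base_counts: BaseCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> list[EditingCall]:
    """Check abnormal codons against mRNA read pileups.

    For each abnormal start (ACG) or stop (CAA/CAG/CGA) codon, the edited
    C is located on the genome, read base counts are taken on the coding
    strand, and the site is confirmed when depth >= min_depth and
    t/(c+t) >= min_ratio. Raw counts are always reported; an uncovered
    site yields confirmed=False with reason "no coverage".
    """
    by_gene = {
        f.name: f
        for f in record.features
        if f.category == PROTEIN
    }
    calls: list[EditingCall] = []
    for c in classifications:
        if c.klass != ABNORMAL:
            continue
        f = by_gene.get(c.gene)
        if f is None:
            continue
        cds = extract_cds(record, f)
        if c.position_kind == START:
            codon_start = 0
        else:
            codon_start = len(cds) - 3 - (len(cds) % 3)
        idx = edited_c_cds_index(codon_start, c.position_kind)
        pos = cds_index_to_genomic(record, f, idx)
        counts = base_counts.at(pos, f.strand)
        depth = sum(counts.values())
        cc, tc = counts["C"], counts["T"]
        ratio = tc / (cc + tc) if (cc + tc) else 0.0
        if depth == 0:
            calls.append(
                EditingCall(c.gene, c.position_kind, pos, 0, 0, 0, 0.0, False, "no coverage")
            )
            continue
        ok = depth >= min_depth and ratio >= min_ratio
        reason = ""
        if not ok:
            reason = "low depth" if depth < min_depth else "low edit ratio"
        calls.append(
            EditingCall(c.gene, c.position_kind, pos, depth, cc, tc, ratio, ok, reason)
        )
    return calls


# ------------------------------------------------------------ simple mapper

def simple_map(
    reads: list[tuple[str, str]],
    record: PlastomeRecord,
    k: int = 31,
    seed_stride: int = 7,
) -> BaseCounts:
    """Place reads on the genome by unique k-mer seed vote, ungapped.

    A lightweight circular-aware read placer for simulated data: each read
    casts votes from its k-mers onto (offset, strand) hypotheses built from
    a unique-k-mer index of the genome; the majority hypothesis places the
    read, ambiguous or unseeded reads are discarded and counted. Per-site
    A/C/G/T tallies come back in the same table shape as
    :func:`plastiddr.pileup.read_alignments`.
    """
    from .records import revcomp

    seq = record.seq
    L = record.length
    s2 = seq + seq[: k - 1]
    index: dict[str, int] = {}
    multi: set[str] = set()
    for i in range(L):
        km = s2[i : i + k]
        if km in multi:
            continue
        if km in index:
            del index[km]
            multi.add(km)
        else:
            index[km] = i
    counts = BaseCounts(L)
    discarded = 0
    for _, rseq in reads:
        n = len(rseq)
        votes: Counter = Counter()
        for orient, s in (("+", rseq), ("-", revcomp(rseq))):
            for j in range(0, max(1, n - k + 1), seed_stride):
                p = index.get(s[j : j + k])
                if p is not None:
                    votes[(p - j) % L, orient] += 1
        if not votes:
            discarded += 1
            continue
        ranked = votes.most_common(2)
        if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
            discarded += 1  # ambiguous placement
            continue
        (start, orient), _ = ranked[0]
        placed = rseq if orient == "+" else revcomp(rseq)
        for t, base in enumerate(placed):
            counts.add((start + t) % L, base)
    if counts.total_reads_placed == 0 and reads:
        warnings.warn("simple_map: no read could be placed on the genome")
    counts.discarded = discarded
    return counts
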