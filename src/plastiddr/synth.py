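"""Synthetic plastome generator with recorded ground truth.

Generates every input the pipeline consumes: annotated circular genomes
with a planted large repeat pair (direct or inverted) separating two
single-copy regions, protein/tRNA/rRNA genes (rRNAs duplicated inside the
repeats), configurable fractions of ACG starts, abnormal stops, planted
internal-stop pseudogenes and two-exon genes; mutated genome pairs with
known SNP/InDel truth; and mRNA-like reads carrying C-to-U editing at
per-site efficiencies plus sequencing error.

Defaults emulate the deposited Selaginella genomes: ~130 kb circles,
~12 kb repeats in direct orientation, GC around 53%, and roughly three
quarters of protein genes starting with ACG. One seeded random stream
drives each dataset, so identical configs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .intervals import CircularInterval
from .records import INTACT, PROTEIN, RRNA, TRNA, GeneFeature, PlastomeRecord, revcomp
from .structure import DIRECT, INVERTED

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NORMAL_STOPS = ["TAA", "TAG", "TGA"]
_ABNORMAL_STOPS = ["CAA", "CAG", "CGA"]

# realistic plastid gene symbol pools
_PROTEIN_NAMES = [
    "psbA", "rbcL", "rpoB",  # marker genes, always placed in the LSC
    "psaA", "psaB", "psaC", "psaI", "psaJ", "psbB", "psbC", "psbD", "psbE",
    "psbF", "psbH", "psbI", "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT",
    "psbZ", "atpA", "atpB", "atpE", "atpF", "atpH", "atpI", "ndhA", "ndhB",
    "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH", "ndhI", "ndhJ", "ndhK",
    "petA", "petB", "petD", "petG", "petL", "petN", "rpoA", "rpoC1", "rpoC2",
    "rpl2", "rpl14", "rpl16", "rpl20", "rpl33", "rpl36", "rps2", "rps3",
    "rps4", "rps7", "rps8", "rps11", "rps12", "rps14", "rps18", "rps19",
    "ycf1", "ycf2", "ycf3", "ycf4", "clpP", "cemA", "ccsA", "chlB", "chlL",
    "chlN", "infA", "matK", "accD",
]
_TRNA_NAMES = [
    "trnF-GAA", "trnN-GUU", "trnL-UAA", "trnG-GCC", "trnI-GAU", "trnA-UGC",
    "trnK-UUU", "trnV-GAC", "trnE-UUC", "trnM-CAU", "trnW-CCA", "trnP-UGG",
    "trnH-GUG", "trnC-GCA", "trnD-GUC", "trnS-GCU", "trnQ-UUG", "trnR-ACG",
]
_RRNA = [("rrn16", 1490), ("rrn23", 2810), ("rrn4.5", 103), ("rrn5", 121)]

MIN_SPACER = 180  # leaves room for junction primers between features


@dataclass
class SynthConfig:
    seed: int
    genome_len: int = 130_000
    repeat_len: int = 12_000
    orientation: str = DIRECT
    n_protein: int = 56
    n_trna: int = 8
    n_rrna: int = 4
    pseudogene_fraction: float = 0.0
    acg_start_fraction: float = 0.77
    abnormal_stop_fraction: float = 0.10
    intron_fraction: float = 0.20
    gc_target: float = 0.53
    read_len: int = 100
    depth: int = 100
    seq_error: float = 0.001
    editing_efficiency: float = 0.9
    # plant round(fraction * n) genes instead of Bernoulli draws — use when
    # a study states the realized count (e.g. "43 of 56 genes start ACG")
    exact_fractions: bool = False

    def __post_init__(self) -> None:
        for name in (
            "pseudogene_fraction", "acg_start_fraction", "abnormal_stop_fraction",
            "intron_fraction", "gc_target", "seq_error", "editing_efficiency",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if 2 * self.repeat_len >= self.genome_len:
            raise ValueError("two repeat copies would exceed the genome")
        if self.orientation not in (DIRECT, INVERTED):
            raise ValueError(f"orientation must be direct/inverted")


@dataclass
class EditingSiteTruth:
    gene: str
    kind: str  # start / stop
    genomic_pos: int
    strand: str
    efficiency: float


@dataclass
class GeneTruth:
    name: str
    category: str
    status: str  # present / pseudogene
    strand: str
    region: str  # LSC / SSC / RepA / RepB
    n_introns: int
    start_codon: str = ""
    stop_codon: str = ""


@dataclass
class TruthRecord:
    repeatA: tuple[int, int] | None = None
    repeatB: tuple[int, int] | None = None
    orientation: str = ""
    lsc: tuple[int, int] | None = None
    ssc: tuple[int, int] | None = None
    genes: list[GeneTruth] = field(default_factory=list)
    editing_sites: list[EditingSiteTruth] = field(default_factory=list)
    snp_positions: list[int] = field(default_factory=list)
    indel_events: list[tuple[int, int, str]] = field(default_factory=list)
    inversion_span: tuple[int, int] | None = None
    expected_site_counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            return c


def _make_cds(
    rng: np.random.Generator, cfg: SynthConfig, pseudo: bool,
    acg: bool, abnormal_stop: bool,
) -> tuple[str, str, str]:
    """Random coding sequence; returns (cds, start_codon, stop_codon)."""
    n_codons = int(rng.integers(90, 380))
    start = "ACG" if acg else "ATG"
    stop = (
        _ABNORMAL_STOPS[rng.integers(3)]
        if abnormal_stop
        else _NORMAL_STOPS[rng.integers(3)]
    )
    body = [_random_codon(rng, cfg.gc_target) for _ in range(n_codons)]
    if pseudo:
        body[n_codons // 2] = "TAA"  # planted internal stop
    return start + "".join(body) + stop, start, stop


@dataclass
class _PlannedGene:
    name: str
    category: str
    genomic: str  # forward-strand genomic sequence of the locus
    strand: str
    exon_offsets: list[tuple[int, int]]  # within the locus, genome order
    status: str
    n_introns: int
    start_codon: str = ""
    stop_codon: str = ""


def _plan_gene(
    rng: np.random.Generator, cfg: SynthConfig, name: str, category: str,
    length: int | None = None, acg: bool = False, abnormal_stop: bool = False,
    pseudo: bool = False,
) -> _PlannedGene:
    if category == PROTEIN:
        cds, start, stop = _make_cds(rng, cfg, pseudo, acg, abnormal_stop)
        if rng.random() < cfg.intron_fraction:
            cut = 3 * int(rng.integers(20, len(cds) // 3 - 20))
            intron = _random_seq(rng, int(rng.integers(200, 800)), cfg.gc_target)
            transcript_genomic = cds[:cut] + intron + cds[cut:]
            exons = [(0, cut), (cut + len(intron), len(transcript_genomic))]
            n_introns = 1
        else:
            transcript_genomic = cds
            exons = [(0, len(cds))]
            n_introns = 0
        status = "pseudogene" if pseudo else "present"
    else:
        n = length if length is not None else int(rng.integers(70, 90))
        transcript_genomic = _random_seq(rng, n, cfg.gc_target)
        exons = [(0, n)]
        n_introns = 0
        status = "present"
        start = stop = ""
        cds = transcript_genomic
    strand = "+" if rng.random() < 0.5 else "-"
    genomic = transcript_genomic if strand == "+" else revcomp(transcript_genomic)
    if strand == "-":  # mirror exon offsets onto the forward strand
        n = len(genomic)
        exons = [(n - e, n - s) for s, e in reversed(exons)]
    return _PlannedGene(
        name, category, genomic, strand, sorted(exons), status, n_introns,
        start if category == PROTEIN else "",
        stop if category == PROTEIN else "",
    )


def _layout_region(
    rng: np.random.Generator, cfg: SynthConfig, genes: list[_PlannedGene],
    target_len: int,
) -> tuple[str, list[tuple[_PlannedGene, int]]]:
    """Concatenate spacers and gene loci to exactly ``target_len`` bases."""
    used = sum(len(g.genomic) for g in genes)
    free = target_len - used
    n_spacers = len(genes) + 1
    if free < n_spacers * MIN_SPACER:
        raise ValueError(
            f"infeasible packing: {len(genes)} genes need {used} bp plus "
            f"{n_spacers * MIN_SPACER} bp spacing, region is {target_len} bp"
        )
    cuts = np.sort(rng.choice(free - n_spacers * MIN_SPACER + 1, size=n_spacers - 1))
    widths = np.diff(np.concatenate([[0], cuts, [free - n_spacers * MIN_SPACER]]))
    spacer_lens = widths + MIN_SPACER
    parts: list[str] = []
    placed: list[tuple[_PlannedGene, int]] = []
    pos = 0
    for g, sp in zip(genes, spacer_lens[:-1]):
        parts.append(_random_seq(rng, int(sp), cfg.gc_target))
        pos += int(sp)
        parts.append(g.genomic)
        placed.append((g, pos))
        pos += len(g.genomic)
    parts.append(_random_seq(rng, int(spacer_lens[-1]), cfg.gc_target))
    return "".join(parts), placed


def _feature_from_planned(
    g: _PlannedGene, locus_start: int, genome_len: int
) -> GeneFeature:
    """Feature for a planned gene placed with its locus at ``locus_start``."""
    strand = g.strand
    offsets = g.exon_offsets
    region_start = locus_start
    genomic_exons = [
        CircularInterval(
            (region_start + s) % genome_len, (region_start + e) % genome_len
        )
        for s, e in offsets
    ]
    if strand == "-":
        genomic_exons = list(reversed(genomic_exons))
    return GeneFeature(
        name=g.name,
        category=g.category,
        strand=strand,
        exons=genomic_exons,
        status=INTACT,
    )


def make_plastome(config: SynthConfig) -> tuple[PlastomeRecord, TruthRecord]:
    """Build one annotated circular plastome plus its ground truth.

    Layout on the circle is LSC | RepA | SSC | RepB, with RepB either a
    verbatim copy (direct) or the reverse complement (inverted) of RepA.
    rRNA genes live inside the repeats and are therefore duplicated; the
    LSC/SSC marker genes psbA, rbcL and rpoB are always placed in the LSC.
    """
    rng = np.random.default_rng(config.seed)
    L, R = config.genome_len, config.repeat_len
    sc_total = L - 2 * R
    lsc_len = int(0.45 * sc_total)
    ssc_len = sc_total - lsc_len

    protein_names = list(_PROTEIN_NAMES[: config.n_protein])
    for i in range(len(protein_names), config.n_protein):
        protein_names.append(f"orf{i:03d}")
    trna_names = [
        _TRNA_NAMES[i % len(_TRNA_NAMES)] for i in range(config.n_trna)
    ]
    rrna_specs = [_RRNA[i % len(_RRNA)] for i in range(config.n_rrna)]

    np_ = config.n_protein

    def _flags(fraction: float) -> np.ndarray:
        if config.exact_fractions:
            k = int(round(fraction * np_))
            flags = np.zeros(np_, dtype=bool)
            flags[rng.choice(np_, size=k, replace=False)] = True
            return flags
        return rng.random(np_) < fraction

    acg_flags = _flags(config.acg_start_fraction)
    stop_flags = _flags(config.abnormal_stop_fraction)
    pseudo_flags = _flags(config.pseudogene_fraction)
    proteins = [
        _plan_gene(
            rng, config, name, PROTEIN,
            acg=bool(acg_flags[i]), abnormal_stop=bool(stop_flags[i]),
            pseudo=bool(pseudo_flags[i]),
        )
        for i, name in enumerate(protein_names)
    ]
    trnas = [_plan_gene(rng, config, n, TRNA) for n in trna_names]
    rrnas = [
        _plan_gene(rng, config, name, RRNA, length=ln) for name, ln in rrna_specs
    ]

    # markers stay in the LSC; remaining single-copy genes split by length
    markers = proteins[:3]
    rest = proteins[3:] + trnas
    order = rng.permutation(len(rest))
    rest = [rest[i] for i in order]
    lsc_genes: list[_PlannedGene] = list(markers)
    ssc_genes: list[_PlannedGene] = []
    lsc_load = sum(len(g.genomic) + MIN_SPACER for g in markers) + MIN_SPACER
    ssc_load = MIN_SPACER
    for g in rest:
        cost = len(g.genomic) + MIN_SPACER
        if (lsc_load + cost) / lsc_len <= (ssc_load + cost) / ssc_len:
            lsc_genes.append(g)
            lsc_load += cost
        else:
            ssc_genes.append(g)
            ssc_load += cost

    lsc_seq, lsc_placed = _layout_region(rng, config, lsc_genes, lsc_len)
    rep_seq, rep_placed = _layout_region(rng, config, rrnas, R)
    ssc_seq, ssc_placed = _layout_region(rng, config, ssc_genes, ssc_len)

    if config.orientation == DIRECT:
        repB_seq = rep_seq
    else:
        repB_seq = revcomp(rep_seq)
    genome = lsc_seq + rep_seq + ssc_seq + repB_seq
    assert len(genome) == L

    features: list[GeneFeature] = []
    truth = TruthRecord(
        repeatA=(lsc_len, lsc_len + R),
        repeatB=(L - R, L),
        orientation=config.orientation,
        lsc=(0, lsc_len),
        ssc=(lsc_len + R, L - R),
    )

    def add(g: _PlannedGene, region_start: int, region: str) -> None:
        f = _feature_from_planned(g, region_start, L)
        features.append(f)
        truth.genes.append(
            GeneTruth(
                g.name, g.category, g.status, f.strand, region, g.n_introns,
                g.start_codon, g.stop_codon,
            )
        )

    for g, off in lsc_placed:
        add(g, off, "LSC")
    repA_start = lsc_len
    for g, off in rep_placed:
        add(g, repA_start + off, "RepA")
    ssc_start = lsc_len + R
    for g, off in ssc_placed:
        add(g, ssc_start + off, "SSC")
    repB_start = L - R
    for g, off in rep_placed:
        if config.orientation == DIRECT:
            add(g, repB_start + off, "RepB")
        else:
            flipped = _mirror_planned(g, off, R)
            add(flipped, repB_start + flipped._mirror_off, "RepB")

    record = PlastomeRecord(
        id=f"SYN{config.seed:06d}",
        species=f"Synthetica plastoma {config.seed}",
        seq=genome,
        circular=True,
        features=features,
    )
    record.validate()
    _fill_editing_truth(record, truth, config)
    return record, truth


def _mirror_planned(g: _PlannedGene, off: int, region_len: int) -> _PlannedGene:
    """Gene as it appears after reverse-complementing its region."""
    n = len(g.genomic)
    new_off = region_len - off - n
    new_exons = sorted((n - e, n - s) for s, e in g.exon_offsets)
    flipped = _PlannedGene(
        g.name, g.category, revcomp(g.genomic),
        "-" if g.strand == "+" else "+",
        new_exons, g.status, g.n_introns, g.start_codon, g.stop_codon,
    )
    flipped._mirror_off = new_off
    return flipped


def _fill_editing_truth(
    record: PlastomeRecord, truth: TruthRecord, config: SynthConfig
) -> None:
    from .editing import ABNORMAL, START, STOP, classify_codon
    from .records import cds_index_to_genomic, extract_cds

    seen: set[str] = set()
    for f in record.features:
        if f.category != PROTEIN or f.name in seen:
            continue
        seen.add(f.name)
        cds = extract_cds(record, f)
        if len(cds) < 6:
            continue
        if classify_codon(cds[:3], START) == ABNORMAL:
            pos = cds_index_to_genomic(record, f, 1)
            truth.editing_sites.append(
                EditingSiteTruth(f.name, START, pos, f.strand, config.editing_efficiency)
            )
        if classify_codon(cds[-3:], STOP) == ABNORMAL:
            pos = cds_index_to_genomic(record, f, len(cds) - 3)
            truth.editing_sites.append(
                EditingSiteTruth(f.name, STOP, pos, f.strand, config.editing_efficiency)
            )


# ----------------------------------------------------------------- mutate

def mutate(
    record: PlastomeRecord,
    n_snp: int,
    n_indel: int,
    max_indel_len: int = 50,
    seed: int = 0,
    min_separation: int = 100,
) -> tuple[PlastomeRecord, TruthRecord]:
    """Plant SNPs and InDels at well-separated positions, truth recorded.

    Events keep ``min_separation`` bases apart so each maps back to
    exactly one alignment column run; positions are reported in the
    original record's coordinates. Feature coordinates are remapped
    through the InDels, so a frameshifting deletion inside a CDS turns
    that gene into a detectable pseudogene.
    """
    rng = np.random.default_rng(seed)
    L = record.length
    total = n_snp + n_indel
    if total == 0:
        return record, TruthRecord()
    margin = max_indel_len + min_separation
    room = L - 2 * margin - total * min_separation
    if room <= total:
        raise ValueError(
            f"cannot place {total} events {min_separation} bp apart on "
            f"{L} bp"
        )
    raw = np.sort(rng.choice(room, size=total, replace=False))
    positions = (raw + margin + np.arange(total) * min_separation).astype(int)
    which_indel = set(
        rng.choice(total, size=n_indel, replace=False).tolist()
    )

    base_order = "ACGT"
    snps: list[tuple[int, str]] = []
    indels: list[tuple[int, int, str, str]] = []  # pos, len, kind, inserted seq
    for i, p in enumerate(positions):
        p = int(p)
        if i in which_indel:
            ln = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:
                indels.append((p, ln, "deletion", ""))
            else:
                ins = "".join(rng.choice(_BASES, size=ln))
                indels.append((p, ln, "insertion", ins))
        else:
            old = record.seq[p]
            choices = [b for b in base_order if b != old]
            snps.append((p, choices[int(rng.integers(3))]))

    seq = list(record.seq)
    for p, nb in snps:
        seq[p] = nb
    # apply indels right-to-left so earlier coordinates stay valid
    shift_points: list[tuple[int, int]] = []  # (orig position, delta)
    for p, ln, kind, ins in sorted(indels, reverse=True):
        if kind == "deletion":
            del seq[p : p + ln]
            shift_points.append((p, -ln))
        else:
            seq[p:p] = list(ins)
            shift_points.append((p, ln))
    shift_points.sort()

    def remap(x: int) -> int:
        delta = 0
        for p, d in shift_points:
            if p < x:
                if d < 0 and x < p - d:
                    return p + delta  # inside a deleted block
                delta += d
        return x + delta

    from dataclasses import replace as dc_replace

    new_features = []
    for f in record.features:
        exons = []
        for e in f.exons:
            if e.wraps:
                raise ValueError(
                    "mutate() expects features not to wrap the origin; "
                    "rotate the record first"
                )
            ns, ne = remap(e.start), remap(e.end)
            if ne > ns:
                exons.append(CircularInterval(ns, ne))
        if exons:
            new_features.append(dc_replace(f, exons=exons))

    mutated = PlastomeRecord(
        id=record.id + "_mut",
        species=record.species + " variant",
        seq="".join(seq),
        circular=record.circular,
        features=new_features,
    )
    truth = TruthRecord(
        snp_positions=[p for p, _ in snps],
        indel_events=[(p, ln, kind) for p, ln, kind, _ in indels],
    )
    return mutated, truth


# ----------------------------------------------------------- read simulator

def simulate_reads(
    record: PlastomeRecord,
    editing_sites: list[EditingSiteTruth],
    depth: int = 100,
    read_len: int = 100,
    seq_error: float = 0.001,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """mRNA-like reads over transcribed regions with planted C-to-U editing.

    Reads are sampled uniformly over each gene's genomic span (circular
    aware, uniform abundance per gene). At a planted site a read carries
    the edited base with probability equal to the site's efficiency —
    on the forward strand T for a plus-strand gene, A for a minus-strand
    gene (the transcript's U reads as T). Independent substitution errors
    are applied at ``seq_error``. Read orientation is random.
    """
    rng = np.random.default_rng(seed)
    L = record.length
    site_by_pos = {s.genomic_pos: s for s in editing_sites}
    reads: list[tuple[str, str]] = []
    expected: dict[int, float] = {}
    for s in editing_sites:
        expected[s.genomic_pos] = s.efficiency
    ridx = 0
    for f in record.features:
        span = f.span(L)
        n = span.length(L)
        eff_len = min(read_len, n + read_len // 2)
        # reads may start up to a read length before the span (UTR-like
        # margin) so terminal codons get full coverage
        window = n + eff_len - 1
        n_reads = max(1, int(round(depth * window / eff_len))) if depth else 0
        for _ in range(n_reads):
            start = (span.start - eff_len + 1 + int(rng.integers(0, window))) % L
            bases = []
            for t in range(eff_len):
                pos = (start + t) % L
                base = record.seq[pos]
                site = site_by_pos.get(pos)
                if site is not None and rng.random() < site.efficiency:
                    base = "T" if site.strand == "+" else "A"
                if seq_error and rng.random() < seq_error:
                    base = str(rng.choice([b for b in "ACGT" if b != base]))
                bases.append(base)
            seq = "".join(bases)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            reads.append((f"read{ridx}_{f.name}_{start}{strand}", seq))
            ridx += 1
    truth = TruthRecord(
        editing_sites=list(editing_sites),
        expected_site_counts={
            str(pos): eff for pos, eff in sorted(expected.items())
        },
    )
    return reads, truth
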