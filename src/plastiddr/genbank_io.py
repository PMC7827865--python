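"""Reading and writing annotated plastomes.

GenBank flat files are the primary interchange format (deposited plastomes
come that way); FASTA + GFF3 is accepted as an alternative. Parsing is
delegated to Biopython/gffutils; this module only maps their feature model
onto :class:`~plastiddr.records.PlastomeRecord`, converting 1-based
inclusive GenBank coordinates to the package's 0-based half-open circular
intervals and merging origin-spanning joins into single wrapping exons.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .intervals import CircularInterval
from .records import (
    INTACT,
    PROTEIN,
    PSEUDOGENE,
    RRNA,
    TRNA,
    GeneFeature,
    PlastomeRecord,
    extract_cds,
)

_TYPE_TO_CATEGORY = {"CDS": PROTEIN, "tRNA": TRNA, "rRNA": RRNA}


def _category_from_name(name: str) -> str:
    low = name.lower()
    if low.startswith("trn"):
        return TRNA
    if low.startswith("rrn"):
        return RRNA
    return PROTEIN


def _merge_origin_exons(
    exons: list[tuple[int, int]], strand: str, genome_length: int
) -> list[CircularInterval]:
    """Collapse a join that merely crosses the origin into one wrapping exon.

    Exons arrive as (start, end) pairs in transcription order. On the plus
    strand a continuation across the origin reads ``(x, L), (0, y)``; on the
    minus strand ``(0, y), (x, L)``. Anything else is a genuine intron.
    """
    merged: list[CircularInterval] = []
    i = 0
    while i < len(exons):
        s, e = exons[i]
        nxt = exons[i + 1] if i + 1 < len(exons) else None
        if nxt is not None:
            if strand == "+" and e == genome_length and nxt[0] == 0:
                merged.append(CircularInterval(s, nxt[1]))
                i += 2
                continue
            if strand == "-" and s == 0 and nxt[1] == genome_length:
                merged.append(CircularInterval(nxt[0], e))
                i += 2
                continue
        merged.append(CircularInterval(s, e % genome_length))
        i += 1
    return merged


def _feature_from_seqfeature(
    sf: SeqFeature, seq: str, ftype: str
) -> GeneFeature:
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
    try:
        strand = "-" if sf.location.strand == -1 else "+"
        parts = list(sf.location.parts)
    except Exception as exc:  # malformed location
        raise ValueError(f"feature {name}: cannot interpret location: {exc}")
    pairs = [(int(p.start), int(p.end)) for p in parts]
    # Biopython lists parts in file order; put them in transcription order,
    # using the extracted transcript as the authority.
    candidate = _merge_origin_exons(pairs, strand, len(seq))
    codon_offset = int(quals.get("codon_start", ["1"])[0]) - 1
    pseudo = "pseudo" in quals or "pseudogene" in quals
    feat = GeneFeature(
        name=name,
        category=_TYPE_TO_CATEGORY[ftype],
        strand=strand,
        exons=candidate,
        status=PSEUDOGENE if pseudo else INTACT,
        codon_offset=codon_offset,
    )
    try:
        expected = str(sf.extract(Seq(seq)))
    except Exception:
        expected = None
    if expected:
        probe = PlastomeRecord(id="_probe", species="", seq=seq)
        got = extract_cds(probe, feat)[: len(expected)]
        if got != expected[codon_offset:][: len(got)]:
            feat.exons = list(reversed(feat.exons))
    return feat


def read_genbank(path: str | os.PathLike) -> list[PlastomeRecord]:
    """Read every LOCUS of a GenBank flat file into plastome records.

    Pseudogene status comes from /pseudo(/pseudogene) qualifiers, or from a
    gene feature that has no CDS/tRNA/rRNA child. The circular flag is taken
    from the LOCUS topology.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "genbank"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) == {"N"}:
            raise ValueError(f"record {rec.id}: empty sequence")
        species = rec.annotations.get("organism", "") or rec.description
        circular = rec.annotations.get("topology", "linear") == "circular"
        features: list[GeneFeature] = []
        typed_names: set[str] = set()
        for sf in rec.features:
            if sf.type in _TYPE_TO_CATEGORY:
                feat = _feature_from_seqfeature(sf, seq, sf.type)
                features.append(feat)
                typed_names.add(feat.name)
        # gene features without a typed child are pseudogene remnants
        for sf in rec.features:
            if sf.type != "gene":
                continue
            name = (sf.qualifiers.get("gene") or sf.qualifiers.get("locus_tag") or ["?"])[0]
            if name in typed_names:
                continue
            strand = "-" if sf.location.strand == -1 else "+"
            pairs = [(int(p.start), int(p.end)) for p in sf.location.parts]
            exons = _merge_origin_exons(pairs, strand, len(seq))
            features.append(
                GeneFeature(
                    name=name,
                    category=_category_from_name(name),
                    strand=strand,
                    exons=exons,
                    status=PSEUDOGENE,
                )
            )
        out = PlastomeRecord(
            id=rec.id, species=species, seq=seq, circular=circular, features=features
        )
        out.validate()
        records.append(out)
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return records


def read_genbank_one(path: str | os.PathLike) -> PlastomeRecord:
    recs = read_genbank(path)
    if len(recs) != 1:
        raise ValueError(f"{path}: expected one record, found {len(recs)}")
    return recs[0]


def _location_for(feature: GeneFeature, genome_length: int):
    strand = -1 if feature.strand == "-" else 1
    parts = []
    for e in feature.exons:
        if e.wraps:
            a = SimpleLocation(e.start, genome_length, strand)
            b = SimpleLocation(0, e.end, strand)
            parts.extend([a, b] if strand == 1 else [b, a])
        else:
            parts.append(SimpleLocation(e.start, e.end, strand))
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def write_genbank(record: PlastomeRecord, path: str | os.PathLike) -> None:
    rec = SeqRecord(
        Seq(record.seq),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description=record.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.species,
        },
    )
    ftype = {PROTEIN: "CDS", TRNA: "tRNA", RRNA: "rRNA"}
    for f in record.features:
        quals = {"gene": [f.name]}
        if f.category == PROTEIN:
            quals["codon_start"] = [str(f.codon_offset + 1)]
        if f.status == PSEUDOGENE:
            quals["pseudo"] = [""]
        loc = _location_for(f, record.length)
        rec.features.append(SeqFeature(loc, type=ftype[f.category], qualifiers=quals))
    SeqIO.write([rec], os.fspath(path), "genbank")


def read_fasta_gff3(fasta_path, gff3_path) -> PlastomeRecord:
    """Assemble a record from a FASTA sequence and a GFF3 annotation."""
    import gffutils

    seq_rec = next(SeqIO.parse(os.fspath(fasta_path), "fasta"))
    seq = str(seq_rec.seq).upper()
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            os.fspath(gff3_path), dbpath, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        features: list[GeneFeature] = []
        gff_type = {"CDS": PROTEIN, "tRNA": TRNA, "rRNA": RRNA}
        by_gene: dict[tuple[str, str], list] = {}
        for ft, cat in gff_type.items():
            for f in db.features_of_type(ft):
                name = (f.attributes.get("gene") or f.attributes.get("Name")
                        or f.attributes.get("ID") or ["?"])[0]
                by_gene.setdefault((name, cat), []).append(f)
        for (name, cat), parts in by_gene.items():
            parts.sort(key=lambda f: f.start)
            strand = parts[0].strand if parts[0].strand in "+-" else "+"
            exons = [CircularInterval(p.start - 1, p.end) for p in parts]
            if strand == "-":
                exons = list(reversed(exons))
            pseudo = any(
                (p.attributes.get("pseudo") or p.attributes.get("pseudogene"))
                for p in parts
            )
            offset = parts[0].frame
            features.append(
                GeneFeature(
                    name=name, category=cat, strand=strand, exons=exons,
                    status=PSEUDOGENE if pseudo else INTACT,
                    codon_offset=int(offset) if offset in ("0", "1", "2") else 0,
                )
            )
    finally:
        os.unlink(dbpath)
    rec = PlastomeRecord(
        id=seq_rec.id, species=seq_rec.description, seq=seq, features=features
    )
    rec.validate()
    return rec


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(os.fspath(path), "fastq")]
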