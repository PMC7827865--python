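"""Gene content, intron and summary-statistic surveys.

Builds the species x gene presence/pseudogene/missing matrix, the intron
presence table over the 19 canonical intron-containing plastid genes, and
per-genome summary statistics (region lengths, GC, category counts in the
two counting conventions: repeat duplicates counted once, or per copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Seq import Seq

from .records import INTACT, PROTEIN, PSEUDOGENE, PlastomeRecord, extract_cds
from .reference import intron_catalog, load_gene_synonyms
from .structure import QuadripartitePartition

PRESENT = "present"
MISSING = "missing"

# plastid genes use the bacterial/plastid translation table
TRANSLATION_TABLE = 11


@lru_cache(maxsize=1)
def _synonyms() -> dict[str, str]:
    return load_gene_synonyms()


def normalize_gene_name(name: str) -> str:
    """Map annotation naming dialects onto one canonical symbol.

    Lower-cased aliases from the shipped synonym table win; tRNA genes
    drop their anticodon suffix (trnF-GAA -> trnF).
    """
    name = name.strip()
    syn = _synonyms()
    if name.lower() in syn:
        return syn[name.lower()]
    if name.lower().startswith("trn"):
        base = name.split("-")[0].split("_")[0]
        # single-letter amino-acid code is upper-cased; trnfM-style names kept
        if len(base) == 4:
            return "trn" + base[3].upper()
        return base
    return name


@dataclass(frozen=True)
class GeneStatusEntry:
    species: str
    gene: str
    status: str  # present / pseudogene / missing
    copies: int = 0
    category: str = ""


@dataclass(frozen=True)
class IntronRecord:
    species: str
    gene: str
    intron_index: int
    state: str  # present / absent / gene-missing

    def __post_init__(self):
        if self.intron_index == 2 and self.gene not in ("clpP", "ycf3"):
            raise ValueError(f"second intron reported for {self.gene}")


def has_internal_stop(cds: str) -> bool:
    """True when the spliced CDS translates with a premature stop (table 11)."""
    if len(cds) < 6 or len(cds) % 3 != 0:
        return True
    aa = str(Seq(cds[:-3]).translate(table=TRANSLATION_TABLE))
    return "*" in aa


def classify_status(record: PlastomeRecord, gene: str) -> GeneStatusEntry:
    """Status of one gene on one genome.

    Missing when unannotated; pseudogene when flagged in the annotation or
    when an annotated protein gene carries an internal stop codon or a
    spliced length not divisible by three; present otherwise.
    """
    target = normalize_gene_name(gene)
    feats = [f for f in record.features if normalize_gene_name(f.name) == target]
    if not feats:
        return GeneStatusEntry(record.species, target, MISSING, 0)
    category = feats[0].category
    status = PRESENT
    if any(f.status == PSEUDOGENE for f in feats):
        status = PSEUDOGENE
    elif category == PROTEIN:
        for f in feats:
            if f.status == INTACT and has_internal_stop(extract_cds(record, f)):
                status = PSEUDOGENE
                break
    return GeneStatusEntry(record.species, target, status, len(feats), category)


@dataclass
class PresenceMatrix:
    """Species x gene status grid plus per-copy counts."""

    status: pd.DataFrame  # values present/pseudogene/missing
    copies: pd.DataFrame  # integer copy counts
    categories: dict[str, str] = field(default_factory=dict)

    def totals(self, per_copy: bool = False) -> pd.Series:
        """Intact genes per species, duplicates counted once or per copy."""
        present = self.status == PRESENT
        if per_copy:
            return (self.copies * present).sum(axis=1)
        return present.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.status.to_csv(path, sep="\t")


def build_matrix(
    records: list[PlastomeRecord], reference_genes: list[str] | None = None
) -> PresenceMatrix:
    """Complete species x gene status matrix over the given genomes.

    The reference gene list defaults to the union of (normalized) gene
    names annotated on the inputs, so every cell gets exactly one status.
    """
    species = [r.species for r in records]
    if len(set(species)) != len(species):
        raise ValueError("duplicate species labels in record list")
    if reference_genes is None:
        names = set()
        for r in records:
            names.update(normalize_gene_name(f.name) for f in r.features)
        reference_genes = sorted(names)
    status_rows, copy_rows = [], []
    categories: dict[str, str] = {}
    for r in records:
        srow, crow = {}, {}
        for g in reference_genes:
            entry = classify_status(r, g)
            srow[g] = entry.status
            crow[g] = entry.copies
            if entry.category:
                categories.setdefault(g, entry.category)
        status_rows.append(srow)
        copy_rows.append(crow)
    return PresenceMatrix(
        status=pd.DataFrame(status_rows, index=species),
        copies=pd.DataFrame(copy_rows, index=species),
        categories=categories,
    )


def intron_survey(record: PlastomeRecord, catalog: dict | None = None) -> list[IntronRecord]:
    """Intron presence over the canonical intron-containing genes.

    Intron *i* is present iff an annotated copy has at least i+1 exons.
    Genes that are missing or pseudogenized score 'gene-missing' (their
    exon structure is not trustworthy), matching the survey convention.
    """
    catalog = catalog if catalog is not None else intron_catalog()
    out = []
    for gene, info in catalog.items():
        entry = classify_status(record, gene)
        feats = [
            f for f in record.features if normalize_gene_name(f.name) == gene
        ]
        max_exons = max((len(f.exons) for f in feats), default=0)
        for i in range(1, info["max_introns"] + 1):
            if entry.status != PRESENT:
                state = "gene-missing"
            else:
                state = "present" if max_exons >= i + 1 else "absent"
            out.append(IntronRecord(record.species, gene, i, state))
    return out


@dataclass
class PlastomeStats:
    species: str
    total_len: int
    lsc_len: int
    ssc_len: int
    repeat_len: int
    orientation: str
    gc: float
    ssc_fraction: float
    counts_once: dict[str, int] = field(default_factory=dict)
    counts_dup: dict[str, int] = field(default_factory=dict)
    total_genes_once: int = 0
    total_genes_per_copy: int = 0

    def as_row(self) -> dict:
        row = {
            "species": self.species,
            "total_len": self.total_len,
            "lsc_len": self.lsc_len,
            "ssc_len": self.ssc_len,
            "repeat_len": self.repeat_len,
            "orientation": self.orientation,
            "gc_percent": self.gc,
            "ssc_fraction": self.ssc_fraction,
            "total_genes": self.total_genes_per_copy,
        }
        for cat in ("protein", "rRNA", "tRNA"):
            row[f"{cat}_genes"] = self.counts_once.get(cat, 0)
            row[f"{cat}_dup"] = self.counts_dup.get(cat, 0)
        return row


def ssc_fraction_percent(ssc_len: int, total_len: int) -> float:
    """SSC length as a percentage of the plastome, reported to 2 decimals."""
    return round(100.0 * ssc_len / total_len, 2)


def stats(
    record: PlastomeRecord,
    part: QuadripartitePartition,
    include_pseudo: bool = False,
) -> PlastomeStats:
    """Summary statistics for one partitioned genome.

    GC is computed over the whole circle with N excluded from the
    denominator. Category counts come in both conventions: distinct gene
    names (``counts_once``) and the number of duplicated names
    (``counts_dup``, the parenthetical); the per-copy total is their sum.
    """
    L = record.length
    lengths = part.lengths(L)
    by_cat_names: dict[str, dict[str, int]] = {}
    for f in record.features:
        if f.status != INTACT and not include_pseudo:
            continue
        name = normalize_gene_name(f.name)
        by_cat_names.setdefault(f.category, {})
        by_cat_names[f.category][name] = by_cat_names[f.category].get(name, 0) + 1
    counts_once = {cat: len(names) for cat, names in by_cat_names.items()}
    counts_dup = {
        cat: sum(c - 1 for c in names.values() if c > 1)
        for cat, names in by_cat_names.items()
    }
    once = sum(counts_once.values())
    per_copy = once + sum(counts_dup.values())
    return PlastomeStats(
        species=record.species,
        total_len=L,
        lsc_len=lengths["LSC"],
        ssc_len=lengths["SSC"],
        repeat_len=part.repeats.length,
        orientation=part.orientation,
        gc=round(record.gc_percent(), 2),
        ssc_fraction=ssc_fraction_percent(lengths["SSC"], L),
        counts_once=counts_once,
        counts_dup=counts_dup,
        total_genes_once=once,
        total_genes_per_copy=per_copy,
    )


def aggregate(
    df: pd.DataFrame, group_col: str, columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-group mean/SD/min/max of the numeric columns, mean and SD to 1 dp.

    Groups come from ``group_col``; an empty group (or empty frame) is an
    error, and SD of a single-member group is reported as 0.
    """
    if df.empty:
        raise ValueError("cannot aggregate an empty table")
    numeric = columns or [
        c for c in df.columns if c != group_col and pd.api.types.is_numeric_dtype(df[c])
    ]
    grouped = df.groupby(group_col)[numeric]
    out = pd.concat(
        {
            "mean": grouped.mean().round(1),
            "sd": grouped.std(ddof=1).fillna(0.0).round(1),
            "min": grouped.min(),
            "max": grouped.max(),
        },
        axis=1,
    )
    out.columns = [f"{col}_{stat}" for stat, col in out.columns]
    return out
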