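"""Gene status classification, presence matrix, introns and statistics."""

from __future__ import annotations

from dataclasses import replace

import pandas as pd
import pytest

from plastiddr import (
    PlastomeRecord,
    SynthConfig,
    aggregate,
    build_matrix,
    classify_status,
    intron_survey,
    make_plastome,
    reverse_complement_record,
    rotate,
    stats,
)
from plastiddr.content import (
    IntronRecord,
    normalize_gene_name,
    ssc_fraction_percent,
)
from plastiddr.intervals import CircularInterval
from plastiddr.records import GeneFeature
from plastiddr.reference import (
    intron_catalog,
    load_intron_table,
    load_plastome_table,
)
from plastiddr.structure import analyse

from conftest import SMALL


def _toy_record(cds: str, name="geneA", strand="+", pseudo_flag=False):
    pad = "ACGG" * 25
    seq = pad + cds + pad
    feat = GeneFeature(
        name=name,
        category="protein",
        strand=strand,
        exons=[CircularInterval(100, 100 + len(cds))],
        status="pseudogene" if pseudo_flag else "intact",
    )
    return PlastomeRecord(id="toy", species="Toy species", seq=seq, features=[feat])


class TestClassifyStatus:
    def test_intact_gene_present(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TAA")
        assert classify_status(rec, "geneA").status == "present"

    def test_planted_internal_stop_is_pseudogene(self):
        body = ["GCA"] * 30
        body[19] = "TAA"  # internal stop at codon 20
        rec = _toy_record("ATG" + "".join(body) + "TAA")
        assert classify_status(rec, "geneA").status == "pseudogene"

    def test_broken_frame_is_pseudogene(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TA")
        assert classify_status(rec, "geneA").status == "pseudogene"

    def test_annotation_flag_wins(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TAA", pseudo_flag=True)
        assert classify_status(rec, "geneA").status == "pseudogene"

    def test_unannotated_gene_missing(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TAA")
        entry = classify_status(rec, "ycf2")
        assert entry.status == "missing" and entry.copies == 0

    def test_acg_start_is_not_pseudogene(self):
        """An editable ACG start must not be mistaken for gene decay."""
        rec = _toy_record("ACG" + "GCA" * 20 + "CAA")
        assert classify_status(rec, "geneA").status == "present"


def test_normalize_gene_name_dialects():
    assert normalize_gene_name("trnF-GAA") == "trnF"
    assert normalize_gene_name("trnfM-CAU") == "trnfM"
    assert normalize_gene_name("PsbA") == "psbA"
    assert normalize_gene_name("rrn16S") == "rrn16"
    assert normalize_gene_name("ndhA") == "ndhA"


def test_build_matrix_matches_generator_truth():
    cfg = SynthConfig(seed=5, pseudogene_fraction=0.3, **SMALL)
    rec, truth = make_plastome(cfg)
    m = build_matrix([rec])
    for g in truth.genes:
        assert m.status.loc[rec.species, normalize_gene_name(g.name)] == g.status


def test_build_matrix_planted_losses(dr_genome):
    recA, _ = dr_genome
    lost = {"psaB", "psbC"}
    recB = replace(
        recA,
        species="Trimmed species",
        features=[f for f in recA.features if f.name not in lost],
    )
    m = build_matrix([recA, recB])
    for g in lost:
        assert m.status.loc[recA.species, g] == "present"
        assert m.status.loc["Trimmed species", g] == "missing"
    # every cell filled
    assert m.status.isin(["present", "pseudogene", "missing"]).all().all()


def test_build_matrix_duplicate_species_error(dr_genome):
    rec, _ = dr_genome
    with pytest.raises(ValueError, match="duplicate"):
        build_matrix([rec, rec])


def test_counting_conventions_consistency(dr_genome):
    """Per-copy total minus once-only total equals the duplicate tally."""
    rec, _ = dr_genome
    part = analyse(rec)
    s = stats(rec, part)
    assert s.total_genes_per_copy - s.total_genes_once == sum(s.counts_dup.values())
    assert s.counts_dup["rRNA"] == 4  # the repeat-duplicated rRNAs
    assert s.lsc_len + s.ssc_len + 2 * s.repeat_len == s.total_len


class TestIntrons:
    def test_two_exon_gene_has_intron(self):
        cds = "ATG" + "GCA" * 40 + "TAA"
        pad = "ACGG" * 50
        seq = pad + cds[:60] + "T" * 30 + cds[60:] + pad
        feat = GeneFeature(
            name="atpF", category="protein", strand="+",
            exons=[CircularInterval(200, 260), CircularInterval(290, 290 + len(cds) - 60)],
        )
        rec = PlastomeRecord(id="t", species="T sp", seq=seq, features=[feat])
        states = {
            (r.gene, r.intron_index): r.state for r in intron_survey(rec)
        }
        assert states[("atpF", 1)] == "present"

    def test_single_exon_clpp_lacks_both_introns(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TAA", name="clpP")
        states = {
            (r.gene, r.intron_index): r.state for r in intron_survey(rec)
        }
        assert states[("clpP", 1)] == "absent"
        assert states[("clpP", 2)] == "absent"

    def test_missing_gene_propagates(self):
        rec = _toy_record("ATG" + "GCA" * 20 + "TAA")
        states = {
            (r.gene, r.intron_index): r.state for r in intron_survey(rec)
        }
        assert states[("petB", 1)] == "gene-missing"

    def test_second_intron_only_for_clpp_ycf3(self):
        with pytest.raises(ValueError, match="second intron"):
            IntronRecord("sp", "atpF", 2, "present")

    def test_generator_truth_recovered(self):
        cfg = SynthConfig(seed=9, intron_fraction=0.5, **SMALL)
        rec, truth = make_plastome(cfg)
        by_gene = {normalize_gene_name(g.name): g for g in truth.genes}
        for r in intron_survey(rec):
            g = by_gene.get(r.gene)
            if g is None or g.status != "present":
                continue
            if r.state == "present":
                assert g.n_introns >= r.intron_index


class TestStats:
    def test_all_gc_toy(self):
        rec = PlastomeRecord(id="t", species="t", seq="GCGCGCGCGC")
        assert rec.gc_percent() == 100.0

    def test_n_excluded_from_denominator(self):
        rec = PlastomeRecord(id="t", species="t", seq="GCGCNNNN")
        assert rec.gc_percent() == 100.0

    def test_gc_invariance(self, dr_genome):
        rec, _ = dr_genome
        assert rotate(rec, 31_000).gc_percent() == pytest.approx(rec.gc_percent())
        assert reverse_complement_record(rec).gc_percent() == pytest.approx(
            rec.gc_percent()
        )

    def test_ssc_fraction_two_decimals(self):
        assert ssc_fraction_percent(61_075, 143_192) == 42.65


class TestAggregate:
    def test_group_mean_rounding(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3, "trna": [27, 30, 32]}
        )
        out = aggregate(df, "group")
        assert out.loc["a", "trna_mean"] == 29.7

    def test_single_member_group_sd_zero(self):
        df = pd.DataFrame({"group": ["a"], "x": [5.0]})
        out = aggregate(df, "group")
        assert out.loc["a", "x_mean"] == 5.0
        assert out.loc["a", "x_sd"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate(pd.DataFrame(columns=["group", "x"]), "group")


class TestReferenceCompendium:
    def test_table_shape_and_structure_identity(self):
        df = load_plastome_table()
        assert len(df) == 19
        # the quadripartite lengths tile every genome
        assert (
            df.lsc_len + df.ssc_len + 2 * df.repeat_len == df.total_len
        ).all()
        # per-copy totals decompose into category counts plus duplicates
        assert (
            df.total_genes
            == df.protein_genes + df.rrna_genes + df.trna_genes
            + df.protein_dup + df.rrna_dup + df.trna_dup
        ).all()

    def test_huperzia_lucidula_intron_pattern(self):
        t = load_intron_table()
        hlu = t[t.species == "Huperzia lucidula"].set_index(["gene", "intron_index"])
        for gene in ["atpF", "petB", "petD", "rpl16", "rpl2", "rpoC1", "rps12", "rps16"]:
            assert hlu.loc[(gene, 1), "state"] == "present", gene
        assert hlu.loc[("clpP", 1), "state"] == "present"
        assert hlu.loc[("clpP", 2), "state"] == "present"
        assert hlu.loc[("ycf3", 1), "state"] == "present"
        assert hlu.loc[("ycf3", 2), "state"] == "present"
        assert hlu.loc[("ycf66", 1), "state"] == "absent"

    def test_catalog_matches_intron_record_schema(self):
        cat = intron_catalog()
        assert cat["clpP"]["max_introns"] == 2
        assert cat["ycf3"]["max_introns"] == 2
        assert all(
            v["max_introns"] == 1
            for k, v in cat.items()
            if k not in ("clpP", "ycf3")
        )
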