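"""Terminal-codon classification, pileup confirmation and the read placer."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from plastiddr import (
    BaseCounts,
    PlastomeRecord,
    SynthConfig,
    confirm_editing,
    make_plastome,
    reverse_complement_record,
    simple_map,
    simulate_reads,
    survey_codons,
)
from plastiddr.editing import (
    ABNORMAL,
    NORMAL,
    OTHER,
    START,
    STOP,
    classify_codon,
)
from plastiddr.intervals import CircularInterval
from plastiddr.records import GeneFeature
from plastiddr.synth import EditingSiteTruth

from conftest import SMALL


@pytest.mark.parametrize(
    "codon,kind,expected",
    [
        ("ATG", START, NORMAL),
        ("ACG", START, ABNORMAL),
        ("GTG", START, OTHER),
        ("TTG", START, OTHER),
        ("TAA", STOP, NORMAL),
        ("TAG", STOP, NORMAL),
        ("TGA", STOP, NORMAL),
        ("CAA", STOP, ABNORMAL),
        ("CAG", STOP, ABNORMAL),
        ("CGA", STOP, ABNORMAL),
        ("AAA", STOP, OTHER),
    ],
)
def test_codon_classification(codon, kind, expected):
    assert classify_codon(codon, kind) == expected


def _gene_record(cds: str):
    pad = "ACGG" * 30
    seq = pad + cds + pad
    feat = GeneFeature(
        name="toyA", category="protein", strand="+",
        exons=[CircularInterval(120, 120 + len(cds))],
    )
    return PlastomeRecord(id="toy", species="Toy", seq=seq, features=[feat])


def test_survey_trivial_codons():
    cls, _ = survey_codons(_gene_record("ATG" + "GCA" * 10 + "TAA"))
    by_kind = {c.position_kind: c.klass for c in cls}
    assert by_kind == {START: NORMAL, STOP: NORMAL}
    cls, _ = survey_codons(_gene_record("ACG" + "GCA" * 10 + "CGA"))
    by_kind = {c.position_kind: c.klass for c in cls}
    assert by_kind == {START: ABNORMAL, STOP: ABNORMAL}


def test_survey_totals_and_percentages(dr_genome):
    """Every surveyed gene gets exactly one start and one stop class and
    the percentages sum to 100."""
    rec, truth = dr_genome
    cls, summary = survey_codons(rec)
    genes = {c.gene for c in cls}
    for kind in (START, STOP):
        assert sum(1 for c in cls if c.position_kind == kind) == len(genes)
        assert sum(summary.percents[kind].values()) == pytest.approx(100.0, abs=0.01)
    # classifications match the generator's planted codons
    planted = {g.name: g for g in truth.genes if g.category == "protein"}
    for c in cls:
        want = (
            planted[c.gene].start_codon
            if c.position_kind == START
            else planted[c.gene].stop_codon
        )
        assert c.codon == want


def test_short_cds_skipped_with_warning():
    rec = _gene_record("ATGAA")
    rec.features[0].exons = [CircularInterval(120, 125)]
    with pytest.warns(UserWarning, match="shorter"):
        cls, _ = survey_codons(rec)
    assert cls == []


def test_strand_symmetry(dr_genome):
    """The survey agrees between a genome and its reverse-complemented,
    feature-mirrored copy."""
    rec, _ = dr_genome
    _, fwd = survey_codons(rec)
    _, rev = survey_codons(reverse_complement_record(rec))
    assert fwd.percents == rev.percents


class TestConfirm:
    def test_planted_sites_confirmed_decoys_not(self):
        """Planted edited sites confirm; unedited decoy sites do not."""
        cfg = SynthConfig(
            seed=11, acg_start_fraction=0.8, abnormal_stop_fraction=0.2,
            editing_efficiency=0.9, **SMALL,
        )
        rec, truth = make_plastome(cfg)
        sites = list(truth.editing_sites)
        assert len(sites) >= 10
        decoys = {(s.gene, s.kind) for s in sites[:3]}
        for s in sites[:3]:
            s.efficiency = 0.0
        reads, _ = simulate_reads(rec, sites, depth=80, seq_error=0.001, seed=4)
        counts = simple_map(reads, rec)
        cls, _ = survey_codons(rec)
        calls = confirm_editing(rec, cls, counts)
        for call in calls:
            if (call.gene, call.position_kind) in decoys:
                assert not call.confirmed, call
            else:
                assert call.confirmed, call

    def test_zero_depth_site_reason(self, dr_genome):
        rec, truth = dr_genome
        cls, _ = survey_codons(rec)
        calls = confirm_editing(rec, cls, BaseCounts(rec.length))
        assert calls, "generator should plant abnormal codons by default"
        assert all(not c.confirmed and c.reason == "no coverage" for c in calls)

    def test_all_t_site_confirmed(self):
        rec = _gene_record("ACG" + "GCA" * 10 + "TAA")
        counts = BaseCounts(rec.length)
        pos = 121  # the C of the planted ACG
        for _ in range(50):
            counts.add(pos, "T")
        cls, _ = survey_codons(rec)
        calls = confirm_editing(rec, cls, counts)
        assert len(calls) == 1
        assert calls[0].edit_ratio == 1.0 and calls[0].confirmed
        assert calls[0].genomic_pos == pos


class TestSimpleMap:
    def test_tiling_reads_uniform_depth(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rec = PlastomeRecord(id="t", species="T", seq=seq)
        read_len, depth = 100, 20
        reads = []
        for d in range(depth):
            for s in range(0, 3000, read_len):
                start = (s + d * 5) % 3000
                iv = CircularInterval(start, (start + read_len) % 3000)
                from plastiddr.intervals import slice_circular

                reads.append((f"r{d}_{s}", slice_circular(seq, iv)))
        counts = simple_map(reads, rec)
        depths = [counts.depth(p) for p in range(3000)]
        assert min(depths) == depth and max(depths) == depth

    def test_foreign_reads_not_placed(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        other = "".join(rng.choice(list("ACGT"), size=2000))
        rec = PlastomeRecord(id="t", species="T", seq=seq)
        reads = [(f"r{i}", other[i : i + 100]) for i in range(0, 1900, 100)]
        with pytest.warns(UserWarning, match="no read"):
            counts = simple_map(reads, rec)
        assert counts.total_reads_placed == 0

    def test_planted_substitutions_recovered(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        rec = PlastomeRecord(id="t", species="T", seq=seq)
        site = 1000
        sub = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[site]]
        reads = []
        for i in range(30):
            start = site - 50 + i  # all reads cover the site
            r = list(seq[start : start + 100])
            r[site - start] = sub
            reads.append((f"r{i}", "".join(r)))
        counts = simple_map(reads, rec)
        assert counts.at(site)[sub] == 30
        assert counts.at(site)[seq[site]] == 0


def test_edit_ratio_precision_improves_with_depth():
    """Mean absolute error of the edit-ratio estimate shrinks with depth."""
    cfg = SynthConfig(seed=3, acg_start_fraction=0.9, editing_efficiency=0.6, **SMALL)
    rec, truth = make_plastome(cfg)
    cls, _ = survey_codons(rec)
    mads = []
    for depth in (20, 320):
        reads, _ = simulate_reads(rec, truth.editing_sites, depth=depth, seq_error=0.0, seed=8)
        counts = simple_map(reads, rec)
        calls = confirm_editing(rec, cls, counts)
        errs = [abs(c.edit_ratio - 0.6) for c in calls if c.depth > 0]
        mads.append(float(np.mean(errs)))
    assert mads[1] < mads[0]
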