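"""Repeat detection, quadripartite partition and junction amplicons."""

from __future__ import annotations

import numpy as np
import pytest

from plastiddr import (
    PlastomeRecord,
    SynthConfig,
    find_repeat_pair,
    make_plastome,
    rotate,
)
from plastiddr import structure as st
from plastiddr.records import revcomp

from conftest import SMALL


def _random_record(seed: int, n: int = 30_000) -> PlastomeRecord:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return PlastomeRecord(id=f"R{seed}", species="random", seq=seq)


def _diverge_copy(record, truth, rate: float, seed: int) -> PlastomeRecord:
    """Substitute bases inside repeat copy B at the given rate."""
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    b0, b1 = truth.repeatB
    for p in range(b0, b1):
        if rng.random() < rate:
            seq[p % record.length] = rng.choice(
                [b for b in "ACGT" if b != seq[p % record.length]]
            )
    from dataclasses import replace

    return replace(record, seq="".join(seq))


@pytest.mark.parametrize("orientation", ["direct", "inverted"])
@pytest.mark.parametrize("seed,divergence", [(1, 0.0), (2, 0.0), (3, 0.005), (4, 0.01)])
def test_planted_repeat_recovery(orientation, seed, divergence):
    """Planted repeats are recovered with exact orientation and near-exact
    boundaries (within one seed length under divergence)."""
    cfg = SynthConfig(seed=seed, orientation=orientation, **SMALL)
    rec, truth = make_plastome(cfg)
    if divergence:
        rec = _diverge_copy(rec, truth, divergence, seed + 100)
    pair = find_repeat_pair(rec, 5000)
    assert pair is not None
    assert pair.orientation == orientation
    # boundaries within one seed length (chance matches in the flanking
    # spacers can genuinely extend the maximal repeat by a base or two)
    tol = st.DEFAULT_SEED_K
    (a0, a1), (b0, b1) = truth.repeatA, truth.repeatB
    assert abs(pair.copyA.start - a0) <= tol
    assert abs(pair.copyA.length(rec.length) - (a1 - a0)) <= 2 * tol
    assert abs(pair.copyB.start - b0) <= tol
    assert pair.identity >= 1 - st.DEFAULT_MAX_DIVERGENCE


def test_no_large_repeat_is_a_result_not_an_error():
    rec = _random_record(5)
    assert find_repeat_pair(rec, 5000) is None


def test_min_len_floor():
    rec = _random_record(6)
    with pytest.raises(ValueError, match="min_len"):
        find_repeat_pair(rec, 500)


def test_rotation_invariance_of_call(dr_genome):
    rec, truth = dr_genome
    base = find_repeat_pair(rec, 5000)
    part0 = st.partition(rec, base)
    for off in (1, 7_919, 51_000):
        r2 = rotate(rec, off)
        p2 = find_repeat_pair(r2, 5000)
        assert p2.orientation == base.orientation
        assert p2.length == base.length
        part2 = st.partition(r2, p2)
        assert part2.lengths(r2.length) == part0.lengths(rec.length)


def test_partition_tiles_and_marker_labeling(dr_genome):
    rec, truth = dr_genome
    pair = find_repeat_pair(rec, 5000)
    part = st.partition(rec, pair)
    lengths = part.lengths(rec.length)
    assert sum(lengths.values()) == rec.length
    # generator plants markers in the (shorter) LSC: labels must follow the
    # markers, not the arc lengths
    assert part.label_basis == "marker-genes"
    # maximal repeat may steal a few chance-matching flank bases from an arc
    assert abs(lengths["LSC"] - (truth.lsc[1] - truth.lsc[0])) <= st.DEFAULT_SEED_K
    assert lengths["SSC"] > lengths["LSC"]


def test_partition_length_fallback(dr_genome):
    from dataclasses import replace

    rec, truth = dr_genome
    stripped = replace(
        rec,
        features=[f for f in rec.features if f.name not in st.DEFAULT_MARKERS],
    )
    pair = find_repeat_pair(stripped, 5000)
    part = st.partition(stripped, pair)
    assert part.label_basis == "length-fallback"
    lengths = part.lengths(stripped.length)
    assert lengths["LSC"] >= lengths["SSC"]


@pytest.fixture(scope="module")
def amplicon_setup(dr_genome):
    rec, _ = dr_genome
    part = st.analyse(rec)
    primers = st.design_junction_primers(rec, part)
    return rec, part, list(primers.values())


class TestAmplicons:
    @pytest.fixture()
    def setup(self, amplicon_setup):
        return amplicon_setup

    def test_dr_genome_dr_combinations_amplify(self, setup):
        rec, part, primers = setup
        preds = st.predict_amplicons(
            rec, part, primers, st.DR_COMBINATIONS, "direct"
        )
        assert all(p.amplifies for p in preds)
        assert all(p.product_size <= st.DEFAULT_MAX_PRODUCT for p in preds)

    def test_dr_genome_ir_combinations_silent(self, setup):
        rec, part, primers = setup
        preds = st.predict_amplicons(
            rec, part, primers, st.IR_COMBINATIONS, "direct"
        )
        assert not any(p.amplifies for p in preds)

    def test_ir_hypothesis_swaps_pattern(self, setup):
        """On the in-silico IR-converted genome the junction pattern flips."""
        rec, part, primers = setup
        dr = st.predict_amplicons(rec, part, primers, [("1", "2"), ("3", "4")], "inverted")
        ir = st.predict_amplicons(rec, part, primers, st.IR_COMBINATIONS, "inverted")
        assert not any(p.amplifies for p in dr)
        assert all(p.amplifies for p in ir)
        # copy-A junctions are identical under both hypotheses
        reps = st.predict_amplicons(rec, part, primers, [("5", "2"), ("3", "6")], "inverted")
        assert all(p.amplifies for p in reps)

    def test_same_strand_primers_never_converge(self, setup):
        rec, part, primers = setup
        fwd = [p for p in primers if p.name in ("1", "5")]
        preds = st.predict_amplicons(rec, part, fwd, [("1", "5")], "direct")
        assert not preds[0].amplifies

    def test_unbindable_primer_reported(self, setup):
        rec, part, primers = setup
        alien = st.Primer("x", "TTAATTAATTAATTAATTAATTAA")
        preds = st.predict_amplicons(
            rec, part, primers + [alien], [("1", "x")], "direct"
        )
        assert preds[0].amplifies is False
        assert preds[0].reason == "no binding site"


def test_primer_tsv_round_trip(tmp_path):
    p = tmp_path / "primers.tsv"
    p.write_text("name\tseq\n1\tACGTACGTACGTACGT\n2\tGGGTTTGGGTTTGGG\n")
    primers = st.read_primers_tsv(p)
    assert [x.name for x in primers] == ["1", "2"]
    assert primers[0].seq == "ACGTACGTACGTACGT"
    bad = tmp_path / "bad.tsv"
    bad.write_text("foo\tbar\nx\ty\n")
    with pytest.raises(ValueError, match="name"):
        st.read_primers_tsv(bad)
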