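"""Shared fixtures: synthetic genomes with recorded ground truth.

Everything is generated at test time from seeded configs; no stored data.
"""

from __future__ import annotations

import pytest

from plastiddr import SynthConfig, make_plastome
from plastiddr.intervals import CircularInterval


SMALL = dict(genome_len=60_000, repeat_len=8_000, n_protein=16, n_trna=4)


@pytest.fixture(scope="session")
def dr_genome():
    """A direct-repeat plastome (60 kb, 8 kb repeat) plus its truth."""
    return make_plastome(SynthConfig(seed=7, **SMALL))


@pytest.fixture(scope="session")
def ir_genome():
    """The inverted-repeat counterpart."""
    return make_plastome(SynthConfig(seed=7, orientation="inverted", **SMALL))


def feature_coverage(record) -> list[bool]:
    """Boolean per-base mask of gene-span positions (introns included)."""
    cov = [False] * record.length
    for f in record.features:
        span = f.span(record.length)
        s, ue = span.unrolled(record.length)
        for p in range(s, ue):
            cov[p % record.length] = True
    return cov


def intergenic_position(record, lo: int, hi: int, cov=None, pad: int = 10) -> int:
    """A position in [lo, hi) at least ``pad`` bases from any feature."""
    cov = cov if cov is not None else feature_coverage(record)
    for p in range(lo, hi):
        if not any(cov[max(0, p - pad) : p + pad]):
            return p
    raise AssertionError(f"no intergenic position in [{lo}, {hi})")


def diverge_repeat_copy(record, truth, rate: float, seed: int):
    """Substitute bases inside repeat copy B at the given per-base rate."""
    import numpy as np
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    b0, b1 = truth.repeatB
    for p in range(b0, b1):
        if rng.random() < rate:
            cur = seq[p % record.length]
            seq[p % record.length] = rng.choice([b for b in "ACGT" if b != cur])
    return replace(record, seq="".join(seq))


def span_over_one_repeat_copy(record, truth) -> CircularInterval:
    """An inversion span containing exactly repeat copy B plus SC margin."""
    cov = feature_coverage(record)
    b0, b1 = truth.repeatB
    start = intergenic_position(record, b0 - 4000, b0, cov)
    end = b1 % record.length  # copy B ends at the origin in the layout
    return CircularInterval(start, end)
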