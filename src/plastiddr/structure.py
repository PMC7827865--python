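"""Quadripartite architecture of a plastome.

Canonical plastomes carry two large inverted repeats (IR_A/IR_B) separating
the long and short single-copy regions. Most Selaginella plastomes instead
carry the same pair in *direct* orientation (DR_A/DR_B). This module finds
the large repeat pair of a circular genome by unique k-mer seeding against
the sequence and its reverse complement, classifies the orientation, tiles
the circle into the four regions, and predicts junction PCR amplicons that
discriminate the two architectures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .intervals import CircularInterval, slice_circular
from .records import PlastomeRecord, revcomp

DIRECT = "direct"
INVERTED = "inverted"

DEFAULT_MIN_REPEAT = 5000
DEFAULT_MAX_DIVERGENCE = 0.02
DEFAULT_SEED_K = 21
DEFAULT_MERGE_GAP = 100
DEFAULT_MARKERS = frozenset({"psbA", "rbcL", "rpoB"})
DEFAULT_MAX_PRODUCT = 5000

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class RepeatPair:
    copyA: CircularInterval
    copyB: CircularInterval
    orientation: str
    length: int
    identity: float


@dataclass
class QuadripartitePartition:
    lsc: CircularInterval
    ssc: CircularInterval
    repeats: RepeatPair
    labels: dict = field(default_factory=dict)
    label_basis: str = "marker-genes"

    @property
    def orientation(self) -> str:
        return self.repeats.orientation

    def lengths(self, genome_length: int) -> dict[str, int]:
        return {
            "LSC": self.lsc.length(genome_length),
            "SSC": self.ssc.length(genome_length),
            "RepA": self.repeats.copyA.length(genome_length),
            "RepB": self.repeats.copyB.length(genome_length),
        }


def _circular_kmer_index(s2: str, L: int, k: int, max_hits: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(s2[i : i + k], []).append(i)
    # uniqueness filtering: drop low-complexity k-mers seen too often
    return {km: ps for km, ps in index.items() if len(ps) <= max_hits and "N" not in km}


def _merge_runs(positions: list[int], k: int, merge_gap: int) -> list[tuple[int, int]]:
    """Collapse sorted seed starts into runs [first, last] bridging small gaps."""
    runs = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev <= merge_gap + k:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    runs.append((start, prev))
    return runs


def _identity(seq: str, a: int, b: int, n: int, L: int, inverted: bool) -> float:
    """Fraction of matching bases between copy at ``a`` and copy at ``b``.

    For an inverted pair, position a+t is compared against the complement
    of position b+n-1-t.
    """
    s = seq
    match = 0
    if inverted:
        comp = s.translate(_COMP)
        for t in range(n):
            if s[(a + t) % L] == comp[(b + n - 1 - t) % L]:
                match += 1
    else:
        for t in range(n):
            if s[(a + t) % L] == s[(b + t) % L]:
                match += 1
    return match / n if n else 0.0


_LOOKAHEAD = 20
_LOOKAHEAD_MIN_MATCH = 16


def _extend_run(match_at, budget: int) -> int:
    """Steps to extend while matches dominate; mismatches are crossed only
    when at least 16 of the next 20 bases match (diverged repeat interior
    vs. the random flank, where ~25% match by chance). The returned length
    never ends on a mismatch."""
    steps = 0
    good = 0
    while steps < budget:
        if match_at(steps):
            steps += 1
            good = steps
            continue
        ahead = sum(
            1
            for t in range(1, _LOOKAHEAD + 1)
            if steps + t < budget and match_at(steps + t)
        )
        if ahead < _LOOKAHEAD_MIN_MATCH:
            break
        steps += 1
    return good


def _extend_direct(seq: str, a: int, b: int, n: int, L: int) -> tuple[int, int, int]:
    # each step moves both copies one base, eating one base from each
    # inter-copy gap
    gap1 = (b - a - n) % L  # between copyA end and copyB start
    gap2 = (a - b - n) % L  # between copyB end and copyA start
    budget = min(gap1, gap2)
    left = _extend_run(
        lambda t: seq[(a - 1 - t) % L] == seq[(b - 1 - t) % L], budget
    )
    a = (a - left) % L
    b = (b - left) % L
    n += left
    budget = min(gap1, gap2) - left
    right = _extend_run(
        lambda t: seq[(a + n + t) % L] == seq[(b + n + t) % L], budget
    )
    n += right
    return a, b, n


def _extend_inverted(seq: str, a: int, b: int, n: int, L: int) -> tuple[int, int, int]:
    comp = seq.translate(_COMP)
    gap1 = (b - a - n) % L  # between copyA end and copyB start
    gap2 = (a - b - n) % L  # between copyB end and copyA start
    # copyA's left edge pairs with copyB's right edge: both grow into gap2
    left = _extend_run(
        lambda t: seq[(a - 1 - t) % L] == comp[(b + n + t) % L], gap2 // 2
    )
    a = (a - left) % L
    n += left
    gap2 -= 2 * left
    # copyA's right edge pairs with copyB's left edge: both grow into gap1
    right = _extend_run(
        lambda t: seq[(a + n + t) % L] == comp[(b - 1 - t) % L], gap1 // 2
    )
    b = (b - right) % L
    n += right
    return a, b, n


def find_repeat_pair(
    record: PlastomeRecord,
    min_len: int = DEFAULT_MIN_REPEAT,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    k: int = DEFAULT_SEED_K,
    merge_gap: int = DEFAULT_MERGE_GAP,
    max_kmer_hits: int = 10,
) -> RepeatPair | None:
    """Locate the large repeat pair of a circular plastome.

    Seeds are shared k-mers between the genome and itself (direct
    candidates) or between the genome and its reverse complement (inverted
    candidates); co-linear seeds closer than ``merge_gap`` are merged, runs
    are extended ungapped, and the longest non-overlapping pair with
    divergence at most ``max_divergence`` wins. Returns ``None`` when no
    pair of at least ``min_len`` exists — the genome simply lacks a large
    repeat; that is a result, not an error.

    The call is invariant to rotation of the input: candidates are ranked
    by (length, then smaller start) on circular coordinates.
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000 for large-repeat detection")
    seq = record.seq
    L = record.length
    if not record.circular:
        raise ValueError(f"record {record.id} is not circular")
    s2 = seq + seq[: k - 1]
    index = _circular_kmer_index(s2, L, k, max_kmer_hits)

    candidates: list[tuple[int, int, int, str]] = []  # (a, b, n, orientation)

    # direct: same k-mer at two positions; constant circular offset d = b - a
    by_diag: dict[int, list[int]] = {}
    for ps in index.values():
        if len(ps) < 2:
            continue
        for x in range(len(ps)):
            for y in range(x + 1, len(ps)):
                d = ps[y] - ps[x]
                by_diag.setdefault(d, []).append(ps[x])
    for d, starts in by_diag.items():
        starts.sort()
        for first, last in _merge_runs(starts, k, merge_gap):
            n = last - first + k
            if n >= min_len // 2:
                candidates.append((first, (first + d) % L, n, DIRECT))

    # inverted: k-mer at p matches reverse complement of k-mer at q;
    # p + q is constant along the pair (anti-diagonal)
    rc_index: dict[str, list[int]] = {}
    for km, ps in index.items():
        rkm = revcomp(km)
        if rkm in index:
            rc_index[km] = index[rkm]
    by_anti: dict[int, list[int]] = {}
    for km, qs in rc_index.items():
        for p in index[km]:
            for q in qs:
                if p < q:
                    by_anti.setdefault(p + q, []).append(p)
    for c, starts in by_anti.items():
        starts = sorted(set(starts))
        for first, last in _merge_runs(starts, k, merge_gap):
            n = last - first + k
            if n >= min_len // 2:
                a = first
                b = (c - last) % L
                candidates.append((a, b, n, INVERTED))

    best: RepeatPair | None = None
    best_key = (-1, L + 1)
    for a, b, n, orient in candidates:
        if orient == DIRECT:
            a, b, n = _extend_direct(seq, a, b, n, L)
        else:
            a, b, n = _extend_inverted(seq, a, b, n, L)
        if n < min_len or 2 * n > L:
            continue
        ivA = CircularInterval(a % L, (a + n) % L)
        ivB = CircularInterval(b % L, (b + n) % L)
        if ivA.overlaps(ivB, L):
            continue
        ident = _identity(seq, a, b, n, L, orient == INVERTED)
        if ident < 1.0 - max_divergence:
            continue
        if ivB.start < ivA.start:
            ivA, ivB = ivB, ivA
        key = (n, ivA.start)
        if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
            best_key = (key[0], key[1])
            best = RepeatPair(
                copyA=ivA, copyB=ivB, orientation=orient, length=n, identity=ident
            )
    return best


def partition(
    record: PlastomeRecord,
    pair: RepeatPair,
    markers: frozenset[str] | set[str] = DEFAULT_MARKERS,
) -> QuadripartitePartition:
    """Tile the circle into LSC, SSC and the two repeat copies.

    The two inter-repeat arcs become the single-copy regions. The arc
    holding the marker genes (default psbA/rbcL/rpoB) is named LSC; when
    markers are absent or found in both arcs, the longer arc is named LSC
    and ``label_basis`` records the fallback.
    """
    L = record.length
    arc1 = CircularInterval(pair.copyA.end, pair.copyB.start)
    arc2 = CircularInterval(pair.copyB.end, pair.copyA.start)
    in1 = in2 = 0
    for f in record.features:
        if f.name in markers:
            pos = f.exons[0].start
            if arc1.contains(pos, L):
                in1 += 1
            elif arc2.contains(pos, L):
                in2 += 1
    if in1 > 0 and in2 == 0:
        lsc, ssc, basis = arc1, arc2, "marker-genes"
    elif in2 > 0 and in1 == 0:
        lsc, ssc, basis = arc2, arc1, "marker-genes"
    else:
        if in1 and in2:
            warnings.warn(
                "marker genes found in both single-copy arcs; "
                "falling back to length for LSC/SSC naming"
            )
        n1, n2 = arc1.length(L), arc2.length(L)
        if n1 > n2 or (n1 == n2 and arc1.start < arc2.start):
            lsc, ssc = arc1, arc2
        else:
            lsc, ssc = arc2, arc1
        basis = "length-fallback"
    part = QuadripartitePartition(lsc=lsc, ssc=ssc, repeats=pair, label_basis=basis)
    part.labels = {
        "LSC": lsc,
        "SSC": ssc,
        "RepA": pair.copyA,
        "RepB": pair.copyB,
    }
    total = sum(iv.length(L) for iv in part.labels.values())
    if total != L:
        raise AssertionError(
            f"partition does not tile the circle: {total} != {L}"
        )
    return part


def analyse(record: PlastomeRecord, **kwargs) -> QuadripartitePartition | None:
    """find_repeat_pair + partition in one call; None when no large repeat."""
    pair = find_repeat_pair(record, **kwargs)
    if pair is None:
        return None
    return partition(record, pair)


def canonical_rotation_offset(part: QuadripartitePartition) -> int:
    """Rotation placing the LSC start at coordinate zero."""
    return part.lsc.start


# ---------------------------------------------------------------- primers

@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    strand: str = "+"
    site: CircularInterval | None = None


@dataclass(frozen=True)
class AmpliconPrediction:
    pair: tuple[str, str]
    amplifies: bool
    product_size: int | None = None
    reason: str = ""


def _hypothesis_sequence(
    record: PlastomeRecord, part: QuadripartitePartition, hypothesis: str
) -> str:
    """Genome sequence under the requested architecture.

    If the observed orientation differs from the hypothesis, repeat copy B
    is reverse-complemented in place, which interconverts DR and IR forms.
    """
    if hypothesis not in (DIRECT, INVERTED):
        raise ValueError(f"unknown structure hypothesis {hypothesis!r}")
    seq = record.seq
    if part.orientation == hypothesis:
        return seq
    L = record.length
    b = part.repeats.copyB
    rot = seq[b.start :] + seq[: b.start]  # copyB now at the front, unwrapped
    n = b.length(L)
    flipped = revcomp(rot[:n]) + rot[n:]
    # rotate back
    return flipped[-b.start :] + flipped[: -b.start] if b.start else flipped


def _binding_sites(genome: str, primer_seq: str) -> tuple[list[int], list[int]]:
    """Circular start positions of forward and reverse-strand matches."""
    L = len(genome)
    doubled = genome + genome[: len(primer_seq) - 1]
    fwd, rev = [], []
    rc = revcomp(primer_seq)
    start = 0
    while True:
        i = doubled.find(primer_seq, start)
        if i < 0 or i >= L:
            break
        fwd.append(i)
        start = i + 1
    start = 0
    while True:
        i = doubled.find(rc, start)
        if i < 0 or i >= L:
            break
        rev.append(i)
        start = i + 1
    return fwd, rev


def predict_amplicons(
    record: PlastomeRecord,
    part: QuadripartitePartition,
    primers: list[Primer],
    pairs: list[tuple[str, str]],
    structure_hypothesis: str,
    max_product: int = DEFAULT_MAX_PRODUCT,
) -> list[AmpliconPrediction]:
    """Predict junction PCR products under a DR or IR hypothesis.

    A pair amplifies iff, on the genome rearranged under the hypothesis,
    one primer binds the plus strand upstream of the other binding the
    minus strand (3' ends converging) within ``max_product`` bases. The
    product size includes both primers.
    """
    genome = _hypothesis_sequence(record, part, structure_hypothesis)
    L = len(genome)
    by_name = {p.name: p for p in primers}
    sites = {p.name: _binding_sites(genome, p.seq) for p in primers}
    out = []
    for nameA, nameB in pairs:
        pa, pb = by_name[nameA], by_name[nameB]
        fa, ra = sites[nameA]
        fb, rb = sites[nameB]
        if not (fa or ra) or not (fb or rb):
            out.append(
                AmpliconPrediction((nameA, nameB), False, None, "no binding site")
            )
            continue
        best = None
        for fwd_sites, rev_sites, fwd_len, rev_len in (
            (fa, rb, len(pa.seq), len(pb.seq)),
            (fb, ra, len(pb.seq), len(pa.seq)),
        ):
            for f in fwd_sites:
                for r in rev_sites:
                    size = (r + rev_len - f) % L
                    if size >= fwd_len + rev_len and size <= max_product:
                        if best is None or size < best:
                            best = size
        if best is None:
            out.append(
                AmpliconPrediction(
                    (nameA, nameB), False, None, "primers do not converge"
                )
            )
        else:
            out.append(AmpliconPrediction((nameA, nameB), True, best))
    return out


def design_junction_primers(
    record: PlastomeRecord,
    part: QuadripartitePartition,
    primer_len: int = 24,
    margin: int = 150,
) -> dict[str, Primer]:
    """Six junction primers discriminating DR from IR architectures.

    Primers 1 and 5 sit in the single-copy regions just upstream of a
    repeat copy (plus strand); primers 4 and 6 just downstream (minus
    strand); primer 2 binds inside the repeat near its start (minus
    strand) and primer 3 inside the repeat near its end (plus strand), so
    2 and 3 each bind both copies. On a DR genome the combinations
    1/2, 3/4, 5/2 and 3/6 converge across the four junctions while the
    IR-specific combinations 1/3 and 2/4 do not; inverting one repeat
    copy swaps the two sets.
    """
    if part.orientation != DIRECT:
        raise ValueError("junction primer design expects a DR-form genome")
    L = record.length
    seq = record.seq

    def fwd(start: int) -> str:
        return slice_circular(seq, CircularInterval(start % L, (start + primer_len) % L))

    def rev(start: int) -> str:
        return revcomp(fwd(start))

    a = part.repeats.copyA
    b = part.repeats.copyB
    rlen = part.repeats.length
    primers = {
        # inside-repeat primers (bind both copies)
        "2": Primer("2", rev(a.start + margin), "-"),
        "3": Primer("3", fwd(a.start + rlen - margin - primer_len), "+"),
        # single-copy flanks of copy B
        "1": Primer("1", fwd(b.start - margin - primer_len), "+"),
        "4": Primer("4", rev(b.start + rlen + margin), "-"),
        # single-copy flanks of copy A
        "5": Primer("5", fwd(a.start - margin - primer_len), "+"),
        "6": Primer("6", rev(a.start + rlen + margin), "-"),
    }
    return primers


DR_COMBINATIONS = [("1", "2"), ("3", "4"), ("5", "2"), ("3", "6")]
IR_COMBINATIONS = [("1", "3"), ("2", "4")]


def read_primers_tsv(path) -> list[Primer]:
    """Primers from a TSV with columns name, seq (extra columns ignored)."""
    primers = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.lower(): i for i, c in enumerate(header)}
        if "name" not in cols or "seq" not in cols:
            raise ValueError(f"{path}: primer TSV needs 'name' and 'seq' columns")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            primers.append(
                Primer(fields[cols["name"]], fields[cols["seq"]].upper())
            )
    return primers
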