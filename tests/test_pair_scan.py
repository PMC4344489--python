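"""Scanner: aligner statistics, filter cascade, classification, coverage."""

import itertools

import numpy as np
import pytest
from Bio import Align

from linenahr.io_formats import GenomeAssembly, RepeatElement
from linenahr.pair_scan import (
    Hsp,
    ScanParams,
    classify_pair,
    extract_elements,
    filter_hsps,
    find_hsps,
    karlin_altschul,
    susceptibility_coverage,
)
from linenahr.synthetic import mutate, random_sequence, revcomp


# ---------------------------------------------------------------------------
# Karlin-Altschul
# ---------------------------------------------------------------------------

def test_karlin_altschul_matches_published_blastn_values():
    lam, k = karlin_altschul(1, -2)
    assert lam == pytest.approx(1.33, abs=0.01)
    assert k == pytest.approx(0.62, abs=0.01)
    lam3, k3 = karlin_altschul(1, -3)
    assert lam3 == pytest.approx(1.37, abs=0.01)
    assert k3 == pytest.approx(0.71, abs=0.01)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extract_filters_and_truncates(toy_genome, element_factory):
    short = element_factory(eid="short", start=100, end=1000)  # 900 bp
    near_start = element_factory(eid="near", start=1000, end=2500)
    interior = element_factory(eid="mid", start=50_000, end=57_000)
    out = extract_elements(toy_genome, [short, near_start, interior])
    assert [f.element.id for f in out] == ["near", "mid"]
    near = out[0]
    assert near.left_flank == 1000 and near.left_truncated
    assert not out[1].left_truncated and out[1].left_flank == 3000


def test_extract_rejects_out_of_bounds(toy_genome, element_factory):
    bad = element_factory(start=99_000, end=101_000)
    with pytest.raises(ValueError, match="outside chromosome"):
        extract_elements(toy_genome, [bad])


# ---------------------------------------------------------------------------
# internal aligner
# ---------------------------------------------------------------------------

def _nw_identity(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    top, bot = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(top, bot))
    return 100.0 * matches / len(top)


def test_identical_sequences_single_perfect_hsp():
    rng = np.random.default_rng(0)
    s = random_sequence(rng, 5000)
    (hsp, *rest) = find_hsps(s, s)
    assert hsp.identity == 100.0
    assert hsp.length == 5000
    assert hsp.orientation == "direct"


def test_reverse_complement_detected_as_inverted():
    rng = np.random.default_rng(1)
    s = random_sequence(rng, 3000)
    hsps = find_hsps(s, revcomp(s))
    best = hsps[0]
    assert best.orientation == "inverted"
    assert best.length == 3000
    assert best.b_start == 0 and best.b_end == 3000  # mapped back to input coords


def test_hsp_identity_matches_needleman_wunsch_oracle():
    rng = np.random.default_rng(2)
    anc = random_sequence(rng, 6000)
    a = mutate(rng, anc, 0.015, 0.0004)
    b = mutate(rng, anc, 0.015, 0.0004)
    hsp = find_hsps(a, b)[0]
    oracle = _nw_identity(a, b)
    assert abs(hsp.identity - oracle) <= 1.0
    assert abs(hsp.length - 6000) <= 0.05 * 6000


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        find_hsps("", "ACGT")


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def _flanked(el, seq_len=13_000, core_offset=3000):
    from linenahr.pair_scan import FlankedElement

    return FlankedElement(
        element=el, seq="A" * seq_len, seq_start=el.start - core_offset,
        left_flank=core_offset, right_flank=seq_len - core_offset - el.length,
    )


def _hsp(a0=3000, a1=9000, b0=3000, b1=9000, orientation="direct",
         length=6000, matches=5800, evalue=1e-200):
    return Hsp(a_start=a0, a_end=a1, b_start=b0, b_end=b1, orientation=orientation,
               length=length, matches=matches, score=float(matches), evalue=evalue)


def test_filter_rules_fire_in_order(element_factory):
    a = element_factory(eid="a", start=10_000, end=16_000)
    b = element_factory(eid="b", start=60_000, end=66_000)
    far = element_factory(eid="far", start=12_000_000, end=12_006_000)
    params = ScanParams()
    fa, fb, ffar = _flanked(a), _flanked(b), _flanked(far)

    cases = [
        ((fa, fa, _hsp()), "self"),
        ((fa, fb, _hsp(a0=2950)), "flank_extension"),  # exits core by 50 bp
        ((fa, fb, _hsp(evalue=1e-40)), "evalue"),
        ((fa, fb, _hsp(a1=3800, b1=3800, length=800, matches=790)), "length"),
        ((fa, fb, _hsp(matches=5460)), "identity"),  # 91.0%
        ((fa, ffar, _hsp()), "span"),  # 11.99 Mbp apart
    ]
    kept, rejected = filter_hsps([c for c, _ in cases], params)
    assert kept == []
    assert [r[3] for r in rejected] == [want for _, want in cases]

    ok = (fa, fb, _hsp())
    kept, rejected = filter_hsps([ok], params)
    assert len(kept) == 1 and rejected == []
    pair = kept[0]
    assert pair.identity == pytest.approx(100 * 5800 / 6000)
    assert pair.span == 50_000
    assert pair.a_start == 10_000 and pair.a_end == 16_000  # genomic mapping


def test_filter_partitions_input(element_factory):
    a = element_factory(eid="a", start=10_000, end=16_000)
    b = element_factory(eid="b", start=60_000, end=66_000)
    fa, fb = _flanked(a), _flanked(b)
    cands = [(fa, fb, _hsp()), (fa, fb, _hsp(matches=5000)), (fa, fa, _hsp())]
    kept, rejected = filter_hsps(cands)
    assert len(kept) + len(rejected) == len(cands)


def test_span_cap_not_applied_to_inverted_pairs(element_factory):
    a = element_factory(eid="a", start=10_000, end=16_000)
    far = element_factory(eid="far", start=12_000_000, end=12_006_000)
    kept, rejected = filter_hsps([(_flanked(a), _flanked(far), _hsp(orientation="inverted"))])
    assert len(kept) == 1 and kept[0].span is None


# ---------------------------------------------------------------------------
# classification truth table
# ---------------------------------------------------------------------------

def test_classification_truth_table(element_factory):
    """Exhaustive: same/diff chromosome x direct/inverted x same/opposite arm."""
    cen = {"chr1": [(45_000, 55_000)], "chr2": [(45_000, 55_000)]}
    p_arm = element_factory(eid="p1", chrom="chr1", start=10_000, end=16_000)
    p_arm2 = element_factory(eid="p2", chrom="chr1", start=20_000, end=26_000)
    q_arm = element_factory(eid="q1", chrom="chr1", start=80_000, end=86_000)
    other = element_factory(eid="o1", chrom="chr2", start=10_000, end=16_000)

    truth = [
        # (element pair, orientation) -> class
        ((p_arm, other), "direct", "translocation"),
        ((p_arm, other), "inverted", "translocation"),
        ((q_arm, other), "direct", "translocation"),
        ((q_arm, other), "inverted", "translocation"),
        ((p_arm, p_arm2), "direct", "deletion_duplication"),
        ((p_arm, p_arm2), "inverted", "inversion"),
        ((p_arm, q_arm), "direct", "excluded(pericentric)"),
        ((p_arm, q_arm), "inverted", "inversion"),  # spans centromere: still inversion
    ]
    for (ea, eb), orientation, want in truth:
        assert classify_pair(ea, eb, orientation, cen) == want, (ea.id, eb.id, orientation)


def test_missing_centromere_treated_as_same_arm(element_factory):
    a = element_factory(eid="a", start=1000, end=7000)
    b = element_factory(eid="b", start=90_000, end=96_000)
    assert classify_pair(a, b, "direct", {}) == "deletion_duplication"


# ---------------------------------------------------------------------------
# susceptibility coverage
# ---------------------------------------------------------------------------

def _dd_pair(a, b, pid="p"):
    from linenahr.pair_scan import PairAlignment

    return PairAlignment(
        id=pid, element_a=a.id, element_b=b.id, chrom_a=a.chromosome,
        chrom_b=b.chromosome, a_start=a.start, a_end=a.end, b_start=b.start,
        b_end=b.end, orientation="direct", length=6000, identity=97.0,
        evalue=0.0, score=5800.0, nahr_class="deletion_duplication",
    )


def test_coverage_empty_and_single_pair(toy_genome, element_factory):
    frac, _ = susceptibility_coverage([], toy_genome)
    assert frac == 0.0
    a = element_factory(eid="a", start=1000, end=7000)
    b = element_factory(eid="b", start=55_000, end=61_000)
    frac, depth = susceptibility_coverage(
        [_dd_pair(a, b)], toy_genome, {"a": a, "b": b}
    )
    assert frac == pytest.approx(0.6)  # [1000, 61000) on 100 kb
    assert depth["chr1"] == [(1000, 61_000, 1)]


def test_coverage_union_matches_sweep_oracle(toy_genome, element_factory):
    rng = np.random.default_rng(8)
    els, pairs = {}, []
    for i in range(12):
        s1 = int(rng.integers(0, 60_000))
        s2 = int(rng.integers(s1 + 3000, 95_000 - 3000))
        a = element_factory(eid=f"a{i}", start=s1, end=s1 + 2000)
        b = element_factory(eid=f"b{i}", start=s2, end=s2 + 2000)
        els[a.id], els[b.id] = a, b
        pairs.append(_dd_pair(a, b, pid=f"p{i}"))
    frac, _ = susceptibility_coverage(pairs, toy_genome, els)
    # independent sweep-line union oracle
    marks = np.zeros(100_000, dtype=bool)
    for p in pairs:
        marks[els[p.element_a].start:els[p.element_b].end] = True
    assert frac == pytest.approx(marks.sum() / 100_000)


def test_coverage_monotone_in_pair_set(toy_genome, element_factory):
    a = element_factory(eid="a", start=1000, end=3000)
    b = element_factory(eid="b", start=20_000, end=22_000)
    c = element_factory(eid="c", start=50_000, end=52_000)
    d = element_factory(eid="d", start=70_000, end=72_000)
    els = {e.id: e for e in (a, b, c, d)}
    f1, _ = susceptibility_coverage([_dd_pair(a, b)], toy_genome, els)
    f2, _ = susceptibility_coverage([_dd_pair(a, b), _dd_pair(c, d, "p2")], toy_genome, els)
    assert f2 >= f1
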