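"""CNV calling from probe runs, DP-LCR filtering, dedupe, pair matching."""

import numpy as np
import pytest

from linenahr.cnv_match import (
    CnvCall,
    call_cnvs,
    dedupe_cnvs,
    dp_lcr_filter,
    match_pairs_to_cnvs,
)
from linenahr.io_formats import ProbeTrack, SegDupPair
from linenahr.pair_scan import PairAlignment


def _track(values, spacing=1000, chrom="chr1", sample="S1"):
    n = len(values)
    return ProbeTrack(sample, [chrom] * n, [spacing * (i + 1) for i in range(n)], values)


def _call(chrom="chr1", inner=(10_000, 20_000), prox=9000, dist=21_000,
          kind="loss", cid="c0", sample="S1", median=-1.0):
    return CnvCall(
        id=cid, sample=sample, chromosome=chrom,
        inner_start=inner[0], inner_end=inner[1],
        prox_start=prox, prox_end=inner[0],
        dist_start=inner[1] - 1, dist_end=dist,
        kind=kind, median_log2=median, n_probes=5,
    )


def _pair(a=(9500, 15_000), b=(18_000, 23_000), chrom="chr1", pid="p0",
          length=5000, identity=97.5, el_len=6000, nahr="deletion_duplication"):
    return PairAlignment(
        id=pid, element_a="ea", element_b="eb", chrom_a=chrom, chrom_b=chrom,
        a_start=a[0], a_end=a[1], b_start=b[0], b_end=b[1], orientation="direct",
        length=length, identity=identity, evalue=0.0, score=1.0,
        nahr_class=nahr, element_length_a=el_len, element_length_b=el_len,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def test_noise_free_deletion_region_construction():
    vals = [0.0] * 10 + [-1.0] * 10 + [0.0] * 10
    (c,) = call_cnvs(_track(vals))
    # probes 11..20 (1-indexed positions 11000..20000) are aberrant
    assert c.kind == "loss"
    assert (c.inner_start, c.inner_end) == (11_000, 20_001)
    assert c.proximal_region == (10_000, 11_000)
    assert c.distal_region == (20_000, 21_000)
    assert not c.truncated
    assert c.median_log2 == pytest.approx(-1.0)


def test_all_normal_track_has_no_calls():
    assert call_cnvs(_track([0.05, -0.1, 0.2] * 10)) == []


def test_duplication_median_passes_stringent_gain_threshold():
    vals = [0.0] * 5 + [float(np.log2(1.5))] * 8 + [0.0] * 5
    (c,) = call_cnvs(_track(vals))
    assert c.kind == "gain"
    assert c.median_log2 > 0.5  # log2(3/2) ~ 0.585


def test_min_probes_and_truncation():
    vals = [-1.0] * 4 + [0.0] * 10
    (c,) = call_cnvs(_track(vals), min_probes=3)
    assert c.truncated  # run starts at the first probe
    assert call_cnvs(_track([-1.0, -1.0] + [0.0] * 5), min_probes=3) == []
    with pytest.raises(ValueError, match="min_probes"):
        call_cnvs(_track([0.0] * 5), min_probes=1)


def test_unsorted_track_rejected():
    with pytest.raises(ValueError, match="increasing"):
        _track([0, 0], spacing=-5)


# ---------------------------------------------------------------------------
# DP-LCR filter
# ---------------------------------------------------------------------------

def test_dp_lcr_filter_orientation_and_both_ends():
    cnv = _call()
    straddling_direct = SegDupPair("chr1", 8500, 9800, "chr1", 20_500, 22_000, "direct")
    straddling_inverted = SegDupPair("chr1", 8500, 9800, "chr1", 20_500, 22_000, "inverted")
    one_end_only = SegDupPair("chr1", 8500, 9800, "chr1", 40_000, 42_000, "direct")

    kept, removed = dp_lcr_filter([cnv], [straddling_direct])
    assert removed == [cnv] and kept == []
    kept, removed = dp_lcr_filter([cnv], [straddling_inverted])
    assert kept == [cnv] and removed == []
    kept, removed = dp_lcr_filter([cnv], [one_end_only])
    assert kept == [cnv]


def test_dp_lcr_filter_partitions():
    cnvs = [_call(cid=f"c{i}", inner=(10_000 + i, 20_000 + i)) for i in range(5)]
    sd = SegDupPair("chr1", 8500, 9800, "chr1", 20_500, 22_000, "direct")
    kept, removed = dp_lcr_filter(cnvs, [sd])
    assert len(kept) + len(removed) == 5


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------

def test_identical_calls_collapse_to_first_sample():
    cnvs = [_call(cid=f"c{i}", sample=f"S{i}") for i in range(3)]
    out = dedupe_cnvs(cnvs)
    assert len(out) == 1 and out[0].sample == "S0"


def test_partial_overlap_below_threshold_kept():
    a = _call(cid="a", inner=(10_000, 20_000))
    b = _call(cid="b", inner=(15_000, 25_000), prox=14_000, dist=26_000)
    assert len(dedupe_cnvs([a, b], reciprocal_overlap=0.9)) == 2


def test_single_linkage_chain_matches_bruteforce_oracle():
    # A~B and B~C overlap >= 0.6 but A~C do not: one cluster via the chain
    a = _call(cid="a", inner=(10_000, 20_000))
    b = _call(cid="b", inner=(13_000, 23_000))
    c = _call(cid="c", inner=(16_000, 26_000))
    thr = 0.6
    out = dedupe_cnvs([a, b, c], reciprocal_overlap=thr)

    # brute-force transitive-closure oracle over the overlap graph
    import itertools

    def ro(x, y):
        ov = min(x.inner_end, y.inner_end) - max(x.inner_start, y.inner_start)
        return max(ov, 0) / max(
            x.inner_end - x.inner_start, y.inner_end - y.inner_start
        )

    nodes = [a, b, c]
    adj = {n.id: {n.id} for n in nodes}
    for x, y in itertools.combinations(nodes, 2):
        if ro(x, y) >= thr:
            adj[x.id].add(y.id)
            adj[y.id].add(x.id)
    # transitive closure
    changed = True
    while changed:
        changed = False
        for n in adj:
            new = set().union(*(adj[m] for m in adj[n]))
            if new != adj[n]:
                adj[n] = new
                changed = True
    n_clusters = len({frozenset(v) for v in adj.values()})
    assert len(out) == n_clusters == 1
    assert out[0].id == "a"


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_generating_pair_matches_planted_deletion():
    cnv = _call()
    good = _pair(pid="good")
    outside = _pair(a=(40_000, 46_000), b=(60_000, 66_000), pid="outside")
    matches = match_pairs_to_cnvs([cnv], [good, outside])
    assert [m.pair_id for m in matches] == ["good"]
    assert matches[0].proximal_element == "ea"


def test_stringent_mode_requires_full_length_high_identity():
    cnv = _call(median=-1.0)
    weak = _pair(identity=95.0, pid="weak")
    short = _pair(length=3000, pid="short")
    small_el = _pair(el_len=3500, pid="small")
    good = _pair(pid="good")
    matches = match_pairs_to_cnvs([cnv], [weak, short, small_el, good], stringent=True)
    assert [m.pair_id for m in matches] == ["good"]
    # low-amplitude CNV fails the stringent log2 requirement
    faint = _call(median=-0.4, cid="faint")
    assert match_pairs_to_cnvs([faint], [good], stringent=True) == []


def test_non_dd_pairs_never_match():
    cnv = _call()
    inv = _pair(pid="inv", nahr="inversion")
    assert match_pairs_to_cnvs([cnv], [inv]) == []


def test_matching_symmetric_under_element_relabeling():
    cnv = _call()
    fwd = _pair(pid="fwd")
    swapped = PairAlignment(
        id="swapped", element_a="eb", element_b="ea", chrom_a="chr1", chrom_b="chr1",
        a_start=18_000, a_end=23_000, b_start=9500, b_end=15_000,
        orientation="direct", length=5000, identity=97.5, evalue=0.0, score=1.0,
        nahr_class="deletion_duplication", element_length_a=6000, element_length_b=6000,
    )
    m1 = match_pairs_to_cnvs([cnv], [fwd])
    m2 = match_pairs_to_cnvs([cnv], [swapped])
    assert len(m1) == len(m2) == 1
    assert m1[0].proximal_element == m2[0].proximal_element == "ea"


# ---------------------------------------------------------------------------
# recall under noise
# ---------------------------------------------------------------------------

def test_recall_on_noisy_tracks():
    """sd=0 recovers planted probe spans exactly; sd=0.15 recall >= 0.95."""
    rng = np.random.default_rng(12)
    spacing = 1000
    n_probes = 6000
    events = []  # (start_idx, n, kind)
    idx = 20
    while len(events) < 200 and idx < n_probes - 20:
        n = int(rng.integers(5, 12))
        kind = "loss" if rng.random() < 0.5 else "gain"
        events.append((idx, n, kind))
        idx += n + int(rng.integers(8, 15))
    assert len(events) == 200

    mean = np.zeros(n_probes)
    for start, n, kind in events:
        mean[start:start + n] = -1.0 if kind == "loss" else np.log2(1.5)

    # noise-free: inner intervals equal planted probe spans exactly
    t0 = _track(list(mean), spacing=spacing)
    calls0 = call_cnvs(t0)
    assert len(calls0) == 200
    for (start, n, kind), c in zip(events, calls0):
        assert c.kind == ("loss" if kind == "loss" else "gain")
        assert c.inner_start == spacing * (start + 1)
        assert c.inner_end == spacing * (start + n) + 1

    # sd = 0.15: an event is recovered when a same-type call overlaps it
    noisy = mean + rng.normal(0, 0.15, size=n_probes)
    calls = call_cnvs(_track(list(noisy), spacing=spacing))
    recovered = 0
    for start, n, kind in events:
        lo, hi = spacing * (start + 1), spacing * (start + n) + 1
        want = "loss" if kind == "loss" else "gain"
        if any(
            c.kind == want and max(c.inner_start, lo) < min(c.inner_end, hi)
            for c in calls
        ):
            recovered += 1
    assert recovered / 200 >= 0.95
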