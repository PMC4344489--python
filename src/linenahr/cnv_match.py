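"""CNV calls, breakpoint-uncertainty regions, and matching to LINE pairs.

aCGH probes only bracket a CNV breakpoint: the true breakpoint lies
somewhere between the last normal-ratio probe and the first aberrant one.
These inter-probe intervals are the *breakpoint uncertainty regions*; a
LINE pair is a plausible NAHR mediator of a CNV when its proximal element
intersects the proximal uncertainty region and its distal element the
distal one.  Probe positions are treated as points (probe length ignored).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .io_formats import ProbeTrack, SegDupPair
from .pair_scan import PairAlignment

#: stringent log2-ratio thresholds for high-confidence calls
STRINGENT_LOSS_LOG2 = -0.6
STRINGENT_GAIN_LOG2 = 0.5


@dataclass
class CnvCall:
    """A probe-derived CNV with its two breakpoint-uncertainty regions."""

    id: str
    sample: str
    chromosome: str
    inner_start: int  # first aberrant probe
    inner_end: int  # last aberrant probe (half-open: +1)
    prox_start: int  # last normal probe before the run
    prox_end: int  # == inner_start
    dist_start: int  # == inner_end - 1 (last aberrant probe position)
    dist_end: int  # first normal probe after the run
    kind: str  # loss | gain
    median_log2: float
    n_probes: int
    truncated: bool = False  # run touched a chromosome end of the track

    @property
    def proximal_region(self) -> tuple[int, int]:
        return self.prox_start, self.prox_end

    @property
    def distal_region(self) -> tuple[int, int]:
        return self.dist_start, self.dist_end


@dataclass
class CnvPairMatch:
    cnv_id: str
    pair_id: str
    proximal_element: str
    distal_element: str
    homology_length: int
    identity: float


def _median(xs: list[float]) -> float:
    ys = sorted(xs)
    n = len(ys)
    return ys[n // 2] if n % 2 else 0.5 * (ys[n // 2 - 1] + ys[n // 2])


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_cnvs(
    track: ProbeTrack,
    loss_thr: float = -0.3,
    gain_thr: float = 0.3,
    min_probes: int = 3,
) -> list[CnvCall]:
    """Threshold-run CNV calling on a sorted probe track.

    Maximal runs of at least ``min_probes`` consecutive probes beyond the
    loss (or gain) threshold become calls; the uncertainty regions run from
    the flanking normal probes to the first/last aberrant probe.  Runs at
    track ends get truncated regions (flagged).
    """
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    calls: list[CnvCall] = []
    idx = 0
    for chrom, grp in groupby(
        range(len(track.positions)), key=lambda i: track.chroms[i]
    ):
        ids = list(grp)
        pos = [track.positions[i] for i in ids]
        vals = [track.log2[i] for i in ids]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"probe track not sorted on {chrom!r}")
        state = ["loss" if v < loss_thr else "gain" if v > gain_thr else "normal" for v in vals]
        i = 0
        while i < len(ids):
            if state[i] == "normal":
                i += 1
                continue
            j = i
            while j < len(ids) and state[j] == state[i]:
                j += 1
            if j - i >= min_probes:
                run_vals = vals[i:j]
                truncated = i == 0 or j == len(ids)
                prox = pos[i - 1] if i > 0 else 0
                dist = pos[j] if j < len(ids) else pos[-1]
                calls.append(
                    CnvCall(
                        id=f"cnv_{idx}",
                        sample=track.sample,
                        chromosome=chrom,
                        inner_start=pos[i],
                        inner_end=pos[j - 1] + 1,
                        prox_start=prox,
                        prox_end=pos[i],
                        dist_start=pos[j - 1],
                        dist_end=dist,
                        kind=state[i],
                        median_log2=_median(run_vals),
                        n_probes=j - i,
                        truncated=truncated,
                    )
                )
                idx += 1
            i = j
    return calls


# ---------------------------------------------------------------------------
# DP-LCR filter
# ---------------------------------------------------------------------------

def _intersects(iv: tuple[int, int], chrom: str, s: int, e: int, c: str) -> bool:
    return chrom == c and max(iv[0], s) < min(iv[1], e)


def dp_lcr_filter(
    cnvs: list[CnvCall], segdups: list[SegDupPair]
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Drop CNVs explainable by directly oriented paralogous LCRs.

    A CNV is removed iff some direct-orientation segdup pair has one copy
    intersecting the proximal uncertainty region and its mate intersecting
    the distal one (either assignment).  Inverted pairs never trigger
    removal: NAHR between inverted LCRs would not produce the CNV.
    """
    kept, removed = [], []
    for cnv in cnvs:
        prox, dist = cnv.proximal_region, cnv.distal_region
        hit = False
        for sd in segdups:
            if sd.orientation != "direct":
                continue
            a_prox = _intersects(prox, cnv.chromosome, sd.start_a, sd.end_a, sd.chrom_a)
            b_dist = _intersects(dist, cnv.chromosome, sd.start_b, sd.end_b, sd.chrom_b)
            b_prox = _intersects(prox, cnv.chromosome, sd.start_b, sd.end_b, sd.chrom_b)
            a_dist = _intersects(dist, cnv.chromosome, sd.start_a, sd.end_a, sd.chrom_a)
            if (a_prox and b_dist) or (b_prox and a_dist):
                hit = True
                break
        (removed if hit else kept).append(cnv)
    return kept, removed


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    if a.chromosome != b.chromosome:
        return 0.0
    ov = min(a.inner_end, b.inner_end) - max(a.inner_start, b.inner_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.inner_end - a.inner_start), ov / (b.inner_end - b.inner_start))


def dedupe_cnvs(cnvs: list[CnvCall], reciprocal_overlap: float = 0.9) -> list[CnvCall]:
    """Collapse same-type CNVs recurring across samples to one representative.

    Same-type calls whose inner intervals reciprocally overlap at or above
    the threshold are clustered by single linkage; the representative is
    the cluster member earliest in input order.  Output order follows the
    input.
    """
    if not 0.0 < reciprocal_overlap <= 1.0:
        raise ValueError("reciprocal_overlap must be in (0, 1]")
    n = len(cnvs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if cnvs[i].kind != cnvs[j].kind:
                continue
            if _reciprocal_overlap(cnvs[i], cnvs[j]) >= reciprocal_overlap:
                parent[find(i)] = find(j)
    seen: set[int] = set()
    out: list[CnvCall] = []
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen.add(root)
            cluster = [k for k in range(n) if find(k) == root]
            out.append(cnvs[min(cluster)])
    return out


# ---------------------------------------------------------------------------
# matching LINE pairs to CNVs
# ---------------------------------------------------------------------------

def match_pairs_to_cnvs(
    cnvs: list[CnvCall],
    pairs: list[PairAlignment],
    stringent: bool = False,
    min_homology: int = 0,
    min_identity: float = 0.0,
) -> list[CnvPairMatch]:
    """Match deletion/duplication pairs to CNV uncertainty regions.

    The left (proximal) element must intersect the proximal region and the
    right (distal) element the distal region; intersection rather than
    containment, because a crossover inside the LINE only implies overlap
    with the inter-probe gap.  Stringent mode additionally demands
    full-length homology (aligned length > 4 kb on elements > 4 kb),
    identity > 96 percent, and a CNV median log2 beyond (-0.6, 0.5).
    """
    out: list[CnvPairMatch] = []
    for pair in pairs:
        if pair.nahr_class != "deletion_duplication":
            continue
        if pair.length < min_homology or pair.identity < min_identity:
            continue
        # order the aligned element intervals by coordinate
        (pa, pb) = sorted(
            [
                (pair.a_start, pair.a_end, pair.element_a),
                (pair.b_start, pair.b_end, pair.element_b),
            ]
        )
        if stringent:
            if not (
                pair.length > 4000
                and pair.identity > 96.0
                and pair.element_length_a > 4000
                and pair.element_length_b > 4000
            ):
                continue
        for cnv in cnvs:
            if cnv.chromosome != pair.chrom_a:
                continue
            if stringent and STRINGENT_LOSS_LOG2 < cnv.median_log2 < STRINGENT_GAIN_LOG2:
                continue
            prox, dist = cnv.proximal_region, cnv.distal_region
            if (
                max(prox[0], pa[0]) < min(prox[1], pa[1])
                and max(dist[0], pb[0]) < min(dist[1], pb[1])
            ):
                out.append(
                    CnvPairMatch(
                        cnv_id=cnv.id,
                        pair_id=pair.id,
                        proximal_element=pa[2],
                        distal_element=pb[2],
                        homology_length=pair.length,
                        identity=pair.identity,
                    )
                )
    return out
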