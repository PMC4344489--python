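"""Scan for LINE pairs capable of mediating NAHR.

The scan mirrors the genome-wide procedure: extract every LINE longer than
a minimum length together with flanking sequence, align all pairs, apply a
fixed filter cascade (self-alignment, flank extension, E-value, alignment
length, identity, intrachromosomal span), classify survivors by chromosome,
orientation and centromere side, and summarize the genome fraction
susceptible to deletion/duplication events.

The internal aligner finds exact shared words (default 11-mers) on both
strands and, where seeds exist, runs a local gapped extension; E-values use
ungapped Karlin-Altschul statistics computed numerically for the scoring
scheme, with effective search space len(A) * len(B).  Externally computed
BLAST tabular HSPs can be imported instead for genome-scale runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .io_formats import GenomeAssembly, RawHsp, RepeatElement
from .synthetic import revcomp

log = logging.getLogger(__name__)

NAHR_CLASSES = ("deletion_duplication", "inversion", "translocation")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Thresholds of the pair-scan filter cascade.

    Defaults are the relaxed genome-wide criteria; :meth:`stringent`
    switches to the full-length criteria (>4 kb elements aligning over
    >4 kb at >96 percent identity) used to nominate validation candidates.
    """

    min_element_length: int = 1000
    flank_length: int = 3000
    evalue_ceiling: float = 1e-50
    min_alignment_length: int = 1000
    min_identity: float = 92.0
    max_span: int = 10_000_000
    flank_tolerance: int = 0
    word_size: int = 11
    match_score: int = 1
    mismatch_score: int = -2
    open_gap_score: int = -5
    extend_gap_score: int = -2

    def stringent(self) -> "ScanParams":
        return replace(
            self,
            min_element_length=4000,
            min_alignment_length=4000,
            min_identity=96.0,
        )


@dataclass
class FlankedElement:
    """A LINE core interval plus the available flanking sequence."""

    element: RepeatElement
    seq: str  # genome-forward: left flank + core + right flank
    seq_start: int  # genomic coordinate of seq[0]
    left_flank: int
    right_flank: int
    left_truncated: bool = False
    right_truncated: bool = False

    @property
    def core_offset(self) -> int:
        return self.left_flank


@dataclass
class Hsp:
    """A local alignment between two flanked element sequences."""

    a_start: int  # offsets into the flanked sequences
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # direct | inverted (genome-forward sense)
    length: int  # alignment columns, gap columns included
    matches: int
    score: float
    evalue: float

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


@dataclass
class PairAlignment:
    """A surviving LINE pair with its classified NAHR potential."""

    id: str
    element_a: str
    element_b: str
    chrom_a: str
    chrom_b: str
    a_start: int  # genomic aligned sub-interval on element A
    a_end: int
    b_start: int
    b_end: int
    orientation: str
    length: int
    identity: float
    evalue: float
    score: float
    nahr_class: str | None = None
    span: int | None = None  # would-be CNV size, deletion_duplication only
    element_length_a: int = 0
    element_length_b: int = 0


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics for the internal scoring scheme
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def karlin_altschul(match: int, mismatch: int, p_match: float = 0.25) -> tuple[float, float]:
    """Numerically solve (lambda, K) for an ungapped match/mismatch scheme.

    lambda solves E[exp(lambda * S)] = 1 for the per-column score S under
    independent uniform backgrounds; K uses the lattice-case series of the
    classical theory, evaluated by convolving the score distribution.
    For +1/-2 this lands on the familiar blastn values (~1.33, ~0.62).
    """
    scores = np.array([match, mismatch])
    probs = np.array([p_match, 1.0 - p_match])

    def mgf(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * scores)) - 1.0)

    lam = brentq(mgf, 1e-6, 10.0)

    # distribution of S_k by repeated convolution on the integer lattice
    lo, hi = mismatch, match
    dist = np.zeros(hi - lo + 1)
    dist[0] = probs[1]
    dist[-1] = probs[0]
    offset = lo  # value of index 0
    sigma = 0.0
    cur = dist.copy()
    cur_off = offset
    for k in range(1, 60):
        vals = np.arange(cur.size) + cur_off
        neg = vals < 0
        term = float(np.sum(cur[neg] * np.exp(lam * vals[neg])) + np.sum(cur[~neg]))
        sigma += term / k
        cur = np.convolve(cur, dist)
        cur_off += offset
    mu_star = float(np.sum(probs * scores * np.exp(lam * scores)))
    delta = math.gcd(abs(match), abs(mismatch))
    k_param = delta * math.exp(-2.0 * sigma) / (mu_star * (1.0 - math.exp(-lam * delta)))
    return lam, k_param


def hsp_evalue(score: float, len_a: int, len_b: int, params: ScanParams) -> float:
    lam, k = karlin_altschul(params.match_score, params.mismatch_score)
    x = math.log(k * len_a * len_b) - lam * score
    return math.exp(x) if x < 700 else math.inf


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_elements(
    genome: GenomeAssembly,
    repeats: list[RepeatElement],
    params: ScanParams = ScanParams(),
) -> list[FlankedElement]:
    """Extract elements >= the minimum length, with flanks truncated at
    chromosome ends (truncation flagged)."""
    out: list[FlankedElement] = []
    for el in repeats:
        if el.chromosome not in genome.sequences:
            raise ValueError(f"element {el.id} on unknown chromosome {el.chromosome!r}")
        n = genome.chrom_length(el.chromosome)
        if not (0 <= el.start < el.end <= n):
            raise ValueError(f"element {el.id} interval outside chromosome bounds")
        if el.length < params.min_element_length:
            continue
        lf = min(params.flank_length, el.start)
        rf = min(params.flank_length, n - el.end)
        seq = genome.sequences[el.chromosome][el.start - lf:el.end + rf]
        out.append(
            FlankedElement(
                element=el,
                seq=seq,
                seq_start=el.start - lf,
                left_flank=lf,
                right_flank=rf,
                left_truncated=lf < params.flank_length,
                right_truncated=rf < params.flank_length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# internal aligner
# ---------------------------------------------------------------------------

def _local_aligner(params: ScanParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    return aligner


def _has_seed(seq_a: str, seq_b: str, w: int, window: int = 100) -> bool:
    """Two-hit seeding: trigger extension only on two non-overlapping word
    hits on the same diagonal within ``window`` bases.

    A single chance word match between unrelated sequences is common
    (expected ~len(A)*len(B)/4^w), but two close hits on one diagonal are
    not, so this keeps all-vs-all scans from running the full gapped
    extension on every unrelated pair.
    """
    if len(seq_a) < w or len(seq_b) < w:
        return False
    words: dict[str, list[int]] = {}
    for i in range(len(seq_a) - w + 1):
        words.setdefault(seq_a[i:i + w], []).append(i)
    anchor: dict[int, int] = {}  # diagonal -> first hit of the current cluster
    for j in range(len(seq_b) - w + 1):
        for i in words.get(seq_b[j:j + w], ()):
            diag = j - i
            last = anchor.get(diag)
            if last is None or j - last > window:
                anchor[diag] = j
            elif j - last >= w:
                return True
            # overlapping hit (gap < w): keep the older anchor
    return False


def _alignment_stats(aln) -> tuple[int, int, int, int, int, int]:
    """(a_start, a_end, b_start, b_end, columns, matches) of a local alignment."""
    a_str, b_str = str(aln[0]), str(aln[1])
    a = np.frombuffer(a_str.encode(), dtype="S1")
    b = np.frombuffer(b_str.encode(), dtype="S1")
    matches = int(np.sum((a == b) & (a != b"-")))
    (a_blocks, b_blocks) = aln.aligned
    a_start, a_end = int(a_blocks[0][0]), int(a_blocks[-1][1])
    b_start, b_end = int(b_blocks[0][0]), int(b_blocks[-1][1])
    return a_start, a_end, b_start, b_end, len(a_str), matches


def find_hsps(seq_a: str, seq_b: str, params: ScanParams = ScanParams()) -> list[Hsp]:
    """Seed-and-extend local alignment of two sequences, both strands.

    Low-complexity masking is deliberately absent.  At most one HSP per
    strand is reported (the optimal local alignment); the list is sorted by
    score.  No shared word on a strand means no alignment is attempted
    there, which is what keeps all-vs-all scans tractable.
    """
    if not seq_a or not seq_b:
        raise ValueError("find_hsps requires non-empty sequences")
    aligner = _local_aligner(params)
    out: list[Hsp] = []
    for orientation, target in (("direct", seq_b), ("inverted", revcomp(seq_b))):
        if not _has_seed(seq_a, target, params.word_size):
            continue
        aln = aligner.align(seq_a, target)[0]
        if aln.score <= 0:
            continue
        a0, a1, b0, b1, cols, matches = _alignment_stats(aln)
        if orientation == "inverted":
            b0, b1 = len(seq_b) - b1, len(seq_b) - b0
        out.append(
            Hsp(
                a_start=a0, a_end=a1, b_start=b0, b_end=b1,
                orientation=orientation, length=cols, matches=matches,
                score=float(aln.score),
                evalue=hsp_evalue(float(aln.score), len(seq_a), len(seq_b), params),
            )
        )
    out.sort(key=lambda h: -h.score)
    return out


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

REJECT_REASONS = ("self", "flank_extension", "evalue", "length", "identity", "span")


def _pair_span(a: RepeatElement, b: RepeatElement) -> int:
    """Size of the CNV a crossover between the two elements would create."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.start


def filter_hsps(
    candidates: list[tuple[FlankedElement, FlankedElement, Hsp]],
    params: ScanParams = ScanParams(),
) -> tuple[list[PairAlignment], list[tuple[str, str, Hsp, str]]]:
    """Apply the filter cascade; every rejection carries the first failing rule.

    Rule order: self-alignment, flank extension beyond the tolerance,
    E-value ceiling, minimum alignment length, minimum identity, and the
    intrachromosomal span cap (the last applied only to would-be
    deletion/duplication pairs, i.e. same-chromosome direct pairs, since
    inversions and translocations create no intrachromosomal CNV).
    """
    kept: list[PairAlignment] = []
    rejected: list[tuple[str, str, Hsp, str]] = []
    for fa, fb, hsp in candidates:
        ea, eb = fa.element, fb.element
        reason = None
        if ea.id == eb.id:
            reason = "self"
        elif (
            hsp.a_start < fa.core_offset - params.flank_tolerance
            or hsp.a_end > fa.core_offset + ea.length + params.flank_tolerance
            or hsp.b_start < fb.core_offset - params.flank_tolerance
            or hsp.b_end > fb.core_offset + eb.length + params.flank_tolerance
        ):
            reason = "flank_extension"
        elif hsp.evalue >= params.evalue_ceiling:
            reason = "evalue"
        elif hsp.length < params.min_alignment_length:
            reason = "length"
        elif hsp.identity < params.min_identity:
            reason = "identity"
        elif (
            ea.chromosome == eb.chromosome
            and hsp.orientation == "direct"
            and _pair_span(ea, eb) > params.max_span
        ):
            reason = "span"
        if reason is not None:
            rejected.append((ea.id, eb.id, hsp, reason))
            continue
        kept.append(
            PairAlignment(
                id=f"{ea.id}|{eb.id}|{hsp.orientation}",
                element_a=ea.id,
                element_b=eb.id,
                chrom_a=ea.chromosome,
                chrom_b=eb.chromosome,
                a_start=fa.seq_start + hsp.a_start,
                a_end=fa.seq_start + hsp.a_end,
                b_start=fb.seq_start + hsp.b_start,
                b_end=fb.seq_start + hsp.b_end,
                orientation=hsp.orientation,
                length=hsp.length,
                identity=hsp.identity,
                evalue=hsp.evalue,
                score=hsp.score,
                span=(
                    _pair_span(ea, eb)
                    if ea.chromosome == eb.chromosome and hsp.orientation == "direct"
                    else None
                ),
                element_length_a=ea.length,
                element_length_b=eb.length,
            )
        )
    return kept, rejected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _centromere_side(
    el: RepeatElement, centromeres: dict[str, list[tuple[int, int]]]
) -> str:
    ivals = centromeres.get(el.chromosome)
    if not ivals:
        log.info("no centromere annotation for %s; treating as one arm", el.chromosome)
        return "p"
    cen_s = min(s for s, _ in ivals)
    cen_e = max(e for _, e in ivals)
    mid = (el.start + el.end) // 2
    return "p" if mid < (cen_s + cen_e) // 2 else "q"


def classify_pair(
    element_a: RepeatElement,
    element_b: RepeatElement,
    orientation: str,
    centromeres: dict[str, list[tuple[int, int]]],
) -> str:
    """NAHR class of a pair from chromosome, orientation and centromere side.

    Different chromosomes -> translocation.  Same chromosome and inverted
    -> inversion, regardless of centromere position.  Same chromosome,
    direct, same arm -> deletion_duplication.  Same chromosome, direct,
    opposite arms -> excluded(pericentric): the crossover would have to
    span the centromere.
    """
    if orientation not in ("direct", "inverted"):
        raise ValueError(f"bad orientation {orientation!r}")
    if element_a.chromosome != element_b.chromosome:
        return "translocation"
    if orientation == "inverted":
        return "inversion"
    side_a = _centromere_side(element_a, centromeres)
    side_b = _centromere_side(element_b, centromeres)
    return "deletion_duplication" if side_a == side_b else "excluded(pericentric)"


# ---------------------------------------------------------------------------
# susceptibility coverage
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap(ivals_a: list[tuple[int, int]], ivals_b: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in ivals_a:
        for s2, e2 in ivals_b:
            total += max(0, min(e, e2) - max(s, s2))
    return total


def susceptibility_coverage(
    pairs: list[PairAlignment],
    genome: GenomeAssembly,
    elements_by_id: dict[str, RepeatElement] | None = None,
) -> tuple[float, dict[str, list[tuple[int, int, int]]]]:
    """Fraction of the non-gap genome between >= 1 deletion_duplication pair.

    A base is susceptible if it lies between the two elements of at least
    one deletion/duplication pair, elements included.  Returns the covered
    fraction of the non-gap genome and a per-chromosome depth track as
    (start, end, n_covering_pairs) runs.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        if p.nahr_class != "deletion_duplication":
            continue
        if elements_by_id is not None:
            a, b = elements_by_id[p.element_a], elements_by_id[p.element_b]
            lo, hi = min(a.start, b.start), max(a.end, b.end)
        else:
            lo, hi = min(p.a_start, p.b_start), max(p.a_end, p.b_end)
        spans.setdefault(p.chrom_a, []).append((lo, hi))

    covered = 0
    depth: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, ivals in spans.items():
        merged = _merge(ivals)
        gaps = genome.gaps.get(chrom, [])
        covered += sum(e - s for s, e in merged) - _overlap(merged, gaps)
        bounds = sorted({x for iv in ivals for x in iv})
        runs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            d = sum(1 for s, e in ivals if s <= lo and hi <= e)
            if d > 0:
                runs.append((lo, hi, d))
        depth[chrom] = runs
    return covered / genome.non_gap_length, depth


# ---------------------------------------------------------------------------
# whole-scan driver
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    elements: list[FlankedElement]
    pairs: list[PairAlignment]
    rejected: list[tuple[str, str, Hsp, str]]
    coverage: float
    depth: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)


def _import_blast_hsps(
    raw: list[RawHsp], by_id: dict[str, FlankedElement], params: ScanParams
) -> list[tuple[FlankedElement, FlankedElement, Hsp]]:
    out = []
    for r in raw:
        if r.qseqid not in by_id or r.sseqid not in by_id:
            raise ValueError(f"BLAST HSP references unknown element {r.qseqid}/{r.sseqid}")
        fa, fb = by_id[r.qseqid], by_id[r.sseqid]
        (q0, q1), (s0, s1) = r.q_interval, r.s_interval
        matches = round(r.length * r.pident / 100.0)
        out.append(
            (
                fa,
                fb,
                Hsp(
                    a_start=q0, a_end=q1, b_start=s0, b_end=s1,
                    orientation="inverted" if r.minus_strand else "direct",
                    length=r.length, matches=matches,
                    score=r.bitscore, evalue=r.evalue,
                ),
            )
        )
    return out


def scan_genome(
    genome: GenomeAssembly,
    repeats: list[RepeatElement],
    params: ScanParams = ScanParams(),
    blast_hsps: list[RawHsp] | None = None,
) -> ScanResult:
    """All-vs-all pair scan: extract, align (or import), filter, classify.

    If several HSPs survive for one element pair the highest-scoring one
    per NAHR class is kept.
    """
    flanked = extract_elements(genome, repeats, params)
    log.info("extracted %d elements >= %d bp", len(flanked), params.min_element_length)
    candidates: list[tuple[FlankedElement, FlankedElement, Hsp]] = []
    if blast_hsps is not None:
        by_id = {f.element.id: f for f in flanked}
        candidates = _import_blast_hsps(blast_hsps, by_id, params)
    else:
        # self-alignments are skipped outright here; the `self` filter rule
        # still applies to imported BLAST HSP tables
        for i in range(len(flanked)):
            for j in range(i + 1, len(flanked)):
                fa, fb = flanked[i], flanked[j]
                for hsp in find_hsps(fa.seq, fb.seq, params):
                    candidates.append((fa, fb, hsp))
    log.info("%d candidate HSPs", len(candidates))
    kept, rejected = filter_hsps(candidates, params)
    log.info("%d HSPs kept, %d rejected", len(kept), len(rejected))

    by_el = {f.element.id: f.element for f in flanked}
    for p in kept:
        p.nahr_class = classify_pair(
            by_el[p.element_a], by_el[p.element_b], p.orientation, genome.centromeres
        )

    # per unordered element pair, best score per class
    best: dict[tuple[str, str, str], PairAlignment] = {}
    for p in kept:
        key = (*sorted((p.element_a, p.element_b)), p.nahr_class or "")
        if key not in best or p.score > best[key].score:
            best[key] = p
    pairs = sorted(best.values(), key=lambda p: p.id)
    log.info("%d classified pairs", len(pairs))

    coverage, depth = susceptibility_coverage(pairs, genome, by_el)
    return ScanResult(elements=flanked, pairs=pairs, rejected=rejected,
                      coverage=coverage, depth=depth)
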