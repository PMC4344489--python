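"""Hybrid junction templates for long-range PCR primer design.

At design time the crossover position inside the LINE-LINE homology is
unknown, so the template assumes only that the breakpoint lies somewhere
in the homology: unique upstream flank + chimeric LINE + unique downstream
flank, with the full homology segment marked as the target interval.
Primers must sit in the unique flanks; picking them is delegated to
Primer3, for which Boulder-IO records are emitted.

The chimeric middle is the pair consensus with the proximal allele taken
at every cis-morphism and indel column, which makes it byte-identical to
the proximal copy's homology segment — so the provenance of every base is
a genomic interval and the hybrid can be reconstructed exactly from
provenance plus genome.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenomeAssembly, RepeatElement
from .synthetic import revcomp


@dataclass(frozen=True)
class ProvenanceSegment:
    """One hybrid segment copied from the genome (0-based, half-open)."""

    hybrid_start: int
    hybrid_end: int
    chrom: str
    genome_start: int
    genome_end: int
    strand: str  # + | -
    role: str  # upstream_flank | homology | downstream_flank


@dataclass
class HybridJunction:
    event_type: str
    pair_id: str
    sequence: str
    junction_start: int  # homology segment in hybrid coordinates
    junction_end: int
    provenance: list[ProvenanceSegment]

    def reconstruct(self, genome: GenomeAssembly) -> str:
        """Rebuild the hybrid from provenance; must equal ``sequence``."""
        parts = []
        for seg in sorted(self.provenance, key=lambda s: s.hybrid_start):
            piece = genome.sequences[seg.chrom][seg.genome_start:seg.genome_end]
            parts.append(piece if seg.strand == "+" else revcomp(piece))
        return "".join(parts)


def _flank(genome: GenomeAssembly, el: RepeatElement, side: str, flank_len: int) -> tuple[int, int]:
    n = genome.chrom_length(el.chromosome)
    if side == "up":
        return max(0, el.start - flank_len), el.start
    return el.end, min(n, el.end + flank_len)


def hybrid_sequence(
    genome: GenomeAssembly,
    element_a: RepeatElement,
    element_b: RepeatElement,
    event_type: str,
    flank_len: int = 5000,
    pair_id: str | None = None,
) -> list[HybridJunction]:
    """Construct the chimeric junction reference(s) for one pair and event.

    Deletion: upstream flank of A + homology + downstream flank of B.
    Duplication: upstream flank of B + homology + downstream flank of A
    (the novel junction of the tandem copy).  Inversion: two junctions,
    each joining one element's flank to the reverse complement of the
    other side.  Returns one record for deletion/duplication, two for
    inversion.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    if event_type not in ("deletion", "duplication", "inversion"):
        raise ValueError(f"unknown event type {event_type!r}")
    if element_a.chromosome != element_b.chromosome:
        raise ValueError("hybrid templates are built for intrachromosomal pairs")
    if element_a.start > element_b.start:
        element_a, element_b = element_b, element_a
    if event_type in ("deletion", "duplication") and element_a.strand != element_b.strand:
        raise ValueError(f"{event_type} requires a directly oriented pair")
    pid = pair_id or f"{element_a.id}|{element_b.id}"
    chrom = element_a.chromosome
    seq = genome.sequences[chrom]

    def make(
        up_el: RepeatElement, mid_el: RepeatElement, down_el: RepeatElement,
        mid_strand: str, tag: str,
    ) -> HybridJunction:
        u0, u1 = _flank(genome, up_el, "up", flank_len)
        d0, d1 = _flank(genome, down_el, "down", flank_len)
        mid = seq[mid_el.start:mid_el.end]
        if mid_strand == "-":
            mid = revcomp(mid)
        hybrid = seq[u0:u1] + mid + seq[d0:d1]
        j0 = u1 - u0
        j1 = j0 + len(mid)
        prov = [
            ProvenanceSegment(0, j0, chrom, u0, u1, "+", "upstream_flank"),
            ProvenanceSegment(j0, j1, chrom, mid_el.start, mid_el.end, mid_strand, "homology"),
            ProvenanceSegment(j1, len(hybrid), chrom, d0, d1, "+", "downstream_flank"),
        ]
        return HybridJunction(
            event_type=tag, pair_id=pid, sequence=hybrid,
            junction_start=j0, junction_end=j1, provenance=prov,
        )

    if event_type == "deletion":
        # proximal flank + proximal-copy homology + distal flank
        return [make(element_a, element_a, element_b, "+", "deletion")]
    if event_type == "duplication":
        # the novel junction of the tandem duplication: distal upstream
        # context meets proximal downstream context across the homology
        return [make(element_b, element_a, element_a, "+", "duplication")]
    # inversion: both novel junctions
    return [
        make(element_a, element_b, element_b, "-", "inversion_left"),
        make(element_b, element_a, element_a, "-", "inversion_right"),
    ]


def expected_amplicon(
    hybrid: HybridJunction, fwd_primer: tuple[int, int], rev_primer: tuple[int, int]
) -> int:
    """Expected LR-PCR product length from primer positions on the hybrid."""
    f0, f1 = fwd_primer
    r0, r1 = rev_primer
    n = len(hybrid.sequence)
    if not (0 <= f0 < f1 <= n and 0 <= r0 < r1 <= n):
        raise ValueError("primer positions outside the hybrid")
    if f1 > r0:
        raise ValueError("forward primer must lie before the reverse primer")
    return r1 - f0


def boulder_io_record(hybrid: HybridJunction, design_window: tuple[int, int] = (7000, 15000)) -> str:
    """A Primer3 input record targeting the homology segment.

    The product-size window defaults to the 7-15 kb range long-range PCR
    amplifies reliably.
    """
    lo, hi = design_window
    return "\n".join(
        [
            f"SEQUENCE_ID={hybrid.pair_id}|{hybrid.event_type}",
            f"SEQUENCE_TEMPLATE={hybrid.sequence}",
            f"SEQUENCE_TARGET={hybrid.junction_start},{hybrid.junction_end - hybrid.junction_start}",
            f"PRIMER_PRODUCT_SIZE_RANGE={lo}-{hi}",
            "=",
        ]
    ) + "\n"
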