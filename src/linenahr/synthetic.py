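"""Synthetic genomes with planted LINE families and NAHR events.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for: a reference genome with annotated LINE copies at
controlled pairwise identity, NAHR-derived deletions / duplications /
inversions with known crossover positions, aCGH probe tracks with Gaussian
log2 noise, and Sanger-like junction reads with PHRED-consistent errors.
Everything is deterministic given the seed.

Divergence model: independent per-base substitutions with a 2:1
transition:transversion bias, plus rare 1-5 bp indels.  Each copy diverges
independently from a common ancestral element, so two copies at per-copy
substitution rate d show pairwise identity ~ 1 - 2d; the generator converts
a target pairwise identity into d accordingly.  At 96-99 percent identity
this yields roughly one informative site per 25-100 bp, the density at
which crossover intervals of order 50-150 bp are resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .io_formats import GenomeAssembly, ProbeTrack, RepeatElement

_BASES = np.frombuffer(b"ACGT", dtype="S1")
#: transitions (A<->G, C<->T) drawn twice as often as either transversion
_TRANSITION = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _consensus_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilySpec:
    """One planted LINE family.

    ``target_identity`` is the intended *pairwise* identity (percent)
    between any two copies.  ``shared_flank`` plants identical sequence
    beyond the annotated element boundary on both sides of every copy
    (emulating a LINE embedded in a larger LCR, the situation the
    flank-extension filter must reject).  ``strands`` optionally fixes the
    genomic strand of each copy; ``positions`` optionally fixes
    (chromosome, start) per copy instead of automatic placement.
    """

    name: str = "L1SIM"
    n_copies: int = 6
    length: int = 6000
    target_identity: float = 97.0
    indel_rate: float | None = None  # per-bp; default 0.03 * substitution rate
    shared_flank: int = 0
    strands: list[str] | None = None
    positions: list[tuple[str, int]] | None = None
    chromosome: str | None = None  # placement chromosome (default: first)

    @property
    def sub_rate(self) -> float:
        """Per-copy substitution rate implied by the target pairwise identity."""
        d = (1.0 - self.target_identity / 100.0) / 2.0
        if not 0.0 <= d < 0.5:
            raise ValueError(f"target identity {self.target_identity} out of range")
        return d


@dataclass
class PlantedEvent:
    """An NAHR event to rearrange a haplotype with, in truth coordinates."""

    family: str
    copy_a: int
    copy_b: int
    event_type: str  # deletion | duplication | inversion
    crossover: int  # column index on the pairwise alignment of the two copies
    sample: str = "case"


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chr1": 500_000})
    families: list[FamilySpec] = field(default_factory=lambda: [FamilySpec()])
    gc: float = 0.41
    min_separation: int = 8000  # >= scan flank length so flanks stay unique
    events: list[PlantedEvent] = field(default_factory=list)
    probe_spacing: int = 1000
    log2_sd: float = 0.15
    read_length: int = 600
    read_quality: int = 40


@dataclass
class PlantedCnv:
    sample: str
    chrom: str
    start: int
    end: int
    kind: str  # deletion | duplication


@dataclass
class SyntheticTruth:
    elements: list[RepeatElement]
    element_seqs: dict[str, str]
    pair_identity: dict[tuple[str, str], float]  # expected, by element id pair
    cnvs: list[PlantedCnv]
    crossovers: dict[str, int]  # sample -> crossover column on the pair alignment

    def elements_of(self, family: str) -> list[RepeatElement]:
        return [e for e in self.elements if e.family == family]


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def mutate(
    rng: np.random.Generator,
    seq: str,
    sub_rate: float,
    indel_rate: float = 0.0,
) -> str:
    """Diverge a sequence: biased substitutions plus rare short indels."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < sub_rate
    for i in np.nonzero(hit)[0]:
        base = bytes(arr[i])
        if rng.random() < 0.5:  # transition (2 of 4 mutation draws)
            arr[i] = _TRANSITION[base]
        else:
            choices = [b for b in (b"A", b"C", b"G", b"T") if b != base and b != _TRANSITION[base]]
            arr[i] = choices[rng.integers(2)]
    out = arr.tobytes().decode()
    if indel_rate > 0:
        n_indels = rng.poisson(indel_rate * len(out))
        for _ in range(n_indels):
            pos = int(rng.integers(1, max(2, len(out) - 6)))
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                out = out[:pos] + out[pos + size:]
            else:
                ins = random_sequence(rng, size)
                out = out[:pos] + ins + out[pos:]
    return out


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def make_genome(config: SimulationConfig) -> tuple[GenomeAssembly, SyntheticTruth]:
    """Build a genome with planted families; deterministic given the seed.

    Copies are placed non-overlapping, separated by at least
    ``min_separation`` so each element's flanks are unique background
    sequence.  Raises if the requested copies do not fit.
    """
    rng = np.random.default_rng(config.seed)
    background = {
        chrom: np.frombuffer(random_sequence(rng, n, config.gc).encode(), dtype="S1").copy()
        for chrom, n in config.chromosomes.items()
    }
    first_chrom = next(iter(config.chromosomes))

    elements: list[RepeatElement] = []
    element_seqs: dict[str, str] = {}
    pair_identity: dict[tuple[str, str], float] = {}

    # automatic placement keeps one cursor per chromosome
    cursors = {chrom: config.min_separation for chrom in config.chromosomes}

    for fam in config.families:
        ancestral = random_sequence(rng, fam.length, config.gc)
        anc_flank_l = random_sequence(rng, fam.shared_flank, config.gc) if fam.shared_flank else ""
        anc_flank_r = random_sequence(rng, fam.shared_flank, config.gc) if fam.shared_flank else ""
        indel_rate = fam.indel_rate if fam.indel_rate is not None else 0.03 * fam.sub_rate
        fam_ids: list[str] = []
        for i in range(fam.n_copies):
            core = mutate(rng, ancestral, fam.sub_rate, indel_rate)
            strand = (fam.strands[i] if fam.strands else "+")
            placed = core if strand == "+" else revcomp(core)
            block = (
                mutate(rng, anc_flank_l, fam.sub_rate) + placed + mutate(rng, anc_flank_r, fam.sub_rate)
                if fam.shared_flank
                else placed
            )
            if fam.positions is not None:
                chrom, start = fam.positions[i]
                block_start = start - fam.shared_flank
            else:
                chrom = fam.chromosome or first_chrom
                jitter = int(rng.integers(0, config.min_separation // 2 + 1))
                block_start = cursors[chrom] + jitter
                start = block_start + fam.shared_flank
                cursors[chrom] = block_start + len(block) + config.min_separation
            end = start + len(placed)
            if block_start < 0 or block_start + len(block) > len(background[chrom]):
                raise ValueError(
                    f"family {fam.name}: copy {i} does not fit on {chrom} "
                    f"(needs [{block_start},{block_start + len(block)}))"
                )
            background[chrom][block_start:block_start + len(block)] = np.frombuffer(
                block.encode(), dtype="S1"
            )
            eid = f"{fam.name}_{i}"
            elements.append(
                RepeatElement(id=eid, chromosome=chrom, start=start, end=end,
                              strand=strand, family=fam.name)
            )
            element_seqs[eid] = placed
            fam_ids.append(eid)
        for a in range(len(fam_ids)):
            for b in range(a + 1, len(fam_ids)):
                pair_identity[(fam_ids[a], fam_ids[b])] = fam.target_identity

    genome = GenomeAssembly(
        sequences={c: arr.tobytes().decode() for c, arr in background.items()}
    )

    truth = SyntheticTruth(
        elements=elements,
        element_seqs=element_seqs,
        pair_identity=pair_identity,
        cnvs=[],
        crossovers={},
    )

    # record the reference-coordinate CNV implied by each planted event
    by_id = {e.id: e for e in elements}
    for ev in config.events:
        a = by_id[f"{ev.family}_{ev.copy_a}"]
        b = by_id[f"{ev.family}_{ev.copy_b}"]
        if ev.event_type in ("deletion", "duplication"):
            pos_a, pos_b, _ = _crossover_images(genome, a, b, ev.crossover)
            truth.cnvs.append(
                PlantedCnv(sample=ev.sample, chrom=a.chromosome,
                           start=pos_a, end=pos_b, kind=ev.event_type)
            )
        truth.crossovers[ev.sample] = ev.crossover
    return genome, truth


# ---------------------------------------------------------------------------
# NAHR rearrangement
# ---------------------------------------------------------------------------

def _crossover_images(
    genome: GenomeAssembly, a: RepeatElement, b: RepeatElement, crossover: int
) -> tuple[int, int, int]:
    """Map an alignment-column crossover to genomic positions in both copies.

    Returns (position in A, position in B, number of alignment columns).
    The two element sequences are globally aligned; the crossover column's
    image in each copy is the count of that copy's bases in earlier columns.
    """
    seq_a = genome.sequences[a.chromosome][a.start:a.end]
    seq_b = genome.sequences[b.chromosome][b.start:b.end]
    aln = _consensus_aligner().align(seq_a, seq_b)[0]
    col_a, col_b = _column_offsets(aln)
    ncols = len(col_a)
    if not 0 <= crossover < ncols:
        raise ValueError(f"crossover column {crossover} outside homology (0..{ncols - 1})")
    return a.start + col_a[crossover], b.start + col_b[crossover], ncols


def _column_offsets(aln) -> tuple[np.ndarray, np.ndarray]:
    """Per-alignment-column offsets into each aligned sequence."""
    a_str, b_str = str(aln[0]), str(aln[1])
    a_gap = np.frombuffer(a_str.encode(), dtype="S1") == b"-"
    b_gap = np.frombuffer(b_str.encode(), dtype="S1") == b"-"
    col_a = np.cumsum(~a_gap) - (~a_gap).astype(int)
    col_b = np.cumsum(~b_gap) - (~b_gap).astype(int)
    return col_a, col_b


@dataclass
class NahrOutcome:
    haplotype: str  # the rearranged chromosome sequence
    junction: int  # junction coordinate in the rearranged haplotype
    ref_start: int  # crossover image in element A (reference coords)
    ref_end: int  # crossover image in element B (reference coords)


def apply_nahr(
    genome: GenomeAssembly,
    element_a: RepeatElement,
    element_b: RepeatElement,
    event_type: str,
    crossover: int,
) -> NahrOutcome:
    """Rearrange one haplotype by NAHR between two elements.

    A deletion removes exactly the segment between the crossover images in A
    and B; a duplication inserts it in tandem; an inversion
    reverse-complements it (length unchanged).
    """
    if element_a.chromosome != element_b.chromosome:
        raise ValueError("apply_nahr requires both elements on the same chromosome")
    if element_a.start > element_b.start:
        element_a, element_b = element_b, element_a
    if event_type not in ("deletion", "duplication", "inversion"):
        raise ValueError(f"unknown event type {event_type!r}")
    chrom_seq = genome.sequences[element_a.chromosome]
    pos_a, pos_b, _ = _crossover_images(genome, element_a, element_b, crossover)
    if event_type == "deletion":
        hap = chrom_seq[:pos_a] + chrom_seq[pos_b:]
        return NahrOutcome(hap, pos_a, pos_a, pos_b)
    if event_type == "duplication":
        hap = chrom_seq[:pos_b] + chrom_seq[pos_a:]
        return NahrOutcome(hap, pos_b, pos_a, pos_b)
    hap = chrom_seq[:pos_a] + revcomp(chrom_seq[pos_a:pos_b]) + chrom_seq[pos_b:]
    return NahrOutcome(hap, pos_a, pos_a, pos_b)


# ---------------------------------------------------------------------------
# aCGH probes
# ---------------------------------------------------------------------------

def simulate_probes(
    genome: GenomeAssembly,
    cnvs: list[PlantedCnv],
    spacing: int,
    sd: float,
    seed: int,
    sample: str = "S1",
) -> ProbeTrack:
    """Evenly spaced log2-ratio probes with Gaussian noise.

    Heterozygous deletions shift the mean to log2(1/2) = -1.0, heterozygous
    duplications to log2(3/2) ~ +0.585; elsewhere the mean is 0.
    """
    if spacing <= 0:
        raise ValueError("probe spacing must be positive")
    if sd < 0:
        raise ValueError("log2 noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    positions: list[int] = []
    means: list[float] = []
    for chrom, seq in genome.sequences.items():
        for pos in range(spacing, len(seq), spacing):
            mu = 0.0
            for c in cnvs:
                if c.sample == sample and c.chrom == chrom and c.start <= pos < c.end:
                    mu = -1.0 if c.kind == "deletion" else float(np.log2(1.5))
                    break
            chroms.append(chrom)
            positions.append(pos)
            means.append(mu)
    noise = rng.normal(0.0, sd, size=len(means)) if sd > 0 else np.zeros(len(means))
    return ProbeTrack(
        sample=sample,
        chroms=chroms,
        positions=positions,
        log2=[float(m + e) for m, e in zip(means, noise)],
    )


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    hybrid_seq: str,
    junction: int,
    n_reads: int,
    read_length: int,
    quality: int,
    seed: int,
    margin: int = 50,
    name_prefix: str = "read",
) -> tuple[list[tuple[str, str, list[int]]], list[int]]:
    """Sanger-like reads spanning a junction, with PHRED-consistent errors.

    Each read covers ``junction`` with at least ``margin`` bases on either
    side.  Substitution errors are injected at rate 10**(-Q/10) per base and
    the emitted quality string reports that same Q.  Returns the FASTQ
    records and the junction offset within each read.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if read_length > len(hybrid_seq):
        raise ValueError("hybrid sequence shorter than read length")
    if read_length < 2 * margin:
        raise ValueError("read length must exceed twice the junction margin")
    rng = np.random.default_rng(seed)
    lo = max(0, junction + margin - read_length)
    hi = min(len(hybrid_seq) - read_length, junction - margin)
    if hi < lo:
        raise ValueError("junction too close to the hybrid ends for the read length")
    err = 10 ** (-quality / 10)
    records = []
    offsets = []
    for i in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        arr = np.frombuffer(hybrid_seq[start:start + read_length].encode(), dtype="S1").copy()
        bad = np.nonzero(rng.random(read_length) < err)[0]
        for j in bad:
            others = [b for b in (b"A", b"C", b"G", b"T") if b != bytes(arr[j])]
            arr[j] = others[rng.integers(3)]
        records.append((f"{name_prefix}_{i}", arr.tobytes().decode(), [quality] * read_length))
        offsets.append(junction - start)
    return records, offsets
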