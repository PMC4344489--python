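# Methods

`linenahr` reconstructs, as tested software, a genome-scale analysis of
nonallelic homologous recombination (NAHR) mediated by LINE retrotransposon
pairs: which pairs of LINE copies are capable of recombining, which
clinical copy-number variants (CNVs) they can explain, how strongly such
pairs are enriched at CNV breakpoints, where inside the LINE–LINE homology
each crossover occurred, and what reference sequence a validation PCR
should expect. The original study ran against the human reference genome
and a proprietary clinical CNV database; this package reproduces the
*procedures* on synthetic genomes with known truth, so every step is
checkable against planted answers.

## Coordinates and formats

All intervals are 0-based half-open (the UCSC table convention), on
genome-forward sequence. Inputs are plain formats: FASTA genomes, BED6 or
UCSC RepeatMasker table dumps for repeats, BED3 for centromeres and
assembly gaps, 12-column BLAST tabular for imported alignments, TSV probe
tracks, genomicSuperDups-style TSV for segmental-duplication pairs, and
Sanger-encoded FASTQ for junction reads. Chromosome names are never
normalized; callers must keep naming consistent across inputs.

## Pair scan

Every LINE longer than 1 kb is extracted with 3 kb of flanking sequence
(truncated and flagged at chromosome ends). Pairs are aligned either by
importing BLAST outfmt-6 HSPs (the route for genome-scale runs) or by the
internal aligner: exact shared 11-mers seed candidate pairs, using a
two-hit rule (two non-overlapping word hits on one diagonal within 100 bp)
so that chance single-word matches between unrelated elements do not
trigger the full gapped extension; seeded pairs are then locally aligned
with match +1, mismatch −2, gap open −5, gap extend −2, on both strands,
without low-complexity masking. Identity is matches over alignment
columns, gap columns included (the BLAST `pident` convention). E-values
use ungapped Karlin–Altschul statistics with λ and K solved numerically
for the scoring scheme (for +1/−2 this reproduces the familiar
blastn constants λ ≈ 1.33, K ≈ 0.62) against an effective search space
len(A)·len(B). Each internal scan reports at most the optimal local
alignment per strand per pair; when several survive filtering for one
element pair the highest-scoring per NAHR class is kept. Self-alignments
are skipped outright in the internal all-vs-all; the `self` filter rule
still guards imported HSP tables.

The filter cascade runs in a fixed order and labels every rejection with
the first failing rule: (i) self-alignment; (ii) alignment extending
outside the element core by more than the flank tolerance — such pairs are
likely embedded in larger low-copy repeats; (iii) E-value ≥ 1e−50;
(iv) alignment shorter than 1 kb; (v) identity below 92%; (vi) would-be
intrachromosomal CNV larger than 10 Mb. The span cap applies only to
same-chromosome, directly oriented pairs: inversions and translocations
create no intrachromosomal CNV, so the cap is not meaningful for them.
The flank tolerance defaults to 0 (strict); in practice a single chance
base match at an element boundary extends an optimal local alignment into
the flank with probability ~1/4 per end, so synthetic-genome studies in
this repository run with a 10 bp tolerance, which also accommodates
target-site duplications.

Classification follows genomic geometry, not annotation strand: a pair is
*directly oriented* when the plus/plus alignment of the genome-forward
sequences is optimal. Different chromosomes → translocation substrate;
same chromosome and inverted → inversion substrate regardless of
centromere position; same chromosome, direct, same chromosome arm →
deletion/duplication substrate; same chromosome, direct, opposite arms →
excluded (the crossover would need to span the centromere). Chromosomes
without centromere annotation are treated as single-arm, with a log
notice. Susceptibility coverage is the fraction of the non-gap genome
lying between the two elements (inclusive) of at least one
deletion/duplication pair, with a per-base depth track.

The stringent parameter set (elements > 4 kb aligning over > 4 kb at
> 96% identity) mirrors the criteria used to nominate validation
candidates; the 96% cutoff is the operative one here, with the looser 95%
variant available as a parameter.

## CNV calls and matching

Array-CGH probes only bracket breakpoints: each call's breakpoint
uncertainty regions run from the last normal-ratio probe to the first
aberrant one (probe positions as points; probe length ignored). Calling
is deliberately simple — maximal runs of ≥ 3 consecutive probes beyond the
loss/gain thresholds (−0.3/+0.3 by default; −0.6/+0.5 for
stringent-amplitude selection, matching heterozygous-deletion and
-duplication expectations of log2 1/2 = −1 and log2 3/2 ≈ +0.585) — since
segmentation quality is not what this package studies. CNVs whose two
uncertainty regions straddle a directly oriented segmental-duplication
pair are removed (the rearrangement is then better explained by that
larger repeat); inverted pairs never trigger removal. Recurrent CNVs
across samples are collapsed by single-linkage clustering at 90%
reciprocal overlap, keeping the earliest representative.

A LINE pair explains a CNV when, after ordering elements by coordinate,
the left element intersects the proximal region and the right element the
distal region. Intersection, not containment: a crossover inside the LINE
implies only overlap with the inter-probe gap, and containment would
reject LINEs larger than the gap.

## Enrichment

The null quantity ε is the expected number of CNVs whose regions a
randomly placed pair would hit: ε = Σ over CNVs of
(len(proximal)/G)·(len(distal)/G), with G the non-gap genome length. This
treats a pair as an *ordered* tuple of two independent uniform points
(proximal first) and ignores element extent; it is accurate when CNVs are
short relative to the genome and uncertainty regions wide relative to the
elements. Note a subtlety: an exchangeable null that drops two points and
sorts them yields twice this expectation, so the calibration fixture
draws pairs with span uniform on (0, G) and location uniform given span —
an ordered placement that matches the estimator to O(span/G). The
enrichment surface is E(l, id) = matched(l, id) / (ε · n_pairs(l, id))
over minimum homology length l and minimum identity id, counting
*distinct* matched CNVs (a CNV matching several pairs counts once) and
leaving cells without qualifying pairs undefined (NaN) rather than zero.

Because CNVs in the calibration fixture overlap one another, matched
counts are overdispersed relative to Poisson (one lucky pair hits a stack
of overlapping CNVs); calibration tests therefore estimate the
Monte-Carlo s.d. per cell from replicate null pair sets instead of a
Poisson formula. An optional border correction rescales each CNV's ε
contribution by G / Σ_arms max(0, arm_len − span), approximating the lost
placements near chromosome ends and centromeres; it is clearly an
approximation and the uncorrected printed estimator is the default.

## Crossover localization (the switch HMM)

For a pair of copies, a global alignment (match +1, mismatch −1, open −5,
extend −1, via Biopython's PairwiseAligner) defines the consensus
coordinate system. Substitution columns are *cis-morphisms* — the
paralogous sequence variants that tell the copies apart; indel columns
are flagged and excluded from informativeness. The consensus base is the
proximal allele at both cis-morphism and indel columns, which also makes
the junction template below byte-identical to the proximal copy's
homology segment.

Junction reads are placed on the consensus by a semi-global
Needleman–Wunsch (read internal to consensus; consensus end-gaps free;
match +1, mismatch −1, gap −2, linear — linear gaps turn the in-row DP
dependency into a running maximum, so each row is two numpy scans). Both
orientations are tried. Each covered column becomes one vote: L if the
read base equals the proximal allele at a cis-morphism, R for the distal
allele, N otherwise; votes carry w = 1 − 10^(−Q/10) from the base's PHRED
quality. The string is framed by S and E markers.

The two-state model: S1 emits L with probability α given an informative
emission, S2 emits R with probability β, both emit N with probability ρ
(so P(L|S1) = (1−ρ)α, P(R|S1) = (1−ρ)(1−α), symmetric for S2), and the
chain may switch S1 → S2 exactly once, with per-emitted-symbol hazard γ —
so posterior intervals naturally live between informative sites. The
switch may also fall before the first symbol or after the last; by
default a switch is forced (junction amplicons contain one), and an
`allow_no_switch` topology is available for screening reads. A vote of
weight w is scored with the affine emission combination
w·b(observed) + (1−w)·b(opposite), so low-quality votes pull the
likelihood toward indifference. ρ cancels from all switch posteriors
(it is state-independent), but is retained for likelihood reporting and
training.

Forward–backward uses per-position scaling; the switch posterior equals
exhaustive enumeration over all placements (tested to 1e−10). Training is
Baum–Welch with Beta-prior MAP updates — priors Beta(20,1) for α and β,
Beta(1,20) for γ, Beta(2,2) for ρ — whose penalized log-likelihood trace
is non-decreasing. Expected counts treat a low-weight vote as an
uncertain symbol (posterior over the true symbol inside the E-step), and
γ's denominator counts hazard decisions actually taken from S1.

Per-read switch posteriors are aggregated into inter-cis-morphism
intervals and pooled across a case's reads by product (sum of logs) on
the shared consensus coordinates; the MAP interval is reported with its
width and posterior mass, ties breaking leftmost. Reads below 80%
identity to the consensus are dropped with a warning; a case with no
usable reads is an error. Calls from multiple cases cluster by
single-linkage on MAP midpoints within 500 bp, the scale at which
recurrent crossovers were considered one hotspot. One caveat: train the
model on the pooled read set of all cases, not per case — with only a
couple of reads the Beta(20,1) priors cap the emission sharpness near
0.95, which lets a wide empty interval outweigh a narrow true one by
prior mass alone. `call_case` trains per case only as a convenience
fallback.

## Junction templates

For a candidate pair and event type, the PCR template is unique upstream
flank + chimeric homology + unique downstream flank, with the full
homology marked as the target interval — at design time the crossover is
unknown, so primers must sit in the unique flanks and Primer3 receives
the homology as the target (Boulder-IO records; product window 7–15 kb,
the reliable long-range PCR span). Deletion joins the proximal element's
upstream context to the distal element's downstream context; duplication
is the reciprocal novel junction; inversion yields two templates joining
each element to the reverse complement of the other side. Since the
chimeric middle is the proximal copy's homology segment (see above),
every base has a genomic provenance record and the hybrid reconstructs
exactly from provenance + genome.

## Synthetic data: what it emulates, and what it does not

The generator plants LINE families by mutating a random ancestral element
independently per copy: substitutions with a 2:1 transition bias at rate
d per copy (pairwise identity ≈ 1 − 2d, realized within ±1 point of
target), plus rare 1–5 bp indels (default rate 3% of the substitution
rate). At 96–99% identity this yields one informative site per ~25–100
bp, the density at which crossover intervals of order 50–150 bp are
resolvable — matching the scale of real LINE–LINE NAHR junctions.
Flanks are unique random sequence so the flank-extension filter is
exercisable; a `shared_flank` option embeds copies in a larger repeat to
violate it deliberately. NAHR events rearrange a haplotype exactly
(deletion and duplication are mutually inverse in length; inversions
preserve length), probe tracks put Gaussian noise around copy-state
means, and junction reads carry substitution errors at the rate their
emitted PHRED qualities imply. Everything is deterministic given the
seed.

Real data differ in ways the simulator does not model: L1 subfamily
phylogeny and its correlated divergence, indel-heavy Sanger error
profiles and chromatogram artifacts, non-uniform probe spacing, mosaic
or homozygous copy states beyond simple het/hom, and reference-genome
gaps/segmental architecture. Passing tests therefore demonstrate the
algorithms' correctness under controlled conditions, not performance on
clinical data.

## Problem sizes and numerical choices

The packaged studies run at desk scale by design: genomes of 0.3–14 Mb,
families of 2–6 copies, 200-event CNV tracks, 100–200 junction cases with
2 reads each, 500-CNV/2000-pair enrichment fixtures, and a
10^6-draw Monte-Carlo ε oracle. The genome-scale counts of the original
analysis (tens of thousands of pairs, billions of HSPs) require hg19 and
cluster-scale alignment and are supported only through the BLAST import
path. Degenerate inputs raise errors naming the offending record or
line; EM stops on penalized log-likelihood improvement < 1e−6 or 200
iterations; MAP estimates are clipped to (1e−6, 1−1e−6) to keep
likelihoods finite; posterior ties break leftmost.

## Known limitations

Indel cis-morphisms are treated as uninformative (N). The per-read edge
masses ("switch outside my window") pool coarsely when reads cover
disjoint ranges; all packaged studies use junction-spanning reads, where
this does not arise. Multi-crossover cases surface as multimodal
posteriors and are reported, not split automatically. The internal
aligner reports one HSP per strand per pair, which is adequate for
element-versus-element scans but would under-report tandem substructure
inside single elements. ε's point-placement approximation inflates
enrichment slightly when uncertainty regions are narrow relative to
element length, as discussed above.
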