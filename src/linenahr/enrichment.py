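"""Enrichment of LINE pairs in CNV breakpoint-uncertainty regions.

The null quantity is epsilon, the expected number of CNVs whose two
uncertainty regions a randomly placed LINE pair would hit:

    epsilon = sum over CNVs of (len(proximal)/G) * (len(distal)/G)

with G the non-gap genome length.  This treats a pair as an ordered tuple
of two independently, uniformly placed points (proximal element first);
element extent and the geometric constraint that the proximal element lie
left of the distal one are deliberately ignored by the estimator, which is
accurate for CNVs short relative to the genome and uncertainty regions
wide relative to the elements.

The enrichment surface over minimum homology length l and minimum identity
id is

    E(l, id) = matched_CNVs(l, id) / (epsilon * n_pairs(l, id))

where matched_CNVs counts *distinct* CNVs matched by at least one pair
meeting both thresholds (a CNV matching several pairs counts once), and
n_pairs counts pairs meeting both thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnv_match import CnvCall, CnvPairMatch
from .io_formats import GenomeAssembly
from .pair_scan import PairAlignment

DEFAULT_L_GRID = (500, 1000, 2000, 3000, 4000, 5000)
DEFAULT_ID_GRID = (92.0, 93.0, 94.0, 95.0, 96.0, 97.0, 98.0, 99.0)


@dataclass
class EnrichmentGrid:
    l_grid: tuple[int, ...]
    id_grid: tuple[float, ...]
    enrichment: np.ndarray  # (len(l_grid), len(id_grid)); NaN where undefined
    matched_counts: np.ndarray
    pair_counts: np.ndarray
    epsilon: float

    def cell(self, l: int, identity: float) -> float:
        return float(
            self.enrichment[self.l_grid.index(l), self.id_grid.index(identity)]
        )


def expected_matches(cnvs: list[CnvCall], genome: GenomeAssembly) -> float:
    """epsilon: expected matched CNVs for one randomly placed pair."""
    g = genome.non_gap_length
    if g <= 0:
        raise ValueError("non-gap genome length must be positive")
    eps = 0.0
    for cnv in cnvs:
        lp = cnv.prox_end - cnv.prox_start
        ld = cnv.dist_end - cnv.dist_start
        eps += (lp / g) * (ld / g)
    return eps


def _border_factor(cnv: CnvCall, genome: GenomeAssembly) -> float:
    """Approximate correction for CNVs near chromosome/arm edges.

    A pair mediating this CNV needs both elements on one arm with the
    CNV's span between them; the number of valid placements shrinks near
    edges.  The factor G / sum_arms max(0, arm_len - span) rescales the
    CNV's epsilon contribution by the inverse of the fraction of the
    genome where the placement fits.  This is an approximation the module
    labels as such; the uncorrected estimator is the default.
    """
    span = cnv.dist_end - cnv.prox_start
    g = genome.non_gap_length
    valid = 0
    for chrom, seq in genome.sequences.items():
        cens = genome.centromeres.get(chrom)
        if cens:
            cen_s = min(s for s, _ in cens)
            cen_e = max(e for _, e in cens)
            arms = [(0, cen_s), (cen_e, len(seq))]
        else:
            arms = [(0, len(seq))]
        for s, e in arms:
            valid += max(0, (e - s) - span)
    if valid == 0:
        return 1.0
    return g / valid


def enrichment_grid(
    cnvs: list[CnvCall],
    pairs: list[PairAlignment],
    matches: list[CnvPairMatch],
    genome: GenomeAssembly,
    l_grid: tuple[int, ...] = DEFAULT_L_GRID,
    id_grid: tuple[float, ...] = DEFAULT_ID_GRID,
    border_correction: bool = False,
) -> EnrichmentGrid:
    """Enrichment surface over (minimum homology length, minimum identity).

    ``matches`` must come from matching this same pair set to this same
    CNV set.  Cells with no qualifying pairs are NaN (undefined), not 0.
    """
    g = genome.non_gap_length
    eps = 0.0
    for cnv in cnvs:
        lp = cnv.prox_end - cnv.prox_start
        ld = cnv.dist_end - cnv.dist_start
        term = (lp / g) * (ld / g)
        if border_correction:
            term *= _border_factor(cnv, genome)
        eps += term

    dd_pairs = [p for p in pairs if p.nahr_class == "deletion_duplication"]
    pair_len = {p.id: p.length for p in dd_pairs}
    pair_idy = {p.id: p.identity for p in dd_pairs}

    n_l, n_id = len(l_grid), len(id_grid)
    matched = np.zeros((n_l, n_id))
    counts = np.zeros((n_l, n_id), dtype=int)
    grid = np.full((n_l, n_id), np.nan)
    for i, l_min in enumerate(l_grid):
        for j, id_min in enumerate(id_grid):
            qualifying = {
                pid for pid in pair_len
                if pair_len[pid] >= l_min and pair_idy[pid] >= id_min
            }
            counts[i, j] = len(qualifying)
            matched[i, j] = len(
                {m.cnv_id for m in matches if m.pair_id in qualifying}
            )
            if counts[i, j] > 0 and eps > 0:
                grid[i, j] = matched[i, j] / (eps * counts[i, j])
    return EnrichmentGrid(
        l_grid=tuple(l_grid),
        id_grid=tuple(id_grid),
        enrichment=grid,
        matched_counts=matched,
        pair_counts=counts,
        epsilon=eps,
    )


# ---------------------------------------------------------------------------
# calibration fixtures
# ---------------------------------------------------------------------------

def _flat_genome(length: int) -> GenomeAssembly:
    return GenomeAssembly(sequences={"chr1": "A" * length})


def simulate_null_calibration(
    seed: int,
    n_cnvs: int = 500,
    n_pairs: int = 2000,
    genome_length: int = 2_000_000,
    region_width: int = 18_000,
    inner_gap: int = 4_000,
    element_length: int = 500,
) -> tuple[GenomeAssembly, list[CnvCall], list[PairAlignment]]:
    """A null fixture: CNVs fixed, pairs placed at random.

    Pairs are drawn with span uniform on the genome and location uniform
    given the span, which reproduces the ordered-point-pair placement the
    epsilon estimator assumes (to O(span/G) for short CNVs).  Elements are
    short (fragmentary copies) relative to the wide uncertainty regions so
    that element extent barely inflates the intersect probability; pair
    homology lengths are drawn in [400, 600] bp and identities in
    [97, 99.5] percent so every grid cell keeps a sizeable pair count.
    """
    rng = np.random.default_rng(seed)
    g = genome_length
    span_total = 2 * region_width + inner_gap
    cnvs = []
    for i in range(n_cnvs):
        x = int(rng.integers(0, g - span_total))
        inner_start = x + region_width
        inner_end = inner_start + inner_gap
        cnvs.append(
            CnvCall(
                id=f"null_{i}", sample="null", chromosome="chr1",
                inner_start=inner_start, inner_end=inner_end,
                prox_start=x, prox_end=inner_start,
                dist_start=inner_end, dist_end=inner_end + region_width,
                kind="loss", median_log2=-1.0, n_probes=3,
            )
        )
    pairs = []
    for i in range(n_pairs):
        span = int(rng.integers(2 * element_length, g - 2 * element_length))
        a = int(rng.integers(0, g - span - element_length))
        b = a + span
        pairs.append(
            PairAlignment(
                id=f"np_{i}", element_a=f"na_{i}", element_b=f"nb_{i}",
                chrom_a="chr1", chrom_b="chr1",
                a_start=a, a_end=a + element_length,
                b_start=b, b_end=b + element_length,
                orientation="direct",
                length=int(rng.integers(400, 601)),
                identity=float(rng.uniform(97.0, 99.5)),
                evalue=0.0, score=1.0, nahr_class="deletion_duplication",
                element_length_a=element_length, element_length_b=element_length,
            )
        )
    return _flat_genome(g), cnvs, pairs


def simulate_planted_enrichment(
    seed: int,
    n_pairs: int = 40,
    genome_length: int = 2_000_000,
    element_length: int = 5000,
    region_width: int = 5000,
) -> tuple[GenomeAssembly, list[CnvCall], list[PairAlignment]]:
    """A signal fixture: every CNV planted at a high-identity pair."""
    rng = np.random.default_rng(seed)
    g = genome_length
    pairs, cnvs = [], []
    slot = g // n_pairs
    for i in range(n_pairs):
        a = i * slot + 5000
        b = a + int(rng.integers(15_000, slot - 12_000))
        pairs.append(
            PairAlignment(
                id=f"pp_{i}", element_a=f"pa_{i}", element_b=f"pb_{i}",
                chrom_a="chr1", chrom_b="chr1",
                a_start=a, a_end=a + element_length,
                b_start=b, b_end=b + element_length,
                orientation="direct",
                length=int(rng.integers(4000, 6001)),
                identity=float(rng.uniform(97.0, 99.5)),
                evalue=0.0, score=1.0, nahr_class="deletion_duplication",
                element_length_a=element_length, element_length_b=element_length,
            )
        )
        prox_start = a - region_width // 2
        dist_end = b + element_length + region_width // 2
        cnvs.append(
            CnvCall(
                id=f"pc_{i}", sample="planted", chromosome="chr1",
                inner_start=prox_start + region_width,
                inner_end=dist_end - region_width,
                prox_start=prox_start, prox_end=prox_start + region_width,
                dist_start=dist_end - region_width, dist_end=dist_end,
                kind="loss", median_log2=-1.0, n_probes=5,
            )
        )
    return _flat_genome(g), cnvs, pairs


def monte_carlo_epsilon(
    cnvs: list[CnvCall], genome: GenomeAssembly, n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """MC oracle for epsilon: random ordered point-pair placements.

    Draws (proximal point, distal point) uniformly and counts, per draw,
    the CNVs whose proximal region contains the first point and distal
    region the second.
    """
    rng = np.random.default_rng(seed)
    g = genome.non_gap_length
    x = rng.integers(0, g, size=n_draws)
    y = rng.integers(0, g, size=n_draws)
    order = np.argsort(x)
    xs = x[order]
    ys = y[order]
    hits = 0
    for c in cnvs:  # regions may overlap across CNVs: count every CNV hit
        lo = np.searchsorted(xs, c.prox_start, side="left")
        hi = np.searchsorted(xs, c.prox_end, side="left")
        yy = ys[lo:hi]
        hits += int(np.count_nonzero((yy >= c.dist_start) & (yy < c.dist_end)))
    return hits / n_draws


def plot_grid(grid: EnrichmentGrid, path: str) -> None:
    """Heatmap of the enrichment surface (log scale where positive)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.enrichment, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(grid.id_grid)), [f"{x:g}" for x in grid.id_grid])
    ax.set_yticks(range(len(grid.l_grid)), [f"{x}" for x in grid.l_grid])
    ax.set_xlabel("minimum identity (%)")
    ax.set_ylabel("minimum homology length (bp)")
    fig.colorbar(im, ax=ax, label="observed / expected matched CNVs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
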