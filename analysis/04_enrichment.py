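"""Enrichment of LINE pairs at CNV breakpoint-uncertainty regions.

Two synthetic experiments bracket the estimator's behavior:
(i) a null in which pairs are placed at random relative to a fixed CNV
set — every cell of the E(l, id) surface should sit near 1; and
(ii) a planted configuration in which every CNV straddles a >= 97%
identity pair — the high-identity cells should be enriched by orders of
magnitude, the pattern that implicates high-identity pairs as NAHR
mediators.  Writes enrichment_null.tsv / enrichment_planted.tsv and a
heatmap under results/study/.
"""

from pathlib import Path

import numpy as np

from linenahr.cnv_match import match_pairs_to_cnvs
from linenahr.enrichment import (
    enrichment_grid,
    expected_matches,
    monte_carlo_epsilon,
    plot_grid,
    simulate_null_calibration,
    simulate_planted_enrichment,
)

OUT = Path("results/study")
SEED = 20_240_104 % 2**16


def write_grid(grid, path) -> None:
    with open(path, "w") as fh:
        fh.write("min_length\tmin_identity\tenrichment\tmatched\tpairs\n")
        for i, l in enumerate(grid.l_grid):
            for j, idy in enumerate(grid.id_grid):
                fh.write(
                    f"{l}\t{idy}\t{grid.enrichment[i, j]:.6g}"
                    f"\t{int(grid.matched_counts[i, j])}\t{int(grid.pair_counts[i, j])}\n"
                )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    genome, cnvs, pairs = simulate_null_calibration(seed=SEED)
    matches = match_pairs_to_cnvs(cnvs, pairs)
    null = enrichment_grid(
        cnvs, pairs, matches, genome,
        l_grid=(100, 200, 300, 400, 500),
        id_grid=(92.0, 93.0, 94.0, 95.0, 96.0, 97.0, 98.0, 99.0),
    )
    eps = expected_matches(cnvs, genome)
    mc = monte_carlo_epsilon(cnvs, genome, seed=SEED + 1)
    write_grid(null, OUT / "enrichment_null.tsv")
    print(f"null: epsilon = {eps:.4f} (MC oracle {mc:.4f}, "
          f"{100 * abs(mc - eps) / eps:.2f}% apart)")
    print(f"null surface mean {np.nanmean(null.enrichment):.3f} "
          f"(range {np.nanmin(null.enrichment):.2f}..{np.nanmax(null.enrichment):.2f}) "
          f"— calibrated near 1")

    g2, c2, p2 = simulate_planted_enrichment(seed=SEED + 2)
    m2 = match_pairs_to_cnvs(c2, p2)
    planted = enrichment_grid(c2, p2, m2, g2)
    write_grid(planted, OUT / "enrichment_planted.tsv")
    plot_grid(planted, str(OUT / "enrichment_planted.png"))
    print(f"planted: E(1 kb, 97%) = {planted.cell(1000, 97.0):.0f} — CNVs "
          f"planted at high-identity pairs dominate the expected rate")


if __name__ == "__main__":
    main()
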