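"""Emit hybrid junction templates for LR-PCR primer design.

For every kept deletion/duplication pair, builds the chimeric reference
(unique upstream flank + homology + unique downstream flank) for both the
deletion and the reciprocal duplication junction, checks the implied
amplicon length against the 7-15 kb LR-PCR window, and writes the FASTA
plus Primer3 Boulder-IO records under results/study/.
"""

from pathlib import Path

import pandas as pd

from linenahr import io_formats, junction

OUT = Path("results/study")
FLANK = 4000


def main() -> None:
    genome = io_formats.GenomeAssembly(
        sequences=io_formats.read_fasta(OUT / "genome.fasta")
    )
    # same id convention as the scan stage, which read repeats.bed
    els = {e.id: e for e in io_formats.read_repeat_table(OUT / "repeats.bed", "bed6")}
    pairs = pd.read_csv(OUT / "pairs.tsv", sep="\t")
    dd = pairs[pairs.nahr_class == "deletion_duplication"]

    hybrids = {}
    n_in_window = 0
    with open(OUT / "primer3_input.txt", "w") as p3:
        for row in dd.itertuples(index=False):
            a, b = els[row.element_a], els[row.element_b]
            for event in ("deletion", "duplication"):
                for hyb in junction.hybrid_sequence(genome, a, b, event,
                                                    flank_len=FLANK, pair_id=row.id):
                    hybrids[f"{hyb.pair_id}|{hyb.event_type}"] = hyb.sequence
                    p3.write(junction.boulder_io_record(hyb))
                    amplicon = junction.expected_amplicon(
                        hyb, (100, 120), (len(hyb.sequence) - 120, len(hyb.sequence) - 100)
                    )
                    n_in_window += 7000 <= amplicon <= 15_000
    io_formats.write_fasta(hybrids, OUT / "hybrids.fasta")
    print(f"{len(dd)} del/dup pairs -> {len(hybrids)} hybrid templates")
    print(f"{n_in_window}/{len(hybrids)} near-full-template amplicons fall in "
          f"the 7-15 kb LR-PCR window")
    print(f"wrote {OUT}/hybrids.fasta and primer3_input.txt")


if __name__ == "__main__":
    main()
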