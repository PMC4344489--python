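"""Scan the study genome for NAHR-capable LINE pairs.

Reads the genome + annotation produced by 01_simulate_genome.py, runs the
all-vs-all pair scan with the filter cascade, classifies survivors, and
reports the funnel (extracted -> HSPs -> kept -> classified) together with
the fraction of the genome susceptible to deletion/duplication NAHR.
Writes pairs.tsv, rejected.tsv and coverage.bedgraph under results/study/.
"""

from pathlib import Path

from linenahr import io_formats, pair_scan

OUT = Path("results/study")


def main() -> None:
    genome = io_formats.GenomeAssembly(
        sequences=io_formats.read_fasta(OUT / "genome.fasta")
    )
    repeats = io_formats.read_repeat_table(OUT / "repeats.bed", "bed6")
    params = pair_scan.ScanParams(flank_tolerance=10)
    result = pair_scan.scan_genome(genome, repeats, params)

    io_formats.dataclass_table(result.pairs, OUT / "pairs.tsv")
    with open(OUT / "rejected.tsv", "w") as fh:
        fh.write("element_a\telement_b\treason\tidentity\tlength\n")
        for ea, eb, hsp, reason in result.rejected:
            fh.write(f"{ea}\t{eb}\t{reason}\t{hsp.identity:.2f}\t{hsp.length}\n")
    with open(OUT / "coverage.bedgraph", "w") as fh:
        for chrom, runs in result.depth.items():
            for s, e, d in runs:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")

    print(f"elements extracted: {len(result.elements)}")
    print(f"pairs kept: {len(result.pairs)} "
          f"({sum(p.nahr_class == 'deletion_duplication' for p in result.pairs)} del/dup)")
    print(f"HSPs rejected: {len(result.rejected)}")
    for p in result.pairs:
        print(f"  {p.element_a} x {p.element_b}: {p.identity:.1f}% over "
              f"{p.length} bp, {p.nahr_class}, span {p.span:,} bp")
    print(f"susceptibility: {100 * result.coverage:.1f}% of the genome lies "
          f"between at least one del/dup pair")


if __name__ == "__main__":
    main()
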