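"""Build the synthetic study genome: planted LINE families with known truth.

One 500 kb chromosome carries a six-copy LINE family at 97% pairwise
identity plus a planted heterozygous deletion between copies 0 and 1, the
configuration every later analysis step consumes.  Writes the genome
FASTA, the repeat annotation, the probe track, the junction reads, and the
truth tables under results/study/.
"""

from pathlib import Path

from linenahr import io_formats, synthetic

OUT = Path("results/study")
SEED = 20_240_101 % 2**16

CONFIG = synthetic.SimulationConfig(
    seed=SEED,
    chromosomes={"chr1": 500_000},
    families=[
        synthetic.FamilySpec(name="L1A", n_copies=6, length=6000, target_identity=97.0),
    ],
    events=[
        synthetic.PlantedEvent(
            family="L1A", copy_a=0, copy_b=1, event_type="deletion",
            crossover=3000, sample="case1",
        )
    ],
    probe_spacing=1000,
    log2_sd=0.15,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, truth = synthetic.make_genome(CONFIG)
    io_formats.write_fasta(genome.sequences, OUT / "genome.fasta")
    io_formats.write_repeat_bed6(truth.elements, OUT / "repeats.bed")
    io_formats.dataclass_table(truth.elements, OUT / "elements.tsv")
    io_formats.dataclass_table(truth.cnvs, OUT / "cnv_truth.tsv")

    track = synthetic.simulate_probes(
        genome, truth.cnvs, CONFIG.probe_spacing, CONFIG.log2_sd,
        seed=SEED + 1, sample="case1",
    )
    io_formats.write_probe_track(track, OUT / "probes.tsv")

    by_id = {e.id: e for e in truth.elements}
    ev = CONFIG.events[0]
    outcome = synthetic.apply_nahr(
        genome, by_id["L1A_0"], by_id["L1A_1"], ev.event_type, ev.crossover
    )
    reads, _ = synthetic.simulate_junction_reads(
        outcome.haplotype, outcome.junction, n_reads=4, read_length=600,
        quality=40, seed=SEED + 2, name_prefix="case1",
    )
    io_formats.write_fastq(reads, OUT / "junction_reads.fastq")

    print(f"genome: {sum(map(len, genome.sequences.values())):,} bp, "
          f"{len(truth.elements)} planted LINEs")
    print(f"planted deletion: chr1:{truth.cnvs[0].start:,}-{truth.cnvs[0].end:,} "
          f"({truth.cnvs[0].end - truth.cnvs[0].start:,} bp)")
    print(f"wrote {OUT}/genome.fasta, repeats.bed, probes.tsv, junction_reads.fastq")


if __name__ == "__main__":
    main()
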