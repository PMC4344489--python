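"""Plain-file pipeline: simulate -> scan -> match -> enrich -> breakpoint -> design.

Stages exchange TSV/FASTA/FASTQ files on disk (no workflow engine) so every
intermediate is inspectable; a run writes a manifest with sha256 checksums
of every artifact, and a rerun with the same config and seed reproduces the
checksums exactly.  Stage logs report record counts after every filter,
mirroring the scan funnel (extracted -> HSPs -> filtered -> classified ->
matched).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cnv_match, enrichment, hmm, io_formats, junction, pair_scan, synthetic

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    scan: dict = field(default_factory=dict)  # ScanParams overrides
    stringent: bool = False
    loss_threshold: float = -0.3
    gain_threshold: float = 0.3
    min_probes: int = 3
    reciprocal_overlap: float = 0.9
    l_grid: list = field(default_factory=lambda: list(enrichment.DEFAULT_L_GRID))
    id_grid: list = field(default_factory=lambda: list(enrichment.DEFAULT_ID_GRID))
    border_correction: bool = False
    n_reads_per_case: int = 4
    design_flank: int = 3000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulation_config(cfg: RunConfig) -> synthetic.SimulationConfig:
    sim = dict(cfg.simulate)
    fams = sim.pop("families", None)
    events = sim.pop("events", None)
    sc = synthetic.SimulationConfig(seed=cfg.seed, **sim)
    if fams is not None:
        sc.families = [synthetic.FamilySpec(**f) for f in fams]
    if events is not None:
        sc.events = [synthetic.PlantedEvent(**e) for e in events]
    return sc


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"outputs": {}, "counts": {}, "seed": config.seed}

    def emit(name: str) -> None:
        manifest["outputs"][name] = _sha256(out / name)

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        sim_cfg = _simulation_config(config)
        genome, truth = synthetic.make_genome(sim_cfg)
        io_formats.write_fasta(genome.sequences, out / "genome.fasta")
        io_formats.write_repeat_bed6(truth.elements, out / "repeats.bed")
        io_formats.dataclass_table(truth.elements, out / "elements.tsv")
        if truth.cnvs:
            io_formats.dataclass_table(truth.cnvs, out / "cnv_truth.tsv")
            emit("cnv_truth.tsv")
        track = synthetic.simulate_probes(
            genome, truth.cnvs, sim_cfg.probe_spacing, sim_cfg.log2_sd,
            seed=config.seed + 1, sample="case",
        )
        io_formats.write_probe_track(track, out / "probes.tsv")
        by_id = {e.id: e for e in truth.elements}
        case_reads: dict[str, list] = {}
        case_pairs: dict[str, tuple[str, str]] = {}
        for ev in sim_cfg.events:
            a = by_id[f"{ev.family}_{ev.copy_a}"]
            b = by_id[f"{ev.family}_{ev.copy_b}"]
            outcome = synthetic.apply_nahr(genome, a, b, ev.event_type, ev.crossover)
            reads, _ = synthetic.simulate_junction_reads(
                outcome.haplotype, outcome.junction,
                n_reads=config.n_reads_per_case,
                read_length=sim_cfg.read_length,
                quality=sim_cfg.read_quality,
                seed=config.seed + 100 + len(case_reads),
                name_prefix=ev.sample,
            )
            case_reads[ev.sample] = reads
            case_pairs[ev.sample] = (a.id, b.id)
        if case_reads:
            io_formats.write_fastq(
                [r for rs in case_reads.values() for r in rs], out / "junction_reads.fastq"
            )
            emit("junction_reads.fastq")
        emit("genome.fasta")
        emit("repeats.bed")
        emit("elements.tsv")
        emit("probes.tsv")
        manifest["counts"]["elements"] = len(truth.elements)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, str(exc)) from exc

    # --- scan ---------------------------------------------------------
    stage = "scan"
    try:
        params = pair_scan.ScanParams(**config.scan)
        if config.stringent:
            params = params.stringent()
        scan = pair_scan.scan_genome(genome, truth.elements, params)
        io_formats.dataclass_table(scan.pairs, out / "pairs.tsv")
        with open(out / "rejected.tsv", "w") as fh:
            fh.write("element_a\telement_b\treason\tidentity\tlength\n")
            for ea, eb, hsp, reason in scan.rejected:
                fh.write(f"{ea}\t{eb}\t{reason}\t{hsp.identity:.2f}\t{hsp.length}\n")
        with open(out / "coverage.bedgraph", "w") as fh:
            for chrom, runs in scan.depth.items():
                for s, e, d in runs:
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")
        emit("pairs.tsv")
        emit("rejected.tsv")
        emit("coverage.bedgraph")
        manifest["counts"].update(
            pairs_kept=len(scan.pairs),
            hsps_rejected=len(scan.rejected),
            susceptibility_fraction=scan.coverage,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- match --------------------------------------------------------
    stage = "match"
    try:
        cnvs = cnv_match.call_cnvs(
            track, config.loss_threshold, config.gain_threshold, config.min_probes
        )
        kept, _removed = cnv_match.dp_lcr_filter(cnvs, [])
        unique = cnv_match.dedupe_cnvs(kept, config.reciprocal_overlap)
        matches = cnv_match.match_pairs_to_cnvs(unique, scan.pairs, stringent=False)
        io_formats.dataclass_table(unique, out / "cnvs.tsv") if unique else (out / "cnvs.tsv").write_text("")
        io_formats.dataclass_table(matches, out / "matches.tsv") if matches else (out / "matches.tsv").write_text("")
        emit("cnvs.tsv")
        emit("matches.tsv")
        manifest["counts"].update(cnvs=len(unique), matches=len(matches))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- enrich -------------------------------------------------------
    stage = "enrich"
    try:
        grid = enrichment.enrichment_grid(
            unique, scan.pairs, matches, genome,
            tuple(config.l_grid), tuple(config.id_grid),
            border_correction=config.border_correction,
        )
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("min_length\tmin_identity\tenrichment\tmatched\tpairs\n")
            for i, l in enumerate(grid.l_grid):
                for j, idy in enumerate(grid.id_grid):
                    fh.write(
                        f"{l}\t{idy}\t{grid.enrichment[i, j]:.6g}"
                        f"\t{int(grid.matched_counts[i, j])}\t{int(grid.pair_counts[i, j])}\n"
                    )
        emit("enrichment.tsv")
        manifest["counts"]["epsilon"] = grid.epsilon
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- breakpoint ---------------------------------------------------
    stage = "breakpoint"
    try:
        with open(out / "breakpoints.tsv", "w") as fh:
            fh.write("sample\tinterval_start\tinterval_end\tlength_bp\tposterior\tn_reads\n")
            for sample, reads in case_reads.items():
                a_id, b_id = case_pairs[sample]
                call = hmm.call_case(
                    reads, truth.element_seqs[a_id], truth.element_seqs[b_id]
                )
                fh.write(
                    f"{sample}\t{call.map_interval[0]}\t{call.map_interval[1]}"
                    f"\t{call.map_length}\t{call.map_mass:.4f}\t{call.n_reads}\n"
                )
        emit("breakpoints.tsv")
        manifest["counts"]["cases"] = len(case_reads)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- design -------------------------------------------------------
    stage = "design"
    try:
        hybrids: dict[str, str] = {}
        with open(out / "primer3_input.txt", "w") as p3, open(out / "junctions.tsv", "w") as jt:
            jt.write("pair_id\tevent\tjunction_start\tjunction_end\thybrid_length\n")
            for pair in scan.pairs:
                if pair.nahr_class != "deletion_duplication":
                    continue
                a, b = by_id[pair.element_a], by_id[pair.element_b]
                for event in ("deletion", "duplication"):
                    for hyb in junction.hybrid_sequence(
                        genome, a, b, event, flank_len=config.design_flank, pair_id=pair.id
                    ):
                        name = f"{hyb.pair_id}|{hyb.event_type}"
                        hybrids[name] = hyb.sequence
                        p3.write(junction.boulder_io_record(hyb))
                        jt.write(
                            f"{hyb.pair_id}\t{hyb.event_type}\t{hyb.junction_start}"
                            f"\t{hyb.junction_end}\t{len(hyb.sequence)}\n"
                        )
        io_formats.write_fasta(hybrids, out / "hybrids.fasta")
        emit("hybrids.fasta")
        emit("primer3_input.txt")
        emit("junctions.tsv")
        manifest["counts"]["hybrid_templates"] = len(hybrids)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def demo_config(outdir: str = "results/demo", seed: int = 0) -> RunConfig:
    """A small complete run: one family, one planted deletion case."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        simulate={
            "chromosomes": {"chr1": 300_000},
            "families": [
                {"name": "L1DEMO", "n_copies": 3, "length": 4000, "target_identity": 97.5}
            ],
            "events": [
                {
                    "family": "L1DEMO",
                    "copy_a": 0,
                    "copy_b": 1,
                    "event_type": "deletion",
                    "crossover": 2000,
                    "sample": "case",
                }
            ],
            "probe_spacing": 2000,
            "log2_sd": 0.12,
        },
        scan={"flank_length": 1500, "flank_tolerance": 10},
        design_flank=1500,
    )
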