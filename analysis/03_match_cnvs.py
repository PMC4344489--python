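"""Call the CNV from the probe track and match it to candidate LINE pairs.

Thresholded-run calling on the noisy log2 track brackets each breakpoint
between the last normal and first aberrant probe; the planted deletion
should be matched to exactly its generating pair by the
uncertainty-region intersection rule.  Writes cnvs.tsv and matches.tsv.
"""

from pathlib import Path

import pandas as pd

from linenahr import cnv_match, io_formats
from linenahr.pair_scan import PairAlignment

OUT = Path("results/study")


def load_pairs(path) -> list[PairAlignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        if row.get("span") != row.get("span"):  # NaN for translocations
            row["span"] = None
        out.append(PairAlignment(**row))
    return out


def main() -> None:
    track = io_formats.read_probe_track(OUT / "probes.tsv")
    cnvs = cnv_match.call_cnvs(track, loss_thr=-0.3, gain_thr=0.3, min_probes=3)
    kept, removed = cnv_match.dp_lcr_filter(cnvs, [])  # no segdups planted
    unique = cnv_match.dedupe_cnvs(kept)
    pairs = load_pairs(OUT / "pairs.tsv")
    matches = cnv_match.match_pairs_to_cnvs(unique, pairs)

    io_formats.dataclass_table(unique, OUT / "cnvs.tsv")
    pd.DataFrame([m.__dict__ for m in matches]).to_csv(
        OUT / "matches.tsv", sep="\t", index=False
    )

    truth = pd.read_csv(OUT / "cnv_truth.tsv", sep="\t")
    print(f"CNV calls: {len(unique)} (DP-LCR removed {len(removed)})")
    for c in unique:
        print(f"  {c.kind} {c.chromosome}:{c.inner_start:,}-{c.inner_end:,} "
              f"median log2 {c.median_log2:.2f}, "
              f"uncertainty regions {c.proximal_region} / {c.distal_region}")
    print(f"planted truth: {truth.iloc[0]['kind']} "
          f"{truth.iloc[0]['chrom']}:{truth.iloc[0]['start']:,}-{truth.iloc[0]['end']:,}")
    print(f"pair matches: {len(matches)}")
    for m in matches:
        print(f"  CNV {m.cnv_id} <- pair {m.pair_id} "
              f"({m.identity:.1f}% over {m.homology_length} bp)")


if __name__ == "__main__":
    main()
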