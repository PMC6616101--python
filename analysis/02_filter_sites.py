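#!/usr/bin/env python
"""Cluster cleavage events into poly(A) site clusters and filter artifacts.

Reads results/data/, chains events within 24 nt, applies the A-rich
internal-priming rules to each cluster's downstream window, and writes the
per-site filter report to results/filter_report.tsv.
"""

import argparse
from pathlib import Path

from polyasig.io import Genome, read_events_bed
from polyasig.sites import cluster_cleavage_events, filter_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--max-gap", type=int, default=24)
    args = ap.parse_args()

    genome = Genome(args.datadir / "genome.fa")
    events, _ = read_events_bed(args.datadir / "events.bed",
                                args.datadir / "counts.tsv")
    clusters = cluster_cleavage_events(events, max_gap=args.max_gap)
    report = filter_report(clusters, genome)
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "filter_report.tsv", sep="\t", index=False)

    n_pass = int((report.status == "pass").sum())
    print(f"{len(events)} events -> {len(clusters)} poly(A) site clusters")
    print(f"{len(clusters) - n_pass} clusters removed as internal-priming "
          f"candidates ({100 * (1 - n_pass / len(clusters)):.1f}%):")
    print(report.status.value_counts().to_string())
    print(f"wrote {args.out / 'filter_report.tsv'}")


if __name__ == "__main__":
    main()
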