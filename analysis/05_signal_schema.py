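#!/usr/bin/env python
"""Discover poly(A) signal elements per genomic region.

Extracts -300..+100 flanks for passing sites, runs the greedy
Markov-background selection in the 3' UTR positioning element (-34..-13),
then builds the full per-class element schema (windows -> significant
hexamers -> clustered consensus elements with PFMs).
"""

import argparse
from pathlib import Path

import pandas as pd

from polyasig.genes import read_gff3
from polyasig.io import Genome, read_events_bed
from polyasig.motifs import greedy_signal_selection
from polyasig.schema import build_schema, nucleotide_profile, write_pfms
from polyasig.sites import cluster_cleavage_events, extract_flank, filter_a_rich


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--resultdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    genome = Genome(args.datadir / "genome.fa")
    read_gff3(args.datadir / "annotation.gff3")  # validates the annotation
    events, _ = read_events_bed(args.datadir / "events.bed",
                                args.datadir / "counts.tsv")
    clusters = cluster_cleavage_events(events)
    passing = {c.cluster_id: c for c in clusters
               if filter_a_rich(c, genome) == "pass"}
    ann = pd.read_csv(args.resultdir / "annotations.tsv", sep="\t")

    flanks_by_class = {}
    for cls in ("3UTR", "5UTR", "CDS", "intron"):
        ids = ann.site_id[ann.region == cls]
        flanks_by_class[cls] = [extract_flank(passing[i], genome)
                                for i in ids if i in passing]
        print(f"{cls}: {len(flanks_by_class[cls])} flanks")

    hits = greedy_signal_selection(flanks_by_class["3UTR"], (-34, -13))
    print("\ngreedy PE selection (3' UTR sites):")
    for h in hits:
        print(f"  {h.kmer}  O={h.o_observed} E={h.o_expected:.1f} "
              f"p={h.p_value:.3g} pos={h.mean_pos:.1f}±{h.pos_sd:.1f} "
              f"coverage={h.coverage:.1%}")

    reports = build_schema(flanks_by_class)
    tables = [r.table for r in reports.values() if len(r.table)]
    elements = pd.concat(tables, ignore_index=True) if tables \
        else pd.DataFrame()
    elements.to_csv(args.resultdir / "elements.tsv", sep="\t", index=False)
    all_el = [e for r in reports.values() for e in r.elements]
    if all_el:
        write_pfms(all_el, args.resultdir / "elements_pfm.jaspar")
    prof = nucleotide_profile(flanks_by_class["3UTR"])
    prof.to_csv(args.resultdir / "nucleotide_profile_3UTR.tsv", sep="\t")
    print(f"\n{len(all_el)} cis elements across "
          f"{sum(len(r.table.window.unique()) for r in reports.values())} "
          "windows; element table:")
    if len(elements):
        print(elements.to_string(index=False, max_rows=30))


if __name__ == "__main__":
    main()
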