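#!/usr/bin/env python
"""Assign filtered sites to genomic regions and relate APA to gene structure.

Writes annotations, per-gene APA statistics, and the Pearson correlation
matrix between APA frequency and gene length / intron count / per-region
frequencies.
"""

import argparse
from pathlib import Path

import pandas as pd

from polyasig.annotate import (annotate_sites, apa_ratio, correlation_matrix,
                               gene_apa_stats)
from polyasig.genes import read_gff3
from polyasig.io import Genome, read_events_bed
from polyasig.sites import cluster_cleavage_events, filter_a_rich


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--extension", type=int, default=1000)
    args = ap.parse_args()

    genome = Genome(args.datadir / "genome.fa")
    genes = read_gff3(args.datadir / "annotation.gff3")
    events, _ = read_events_bed(args.datadir / "events.bed",
                                args.datadir / "counts.tsv")
    clusters = cluster_cleavage_events(events)
    passing = [c for c in clusters if filter_a_rich(c, genome) == "pass"]

    ann = annotate_sites(passing, genes, extension=args.extension)
    stats = gene_apa_stats(ann, genes)
    r, p = correlation_matrix(stats)
    args.out.mkdir(parents=True, exist_ok=True)
    ann.to_csv(args.out / "annotations.tsv", sep="\t", index=False)
    stats.to_csv(args.out / "gene_apa_stats.tsv", sep="\t")
    r.to_csv(args.out / "correlation_r.tsv", sep="\t")
    p.to_csv(args.out / "correlation_p.tsv", sep="\t")

    print(f"annotated {len(ann)} passing sites:")
    print(ann.region.value_counts().to_string())
    print("\nAPA gene categories:")
    print(stats.category.value_counts().to_string())
    ratios = {reg: apa_ratio(ann, reg)
              for reg in ("3UTR", "CDS", "intron", "5UTR")}
    print("\nAPA ratio (sites per site-bearing gene) by region:")
    print(pd.Series(ratios).round(2).to_string())
    print(f"\nr(total APA freq, gene length) = "
          f"{r.loc['total', 'length']:.2f} "
          f"(p = {p.loc['total', 'length']:.2g})")
    print(f"r(total APA freq, intron count) = "
          f"{r.loc['total', 'intron_count']:.2f}")


if __name__ == "__main__":
    main()
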