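#!/usr/bin/env python
"""Classify sites by polyadenylation efficiency and sample matched controls.

Strong sites carry >70% of their gene's pooled reads; weak sites are their
siblings; multi-site genes without a strong site have universal sites;
single-site genes have unique sites. Controls are genomic AAUAAA positions
with no real site within 50 nt of the signal.
"""

import argparse
from pathlib import Path

import pandas as pd

from polyasig.classify import classify_sites, sample_control_sites
from polyasig.io import Genome


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--resultdir", type=Path, default=Path("results"))
    ap.add_argument("--n-controls", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    ann = pd.read_csv(args.resultdir / "annotations.tsv", sep="\t")
    in_gene = ann[ann.gene_id.notna() & (ann.gene_id != "")]
    classes = classify_sites(in_gene[["site_id", "gene_id", "total_reads"]])
    classes.to_csv(args.resultdir / "usage_classes.tsv", sep="\t")
    print("usage classes over", len(classes), "genic sites:")
    print(classes["class"].value_counts().to_string())

    genome = Genome(args.datadir / "genome.fa")
    controls = sample_control_sites(genome, ann[["chrom", "position"]],
                                    n=args.n_controls, seed=args.seed)
    controls.to_csv(args.resultdir / "control_sites.tsv", sep="\t",
                    index=False)
    print(f"\nsampled {len(controls)} control pseudo-sites "
          "(AAUAAA, no real site within 50 nt)")


if __name__ == "__main__":
    main()
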