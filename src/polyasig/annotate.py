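"""Genomic-region assignment of poly(A) sites and per-gene APA statistics.

Each passing site is assigned exactly one region label. Within annotated
transcripts the precedence across overlapping same-strand features is
3UTR > CDS > 5UTR > intron (favouring mature-mRNA assignments). Sites
outside every same-strand transcript but within ``extension`` nt downstream
of an annotated 3' end become Ex_3UTR (extended 3' UTR, with the distance
recorded); the mirror case upstream of a 5' end becomes Ex_5UTR; everything
else is intergenic. Antisense overlap does not count: assignment is
strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genes import GeneModel

REGIONS = ["3UTR", "Ex_3UTR", "5UTR", "Ex_5UTR", "CDS", "intron", "intergenic"]
_PRECEDENCE = ["3UTR", "CDS", "5UTR", "intron"]


@dataclass
class SiteAnnotation:
    site_id: str
    gene_id: str          # "" for intergenic
    region: str
    distance: int = 0     # to the annotated 3'/5' end, for Ex_* regions


class RegionIndex:
    """Interval lookup over gene models, per (chromosome, strand)."""

    def __init__(self, genes: list[GeneModel]):
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        self.tes: dict[tuple[str, str], list[tuple[int, str]]] = {}
        self.tss: dict[tuple[str, str], list[tuple[int, str]]] = {}
        self.genes = {g.gene_id: g for g in genes}
        for g in genes:
            key = (g.chrom, g.strand)
            tree = self.trees.setdefault(key, IntervalTree())
            for region, ivs in (("3UTR", g.utr3), ("CDS", g.cds),
                                ("5UTR", g.utr5), ("intron", g.introns)):
                for s, e in ivs:
                    tree[s:e + 1] = (region, g.gene_id)
            self.tes.setdefault(key, []).append((g.tes, g.gene_id))
            self.tss.setdefault(key, []).append((g.tss, g.gene_id))


def assign_region(chrom: str, strand: str, position: int, index: RegionIndex,
                  extension: int = 1000, site_id: str = "") -> SiteAnnotation:
    """Assign one region label to a site (see module docstring for rules)."""
    key = (chrom, strand)
    hits = index.trees.get(key, IntervalTree())[position]
    if hits:
        found = {d[0]: d[1] for _, _, d in
                 sorted((iv.begin, iv.end, iv.data) for iv in hits)}
        for region in _PRECEDENCE:
            if region in found:
                return SiteAnnotation(site_id, found[region], region)
    sign = 1 if strand == "+" else -1
    best = None  # (distance, gene_id, region)
    for tes, gid in index.tes.get(key, []):
        d = sign * (position - tes)
        if 1 <= d <= extension and (best is None or d < best[0]):
            best = (d, gid, "Ex_3UTR")
    if best is None:
        for tss, gid in index.tss.get(key, []):
            d = sign * (tss - position)
            if 1 <= d <= extension and (best is None or d < best[0]):
                best = (d, gid, "Ex_5UTR")
    if best is not None:
        return SiteAnnotation(site_id, best[1], best[2], distance=best[0])
    return SiteAnnotation(site_id, "", "intergenic")


def annotate_sites(clusters, genes: list[GeneModel],
                   extension: int = 1000) -> pd.DataFrame:
    """Annotate a list of PolyACluster; returns one row per site."""
    index = RegionIndex(genes)
    rows = []
    for c in clusters:
        ann = assign_region(c.chrom, c.strand, c.representative, index,
                            extension, site_id=c.cluster_id)
        biotype = (index.genes[ann.gene_id].biotype if ann.gene_id else "")
        rows.append((ann.site_id, c.chrom, c.strand, c.representative,
                     ann.gene_id, ann.region, ann.distance, c.total, biotype))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "strand", "position",
                                       "gene_id", "region", "distance",
                                       "total_reads", "biotype"])


def apa_gene_category(total: int) -> str:
    """0 sites -> non, 1 -> rare, 2-4 -> moderate, >4 -> abundant."""
    if total < 0:
        raise ValueError("negative site count")
    if total == 0:
        return "non"
    if total == 1:
        return "rare"
    if total <= 4:
        return "moderate"
    return "abundant"


def gene_apa_stats(annotations: pd.DataFrame,
                   genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene APA frequency table: counts per region, structure covariates.

    Proximal counts pool 5' UTR, CDS and intron sites; distal counts pool
    3' UTR and extended 3' UTR sites.
    """
    per_gene = annotations[annotations.gene_id != ""].groupby(
        ["gene_id", "region"]).size().unstack(fill_value=0)
    rows = []
    for g in genes:
        counts = {r: int(per_gene.loc[g.gene_id, r])
                  if g.gene_id in per_gene.index and r in per_gene.columns else 0
                  for r in REGIONS if r != "intergenic"}
        total = sum(counts.values())
        introns = g.introns
        rows.append({
            "gene_id": g.gene_id, "length": g.length,
            "intron_count": len(introns),
            "mean_intron_length": float(np.mean([e - s + 1 for s, e in introns]))
            if introns else 0.0,
            **{f"n_{r}": c for r, c in counts.items()},
            "total": total,
            "proximal": counts["5UTR"] + counts["CDS"] + counts["intron"],
            "distal": counts["3UTR"] + counts["Ex_3UTR"],
            "category": apa_gene_category(total),
        })
    return pd.DataFrame(rows).set_index("gene_id")


def apa_ratio(annotations: pd.DataFrame, region: str | None = None
              ) -> float | None:
    """Sites per site-bearing gene, optionally restricted to one region.

    Returns None when no gene owns a site in the region (ratio undefined).
    """
    sub = annotations[annotations.gene_id != ""]
    if region is not None:
        sub = sub[sub.region == region]
    n_genes = sub.gene_id.nunique()
    if n_genes == 0:
        return None
    return len(sub) / n_genes


DEFAULT_CORR_VARS = ["total", "length", "intron_count", "mean_intron_length",
                     "n_3UTR", "n_5UTR", "n_CDS", "n_intron", "proximal",
                     "distal"]


def correlation_matrix(gene_stats: pd.DataFrame,
                       variables: list[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over gene-level variables.

    Zero-variance columns yield NaN for their pairs (flagged by NaN rather
    than an arbitrary value).
    """
    if variables is None:
        variables = [v for v in DEFAULT_CORR_VARS if v in gene_stats.columns]
    if len(gene_stats) < 3:
        raise ValueError("need at least 3 genes for correlations")
    r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((len(variables), len(variables))),
                     index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            x = gene_stats[a].to_numpy(dtype=float)
            y = gene_stats[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p
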