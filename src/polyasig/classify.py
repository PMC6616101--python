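"""Usage classes of poly(A) sites and matched control positions.

A site supported by strictly more than 70% of its gene's pooled reads is
``strong``; the other sites of such a gene are ``weak``. Multi-site genes
with no strong site carry ``universal`` sites; single-site genes carry
``unique`` sites. ``control`` positions are genomic AAUAAA occurrences with
no real site within 50 nt of the signal, with a pseudo-cleavage site placed
so the hexamer sits at the canonical -23 offset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

STRONG_SHARE = 0.7
CONTROL_OFFSET = 23  # hexamer 3' base sits at relative -23 from the pseudo-site


def classify_sites(site_table: pd.DataFrame,
                   share_cutoff: float = STRONG_SHARE) -> pd.DataFrame:
    """Classify sites by per-gene read share.

    ``site_table`` needs columns ``site_id, gene_id, total_reads`` (reads
    pooled over all samples). Returns site_id-indexed ``class`` and
    ``share``; genes with zero total reads are flagged ``unclassified``.
    """
    out = []
    for gene_id, grp in site_table.groupby("gene_id"):
        total = grp.total_reads.sum()
        if total <= 0:
            for sid in grp.site_id:
                out.append((sid, gene_id, "unclassified", np.nan))
            continue
        shares = grp.total_reads / total
        if len(grp) == 1:
            out.append((grp.site_id.iloc[0], gene_id, "unique", 1.0))
            continue
        has_strong = (shares > share_cutoff).any()
        for sid, share in zip(grp.site_id, shares):
            if has_strong:
                cls = "strong" if share > share_cutoff else "weak"
            else:
                cls = "universal"
            out.append((sid, gene_id, cls, float(share)))
    return pd.DataFrame(out, columns=["site_id", "gene_id", "class", "share"]
                        ).set_index("site_id")


def find_hexamer_sites(genome, hexamer_dna: str = "AATAAA") -> pd.DataFrame:
    """All genomic occurrences of the hexamer on both strands.

    Returns chrom / strand / start (1-based, 5'-most base on the given
    strand's sense) / pseudo-site position (hexamer end + 22 nt downstream,
    putting the hexamer 3' base at relative -23).
    """
    rows = []
    k = len(hexamer_dna)
    rc = hexamer_dna[::-1].translate(str.maketrans("ACGT", "TGCA"))
    for chrom in genome.chroms():
        seq = genome.fetch(chrom, 1, genome.chrom_length(chrom))
        start = seq.find(hexamer_dna)
        while start != -1:
            h = start + 1
            rows.append((chrom, "+", h, h + k - 1, h + k - 1 + 22))
            start = seq.find(hexamer_dna, start + 1)
        start = seq.find(rc)
        while start != -1:
            h = start + 1  # plus-strand coordinate of the match start
            rows.append((chrom, "-", h, h + k - 1, h - 22))
            start = seq.find(rc, start + 1)
    return pd.DataFrame(rows, columns=["chrom", "strand", "hex_lo", "hex_hi",
                                       "position"])


def sample_control_sites(genome, true_sites: pd.DataFrame, n: int, seed: int,
                         exclusion: int = 50) -> pd.DataFrame:
    """Sample control pseudo-sites: AAUAAA with no real site within 50 nt.

    ``true_sites`` needs columns ``chrom, position``. Qualifying hexamer
    occurrences are sampled uniformly without replacement; if fewer than
    ``n`` qualify, all are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    occ = find_hexamer_sites(genome)
    by_chrom = {c: np.sort(g.position.to_numpy())
                for c, g in true_sites.groupby("chrom")}
    keep = []
    for row in occ.itertuples(index=False):
        if row.position < 1 or row.position > genome.chrom_length(row.chrom):
            continue
        lo = row.hex_lo - exclusion
        hi = row.hex_hi + exclusion
        pos = by_chrom.get(row.chrom)
        if pos is not None:
            i = np.searchsorted(pos, lo)
            if i < len(pos) and pos[i] <= hi:
                continue
        keep.append(row)
    qualified = pd.DataFrame(keep, columns=occ.columns)
    if len(qualified) == 0:
        warnings.warn("no qualifying AAUAAA occurrence in the genome")
        return qualified
    if len(qualified) < n:
        warnings.warn(f"only {len(qualified)} qualifying occurrences "
                      f"(requested {n}); returning all")
        return qualified.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(qualified), size=n, replace=False)
    return qualified.iloc[np.sort(idx)].reset_index(drop=True)
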