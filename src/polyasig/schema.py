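"""Region models of poly(A) signals and clustered cis-element schemas.

Flanks are segmented into named signal windows relative to the cleavage
site; the windows differ by the genomic class of the site. 3' UTR sites use
the five-element vertebrate model (USE, PE, CEL, CER, DSE); 5' UTR and
intronic sites use variants with shifted boundaries; CDS sites collapse the
cleavage-proximal windows into one CE. Within each window, significant
hexamers (over-represented against the Markov background and, when strong
and weak site sets are given, differentially used between them) are grouped
by a shift-penalized mismatch distance, aligned at their best shifts
against the group medoid, and summarized as consensus strings plus position
frequency matrices (JASPAR-style text, the machine-readable form of a
sequence logo).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import motifs
from .motifs import RNA

Window = tuple[str, int, int]

REGION_SCHEMAS: dict[str, list[Window]] = {
    "3UTR": [("USE", -100, -35), ("PE", -34, -13), ("CEL", -12, -3),
             ("CER", 1, 33), ("DSE", 34, 100)],
    "5UTR": [("USE", -100, -40), ("PE", -40, -10), ("CE", -10, 10),
             ("DSE", 10, 100)],
    "CDS": [("USE", -100, -30), ("CE", -30, 30), ("DSE", 30, 100)],
    "intron": [("USE", -100, -40), ("PE", -40, -10), ("CEL", -10, -1),
               ("CER", 1, 30), ("DSE", 30, 100)],
}

IUPAC = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
         frozenset("U"): "U", frozenset("AG"): "R", frozenset("CU"): "Y",
         frozenset("GU"): "K", frozenset("AC"): "M", frozenset("CG"): "S",
         frozenset("AU"): "W", frozenset("CGU"): "B", frozenset("AGU"): "D",
         frozenset("ACU"): "H", frozenset("ACG"): "V",
         frozenset("ACGU"): "N"}


@dataclass
class RegionSchema:
    site_class: str
    windows: list[Window]


@dataclass
class SignalElement:
    """A clustered hexamer group with its alignment, consensus and PFM."""

    region: str                  # window name, e.g. "PE"
    label: str                   # e.g. "PE.1"
    members: list[str]
    shifts: list[int]            # column offset of each member vs the medoid
    consensus: str
    pfm: pd.DataFrame            # rows A/C/G/U, integer counts per column
    stats: pd.DataFrame | None = field(default=None, repr=False)


def segment_regions(site_class: str) -> RegionSchema:
    """The signal-window table for a genomic class of poly(A) sites."""
    if site_class not in REGION_SCHEMAS:
        raise ValueError(f"unknown site class {site_class!r}; expected one of "
                         f"{sorted(REGION_SCHEMAS)}")
    return RegionSchema(site_class, list(REGION_SCHEMAS[site_class]))


def hexamer_distance(a: str, b: str, max_shift: int = 3,
                     shift_penalty: float = 0.5) -> float:
    """Min over relative shifts of (mismatches in overlap + 0.5 * |shift|)."""
    k = len(a)
    best = float("inf")
    for s in range(-max_shift, max_shift + 1):
        mism = sum(1 for i in range(max(0, s), min(k, k + s))
                   if a[i] != b[i - s])
        best = min(best, mism + shift_penalty * abs(s))
    return best


def cluster_hexamers(hexamers: list[str], cutoff: float = 2.6) -> list[list[str]]:
    """Average-linkage clustering under the shift-penalized distance.

    Groups are returned largest first; membership is invariant to the input
    order of the hexamers.
    """
    hexamers = sorted(set(hexamers))
    if not hexamers:
        raise ValueError("no hexamers to cluster")
    if len(hexamers) == 1:
        return [list(hexamers)]
    n = len(hexamers)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = hexamer_distance(hexamers[i], hexamers[j])
    labels = fcluster(linkage(squareform(dm), method="average"),
                      t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for h, lab in zip(hexamers, labels):
        groups.setdefault(int(lab), []).append(h)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def _best_shift(member: str, medoid: str, max_shift: int = 3,
                shift_penalty: float = 0.5) -> int:
    k = len(member)
    best = (float("inf"), 0)
    for s in range(-max_shift, max_shift + 1):
        mism = sum(1 for i in range(max(0, s), min(k, k + s))
                   if medoid[i] != member[i - s])
        d = mism + shift_penalty * abs(s)
        key = (d, abs(s), s)
        if key < (best[0], abs(best[1]), best[1]):
            best = (d, s)
    return best[1]


def align_and_consensus(group: list[str], region: str = "",
                        rank: int = 1) -> SignalElement:
    """Medoid-anchored shift alignment, PFM and majority consensus.

    The medoid minimizes the summed distance to the group (ties broken
    lexicographically); each member is placed at its distance-minimizing
    shift. Consensus takes the per-column majority base, falling back to the
    IUPAC ambiguity code on ties.
    """
    if not group:
        raise ValueError("empty group")
    group = list(group)
    k = len(group[0])
    sums = [sum(hexamer_distance(a, b) for b in group) for a in group]
    medoid = sorted(zip(sums, group))[0][1]
    shifts = [_best_shift(m, medoid) for m in group]
    # member occupies columns shift..shift+k-1 relative to medoid start
    lo = min(shifts)
    hi = max(shifts) + k - 1
    ncol = hi - lo + 1
    pfm = pd.DataFrame(0, index=list(RNA), columns=range(ncol))
    for m, s in zip(group, shifts):
        for i, ch in enumerate(m):
            pfm.loc[ch, s - lo + i] += 1
    consensus = []
    for col in pfm.columns:
        counts = pfm[col]
        top = counts.max()
        if top == 0:
            consensus.append("N")
            continue
        winners = frozenset(counts.index[counts == top])
        consensus.append(IUPAC[winners])
    label = f"{region}.{rank}" if region else f"group.{rank}"
    return SignalElement(region=region, label=label, members=group,
                         shifts=[s - lo for s in shifts],
                         consensus="".join(consensus), pfm=pfm)


def select_significant_hexamers(kmer_table: pd.DataFrame,
                                sw_table: pd.DataFrame | None = None,
                                q: float = 0.01,
                                z_sw_cut: float = 1.96) -> list[str]:
    """Hexamers above the region's empirical z_oe quantile (1 - q), and —
    when a strong/weak table is supplied — with z_sw >= z_sw_cut."""
    z = kmer_table.z_oe.dropna()
    if z.empty:
        return []
    thr = z.quantile(1.0 - q)
    chosen = set(z.index[z > thr])
    if sw_table is not None:
        zsw = sw_table.z_sw.reindex(chosen)
        chosen = set(zsw.index[zsw >= z_sw_cut])
    return sorted(chosen)


def nucleotide_profile(flanks, rel_range: tuple[int, int] = (-300, 100)
                       ) -> pd.DataFrame:
    """Per-relative-position A/C/G/U fractions over a flank set.

    Positions with zero coverage are dropped; covered rows sum to 1.
    """
    lo, hi = rel_range
    positions = [r for r in range(lo, hi + 1) if r != 0]
    counts = pd.DataFrame(0, index=positions, columns=list(RNA))
    cover = pd.Series(0, index=positions)
    for f in flanks:
        for r in positions:
            idx = f.idx_of(r)
            if 0 <= idx < len(f.seq):
                ch = f.seq[idx]
                if ch in RNA:
                    counts.loc[r, ch] += 1
                    cover[r] += 1
    covered = cover > 0
    frac = counts[covered].div(cover[covered], axis=0)
    frac.index.name = "position"
    return frac


@dataclass
class SchemaReport:
    site_class: str
    schema: RegionSchema
    elements: list[SignalElement]
    table: pd.DataFrame


def build_schema(flanks_by_class: dict[str, list],
                 strong_weak: dict[str, tuple[list, list]] | None = None,
                 k: int = 6, q: float = 0.01, z_sw_cut: float = 1.96,
                 cluster_cutoff: float = 2.6) -> dict[str, SchemaReport]:
    """Full per-class element discovery: windows -> hexamers -> elements.

    For each genomic class and each of its signal windows, hexamers are
    scored against the window's own Markov background, screened by the
    z-score cutoff pair, clustered, and aligned into consensus elements.
    Element labels rank groups by member count within each window.
    """
    reports = {}
    for cls, flanks in flanks_by_class.items():
        schema = segment_regions(cls)
        elements: list[SignalElement] = []
        rows = []
        for name, a, b in schema.windows:
            seqs = [f.window(a, b) for f in flanks]
            seqs = [s for s in seqs if len(s) >= k]
            if not seqs:
                continue
            ktab = motifs.kmer_stat_table(seqs, k=k)
            swtab = None
            if strong_weak is not None and cls in strong_weak:
                sflank, wflank = strong_weak[cls]
                sseqs = [f.window(a, b) for f in sflank]
                wseqs = [f.window(a, b) for f in wflank]
                if sseqs and wseqs:
                    swtab = motifs.strong_weak_table(sseqs, wseqs, k=k)
            selected = select_significant_hexamers(ktab, swtab, q=q,
                                                   z_sw_cut=z_sw_cut)
            if not selected:
                continue
            groups = cluster_hexamers(selected, cutoff=cluster_cutoff)
            for rank, grp in enumerate(groups, 1):
                el = align_and_consensus(grp, region=name, rank=rank)
                el.stats = ktab.loc[ktab.index.intersection(grp)]
                elements.append(el)
                top3 = sorted(grp, key=lambda h: -ktab.loc[h, "o_observed"])[:3]
                rows.append({"class": cls, "window": name, "element": el.label,
                             "n_hexamers": len(grp),
                             "top_hexamers": ",".join(top3),
                             "consensus": el.consensus})
        reports[cls] = SchemaReport(
            site_class=cls, schema=schema, elements=elements,
            table=pd.DataFrame(rows, columns=["class", "window", "element",
                                              "n_hexamers", "top_hexamers",
                                              "consensus"]))
    return reports


def write_pfms(elements: list[SignalElement], path: str | Path) -> None:
    """Write position frequency matrices in JASPAR text format."""
    lines = []
    for el in elements:
        lines.append(f">{el.label} {el.consensus}")
        for base in RNA:
            vals = " ".join(str(int(v)) for v in el.pfm.loc[base])
            lines.append(f"{base} [ {vals} ]")
    Path(path).write_text("\n".join(lines) + "\n")
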