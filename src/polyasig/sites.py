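"""Cleavage-event clustering, internal-priming filters and flank extraction.

A cleavage event is one observed 3'-end position (the last templated
nucleotide, relative coordinate -1; the poly(A) tail begins at +1). Nearby
events on the same chromosome and strand are chained into poly(A) site
clusters (PACs) whenever adjacent events are at most ``max_gap`` (24 nt)
apart. Each cluster is represented by its highest-count member and inherits
the summed per-stage counts of its members.

Because 3'-end libraries are primed on the poly(A) tail, genomic A-rich
stretches downstream of a putative site produce internal-priming artifacts.
Three removal rules are checked, in order, on the 10-nt sense-strand window
immediately downstream (+1..+10):

1. ``fail_ARS``      — six or more adenines anywhere in the window;
2. ``fail_tetramer`` — the window starts with AAAA, AGAA, AAGA or AAAG;
3. ``fail_runA``     — a run of more than five consecutive adenines.

Relative coordinates skip zero: ..., -2, -1 (cleavage site), +1, +2, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import transcribe

A_RICH_WINDOW = 10
BAD_TETRAMERS = ("AAAA", "AGAA", "AAGA", "AAAG")


@dataclass
class CleavageEvent:
    chrom: str
    strand: str
    position: int             # 1-based coordinate of the last templated nt
    counts: np.ndarray        # per-stage (or per-sample) read counts
    event_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if self.counts.sum() <= 0:
            raise ValueError("event must have at least one read")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PolyACluster:
    """A poly(A) site cluster: chained events and their representative."""

    chrom: str
    strand: str
    members: list[CleavageEvent]
    representative: int       # position of the max-count member
    counts: np.ndarray        # per-stage counts summed over members
    cluster_id: str = ""
    filter_status: str = "unfiltered"
    edge_flag: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class FlankSequence:
    """Sense-strand RNA sequence around a site: upstream -U..-1, downstream +1..+D."""

    site_id: str
    up: str
    down: str
    up_truncated: bool = False
    down_truncated: bool = False

    @property
    def seq(self) -> str:
        return self.up + self.down

    def rel_of(self, idx: int) -> int:
        """Relative coordinate of index ``idx`` in ``self.seq`` (no zero)."""
        return idx - len(self.up) if idx < len(self.up) else idx - len(self.up) + 1

    def idx_of(self, rel: int) -> int:
        if rel == 0:
            raise ValueError("relative coordinate 0 does not exist")
        return rel + len(self.up) if rel < 0 else len(self.up) + rel - 1

    def window(self, a: int, b: int) -> str:
        """Subsequence covering relative coordinates [a, b], clipped to the flank."""
        if a == 0 or b == 0 or a > b:
            raise ValueError(f"bad window ({a}, {b})")
        i = max(0, self.idx_of(a))
        j = min(len(self.seq) - 1, self.idx_of(b))
        if j < i:
            return ""
        return self.seq[i:j + 1]


def cluster_cleavage_events(events: list[CleavageEvent],
                            max_gap: int = 24) -> list[PolyACluster]:
    """Single-linkage chaining of events within ``max_gap`` nt per (chrom, strand).

    The representative is the member with the largest total count; ties go to
    the most downstream member in the direction of transcription. Clustering
    is independent of input order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    seen = set()
    for e in events:
        key = (e.chrom, e.strand, e.position)
        if key in seen:
            raise ValueError(f"duplicate event at {key}")
        seen.add(key)
    groups: dict[tuple[str, str], list[CleavageEvent]] = {}
    for e in events:
        groups.setdefault((e.chrom, e.strand), []).append(e)
    clusters = []
    for (chrom, strand), evs in sorted(groups.items()):
        evs = sorted(evs, key=lambda e: e.position)
        block = [evs[0]]
        for e in evs[1:]:
            if e.position - block[-1].position <= max_gap:
                block.append(e)
            else:
                clusters.append(_make_cluster(chrom, strand, block))
                block = [e]
        clusters.append(_make_cluster(chrom, strand, block))
    for i, c in enumerate(clusters):
        if not c.cluster_id:
            c.cluster_id = f"PAC{i + 1:06d}"
    return clusters


def _make_cluster(chrom: str, strand: str,
                  members: list[CleavageEvent]) -> PolyACluster:
    best = max(members, key=lambda e: (e.total,
                                       e.position if strand == "+" else -e.position))
    counts = np.sum([e.counts for e in members], axis=0)
    # name the cluster after its representative event where events carry ids
    cid = best.event_id.split(".")[0] if best.event_id else ""
    return PolyACluster(chrom=chrom, strand=strand, members=members,
                        representative=best.position, counts=counts,
                        cluster_id=cid)


def downstream_window(cluster: PolyACluster, genome,
                      length: int = A_RICH_WINDOW) -> str:
    """Sense-strand DNA of relative +1..+length downstream of the representative."""
    p = cluster.representative
    if cluster.strand == "+":
        return genome.fetch(cluster.chrom, p + 1, p + length)
    return genome.fetch_strand(cluster.chrom, p - length, p - 1, "-")


def filter_a_rich(cluster: PolyACluster, genome) -> str:
    """Classify a cluster against the three internal-priming rules.

    Returns one of ``pass, fail_ARS, fail_tetramer, fail_runA`` (first rule
    that fires). Clusters with less than 10 nt of downstream contig are kept
    and edge-flagged.
    """
    win = downstream_window(cluster, genome)
    if len(win) < A_RICH_WINDOW:
        cluster.edge_flag = True
        cluster.filter_status = "pass"
        return "pass"
    status = classify_window(win)
    cluster.filter_status = status
    return status


def classify_window(win: str) -> str:
    """Apply the A-rich rules to a 10-nt downstream window (DNA or RNA)."""
    win = win.upper().replace("U", "T")
    if win.count("A") >= 6:
        return "fail_ARS"
    if win[:4] in BAD_TETRAMERS:
        return "fail_tetramer"
    run = best = 0
    for ch in win:
        run = run + 1 if ch == "A" else 0
        best = max(best, run)
    if best > 5:
        return "fail_runA"
    return "pass"


def apply_filters(clusters: list[PolyACluster], genome) -> list[PolyACluster]:
    """Run filter_a_rich over all clusters; return the passing ones."""
    return [c for c in clusters if filter_a_rich(c, genome) == "pass"]


def extract_flank(cluster: PolyACluster, genome, up: int = 300,
                  down: int = 100) -> FlankSequence:
    """Sense-strand RNA flank around the representative position.

    Upstream covers relative -up..-1 (the cleavage nucleotide is -1),
    downstream +1..+down. Minus-strand sites are reverse-complemented so the
    flank reads in the direction of transcription; T is transcribed to U.
    Truncation at contig edges is flagged.
    """
    p = cluster.representative
    chrom, strand = cluster.chrom, cluster.strand
    n = genome.chrom_length(chrom)
    if strand == "+":
        up_seq = genome.fetch(chrom, p - up + 1, p)
        down_seq = genome.fetch(chrom, p + 1, p + down)
    else:
        up_seq = genome.fetch_strand(chrom, p, p + up - 1, "-")
        down_seq = genome.fetch_strand(chrom, p - down, p - 1, "-")
    return FlankSequence(
        site_id=cluster.cluster_id, up=transcribe(up_seq), down=transcribe(down_seq),
        up_truncated=len(up_seq) < up, down_truncated=len(down_seq) < down)


def filter_report(clusters: list[PolyACluster], genome):
    """Per-cluster filter outcome table (site id, status, offending window)."""
    import pandas as pd

    rows = []
    for c in clusters:
        status = c.filter_status
        if status == "unfiltered":
            status = filter_a_rich(c, genome)
        rows.append((c.cluster_id, c.chrom, c.strand, c.representative,
                     c.total, status, downstream_window(c, genome)))
    return pd.DataFrame(rows, columns=["site_id", "chrom", "strand", "position",
                                       "total_reads", "status", "downstream_window"])
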