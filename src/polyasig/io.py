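"""File-format boundaries: FASTA genomes, BED6 cleavage sites, count tables.

Coordinate conventions are centralized here: BED is 0-based half-open on
disk; everything in memory is 1-based inclusive (GFF3-style). Count matrices
are TSV with cleavage-site ids as the index and stage labels as columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from ._util import revcomp


class Genome:
    """Random access to chromosome sequence, from a dict or a FASTA file.

    ``fetch`` uses 1-based inclusive coordinates and clips to contig bounds;
    ``fetch_strand`` additionally reverse-complements for the minus strand.
    """

    def __init__(self, source: dict[str, str] | str | Path):
        if isinstance(source, (str, Path)):
            self._fasta = Fasta(str(source), sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        self._check(chrom)
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive, clipped to the contig."""
        self._check(chrom)
        n = self.chrom_length(chrom)
        start, end = max(start, 1), min(end, n)
        if end < start:
            return ""
        if self._dict is not None:
            return self._dict[chrom][start - 1:end]
        return str(self._fasta[chrom][start - 1:end]).upper()

    def fetch_strand(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.fetch(chrom, start, end)
        if strand == "-":
            return revcomp(seq)
        if strand != "+":
            raise ValueError(f"unknown strand {strand!r}")
        return seq

    def _check(self, chrom: str) -> None:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in genome")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_events_bed(events, path: str | Path) -> None:
    """Write cleavage events as BED6 (name=site id, score=total reads)."""
    rows = [(e.chrom, e.position - 1, e.position, e.event_id,
             int(sum(e.counts)), e.strand) for e in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_events_bed(bed_path: str | Path, counts_path: str | Path):
    """Load cleavage events from BED6 + a site-by-stage count matrix TSV."""
    from .sites import CleavageEvent

    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    counts = read_counts(counts_path)
    events = []
    for row in bed.itertuples(index=False):
        c = counts.loc[row.name].to_numpy() if row.name in counts.index else None
        if c is None:
            raise ValueError(f"event {row.name!r} missing from count matrix")
        events.append(CleavageEvent(chrom=row.chrom, strand=row.strand,
                                    position=int(row.end), counts=c,
                                    event_id=str(row.name)))
    return events, list(counts.columns)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="site_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id")
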