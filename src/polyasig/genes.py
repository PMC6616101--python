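"""Gene models: an in-memory transcript structure plus GFF3 round-trip.

Coordinates are GFF3-style throughout this module: 1-based, inclusive on both
ends. A ``GeneModel`` carries one transcript per gene (the simulator emits one
isoform; real annotations collapse to one record per mRNA), with exons, CDS
segments and UTRs in genomic order. Introns are derived as the gaps between
consecutive exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Interval = tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int   # 1-based inclusive
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(self, name, sorted(getattr(self, name)))
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment ({s},{e}) outside exons")

    @property
    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start (5' end in transcription direction)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end (annotated 3' end)."""
        return self.end if self.strand == "+" else self.start


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS/UTR features as a GFF3 file."""
    lines = ["##gff-version 3"]
    for g in genes:
        tid = f"{g.gene_id}.t1"
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        lines.append(_row(g.chrom, "gene", g.start, g.end, g.strand, attrs))
        lines.append(_row(g.chrom, "mRNA", g.start, g.end, g.strand,
                          f"ID={tid};Parent={g.gene_id}"))
        for kind, ivs in (("exon", g.exons), ("CDS", g.cds),
                          ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
            for i, (s, e) in enumerate(ivs, 1):
                lines.append(_row(g.chrom, kind, s, e, g.strand,
                                  f"ID={tid}.{kind}.{i};Parent={tid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def _row(chrom: str, kind: str, s: int, e: int, strand: str, attrs: str) -> str:
    return "\t".join([chrom, "polyasig", kind, str(s), str(e), ".", strand, ".", attrs])


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 via gffutils (in-memory db)."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else g
        kinds = {"exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
        for kind in kinds:
            for f in db.children(parent, featuretype=kind):
                kinds[kind].append((f.start, f.end))
        biotype = g.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand, start=g.start, end=g.end,
            exons=kinds["exon"], cds=kinds["CDS"], utr5=kinds["five_prime_UTR"],
            utr3=kinds["three_prime_UTR"], biotype=biotype))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
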