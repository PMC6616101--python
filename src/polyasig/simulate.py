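"""Synthetic genomes with planted poly(A) sites and known ground truth.

The generator builds multi-chromosome genomes of protein-coding gene models
(5' UTR / CDS with introns / 3' UTR, intergenic spacers), plants cleavage
sites in configurable genomic regions, writes signal motifs into the sequence
at sampled offsets (e.g. AAUAAA ending at -23 +/- 4 nt for 3' UTR sites),
writes a YA dinucleotide at (-2, -1) for a configurable fraction of sites,
rewrites a configurable fraction of downstream windows into internal-priming
artifacts, and draws a 9-stage read-count matrix from per-site expression
archetypes (stage-specific, constitutive, or background). Every emitted
cleavage event maps to exactly one row of the truth table, so each
downstream analysis stage has a closed-loop test.

Background sequence is iid uniform over ACGT. The 10-nt window downstream of
every non-artifact site is drawn by rejection sampling so that it satisfies
none of the internal-priming removal rules; artifact windows are written to
satisfy one rule chosen uniformly at random. Identical (config, seed) pairs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import back_transcribe, revcomp, transcribe
from .genes import GeneModel, write_gff3
from .io import Genome, write_counts, write_events_bed, write_fasta
from .sites import CleavageEvent, FlankSequence, classify_window

STAGES = ["embryo_6", "embryo_8", "embryo_11", "embryo_15", "embryo_28",
          "young_female", "growing_female", "young_male", "growing_male"]

DNA = "ACGT"
BAD_TETRAMERS_DNA = ("AAAA", "AGAA", "AAGA", "AAAG")


@dataclass(frozen=True)
class SignalSpec:
    """One grammar rule: plant ``motif`` near sites of ``region``.

    ``mean_offset`` is the relative coordinate of the motif's 3'-most base
    (AAUAAA at -23 occupies -28..-23); offsets are drawn from a rounded
    normal unless ``uniform_range`` is given, in which case they are drawn
    uniformly over that range (used for scattered decoy motifs).
    """

    motif: str
    region: str            # 3UTR | 5UTR | CDS | intron | Ex_3UTR | '*'
    mean_offset: float
    sd_offset: float
    prob: float
    uniform_range: tuple[int, int] | None = None


DEFAULT_GRAMMAR = (
    SignalSpec("AAUAAA", "3UTR", -23, 4.0, 0.50),
    SignalSpec("AUUAAA", "3UTR", -23, 4.0, 0.20),
    SignalSpec("UGUUUU", "3UTR", +20, 5.0, 0.40),
    SignalSpec("AAUAAA", "intron", -23, 4.0, 0.40),
    SignalSpec("AAGAAA", "CDS", -15, 5.0, 0.30),
    SignalSpec("AAUAAA", "5UTR", -23, 4.0, 0.40),
)


@dataclass
class SimConfig:
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (3000, 10000)
    intron_count_range: tuple[int, int] = (0, 7)
    signal_grammar: tuple[SignalSpec, ...] = DEFAULT_GRAMMAR
    artifact_rate: float = 0.1
    n_stages: int = 9
    stage_labels: tuple[str, ...] = tuple(STAGES)
    seed: int = 0
    # stage-profile archetypes and their negative-binomial count parameters
    frac_specific: float = 0.2
    frac_constitutive: float = 0.2
    specific_mean: float = 200.0
    constitutive_mean: float = 50.0
    background_mean: float = 0.3
    intermediate_mean: float = 30.0
    intermediate_stages: tuple[int, int] = (2, 6)
    dispersion: float = 0.2
    # geometry
    genes_per_chrom: int = 50
    spacer: int = 2000
    utr5_range: tuple[int, int] = (100, 300)
    utr3_range: tuple[int, int] = (300, 800)
    cds_range: tuple[int, int] = (900, 1800)
    # site layout
    n_utr3_sites: tuple[int, int] = (1, 3)
    n_intron_sites: tuple[int, int] = (0, 2)
    n_cds_sites: tuple[int, int] = (0, 1)
    n_utr5_sites: tuple[int, int] = (0, 1)
    p_ex3utr_site: float = 0.15
    ex3utr_offset_range: tuple[int, int] = (50, 900)
    min_site_spacing: int = 50
    ya_fraction: float = 0.8
    events_per_site: tuple[int, int] = (1, 3)

    def __post_init__(self):
        for p in (self.artifact_rate, self.frac_specific, self.frac_constitutive,
                  self.p_ex3utr_site, self.ya_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for spec in self.signal_grammar:
            if not 0.0 <= spec.prob <= 1.0:
                raise ValueError(f"grammar probability {spec.prob} outside [0, 1]")
        for rng_ in (self.gene_length_range, self.intron_count_range,
                     self.utr5_range, self.utr3_range, self.cds_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"empty range {rng_}")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if len(self.stage_labels) != self.n_stages:
            self.stage_labels = tuple(f"stage_{i + 1}"
                                      for i in range(self.n_stages))
        min_exonic = self.utr5_range[0] + self.cds_range[0] + self.utr3_range[0]
        if self.gene_length_range[1] < min_exonic:
            raise ValueError(
                "infeasible geometry: maximum gene length "
                f"{self.gene_length_range[1]} is shorter than the minimal exonic "
                f"content {min_exonic}")


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    strand: str
    position: int                      # relative -1 coordinate, 1-based
    gene_id: str
    region: str
    motifs: list[tuple[str, int]] = field(default_factory=list)
    ya: bool = False
    artifact: bool = False
    artifact_rule: str = ""
    specificity: str = ""              # specific | constitutive | background
    specific_stage: int = -1
    stage_means: np.ndarray | None = None
    events: list[tuple[int, np.ndarray]] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    sites: list[PlantedSite]
    truth: pd.DataFrame
    events: list[CleavageEvent]
    counts: pd.DataFrame               # event-level counts, stages as columns

    @property
    def genome(self) -> Genome:
        return Genome(self.sequences)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "events": outdir / "events.bed",
            "counts": outdir / "counts.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.sequences, paths["genome"])
        write_gff3(self.genes, paths["annotation"])
        write_events_bed(self.events, paths["events"])
        write_counts(self.counts, paths["counts"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# coordinate helpers

def rel_to_genomic(position: int, strand: str, rel: int) -> int:
    """Map a relative coordinate (no zero; -1 == position) to genomic."""
    if rel == 0:
        raise ValueError("relative coordinate 0 does not exist")
    if strand == "+":
        return position + rel + 1 if rel < 0 else position + rel
    return position - rel - 1 if rel < 0 else position - rel


class _SeqSpace:
    """Mutable chromosome sequences plus an occupied-position registry.

    Planted motifs, YA dinucleotides and downstream windows must never
    overwrite each other, or the truth table would lie about what the final
    sequence contains; every deliberate write claims its genomic footprint
    here first.
    """

    def __init__(self):
        self.seqs: dict[str, bytearray] = {}
        self.occupied: dict[str, set[int]] = {}

    def add_chrom(self, name: str, seq: bytearray) -> None:
        self.seqs[name] = seq
        self.occupied[name] = set()

    def is_free(self, chrom: str, lo: int, hi: int) -> bool:
        occ = self.occupied[chrom]
        return 1 <= lo and hi <= len(self.seqs[chrom]) and \
            not any(g in occ for g in range(lo, hi + 1))

    def claim(self, chrom: str, lo: int, hi: int) -> None:
        self.occupied[chrom].update(range(lo, hi + 1))

    def write_sense(self, chrom: str, strand: str, lo: int, hi: int,
                    sense_dna: str) -> None:
        """Write a sense-strand DNA string onto genomic interval [lo, hi]."""
        assert hi - lo + 1 == len(sense_dna)
        if strand == "-":
            sense_dna = revcomp(sense_dna)
        self.seqs[chrom][lo - 1:hi] = sense_dna.encode()

    def finalize(self) -> dict[str, str]:
        return {k: v.decode() for k, v in self.seqs.items()}


# ---------------------------------------------------------------------------
# gene geometry

def _build_gene(rng: np.random.Generator, cfg: SimConfig, gene_id: str,
                chrom: str, strand: str, start: int) -> GeneModel:
    for _ in range(200):
        length = int(rng.integers(cfg.gene_length_range[0],
                                  cfg.gene_length_range[1] + 1))
        m = int(rng.integers(cfg.intron_count_range[0],
                             cfg.intron_count_range[1] + 1))
        u = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        t = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        if m == 0:
            c = length - u - t
            c -= c % 3
            t = length - u - c
            if c < 3 * 1:
                continue
            intron_sizes: list[int] = []
        else:
            c = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1))
            c -= c % 3
            intronic = length - u - c - t
            if intronic < 80 * m:
                continue  # resample: not enough room for m introns
            extra = rng.multinomial(intronic - 80 * m, [1.0 / m] * m)
            intron_sizes = [80 + int(x) for x in extra]
        # CDS split into m+1 chunks of >= 30 nt; exon i carries chunk i
        chunks = [c] if m == 0 else \
            [30 + int(x) for x in rng.multinomial(c - 30 * (m + 1),
                                                  [1.0 / (m + 1)] * (m + 1))]
        if min(chunks) < 30:
            continue
        return _assemble_gene(gene_id, chrom, strand, start, length, u, t,
                              chunks, intron_sizes)
    raise ValueError(
        f"infeasible geometry for gene {gene_id}: cannot fit "
        f"{cfg.intron_count_range} introns into length {cfg.gene_length_range}")


def _assemble_gene(gene_id, chrom, strand, start, length, u, t, chunks,
                   intron_sizes) -> GeneModel:
    # transcript-order segment list: (kind, length)
    segs: list[tuple[str, int]] = [("utr5", u)]
    for i, ch in enumerate(chunks):
        segs.append(("cds", ch))
        if i < len(intron_sizes):
            segs.append(("intron", intron_sizes[i]))
    segs.append(("utr3", t))
    end = start + length - 1
    cursor = start if strand == "+" else end
    step = 1 if strand == "+" else -1
    placed: list[tuple[str, int, int]] = []
    for kind, ln in segs:
        g1 = cursor
        g2 = cursor + step * (ln - 1)
        placed.append((kind, min(g1, g2), max(g1, g2)))
        cursor = g2 + step
    utr5 = [(s, e) for k, s, e in placed if k == "utr5"]
    utr3 = [(s, e) for k, s, e in placed if k == "utr3"]
    cds = [(s, e) for k, s, e in placed if k == "cds"]
    # exons = maximal runs of non-intron segments
    exons: list[tuple[int, int]] = []
    for k, s, e in sorted(placed, key=lambda x: x[1]):
        if k == "intron":
            continue
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                     end=end, exons=exons, cds=cds, utr5=utr5, utr3=utr3)


def generate_genome(cfg: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[_SeqSpace, list[GeneModel]]:
    """Build chromosome backbones and gene models (no sites yet).

    Chromosomes carry ``genes_per_chrom`` genes separated by ``spacer`` nt of
    intergenic background; with ``n_genes=0`` a single gene-free chromosome
    is still emitted.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    space = _SeqSpace()
    genes: list[GeneModel] = []
    n_chroms = max(1, -(-cfg.n_genes // cfg.genes_per_chrom))
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = cfg.spacer
        chrom_genes = []
        n_here = min(cfg.genes_per_chrom, cfg.n_genes - gi)
        for _ in range(max(n_here, 0)):
            gi += 1
            strand = "+" if gi % 2 else "-"
            g = _build_gene(rng, cfg, f"g{gi:05d}", chrom, strand, cursor + 1)
            chrom_genes.append(g)
            cursor = g.end + cfg.spacer
        length = max(cursor, cfg.spacer * 2)
        codes = rng.integers(0, 4, size=length)
        seq = bytearray(bytes(np.frombuffer(DNA.encode(), dtype=np.uint8)[codes]))
        space.add_chrom(chrom, seq)
        genes.extend(chrom_genes)
    return space, genes


# ---------------------------------------------------------------------------
# site planting

_REGION_MARGIN = {"3UTR": 10, "5UTR": 20, "CDS": 30, "intron": 30}


def _candidate_intervals(gene: GeneModel, region: str) -> list[tuple[int, int]]:
    margin = _REGION_MARGIN[region]
    ivs = {"3UTR": gene.utr3, "5UTR": gene.utr5, "CDS": gene.cds,
           "intron": gene.introns}[region]
    out = []
    for s, e in ivs:
        if e - margin >= s + margin:
            out.append((s + margin, e - margin))
    return out


def _place_sites_for_gene(rng, cfg: SimConfig, gene: GeneModel,
                          taken: dict[str, list[int]]) -> list[PlantedSite]:
    wanted: list[str] = []
    wanted += ["3UTR"] * int(rng.integers(cfg.n_utr3_sites[0],
                                          cfg.n_utr3_sites[1] + 1))
    wanted += ["intron"] * int(rng.integers(cfg.n_intron_sites[0],
                                            cfg.n_intron_sites[1] + 1))
    wanted += ["CDS"] * int(rng.integers(cfg.n_cds_sites[0],
                                         cfg.n_cds_sites[1] + 1))
    wanted += ["5UTR"] * int(rng.integers(cfg.n_utr5_sites[0],
                                          cfg.n_utr5_sites[1] + 1))
    if rng.random() < cfg.p_ex3utr_site:
        wanted.append("Ex_3UTR")
    sites = []
    positions = taken.setdefault(gene.chrom, [])
    for region in wanted:
        if region == "Ex_3UTR":
            lo, hi = cfg.ex3utr_offset_range
            cands = [(gene.tes + (lo if gene.strand == "+" else -hi),
                      gene.tes + (hi if gene.strand == "+" else -lo))]
        else:
            cands = _candidate_intervals(gene, region)
        if not cands:
            continue
        for _ in range(40):
            s, e = cands[int(rng.integers(len(cands)))]
            pos = int(rng.integers(s, e + 1))
            if all(abs(pos - q) >= cfg.min_site_spacing for q in positions):
                positions.append(pos)
                sites.append(PlantedSite(site_id="", chrom=gene.chrom,
                                         strand=gene.strand, position=pos,
                                         gene_id=gene.gene_id, region=region))
                break
    return sites


def _plant_motif(rng, space: _SeqSpace, site: PlantedSite, spec: SignalSpec,
                 max_up: int = 300, max_down: int = 100) -> None:
    k = len(spec.motif)
    for _ in range(30):
        if spec.uniform_range is not None:
            off = int(rng.integers(spec.uniform_range[0],
                                   spec.uniform_range[1] + 1))
        else:
            off = int(round(rng.normal(spec.mean_offset, spec.sd_offset)))
        if off == 0:
            continue
        rel_lo = off - k + 1
        if rel_lo <= 0 <= off or rel_lo < -max_up or off > max_down:
            continue  # motif may not straddle the cleavage site
        g1 = rel_to_genomic(site.position, site.strand, rel_lo)
        g2 = rel_to_genomic(site.position, site.strand, off)
        lo, hi = min(g1, g2), max(g1, g2)
        if not space.is_free(site.chrom, lo, hi):
            continue
        space.claim(site.chrom, lo, hi)
        space.write_sense(site.chrom, site.strand, lo, hi,
                          back_transcribe(spec.motif))
        site.motifs.append((spec.motif, off))
        return


def _write_rel_window(space: _SeqSpace, site: PlantedSite, rel_lo: int,
                      rel_hi: int, sense_dna: str) -> None:
    g1 = rel_to_genomic(site.position, site.strand, rel_lo)
    g2 = rel_to_genomic(site.position, site.strand, rel_hi)
    space.write_sense(site.chrom, site.strand, min(g1, g2), max(g1, g2),
                      sense_dna)


def _clean_window(rng) -> str:
    """A 10-nt window passing every internal-priming rule (rejection sample)."""
    while True:
        win = "".join(DNA[i] for i in rng.integers(0, 4, size=10))
        if classify_window(win) == "pass":
            return win


def _artifact_window(rng) -> tuple[str, str]:
    """A 10-nt window violating one removal rule chosen uniformly."""
    rule = ("ARS", "tetramer", "runA")[int(rng.integers(3))]
    if rule == "ARS":
        n_a = int(rng.integers(6, 11))
        pos = rng.permutation(10)[:n_a]
        win = ["ACGT"[1 + int(i)] for i in rng.integers(0, 3, size=10)]  # C/G/T
        for p in pos:
            win[p] = "A"
        return "".join(win), rule
    if rule == "tetramer":
        tet = BAD_TETRAMERS_DNA[int(rng.integers(4))]
        rest = "".join(DNA[i] for i in rng.integers(0, 4, size=6))
        return tet + rest, rule
    start = int(rng.integers(0, 5))
    win = ["ACGT"[1 + int(i)] for i in rng.integers(0, 3, size=10)]
    for p in range(start, start + 6):
        win[p] = "A"
    return "".join(win), rule


def plant_polya_sites(space: _SeqSpace, genes: list[GeneModel], cfg: SimConfig,
                      rng: np.random.Generator) -> list[PlantedSite]:
    """Place sites, reserve their YA/downstream zones, write grammar motifs."""
    taken: dict[str, list[int]] = {}
    sites: list[PlantedSite] = []
    for gene in genes:
        sites.extend(_place_sites_for_gene(rng, cfg, gene, taken))
    for i, site in enumerate(sites):
        site.site_id = f"PS{i + 1:06d}"
    # reserve the (-2..-1) dinucleotide and +1..+10 window of every site first,
    # so no later motif write can clobber them (or vice versa)
    for site in sites:
        g1 = rel_to_genomic(site.position, site.strand, -2)
        g2 = rel_to_genomic(site.position, site.strand, 10)
        space.claim(site.chrom, min(g1, g2), max(g1, g2))
    for site in sites:
        for spec in cfg.signal_grammar:
            if spec.region not in ("*", site.region):
                continue
            if rng.random() < spec.prob:
                _plant_motif(rng, space, site, spec)
    for site in sites:
        if rng.random() < cfg.ya_fraction:
            site.ya = True
            y = "CT"[int(rng.integers(2))]
            _write_rel_window(space, site, -2, -1, y + "A")
        _write_rel_window(space, site, 1, 10, _clean_window(rng))
    return sites


def inject_internal_priming(space: _SeqSpace, sites: list[PlantedSite],
                            rate: float, rng: np.random.Generator) -> int:
    """Rewrite a ``rate`` fraction of downstream windows into artifacts.

    Returns the realized (binomial) number of flagged sites; flags and the
    intended rule are recorded on the sites themselves.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"artifact rate {rate} outside [0, 1]")
    n_flagged = 0
    for site in sites:
        if rng.random() < rate:
            win, rule = _artifact_window(rng)
            _write_rel_window(space, site, 1, 10, win)
            site.artifact = True
            site.artifact_rule = rule
            n_flagged += 1
    return n_flagged


# ---------------------------------------------------------------------------
# stage-expression archetypes

def _nb_draw(rng, mean: float, dispersion: float, size=None):
    if mean <= 0:
        return np.zeros(size if size else (), dtype=np.int64)
    if dispersion <= 0:
        out = np.full(size if size else (), round(mean), dtype=np.int64)
        return out
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(n, p, size=size)


def assign_stage_profiles(sites: list[PlantedSite], cfg: SimConfig,
                          rng: np.random.Generator) -> None:
    """Attach an expression archetype and per-stage mean counts to each site."""
    n = cfg.n_stages
    for site in sites:
        u = rng.random()
        means = np.full(n, cfg.background_mean)
        if u < cfg.frac_specific:
            site.specificity = "specific"
            site.specific_stage = int(rng.integers(n))
            means[site.specific_stage] = cfg.specific_mean
        elif u < cfg.frac_specific + cfg.frac_constitutive:
            site.specificity = "constitutive"
            means[:] = cfg.constitutive_mean
        else:
            site.specificity = "background"
            k = int(rng.integers(cfg.intermediate_stages[0],
                                 cfg.intermediate_stages[1] + 1))
            stages = rng.permutation(n)[:k]
            means[stages] = cfg.intermediate_mean
        site.stage_means = means


def emit_events(sites: list[PlantedSite], cfg: SimConfig,
                rng: np.random.Generator) -> None:
    """Draw realized counts and split each site into 1-3 cleavage events.

    The event at the true position always carries the strictly largest total
    so that cluster representatives recover planted positions exactly.
    """
    for site in sites:
        counts = np.array([int(_nb_draw(rng, m, cfg.dispersion))
                           for m in site.stage_means], dtype=np.int64)
        if counts.sum() == 0:
            counts[int(rng.integers(cfg.n_stages))] = 1
        n_ev = int(rng.integers(cfg.events_per_site[0],
                                cfg.events_per_site[1] + 1))
        offsets = [0]
        pool = [d for d in range(-8, 9) if d != 0]
        for d in rng.permutation(pool)[:n_ev - 1]:
            offsets.append(int(d))
        main_w = rng.uniform(0.6, 0.9)
        weights = np.array([main_w] + [(1 - main_w) / max(n_ev - 1, 1)] *
                           (n_ev - 1))
        weights /= weights.sum()
        per_event = np.zeros((n_ev, cfg.n_stages), dtype=np.int64)
        for s in range(cfg.n_stages):
            per_event[:, s] = rng.multinomial(counts[s], weights)
        # guarantee the true position is the strict representative
        while n_ev > 1 and per_event[1:].sum(axis=1).max() >= per_event[0].sum():
            j = 1 + int(np.argmax(per_event[1:].sum(axis=1)))
            s = int(np.argmax(per_event[j]))
            per_event[j, s] -= 1
            per_event[0, s] += 1
        step = 1 if site.strand == "+" else -1
        site.events = []
        for j in range(n_ev):
            if per_event[j].sum() == 0:
                continue
            site.events.append((site.position + step * offsets[j],
                                per_event[j].copy()))


# ---------------------------------------------------------------------------
# orchestration

def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: genome -> sites -> artifacts -> counts."""
    rng = np.random.default_rng(cfg.seed)
    space, genes = generate_genome(cfg, rng)
    sites = plant_polya_sites(space, genes, cfg, rng)
    inject_internal_priming(space, sites, cfg.artifact_rate, rng)
    assign_stage_profiles(sites, cfg, rng)
    emit_events(sites, cfg, rng)
    sequences = space.finalize()
    events = []
    count_rows = {}
    for site in sites:
        for j, (pos, c) in enumerate(site.events):
            eid = f"{site.site_id}.{j}"
            events.append(CleavageEvent(chrom=site.chrom, strand=site.strand,
                                        position=pos, counts=c, event_id=eid))
            count_rows[eid] = c
    counts = pd.DataFrame.from_dict(count_rows, orient="index",
                                    columns=list(cfg.stage_labels))
    counts.index.name = "site_id"
    truth = truth_table(sites, cfg)
    return SimResult(config=cfg, sequences=sequences, genes=genes, sites=sites,
                     truth=truth, events=events, counts=counts)


def truth_table(sites: list[PlantedSite], cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id, "chrom": s.chrom, "strand": s.strand,
            "position": s.position, "gene_id": s.gene_id, "region": s.region,
            "motifs": ";".join(f"{m}@{o}" for m, o in s.motifs),
            "ya": s.ya, "artifact": s.artifact, "artifact_rule": s.artifact_rule,
            "specificity": s.specificity, "specific_stage": s.specific_stage,
            "n_events": len(s.events),
        }
        for lbl, m in zip(cfg.stage_labels, s.stage_means):
            row[f"mean_{lbl}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# light-weight generators for focused tests

def simulate_flank_set(n: int, grammar: tuple[SignalSpec, ...],
                       up: int = 300, down: int = 100, seed: int = 0,
                       region: str = "3UTR", ya_fraction: float = 0.0
                       ) -> tuple[list[FlankSequence], pd.DataFrame]:
    """Generate standalone site flanks with planted motifs (no genome).

    Returns the flanks (sense-strand RNA) and a truth table of planted
    (flank id, motif, offset) rows. Background is iid uniform; the +1..+10
    window is rejection-sampled clean as in the full generator.
    """
    rng = np.random.default_rng(seed)
    flanks = []
    rows = []
    for i in range(n):
        fid = f"F{i + 1:06d}"
        seq = list("".join(DNA[j] for j in rng.integers(0, 4, size=up + down)))
        occupied: set[int] = set()

        def idx_of(rel: int) -> int:
            return rel + up if rel < 0 else up + rel - 1

        for r in range(-2, 11):
            if r != 0:
                occupied.add(idx_of(r))
        planted = []
        for spec in grammar:
            if spec.region not in ("*", region) or rng.random() >= spec.prob:
                continue
            k = len(spec.motif)
            for _ in range(30):
                if spec.uniform_range is not None:
                    off = int(rng.integers(spec.uniform_range[0],
                                           spec.uniform_range[1] + 1))
                else:
                    off = int(round(rng.normal(spec.mean_offset, spec.sd_offset)))
                rel_lo = off - k + 1
                if off == 0 or (rel_lo <= 0 <= off) or rel_lo < -up or off > down:
                    continue
                idxs = [idx_of(r) for r in range(rel_lo, off + 1) if r != 0]
                if any(ix in occupied for ix in idxs):
                    continue
                occupied.update(idxs)
                for ix, ch in zip(idxs, back_transcribe(spec.motif)):
                    seq[ix] = ch
                planted.append((spec.motif, off))
                break
        if rng.random() < ya_fraction:
            seq[idx_of(-2)] = "CT"[int(rng.integers(2))]
            seq[idx_of(-1)] = "A"
        win = _clean_window(rng)
        for r, ch in zip(range(1, 11), win):
            seq[idx_of(r)] = ch
        s = "".join(seq)
        flanks.append(FlankSequence(site_id=fid, up=transcribe(s[:up]),
                                    down=transcribe(s[up:])))
        for m, o in planted:
            rows.append({"site_id": fid, "motif": m, "offset": o})
    return flanks, pd.DataFrame(rows, columns=["site_id", "motif", "offset"])


def simulate_stage_matrix(n_sites: int, cfg: SimConfig | None = None,
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-expression counts for n_sites standalone sites plus truth labels."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(seed)
    sites = [PlantedSite(site_id=f"PS{i + 1:06d}", chrom="chr1", strand="+",
                         position=1000 + 100 * i, gene_id=f"g{i // 3:05d}",
                         region="3UTR") for i in range(n_sites)]
    assign_stage_profiles(sites, cfg, rng)
    counts = {}
    for s in sites:
        c = np.array([int(_nb_draw(rng, m, cfg.dispersion))
                      for m in s.stage_means], dtype=np.int64)
        counts[s.site_id] = c
    mat = pd.DataFrame.from_dict(counts, orient="index",
                                 columns=list(cfg.stage_labels))
    mat.index.name = "site_id"
    return mat, truth_table(sites, cfg)
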