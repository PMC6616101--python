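"""End-to-end orchestration: simulate/load -> filter -> annotate -> classify
-> scan -> schema -> entropy, with a manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import shutil
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as annotate_mod
from . import classify as classify_mod
from . import entropy as entropy_mod
from . import schema as schema_mod
from ._util import sha256_file
from .genes import read_gff3
from .io import Genome, read_events_bed
from .simulate import SimConfig, simulate
from .sites import cluster_cleavage_events, extract_flank, filter_report

log = logging.getLogger("polyasig")


@dataclass
class PipelineConfig:
    outdir: str = "polyasig_out"
    # input paths; left empty when `simulate` is set
    genome: str = ""
    gff: str = ""
    sites_bed: str = ""
    counts_tsv: str = ""
    simulate: SimConfig | None = None
    # stage parameters, mirroring each module default
    max_gap: int = 24
    extension: int = 1000
    flank_up: int = 300
    flank_down: int = 100
    k: int = 6
    p_cut: float = 1e-5
    sd_cut: float = 7.0
    cluster_cutoff: float = 2.6
    pct: float = 5.0
    min_reads: int = 5
    n_controls: int = 0
    min_strong_weak: int = 30  # apply the z_sw screen only above this set size
    seed: int = 0
    classes: tuple[str, ...] = ("3UTR", "5UTR", "CDS", "intron")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim) if isinstance(sim, dict) else SimConfig()
        return cfg


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _checksums(outdir: Path) -> dict[str, str]:
    return {p.name: sha256_file(p) for p in sorted(outdir.iterdir())
            if p.is_file()}


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage; on failure, retain outputs under a quarantine dir.

    Identical config + seed produce identical outputs. The manifest records
    parameters, input checksums, per-stage record counts and output
    checksums.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {k: v for k, v in vars(cfg).items()
                                     if not isinstance(v, SimConfig)},
                      "stages": {}}
    stage = "setup"
    t0 = time.time()
    try:
        # ------------------------------------------------------------ inputs
        if cfg.simulate is not None:
            stage = "simulate"
            sim = simulate(cfg.simulate)
            paths = sim.write(outdir / "simulated")
            genome = sim.genome
            genes = sim.genes
            events = sim.events
            stage_labels = list(sim.config.stage_labels)
            manifest["stages"]["simulate"] = {
                "n_genes": len(genes), "n_sites": len(sim.sites),
                "n_events": len(events)}
            manifest["inputs"] = {k: sha256_file(v) for k, v in paths.items()}
        else:
            stage = "load"
            for name in ("genome", "gff", "sites_bed", "counts_tsv"):
                if not getattr(cfg, name):
                    raise ValueError(f"config field {name!r} is required when "
                                     "no simulation block is given")
                if not Path(getattr(cfg, name)).exists():
                    raise FileNotFoundError(f"{name}: {getattr(cfg, name)}")
            genome = Genome(cfg.genome)
            genes = read_gff3(cfg.gff)
            events, stage_labels = read_events_bed(cfg.sites_bed, cfg.counts_tsv)
            manifest["inputs"] = {name: sha256_file(getattr(cfg, name))
                                  for name in ("genome", "gff", "sites_bed",
                                               "counts_tsv")}

        # ------------------------------------------------------------ filter
        stage = "filter"
        clusters = cluster_cleavage_events(events, max_gap=cfg.max_gap)
        report = filter_report(clusters, genome)
        report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        passing = [c for c in clusters if c.filter_status == "pass"]
        manifest["stages"]["filter"] = {
            "n_clusters": len(clusters), "n_pass": len(passing),
            "removed_by_rule": report.status.value_counts().to_dict()}
        _log_stage("filter", t0, len(events), len(passing))

        # ---------------------------------------------------------- annotate
        stage = "annotate"
        annotations = annotate_mod.annotate_sites(passing, genes,
                                                  extension=cfg.extension)
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        gene_stats = annotate_mod.gene_apa_stats(annotations, genes)
        gene_stats.to_csv(outdir / "gene_apa_stats.tsv", sep="\t")
        if len(gene_stats) >= 3:
            r, p = annotate_mod.correlation_matrix(gene_stats)
            r.to_csv(outdir / "correlation_r.tsv", sep="\t")
            p.to_csv(outdir / "correlation_p.tsv", sep="\t")
        manifest["stages"]["annotate"] = {
            "n_annotated": len(annotations),
            "by_region": annotations.region.value_counts().to_dict()}

        # ---------------------------------------------------------- classify
        stage = "classify"
        in_gene = annotations[annotations.gene_id != ""]
        classes = classify_mod.classify_sites(
            in_gene[["site_id", "gene_id", "total_reads"]])
        classes.to_csv(outdir / "usage_classes.tsv", sep="\t")
        manifest["stages"]["classify"] = \
            classes["class"].value_counts().to_dict()
        if cfg.n_controls > 0:
            controls = classify_mod.sample_control_sites(
                genome, annotations[["chrom", "position"]], cfg.n_controls,
                seed=cfg.seed)
            controls.to_csv(outdir / "control_sites.tsv", sep="\t", index=False)
            manifest["stages"]["classify"]["control"] = len(controls)

        # ------------------------------------------------------ scan + schema
        stage = "schema"
        cluster_by_id = {c.cluster_id: c for c in passing}
        ann_by_region = annotations.set_index("site_id")
        flanks_by_class: dict[str, list] = {}
        for cls in cfg.classes:
            ids = ann_by_region.index[ann_by_region.region == cls]
            flanks_by_class[cls] = [
                extract_flank(cluster_by_id[i], genome, up=cfg.flank_up,
                              down=cfg.flank_down) for i in ids]
        strong_weak = None
        cls3 = flanks_by_class.get("3UTR")
        if cls3:
            sids = set(classes.index[classes["class"] == "strong"])
            wids = set(classes.index[classes["class"] == "weak"])
            sw = ([f for f in cls3 if f.site_id in sids],
                  [f for f in cls3 if f.site_id in wids])
            if min(len(sw[0]), len(sw[1])) >= cfg.min_strong_weak:
                strong_weak = {"3UTR": sw}
        reports = schema_mod.build_schema(
            flanks_by_class, strong_weak, k=cfg.k,
            cluster_cutoff=cfg.cluster_cutoff)
        all_elements = []
        tables = []
        for cls, rep in reports.items():
            tables.append(rep.table)
            all_elements.extend(rep.elements)
        elements_table = pd.concat(tables, ignore_index=True) if tables \
            else pd.DataFrame()
        elements_table.to_csv(outdir / "elements.tsv", sep="\t", index=False)
        if all_elements:
            schema_mod.write_pfms(all_elements, outdir / "elements_pfm.jaspar")
        if cls3:
            prof = schema_mod.nucleotide_profile(
                cls3, rel_range=(-cfg.flank_up, cfg.flank_down))
            prof.to_csv(outdir / "nucleotide_profile_3UTR.tsv", sep="\t")
        manifest["stages"]["schema"] = {
            cls: len(rep.elements) for cls, rep in reports.items()}

        # ----------------------------------------------------------- entropy
        stage = "entropy"
        site_counts = pd.DataFrame(
            {c.cluster_id: pd.Series(c.counts, index=stage_labels)
             for c in passing}).T
        site_counts.index.name = "site_id"
        records, cutoffs = entropy_mod.call_specific_constitutive(
            site_counts, pct=cfg.pct, min_reads=cfg.min_reads)
        records.to_csv(outdir / "entropy.tsv", sep="\t")
        summaries = entropy_mod.stage_summaries(records, site_counts,
                                                annotations)
        for name, df in summaries.items():
            df.to_csv(outdir / f"stage_{name}.tsv", sep="\t")
        manifest["stages"]["entropy"] = {
            "cutoffs": cutoffs,
            "labels": records.label.value_counts().to_dict()}

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        manifest["outputs"] = _checksums(outdir)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        return PipelineResult(outdir=outdir, manifest=manifest,
                              tables={"annotations": annotations,
                                      "gene_stats": gene_stats,
                                      "classes": classes,
                                      "elements": elements_table,
                                      "entropy": records})
    except Exception as exc:
        quarantine = outdir.parent / (outdir.name + "_quarantine")
        if quarantine.exists():
            shutil.rmtree(quarantine)
        if outdir.exists():
            shutil.move(str(outdir), str(quarantine))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _log_stage(name: str, t0: float, n_in: int, n_out: int) -> None:
    log.info("stage=%s wall=%.1fs records_in=%d records_out=%d",
             name, time.time() - t0, n_in, n_out)


def configure_logging(outdir: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(outdir) / "polyasig.log"))
    logging.basicConfig(level=logging.INFO, handlers=handlers,
                        format="%(asctime)s %(name)s %(message)s", force=True)
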