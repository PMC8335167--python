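"""Three-phase pipeline orchestration.

Phase I runs both gene statistics (sum-of-chi-squareds and min-p) against
the LD-aware simulation null; phase II Fisher-combines the two methods on
their nominal intersection and applies the meta-Bonferroni and stringent
dual-threshold selection rules; phase III runs hypergeometric
over-representation of the selected genes against a pathway collection.

Every intermediate table is written as TSV and a YAML run manifest records
the output paths, the thresholds actually used (with their runtime
divisors) and the counts at each stage.  Given identical inputs, config
and seed, every output is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as io
from .enrichment import EnrichmentConfig, run_ora
from .gene_mapping import DEFAULT_FLANK_BP, assign_snps, count_tested_genes
from .gene_tests import GeneTestConfig, Statistic, estimate_ld, run_gene_tests
from .meta_combine import (SelectionThresholds, bonferroni_threshold,
                           meta_analyse, select_meta_significant)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("genewise")


@dataclass
class PipelineConfig:
    """Validated configuration of one end-to-end run."""

    assoc: str
    glist: str
    genotypes: str
    gmt: str
    out_dir: str
    flank_bp: int = DEFAULT_FLANK_BP
    stages: tuple[int, ...] = (1_000, 10_000, 1_000_000)
    stage_thresholds: tuple[float, ...] = (0.1, 0.001)
    eigen_floor: float = 1e-8
    nominal_alpha: float = 0.05
    meta_alpha: float = 0.05
    stringent_alpha: float = 0.05
    n_tested_b: int | None = None
    min_size: int = 20
    max_size: int = 300
    ora_alpha: float = 0.05
    tail: str = "at_least"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["stage_thresholds"] = list(self.stage_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"assoc", "glist", "genotypes", "gmt", "out_dir"} - set(d)
        if missing:
            raise ValueError(f"missing required config keys: {sorted(missing)}")
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "stage_thresholds" in d:
            d["stage_thresholds"] = tuple(d["stage_thresholds"])
        cfg = cls(**d)
        # fail fast on invariants the gene tests would otherwise hit mid-run
        GeneTestConfig(stages=cfg.stages, stage_thresholds=cfg.stage_thresholds,
                       eigen_floor=cfg.eigen_floor)
        EnrichmentConfig(min_size=cfg.min_size, max_size=cfg.max_size,
                         alpha=cfg.ora_alpha, tail=cfg.tail)
        return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load + validate a YAML config; unknown keys and missing files error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw)
    for key in ("assoc", "glist", "genotypes", "gmt"):
        p = getattr(cfg, key)
        if not Path(p).exists():
            raise FileNotFoundError(f"config {key}: no such file {p!r}")
    log.info("effective config: %s", cfg.to_dict())
    return cfg


def _panel_ld_source(panel_path: str | Path, eigen_floor: float):
    """LD estimated per gene from a genotype reference panel TSV.

    The panel has one column per SNP id and one row per individual.
    """
    panel = pd.read_csv(panel_path, sep="\t")

    def ld_for(assignment, assoc):
        ids = [assoc[i].snp_id for i in assignment.snp_indices]
        missing = [s for s in ids if s not in panel.columns]
        if missing:
            raise KeyError(f"gene {assignment.gene.name!r}: SNPs missing from "
                           f"reference panel: {missing[:5]}")
        return estimate_ld(panel[ids].to_numpy(float), ids, eigen_floor)

    return ld_for


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all three phases; returns the run manifest (also written as YAML)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    assoc = io.read_assoc(config.assoc)
    genes = io.read_gene_ranges(config.glist)
    collection = io.read_gmt(config.gmt)
    assignments = assign_snps(assoc, genes, config.flank_bp)
    n_tested = count_tested_genes(assignments)
    log.info("phase I: %d SNPs, %d genes, %d testable (flank %d bp)",
             len(assoc), len(genes), n_tested, config.flank_bp)

    # ---- phase I: both gene statistics ------------------------------------
    ld_for = _panel_ld_source(config.genotypes, config.eigen_floor)
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    def run_method(statistic: Statistic, seed_seq) -> list:
        gcfg = GeneTestConfig(statistic=statistic, stages=config.stages,
                              stage_thresholds=config.stage_thresholds,
                              eigen_floor=config.eigen_floor,
                              seed=int(seed_seq.generate_state(1)[0] % (2**31)))
        return run_gene_tests(assoc, assignments,
                              lambda a: ld_for(a, assoc), gcfg)

    results_a = run_method(Statistic.SUM_CHISQ, seeds[0])
    results_b = run_method(Statistic.MIN_P, seeds[1])
    paths = {"gene_tests_a": out / "gene_tests_a.tsv",
             "gene_tests_b": out / "gene_tests_b.tsv"}
    io.write_gene_results(results_a, paths["gene_tests_a"])
    io.write_gene_results(results_b, paths["gene_tests_b"])

    # ---- phase II: meta-combination + selection ---------------------------
    n_tested_b = config.n_tested_b if config.n_tested_b is not None else n_tested
    thresholds = SelectionThresholds(nominal_alpha=config.nominal_alpha,
                                     meta_alpha=config.meta_alpha,
                                     stringent_alpha=config.stringent_alpha,
                                     n_tested_b=n_tested_b)
    meta = meta_analyse(results_a, results_b, thresholds)
    n_shared = thresholds.n_shared or 0
    meta_thr = bonferroni_threshold(config.meta_alpha, max(n_shared, 1))
    stringent_thr = bonferroni_threshold(config.stringent_alpha, n_tested_b)
    log.info("phase II: n_shared=%d, meta threshold %g = %g/%d, stringent "
             "threshold %g = %g/%d", n_shared, meta_thr, config.meta_alpha,
             max(n_shared, 1), stringent_thr, config.stringent_alpha, n_tested_b)

    meta_sig = select_meta_significant(meta, meta_thr)
    stringent = [r for r in meta if r.passes_stringent]
    paths["intersection"] = out / "intersection.tsv"
    paths["meta_all"] = out / "meta_all.tsv"
    paths["meta_significant"] = out / "meta_significant.tsv"
    paths["stringent"] = out / "stringent.tsv"
    io.write_results_table(meta, paths["intersection"])
    io.write_results_table(meta, paths["meta_all"])
    io.write_results_table(meta_sig, paths["meta_significant"])
    io.write_results_table(stringent, paths["stringent"])

    # ---- phase III: over-representation -----------------------------------
    universe = [a.gene.name for a in assignments if a.n_snps >= 1]
    targets = [r.gene for r in meta_sig]
    ecfg = EnrichmentConfig(min_size=config.min_size, max_size=config.max_size,
                            alpha=config.ora_alpha, tail=config.tail)
    ora_results, risk = run_ora(targets, universe, collection, ecfg)
    paths["enrichment"] = out / "enrichment.tsv"
    with open(paths["enrichment"], "w") as fh:
        fh.write("pathway\tname\tS\tJ\toverlap\tp\trisk_flag\n")
        for r in ora_results:
            fh.write(f"{r.pathway_id}\t{r.name}\t{r.S}\t{r.J}\t"
                     f"{','.join(r.overlap_genes)}\t{r.p:.6g}\t{int(r.p < ecfg.alpha)}\n")
    log.info("phase III: %d pathways tested, %d in risk subset",
             len(ora_results), len(risk))

    manifest = {
        "outputs": {k: str(v) for k, v in paths.items()},
        "counts": {
            "n_snps": len(assoc),
            "n_genes": len(genes),
            "n_tested": n_tested,
            "n_shared": n_shared,
            "n_meta_significant": len(meta_sig),
            "n_stringent": len(stringent),
            "n_pathways_tested": len(ora_results),
            "n_risk_pathways": len(risk),
        },
        "thresholds": {
            "nominal_alpha": config.nominal_alpha,
            "meta_bonferroni": meta_thr,
            "meta_divisor": max(n_shared, 1),
            "stringent": stringent_thr,
            "stringent_divisor": n_tested_b,
            "ora_alpha": config.ora_alpha,
        },
        "seed": config.seed,
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
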