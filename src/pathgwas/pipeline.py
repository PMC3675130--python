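"""End-to-end orchestration: simulate/load → QC → associate → map →
GSEA screen → ARTP validation → discordance exclusion → overlap pruning
→ report.

Stage ordering is enforced: ARTP only ever runs on the GSEA candidate
list, and superset elimination only on pathways that survive both
methods.  Given a fixed seed the whole run — including every rendered
table — is byte-identical across invocations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, artp, gsea, io_formats, mapping, qc
from .association import association_table, multivariate_demographics
from .containers import Cohort, GeneCatalog, PathwayCatalog
from .errors import PathgwasError, ValidationError
from .perm import permutation_engine
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    # either a directory of input files ...
    input_dir: str | None = None
    # ... or an inline simulation
    simulate: dict | None = None

    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    hwe_stratum: str = "controls"

    flank_bp: int = 20_000
    min_genes: int = 20
    max_genes: int = 200

    models: tuple = ("additive", "dominant")
    n_permutations: int = 1000
    stat_method: str = "score"
    stratified_permutation: bool = False

    gsea_weight: float = 1.0
    screen_p_max: float = 0.025
    screen_fdr_max: float = 0.25

    artp_k_set: tuple = artp.DEFAULT_K_SET
    artp_p_max: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        bad = set(self.models) - {"additive", "dominant"}
        if bad:
            raise ValidationError(f"unknown genetic models {sorted(bad)}")
        for name in ("maf_min", "call_rate_min", "hwe_p_min",
                     "screen_p_max", "screen_fdr_max", "artp_p_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "artp_k_set" in raw:
            raw["artp_k_set"] = tuple(raw["artp_k_set"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["artp_k_set"] = list(self.artp_k_set)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config: PipelineConfig
    qc_report: qc.QcReport
    counts: dict
    demographics: pd.DataFrame
    gsea_results: dict                  # model -> EnrichmentResult
    artp_results: dict                  # model -> DataFrame
    candidates: list
    validated: list
    discordant: pd.DataFrame
    final_pathways: list
    overlap: pd.DataFrame
    removal_log: pd.DataFrame
    stage_seconds: dict = field(default_factory=dict)

    @property
    def provenance(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
        }


def _stage(name, stages, t0):
    dt = time.perf_counter() - t0
    stages[name] = round(dt, 3)
    log.info("stage %-12s %.2fs", name, dt)
    return time.perf_counter()


def load_inputs(config: PipelineConfig):
    if (config.input_dir is None) == (config.simulate is None):
        raise ValidationError("config needs exactly one of input_dir / simulate")
    if config.simulate is not None:
        sim_cfg = dict(config.simulate)
        sim_cfg.setdefault("seed", config.seed)
        for key in ("n_snps_per_gene", "maf_range", "causal_pathways", "age_range"):
            if key in sim_cfg and isinstance(sim_cfg[key], list):
                sim_cfg[key] = tuple(sim_cfg[key])
        sim = simulate_cohort(SimulationConfig(**sim_cfg))
        return sim.cohort, sim.genes, sim.pathways
    d = Path(config.input_dir)
    cohort = io_formats.load_cohort_dir(d)
    genes = io_formats.read_gene_bed(d / "genes.bed")
    pathways = io_formats.read_gmt(d / "pathways.gmt")
    return cohort, genes, pathways


def run_pipeline(config: PipelineConfig) -> RunReport:
    stages: dict = {}
    t = time.perf_counter()
    try:
        cohort, genes, pathways = load_inputs(config)
    except PathgwasError as exc:
        raise PathgwasError(f"stage 'load': {exc}") from exc
    t = _stage("load", stages, t)

    thresholds = qc.QcThresholds(config.maf_min, config.call_rate_min,
                                 config.hwe_p_min)
    cohort_qc, qc_report = qc.apply_qc(cohort, thresholds, config.hwe_stratum)
    t = _stage("qc", stages, t)

    demographics = multivariate_demographics(cohort_qc)
    index = mapping.build_gene_snp_index(
        genes, cohort_qc.snp_ids, cohort_qc.snp_chrom, cohort_qc.snp_pos,
        flank=config.flank_bp,
    )
    filtered = mapping.filter_gene_sets(
        pathways, index.genes, config.min_genes, config.max_genes
    )
    if len(filtered) == 0:
        raise PathgwasError("stage 'map': no pathway survives the size filter")
    t = _stage("map", stages, t)

    perm = permutation_engine(
        cohort_qc, index, models=config.models, B=config.n_permutations,
        seed=config.seed, stat_method=config.stat_method,
        stratified=config.stratified_permutation,
    )
    t = _stage("permute", stages, t)

    gsea_results = {
        model: gsea.run_gsea(perm.gene_stats[model], filtered, config.gsea_weight)
        for model in config.models
    }
    candidates = gsea.screen_candidates(
        gsea_results, config.screen_p_max, config.screen_fdr_max
    )
    t = _stage("gsea", stages, t)

    # validation stage only ever sees the GSEA candidates
    artp_results = {
        model: artp.run_artp(perm.gene_stats[model], filtered, candidates,
                             config.artp_k_set)
        for model in config.models
    }
    validated, discordant = artp.validate_candidates(
        artp_results, gsea_results, config.artp_p_max,
        config.screen_p_max, config.screen_fdr_max,
    )
    surviving = [n for n in validated
                 if n not in set(discordant["pathway"])]
    t = _stage("artp", stages, t)

    overlap = (mapping.overlap_matrix(filtered.subset(surviving))
               if surviving else pd.DataFrame())
    final, removal_log = mapping.eliminate_supersets(filtered, surviving)
    t = _stage("prune", stages, t)

    mapped_snp_ids = sorted({int(j) for lst in index.snp_lists for j in lst})
    counts = {
        "n_samples": cohort_qc.n_samples,
        "n_snps_input": cohort.n_snps,
        "n_snps_pass_qc": cohort_qc.n_snps,
        "n_snps_mapped": len(mapped_snp_ids),
        "n_genes_mapped": len(index.genes),
        "n_genes_unmappable": len(index.unmappable),
        "n_pathways_input": len(pathways),
        "n_pathways_size_filtered": len(filtered),
        "n_candidates": len(candidates),
        "n_validated": len(validated),
        "n_final": len(final),
    }
    return RunReport(
        config=config, qc_report=qc_report, counts=counts,
        demographics=demographics, gsea_results=gsea_results,
        artp_results=artp_results, candidates=candidates, validated=validated,
        discordant=discordant, final_pathways=final, overlap=overlap,
        removal_log=removal_log, stage_seconds=stages,
    )


def candidate_table(report: RunReport) -> pd.DataFrame:
    """Wide per-candidate table: GSEA and ARTP statistics per model."""
    rows = []
    models = report.config.models
    for name in report.candidates:
        row: dict = {"pathway": name}
        for model in models:
            gt = report.gsea_results[model].table.set_index("pathway")
            g = gt.loc[name]
            row.setdefault("source", g["source"])
            row.setdefault("n_genes", int(g["n_genes"]))
            row[f"nes_{model}"] = g["nes"]
            row[f"gsea_p_{model}"] = g["p"]
            row[f"fdr_{model}"] = g["fdr"]
            at = report.artp_results[model].set_index("pathway")
            row[f"artp_p_{model}"] = at.loc[name, "adjusted_p"]
        row["validated"] = name in set(report.validated)
        row["final"] = name in set(report.final_pathways)
        rows.append(row)
    return pd.DataFrame(rows)


def render_tables(report: RunReport, outdir) -> dict:
    """Write the report as deterministic TSV files; returns path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = report.config.config_hash()
    paths = {}

    def emit(name, frame, index=False):
        path = out / name
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# pathgwas v{__version__} config={h} seed={report.config.seed}\n")
            frame.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)
        paths[name] = path

    cand = candidate_table(report)
    if cand.empty:
        cols = ["pathway", "source", "n_genes"]
        for m in report.config.models:
            cols += [f"nes_{m}", f"gsea_p_{m}", f"fdr_{m}", f"artp_p_{m}"]
        cand = pd.DataFrame(columns=cols + ["validated", "final"])
    emit("candidate_pathways.tsv", cand)
    emit("qc_summary.tsv", report.qc_report.frame)
    emit("demographics.tsv", report.demographics)
    emit("overlap_matrix.tsv", report.overlap, index=True)
    emit("removal_log.tsv", report.removal_log)
    for model in report.config.models:
        emit(f"gsea_{model}.tsv", report.gsea_results[model].table)
        emit(f"artp_{model}.tsv", report.artp_results[model])

    info = pd.DataFrame(
        sorted({**report.counts, **report.provenance}.items()),
        columns=["key", "value"],
    )
    emit("run_info.tsv", info)
    (out / "config.resolved.yaml").write_text(
        yaml.safe_dump(report.config.resolved(), sort_keys=True)
    )
    return paths
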