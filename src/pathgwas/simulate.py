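"""Synthetic case-control cohort generator.

Emulates the statistical structure the pathway pipeline assumes: HWE
genotypes at MAFs drawn from a configurable range, genes laid out on
synthetic chromosomes with >=50 kb gaps (so ±20 kb windows never leak
across genes), a pathway catalog with guaranteed subset and disjoint
pairs, demographic covariates, and case-control status drawn by
rejection from the logistic model

    logit P(case) = b0 + sum(beta_g * g) + beta_age*age
                    + beta_gender*gender + beta_smoking*smoking

with genotype effects planted only in designated pathway genes and the
intercept b0 calibrated by bisection so the expected case fraction
matches the requested design.  Default covariate odds ratios (gender
0.48, ever-smoking 0.52, age 0.98 per year) mirror the multivariate
demographic profile of a Korean NSCLC case-control panel; default
cohort size is 869 cases and 1,533 controls.

All randomness flows from a single seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .containers import Cohort, GeneCatalog, PathwayCatalog
from .errors import CalibrationError, ValidationError

import pandas as pd


@dataclass
class SimulationConfig:
    n_cases: int = 869
    n_controls: int = 1533
    n_genes: int = 300
    n_snps_per_gene: tuple = (2, 12)      # inclusive range, or a single int
    n_pathways: int = 40
    genes_per_pathway: int = 25
    maf_range: tuple = (0.05, 0.5)
    causal_pathways: tuple = ()           # indices into the base pathways
    causal_fraction: float = 0.5
    per_allele_or: float = 1.5
    or_gender: float = 0.48
    or_smoking: float = 0.52
    or_age_per_year: float = 0.98
    age_range: tuple = (40, 75)
    p_gender: float = 0.55                # P(gender == 1)
    p_smoking: float = 0.50
    missing_rate: float = 0.01
    genes_per_chromosome: int = 50
    gene_gap_bp: int = 60_000             # >= 50 kb so ±20 kb windows are isolated
    subset_pair_fraction: float = 0.8     # size of the guaranteed subset child
    ld_block: bool = False                # optional within-gene LD (copy-with-flip)
    ld_flip_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_snps_per_gene, int):
            self.n_snps_per_gene = (self.n_snps_per_gene, self.n_snps_per_gene)
        for name in ("n_cases", "n_controls", "n_genes", "n_pathways",
                     "genes_per_pathway"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        for name in ("per_allele_or", "or_gender", "or_smoking", "or_age_per_year"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be a positive odds ratio")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_genes < 2 * self.genes_per_pathway:
            raise ValidationError(
                "need n_genes >= 2*genes_per_pathway to guarantee a disjoint pair"
            )


@dataclass
class SimulationResult:
    cohort: Cohort
    genes: GeneCatalog
    pathways: PathwayCatalog
    truth: dict


def _gene_layout(cfg: SimulationConfig, rng: np.random.Generator):
    symbols, chroms, starts, ends, strands = [], [], [], [], []
    pos = 1
    for i in range(cfg.n_genes):
        chrom_i = i // cfg.genes_per_chromosome
        if i % cfg.genes_per_chromosome == 0:
            pos = 1
        length = int(rng.integers(5_000, 50_001))
        symbols.append(f"G{i:04d}")
        chroms.append(f"chr{chrom_i + 1}")
        starts.append(pos)
        ends.append(pos + length - 1)
        strands.append("+" if rng.random() < 0.5 else "-")
        pos += length + cfg.gene_gap_bp
    frame = pd.DataFrame({
        "symbol": symbols, "chrom": chroms, "start": starts,
        "end": ends, "strand": strands,
    })
    return GeneCatalog(frame)


def _snp_panel(cfg: SimulationConfig, genes: GeneCatalog, rng: np.random.Generator):
    snp_ids, snp_chrom, snp_pos, snp_gene, mafs = [], [], [], [], []
    lo, hi = cfg.n_snps_per_gene
    for row in genes.frame.itertuples(index=False):
        k = int(rng.integers(lo, hi + 1))
        span = row.end - row.start + 1
        offs = np.sort(rng.choice(span, size=min(k, span), replace=False))
        for o in offs:
            snp_ids.append(f"rs{len(snp_ids):06d}")
            snp_chrom.append(row.chrom)
            snp_pos.append(int(row.start + o))
            snp_gene.append(row.symbol)
            mafs.append(float(rng.uniform(*cfg.maf_range)))
    return (np.asarray(snp_ids, dtype=object), np.asarray(snp_chrom, dtype=object),
            np.asarray(snp_pos, dtype=np.int64), np.asarray(snp_gene, dtype=object),
            np.asarray(mafs))


def _base_pathways(cfg: SimulationConfig, genes: GeneCatalog,
                   rng: np.random.Generator) -> PathwayCatalog:
    """Base pathways; pathways 0 and 1 are guaranteed disjoint."""
    symbols = list(genes.symbols)
    half = len(symbols) // 2
    names, sources, members = [], [], []
    for i in range(cfg.n_pathways):
        if i == 0:
            pool = symbols[:half]
        elif i == 1:
            pool = symbols[half:]
        else:
            pool = symbols
        sel = rng.choice(len(pool), size=cfg.genes_per_pathway, replace=False)
        names.append(f"PW{i:03d}")
        sources.append("synthetic")
        members.append(tuple(pool[j] for j in sorted(sel)))
    return PathwayCatalog(names=names, sources=sources, members=members)


def plant_subset_pathway(catalog: PathwayCatalog, parent: str, fraction: float,
                         name: str | None = None,
                         rng: np.random.Generator | None = None) -> PathwayCatalog:
    """Append a pathway whose genes are a random subset of ``parent``.

    With ``fraction`` = 1 the child's gene set equals the parent's (only
    the name differs); the child always overlaps the parent 100% under
    the min-denominator overlap definition.
    """
    if parent not in catalog:
        raise ValidationError(f"parent pathway {parent!r} not in catalog")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    genes = catalog.genes_of(parent)
    k = max(1, int(round(fraction * len(genes))))
    rng = rng or np.random.default_rng(0)
    sel = sorted(rng.choice(len(genes), size=k, replace=False))
    child = tuple(genes[i] for i in sel)
    return catalog.add(name or f"{parent}_subset", catalog.source_of(parent), child)


def plant_superset_pathway(catalog: PathwayCatalog, child: str, extra_genes,
                           name: str | None = None) -> PathwayCatalog:
    """Append a pathway that strictly contains ``child`` (child ∪ extras)."""
    genes = tuple(catalog.genes_of(child)) + tuple(
        g for g in extra_genes if g not in set(catalog.genes_of(child))
    )
    if len(genes) == len(catalog.genes_of(child)):
        raise ValidationError("superset needs at least one extra gene")
    return catalog.add(name or f"{child}_superset", catalog.source_of(child), genes)


def _calibrate_beta0(eta_nointercept: np.ndarray, target: float) -> float:
    """Bisection for the intercept giving E[expit(b0 + eta)] = target."""
    lo, hi = -30.0, 30.0
    f = lambda b0: float(np.mean(expit(b0 + eta_nointercept))) - target  # noqa: E731
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            "cannot calibrate baseline risk: planted effects too extreme"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimulationConfig) -> SimulationResult:
    """Generate a full synthetic study: cohort, genes, pathways, truth."""
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_layout(cfg, rng)
    snp_ids, snp_chrom, snp_pos, snp_gene, mafs = _snp_panel(cfg, genes, rng)
    m = len(snp_ids)

    pathways = _base_pathways(cfg, genes, rng)
    base_names = list(pathways.names)
    pathways = plant_subset_pathway(
        pathways, base_names[0], cfg.subset_pair_fraction,
        name=f"{base_names[0]}_subset", rng=rng,
    )

    # causal genes: a fraction of each causal pathway's genes, one causal
    # SNP per causal gene (its first SNP by position)
    causal_genes: list[str] = []
    for pi in cfg.causal_pathways:
        members = pathways.genes_of(base_names[pi])
        k = max(1, math.ceil(cfg.causal_fraction * len(members)))
        sel = rng.choice(len(members), size=k, replace=False)
        causal_genes.extend(members[i] for i in sorted(sel))
    causal_gene_set = set(causal_genes)
    causal_snp_idx = []
    seen = set()
    for j in range(m):
        if snp_gene[j] in causal_gene_set and snp_gene[j] not in seen:
            causal_snp_idx.append(j)
            seen.add(snp_gene[j])
    causal_snp_idx = np.asarray(causal_snp_idx, dtype=np.int64)
    beta_g = math.log(cfg.per_allele_or)

    n_total = cfg.n_cases + cfg.n_controls
    target = cfg.n_cases / n_total
    b_age = math.log(cfg.or_age_per_year)
    b_gender = math.log(cfg.or_gender)
    b_smoking = math.log(cfg.or_smoking)
    age_lo, age_hi = cfg.age_range

    def draw_candidates(k):
        age = rng.integers(age_lo, age_hi + 1, size=k)
        gender = (rng.random(k) < cfg.p_gender).astype(np.int8)
        smoking = (rng.random(k) < cfg.p_smoking).astype(np.int8)
        gcausal = rng.binomial(2, mafs[causal_snp_idx], size=(k, len(causal_snp_idx)))
        eta = (b_age * age + b_gender * gender + b_smoking * smoking
               + beta_g * gcausal.sum(axis=1))
        return age, gender, smoking, gcausal, eta

    # calibrate b0 on a dedicated large draw
    cal = draw_candidates(20_000)
    beta0 = _calibrate_beta0(cal[4], target)

    # rejection sampling until both pools are filled
    cases, controls = [], []
    max_rounds = 200
    for _ in range(max_rounds):
        if len(cases) >= cfg.n_cases and len(controls) >= cfg.n_controls:
            break
        age, gender, smoking, gcausal, eta = draw_candidates(n_total)
        is_case = rng.random(n_total) < expit(beta0 + eta)
        for i in range(n_total):
            rec = (int(age[i]), int(gender[i]), int(smoking[i]), gcausal[i])
            if is_case[i] and len(cases) < cfg.n_cases:
                cases.append(rec)
            elif not is_case[i] and len(controls) < cfg.n_controls:
                controls.append(rec)
    if len(cases) < cfg.n_cases or len(controls) < cfg.n_controls:
        raise CalibrationError("rejection sampling failed to fill case/control pools")

    records = cases + controls
    phenotype = np.concatenate([np.ones(cfg.n_cases, dtype=np.int8),
                                np.zeros(cfg.n_controls, dtype=np.int8)])
    age = np.array([r[0] for r in records], dtype=np.int64)
    gender = np.array([r[1] for r in records], dtype=np.int8)
    smoking = np.array([r[2] for r in records], dtype=np.int8)

    # non-causal genotypes are independent of status: fill the matrix in
    # HWE and overwrite causal columns with the status-linked draws
    genotypes = rng.binomial(2, mafs, size=(n_total, m)).astype(np.float64)
    if len(causal_snp_idx):
        gcausal = np.vstack([r[3] for r in records]).astype(np.float64)
        genotypes[:, causal_snp_idx] = gcausal

    if cfg.ld_block:
        # copy-with-flip LD: each non-causal SNP after the first in a gene
        # copies its gene's first SNP with per-allele flip noise
        first_of_gene: dict[str, int] = {}
        for j in range(m):
            g = snp_gene[j]
            if g not in first_of_gene:
                first_of_gene[g] = j
            elif j not in set(causal_snp_idx.tolist()):
                src = genotypes[:, first_of_gene[g]]
                noise = rng.binomial(2, cfg.ld_flip_rate, size=n_total)
                genotypes[:, j] = np.clip(src + noise - 1, 0, 2)

    if cfg.missing_rate > 0:
        mask = rng.random((n_total, m)) < cfg.missing_rate
        genotypes[mask] = np.nan

    cohort = Cohort(
        sample_ids=np.asarray([f"S{i:05d}" for i in range(n_total)], dtype=object),
        phenotype=phenotype, age=age, gender=gender, smoking=smoking,
        genotypes=genotypes, snp_ids=snp_ids, snp_chrom=snp_chrom, snp_pos=snp_pos,
    )
    truth = {
        "beta0": beta0,
        "beta_per_allele": beta_g if len(causal_snp_idx) else 0.0,
        "beta_age": b_age,
        "beta_gender": b_gender,
        "beta_smoking": b_smoking,
        "causal_snps": [str(snp_ids[j]) for j in causal_snp_idx],
        "causal_genes": sorted(causal_gene_set),
        "causal_pathways": [base_names[i] for i in cfg.causal_pathways],
        "subset_pair": [f"{base_names[0]}_subset", base_names[0]],
        "disjoint_pair": [base_names[0], base_names[1]],
        "maf": mafs.tolist(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return SimulationResult(cohort=cohort, genes=genes, pathways=pathways, truth=truth)


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write genotypes.tsv, samples.tsv, snps.tsv, genes.bed, pathways.gmt,
    truth.json into ``outdir``."""
    from . import io_formats as io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    c = result.cohort
    io.write_genotypes(out / "genotypes.tsv", c.sample_ids, c.snp_ids, c.genotypes)
    io.write_samples(out / "samples.tsv", c)
    io.write_snp_map(out / "snps.tsv", c.snp_ids, c.snp_chrom, c.snp_pos)
    io.write_gene_bed(out / "genes.bed", result.genes)
    io.write_gmt(out / "pathways.gmt", result.pathways)
    (out / "truth.json").write_text(json.dumps(result.truth, indent=1, sort_keys=True))
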