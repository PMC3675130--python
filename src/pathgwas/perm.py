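"""Phenotype-permutation engine shared by the GSEA and ARTP stages.

Column 0 is always the identity permutation (observed labels) and is
computed by exactly the same code path as the permuted columns, so the
identity column reproduces the observed statistics bit-for-bit.  The
same permutation set drives both pathway methods: GSEA consumes each
gene's best-SNP |statistic|, ARTP the matching best-SNP p-value, from
one :class:`GeneStatMatrix` per genetic model.

Permutations are unrestricted label shuffles: covariates and genotypes
stay attached to their samples and the covariate-adjusted model is refit
(score test) or re-evaluated under each relabeling.  A stratified option
(shuffling within gender × smoking strata) is available because an
unrestricted shuffle breaks any covariate–phenotype association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    GENETIC_MODELS,
    batch_logistic_score,
    batch_logistic_wald,
    code_genotypes,
    fit_null_logistic,
    mean_impute,
)
from .containers import COVARIATES, Cohort
from .errors import ValidationError
from .mapping import GeneSnpIndex, best_snp_reduce


@dataclass
class GeneStatMatrix:
    """Best-SNP statistic and p-value per gene per phenotype column.

    Column 0 holds the observed labels; columns 1..B the permutations.
    Genes are sorted by symbol (the deterministic tie-break order used
    for ranking).
    """

    genes: np.ndarray
    stat: np.ndarray      # (G, B+1) best-SNP |stat|
    pval: np.ndarray      # (G, B+1) best-SNP p
    chosen: np.ndarray    # (G, B+1) SNP column index, -1 = gene missing
    model: str

    @property
    def n_perm(self) -> int:
        return self.stat.shape[1] - 1


@dataclass
class PermutationResult:
    gene_stats: dict            # model -> GeneStatMatrix
    perm_labels: np.ndarray     # (B+1, n) phenotype columns; row 0 observed
    stat_method: str
    seed: int


def permutation_labels(phenotype: np.ndarray, B: int, rng: np.random.Generator,
                       strata: np.ndarray | None = None) -> np.ndarray:
    """(B+1, n) label matrix; row 0 is the observed phenotype."""
    if B < 1:
        raise ValidationError("need at least one permutation (B >= 1)")
    y = np.asarray(phenotype, dtype=np.int8)
    n = len(y)
    out = np.empty((B + 1, n), dtype=np.int8)
    out[0] = y
    if strata is None:
        for b in range(1, B + 1):
            out[b] = y[rng.permutation(n)]
    else:
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for b in range(1, B + 1):
            row = np.empty(n, dtype=np.int8)
            for idx in groups:
                row[idx] = y[idx][rng.permutation(len(idx))]
            out[b] = row
    return out


def permutation_engine(cohort: Cohort, index: GeneSnpIndex,
                       models=GENETIC_MODELS, B: int = 1000, seed: int = 0,
                       stat_method: str = "score", adjust=COVARIATES,
                       stratified: bool = False) -> PermutationResult:
    """Recompute per-SNP association and best-SNP reduction per permutation.

    ``stat_method="score"`` (default) uses the covariate-null score test
    with mean-imputed genotypes — one small null fit plus a few matrix
    products per column.  ``"wald"`` runs the full batched IRLS refit
    with exact casewise deletion for every column (slow; small data).
    """
    if stat_method not in ("score", "wald"):
        raise ValidationError(f"unknown stat_method {stat_method!r}")
    rng = np.random.default_rng(seed)
    strata = None
    if stratified:
        strata = cohort.gender.astype(np.int64) * 2 + cohort.smoking
    labels = permutation_labels(cohort.phenotype, B, rng, strata)
    C = cohort.covariate_matrix(adjust)
    ncol = B + 1

    gene_stats = {}
    for model in models:
        G = code_genotypes(cohort.genotypes, model)
        m = G.shape[1]
        stat = np.empty((m, ncol))
        pval = np.empty((m, ncol))
        flags = np.empty((m, ncol), dtype=object)
        if stat_method == "score":
            Gimp = mean_impute(G)
            for b in range(ncol):
                y = labels[b].astype(np.float64)
                null_beta = fit_null_logistic(C, y)
                z, p, fl = batch_logistic_score(Gimp, C, y, null_beta)
                stat[:, b], pval[:, b], flags[:, b] = z, p, fl
        else:
            for b in range(ncol):
                _, _, t, p, fl = batch_logistic_wald(G, C, labels[b])
                stat[:, b], pval[:, b], flags[:, b] = t, p, fl
        gstat, gp, chosen = best_snp_reduce(index, stat, pval, flags)
        gene_stats[model] = GeneStatMatrix(
            genes=np.asarray(index.genes, dtype=object),
            stat=gstat, pval=gp, chosen=chosen, model=model,
        )
    return PermutationResult(gene_stats=gene_stats, perm_labels=labels,
                             stat_method=stat_method, seed=seed)
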