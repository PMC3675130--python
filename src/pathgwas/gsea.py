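"""Gene set enrichment screening over ranked best-SNP gene statistics.

For each phenotype column, genes are ranked by their best-SNP |t|
(largest first, ties broken by gene symbol) and a weighted
Kolmogorov-Smirnov-like running sum is walked down the list: hits add
|r_j|^w / N_R (N_R the sum of weighted member statistics), misses
subtract 1/(N - N_H).  The enrichment score ES is the signed maximum of
the running sum — enrichment at the *top* of the list is the hypothesis.

The permutation columns give each pathway a null ES distribution; the
normalized score is NES = (ES_obs − mean ES_perm) / sd ES_perm, the
nominal p uses the add-one estimator, and the FDR is the
ratio-of-tail-fractions estimator over pooled permuted NES values,
computed on the positive-enrichment side and clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PathwayCatalog
from .errors import ValidationError
from .perm import GeneStatMatrix, PermutationResult, permutation_engine  # noqa: F401

DEFAULT_WEIGHT = 1.0
SCREEN_P_MAX = 0.025
SCREEN_FDR_MAX = 0.25


def enrichment_score(stats: np.ndarray, member: np.ndarray,
                     weight: float = DEFAULT_WEIGHT) -> float:
    """ES for one ranked list (single column convenience wrapper).

    ``stats`` are per-gene statistics in *gene order* (not pre-sorted);
    ``member`` is the boolean membership mask over the same genes.
    """
    stats = np.asarray(stats, dtype=np.float64)
    member = np.asarray(member, dtype=bool)
    return float(_es_columns(stats[:, None], member, weight)[0])


def _es_columns(stats: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    """Vectorized ES over columns of a (G, C) gene-stat matrix.

    NaN gene entries (gene missing in a column) are dropped from that
    column's ranking; member genes among them shrink N_H accordingly.
    """
    G, C = stats.shape
    nh_total = int(member.sum())
    if nh_total == 0:
        raise ValidationError("empty member set")
    valid = ~np.isnan(stats)
    n_col = valid.sum(axis=0)
    key = np.where(valid, stats, -np.inf)
    order = np.argsort(-key, axis=0, kind="stable")   # genes pre-sorted by symbol
    r = np.take_along_axis(np.abs(np.where(valid, stats, 0.0)), order, axis=0)
    msort = np.take_along_axis(member[:, None] & valid, order, axis=0)
    vsort = np.take_along_axis(valid, order, axis=0)

    nh = msort.sum(axis=0)
    if (nh >= n_col).any():
        raise ValidationError("pathway contains every ranked gene")
    if (nh == 0).any():
        raise ValidationError("pathway has no ranked gene in some column")

    rw = np.where(msort, r ** weight, 0.0)
    nr = rw.sum(axis=0)
    hit = np.divide(rw, nr, out=np.zeros_like(rw), where=nr > 0)
    # all member stats exactly zero: fall back to unweighted hit steps
    degenerate = nr <= 0
    if degenerate.any():
        hit[:, degenerate] = msort[:, degenerate] / nh[degenerate]
    miss = (vsort & ~msort) / (n_col - nh)
    return np.max(np.cumsum(hit - miss, axis=0), axis=0)


def normalize_and_p(es_obs: float, es_perm: np.ndarray) -> tuple[float, float]:
    """NES and add-one nominal p from a pathway's permutation ES sample."""
    es_perm = np.asarray(es_perm, dtype=np.float64)
    B = len(es_perm)
    if B < 2:
        raise ValidationError("need at least 2 permutations to normalize")
    p = (1.0 + np.sum(es_perm >= es_obs)) / (B + 1.0)
    sd = float(np.std(es_perm, ddof=1))
    if sd <= 0:
        return float("nan"), float(p)
    nes = (es_obs - float(np.mean(es_perm))) / sd
    return float(nes), float(p)


def gsea_fdr(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """Permutation FDR: ratio of pooled-null to observed tail fractions.

    Positive-enrichment side only; pathways with non-positive observed
    NES get FDR = 1.  Estimator can exceed 1 and is clamped to [0, 1].
    """
    nes_obs = np.asarray(nes_obs, dtype=np.float64)
    pool = np.asarray(nes_perm, dtype=np.float64).ravel()
    pool = pool[~np.isnan(pool)]
    obs = nes_obs[~np.isnan(nes_obs)]
    out = np.ones_like(nes_obs)
    for i, star in enumerate(nes_obs):
        if not np.isfinite(star) or star <= 0:
            continue
        num = np.mean(pool >= star) if pool.size else 0.0
        den = np.mean(obs >= star) if obs.size else 1.0
        out[i] = min(1.0, num / den) if den > 0 else 1.0
    return out


@dataclass
class EnrichmentResult:
    """Per-pathway GSEA table for one genetic model plus raw ES arrays."""

    model: str
    table: pd.DataFrame          # pathway, source, n_genes, es, nes, p, fdr
    es: np.ndarray               # (P, B+1) observed + permuted ES
    nes: np.ndarray              # (P, B+1) normalized scores


def run_gsea(gsm: GeneStatMatrix, catalog: PathwayCatalog,
             weight: float = DEFAULT_WEIGHT) -> EnrichmentResult:
    """Score every pathway in ``catalog`` against one GeneStatMatrix."""
    gene_pos = {g: i for i, g in enumerate(gsm.genes)}
    P, C = len(catalog), gsm.stat.shape[1]
    es = np.empty((P, C))
    n_genes = np.empty(P, dtype=int)
    for i, (name, _, genes) in enumerate(catalog.items()):
        member = np.zeros(len(gsm.genes), dtype=bool)
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            raise ValidationError(f"pathway {name!r} has no gene in the ranked list")
        member[idx] = True
        n_genes[i] = len(idx)
        es[i] = _es_columns(gsm.stat, member, weight)

    mean = es[:, 1:].mean(axis=1)
    sd = es[:, 1:].std(axis=1, ddof=1)
    with np.errstate(all="ignore"):
        nes = (es - mean[:, None]) / sd[:, None]
    nes[sd <= 0, :] = np.nan
    pvals = (1.0 + np.sum(es[:, 1:] >= es[:, [0]], axis=1)) / (C - 1 + 1.0)
    fdr = gsea_fdr(nes[:, 0], nes[:, 1:])
    table = pd.DataFrame({
        "pathway": catalog.names,
        "source": catalog.sources,
        "n_genes": n_genes,
        "es": es[:, 0],
        "nes": nes[:, 0],
        "p": pvals,
        "fdr": fdr,
    })
    return EnrichmentResult(model=gsm.model, table=table, es=es, nes=nes)


def screen_candidates(results: dict, p_max: float = SCREEN_P_MAX,
                      fdr_max: float = SCREEN_FDR_MAX) -> list:
    """Two-stage screen: candidate iff p <= p_max AND fdr <= fdr_max in
    *any* genetic model (inclusive boundaries).  Preserves catalog order."""
    candidates: list[str] = []
    order: list[str] = []
    hits = set()
    for model, res in results.items():
        for row in res.table.itertuples(index=False):
            if row.pathway not in order:
                order.append(row.pathway)
            if row.p <= p_max and row.fdr <= fdr_max:
                hits.add(row.pathway)
    candidates = [n for n in order if n in hits]
    return candidates
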