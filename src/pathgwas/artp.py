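"""Adaptive rank truncated product (ARTP) pathway validation.

For one pathway with L analyzed genes, each phenotype column's best-SNP
gene p-values are sorted ascending (P_1 <= ... <= P_L) and the rank
truncated product W(K) = prod_{i<=K} P_i is computed (as a sum of logs)
for every candidate truncation point K.  A single shared permutation
layer estimates, for every column b (0 = observed), the per-K
significance

    s_b(K) = (1 + #{b' != b : W_{b'}(K) <= W_b(K)}) / (B + 1),

the adaptive statistic t_b = min_K s_b(K), and the adjusted p-value

    p_adj = (1 + #{b >= 1 : t_b <= t_0}) / (B + 1).

Because every K reuses the same columns, no second permutation layer is
needed and the adjusted p is comparable across pathways of any size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PathwayCatalog
from .errors import ValidationError
from .perm import GeneStatMatrix

DEFAULT_K_SET = (1, 2, 3, 4, 5, 10, 15, 20)
VALIDATE_P_MAX = 0.01


def rtp_statistic(sorted_p: np.ndarray, K: int) -> float:
    """Product of the K smallest p-values, computed in log space."""
    sorted_p = np.asarray(sorted_p, dtype=np.float64)
    if K < 1 or K > len(sorted_p):
        raise ValidationError(f"truncation point K={K} outside 1..{len(sorted_p)}")
    if (sorted_p <= 0).any() or (sorted_p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return float(np.exp(np.sum(np.log(sorted_p[:K]))))


@dataclass
class ArtpResult:
    pathway: str
    model: str
    k_set: tuple                 # truncation points actually used
    w_obs: np.ndarray            # observed W(K) profile
    s_obs: np.ndarray            # observed per-K significance s_0(K)
    t_obs: float                 # adaptive statistic min_K s_0(K)
    adjusted_p: float
    n_genes: int


def artp_adjusted_p(gene_p: np.ndarray, k_set=DEFAULT_K_SET,
                    pathway: str = "", model: str = "") -> ArtpResult:
    """Single-layer adaptive RTP p-value for one pathway.

    ``gene_p`` is (L, B+1): best-SNP p-values of the pathway's genes for
    the observed (column 0) and permuted columns.  Genes missing a
    usable p in a column are skipped in that column's sort; K is clamped
    to the number of usable genes per column.
    """
    gene_p = np.asarray(gene_p, dtype=np.float64)
    if gene_p.ndim != 2:
        raise ValidationError("gene_p must be (genes, columns)")
    L, C = gene_p.shape
    if C < 2:
        raise ValidationError("need at least one permutation column")
    k_set = tuple(sorted({int(k) for k in k_set if 1 <= int(k) <= L}))
    if not k_set:
        raise ValidationError("empty truncation set after intersecting with 1..L")

    logp = np.where(np.isnan(gene_p), np.inf, np.log(np.clip(gene_p, 1e-300, 1.0)))
    logp_sorted = np.sort(logp, axis=0)
    n_usable = (~np.isnan(gene_p)).sum(axis=0)
    if (n_usable == 0).any():
        raise ValidationError("a column has no usable gene p-value")
    cum = np.cumsum(np.where(np.isinf(logp_sorted), 0.0, logp_sorted), axis=0)

    nK = len(k_set)
    logW = np.empty((nK, C))
    for ki, K in enumerate(k_set):
        k_eff = np.minimum(K, n_usable)           # clamp where a column lost genes
        logW[ki] = cum[k_eff - 1, np.arange(C)]

    # per-K significance: rank of each column's W among all columns
    s = np.empty((nK, C))
    for ki in range(nK):
        w = logW[ki]
        order = np.sort(w)
        cnt_le = np.searchsorted(order, w, side="right")   # includes self
        s[ki] = cnt_le / C                                  # = (1 + #others<=) / (B+1)
    t = s.min(axis=0)
    adjusted = (1.0 + np.sum(t[1:] <= t[0])) / C
    return ArtpResult(
        pathway=pathway, model=model, k_set=k_set,
        w_obs=np.exp(logW[:, 0]), s_obs=s[:, 0], t_obs=float(t[0]),
        adjusted_p=float(adjusted), n_genes=L,
    )


def run_artp(gsm: GeneStatMatrix, catalog: PathwayCatalog, candidates=None,
             k_set=DEFAULT_K_SET) -> pd.DataFrame:
    """ARTP adjusted p for each (candidate) pathway under one model."""
    names = list(catalog.names) if candidates is None else [
        n for n in catalog.names if n in set(candidates)
    ]
    gene_pos = {g: i for i, g in enumerate(gsm.genes)}
    rows = []
    for name in names:
        idx = [gene_pos[g] for g in catalog.genes_of(name) if g in gene_pos]
        if not idx:
            raise ValidationError(f"pathway {name!r} has no analyzed gene")
        res = artp_adjusted_p(gsm.pval[idx, :], k_set, pathway=name, model=gsm.model)
        rows.append({
            "pathway": name,
            "source": catalog.source_of(name),
            "n_genes": res.n_genes,
            "t_obs": res.t_obs,
            "adjusted_p": res.adjusted_p,
        })
    return pd.DataFrame(rows)


def validate_candidates(artp_results: dict, gsea_results: dict | None = None,
                        threshold: float = VALIDATE_P_MAX,
                        gsea_p_max: float = 0.025,
                        gsea_fdr_max: float = 0.25):
    """Validate GSEA candidates by ARTP and flag method discordance.

    A candidate is validated iff its ARTP adjusted p <= ``threshold`` in
    any genetic model.  The discordance report lists, per model, every
    candidate that passed the GSEA screen in that model but whose ARTP
    p in the same model exceeds the threshold.

    Returns ``(validated names, discordance DataFrame)``.
    """
    validated, order = set(), []
    for model, table in artp_results.items():
        for row in table.itertuples(index=False):
            if row.pathway not in order:
                order.append(row.pathway)
            if row.adjusted_p <= threshold:
                validated.add(row.pathway)

    discord = []
    if gsea_results is not None:
        for model, table in artp_results.items():
            gres = gsea_results.get(model)
            if gres is None:
                continue
            gt = gres.table.set_index("pathway")
            for row in table.itertuples(index=False):
                if row.pathway not in gt.index:
                    continue
                g = gt.loc[row.pathway]
                gsea_sig = g["p"] <= gsea_p_max and g["fdr"] <= gsea_fdr_max
                if gsea_sig and row.adjusted_p > threshold:
                    discord.append({
                        "pathway": row.pathway,
                        "model": model,
                        "gsea_p": float(g["p"]),
                        "gsea_fdr": float(g["fdr"]),
                        "artp_p": float(row.adjusted_p),
                    })
    discord_df = pd.DataFrame(discord,
                              columns=["pathway", "model", "gsea_p", "gsea_fdr", "artp_p"])
    return [n for n in order if n in validated], discord_df
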