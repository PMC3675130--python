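"""SNP-to-gene mapping, best-SNP reduction and pathway set structure.

A SNP belongs to a gene's region when it lies within ``flank`` bp
(default 20 kb) of the gene's genomic span, boundaries inclusive; the
flank is applied symmetrically regardless of strand, so the 5'/3'
distinction is immaterial.  SNPs between nearby genes may map to more
than one gene.  Each gene is then represented by its single most
significant SNP.

Pathway-level set operations live here too: size filtering on mappable
membership, the min-denominator overlap fraction, and superset
elimination among candidate pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneCatalog, PathwayCatalog
from .errors import ValidationError

DEFAULT_FLANK = 20_000


@dataclass
class GeneSnpIndex:
    """Bidirectional gene <-> SNP index over a cohort's SNP panel.

    ``genes`` are sorted by symbol; ``snp_lists[i]`` holds the column
    indices of the SNPs in gene i's extended region, sorted by
    (position, SNP id) so that downstream argmax tie-breaks are
    deterministic.  Genes with no mapped SNP are listed separately as
    unmappable and excluded from gene sets downstream.
    """

    genes: list
    snp_lists: list                      # list[np.ndarray of SNP column indices]
    unmappable: list = field(default_factory=list)
    n_snps: int = 0

    def __post_init__(self) -> None:
        if any(len(s) == 0 for s in self.snp_lists):
            raise ValidationError("mappable gene with empty SNP list")

    @property
    def snp_to_genes(self) -> dict:
        out: dict[int, list] = {}
        for gene, snps in zip(self.genes, self.snp_lists):
            for j in snps:
                out.setdefault(int(j), []).append(gene)
        return out


def build_gene_snp_index(genes: GeneCatalog, snp_ids, snp_chrom, snp_pos,
                         flank: int = DEFAULT_FLANK) -> GeneSnpIndex:
    """Map SNPs to extended gene regions (inclusive ±flank windows)."""
    snp_ids = np.asarray(snp_ids, dtype=object)
    snp_chrom = np.asarray(snp_chrom, dtype=object)
    snp_pos = np.asarray(snp_pos, dtype=np.int64)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in np.unique(snp_chrom):
        idx = np.flatnonzero(snp_chrom == chrom)
        order = np.lexsort((snp_ids[idx].astype(str), snp_pos[idx]))
        idx = idx[order]
        by_chrom[str(chrom)] = (snp_pos[idx], idx)

    mapped_genes, snp_lists, unmappable = [], [], []
    frame = genes.frame.sort_values("symbol", kind="stable")
    for row in frame.itertuples(index=False):
        entry = by_chrom.get(str(row.chrom))
        hits = np.empty(0, dtype=np.int64)
        if entry is not None:
            pos, idx = entry
            lo = np.searchsorted(pos, row.start - flank, side="left")
            hi = np.searchsorted(pos, row.end + flank, side="right")
            hits = idx[lo:hi]
        if hits.size:
            mapped_genes.append(row.symbol)
            snp_lists.append(hits)
        else:
            unmappable.append(row.symbol)
    return GeneSnpIndex(genes=mapped_genes, snp_lists=snp_lists,
                        unmappable=unmappable, n_snps=len(snp_ids))


def best_snp_reduce(index: GeneSnpIndex, stat: np.ndarray, pval: np.ndarray,
                    flags: np.ndarray | None = None):
    """Select each gene's most significant SNP per column.

    Parameters
    ----------
    stat, pval : (n_snps, C) per-SNP statistic (signed) and p-value;
        columns are observed/permuted phenotype labelings.
    flags : optional (n_snps, C) or (n_snps,) truthy = SNP ineligible.

    Returns
    -------
    gene_stat, gene_p : (G, C) best-SNP |stat| and its p-value (NaN where
        a gene has no eligible SNP in a column)
    chosen : (G, C) SNP column index of the selected SNP, -1 if none
    """
    stat = np.atleast_2d(np.asarray(stat, dtype=np.float64))
    pval = np.atleast_2d(np.asarray(pval, dtype=np.float64))
    if stat.ndim == 2 and stat.shape[0] == 1 and index.n_snps != 1:
        stat, pval = stat.T, pval.T
    m, C = stat.shape
    absstat = np.abs(stat)
    if flags is not None:
        flags = np.asarray(flags)
        bad = flags.astype(bool) if flags.dtype != object else (flags != "")
        if bad.ndim == 1:
            bad = bad[:, None] & np.ones((1, C), dtype=bool)
        absstat = np.where(bad, -np.inf, absstat)
    absstat = np.where(np.isnan(absstat), -np.inf, absstat)

    G = len(index.genes)
    gene_stat = np.full((G, C), np.nan)
    gene_p = np.full((G, C), np.nan)
    chosen = np.full((G, C), -1, dtype=np.int64)
    for i, snps in enumerate(index.snp_lists):
        sub = absstat[snps]                       # (k, C)
        pick = np.argmax(sub, axis=0)             # first max = (pos, id) tie-break
        best = sub[pick, np.arange(C)]
        ok = np.isfinite(best)
        gene_stat[i, ok] = best[ok]
        gene_p[i, ok] = pval[snps[pick[ok]], np.flatnonzero(ok)]
        chosen[i, ok] = snps[pick[ok]]
    return gene_stat, gene_p, chosen


def filter_gene_sets(catalog: PathwayCatalog, mappable_genes,
                     min_size: int = 20, max_size: int = 200) -> PathwayCatalog:
    """Intersect membership with mappable genes, then size-filter.

    The returned catalog carries the *intersected* membership (the genes
    the statistics actually see); boundaries are inclusive.
    """
    mappable = set(mappable_genes)
    names, sources, members = [], [], []
    for name, source, genes in catalog.items():
        kept = tuple(g for g in genes if g in mappable)
        if min_size <= len(kept) <= max_size:
            names.append(name)
            sources.append(source)
            members.append(kept)
    return PathwayCatalog(names=names, sources=sources, members=members)


def overlap_fraction(a, b) -> float:
    """Overlap percentage 100·|A∩B| / min(|A|,|B|).

    100% means one set is contained in the other (or the sets are equal).
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValidationError("overlap fraction undefined for an empty gene set")
    return 100.0 * len(a & b) / min(len(a), len(b))


def overlap_matrix(catalog: PathwayCatalog) -> pd.DataFrame:
    """Symmetric pathway × pathway overlap-percentage matrix."""
    n = len(catalog)
    out = np.zeros((n, n))
    sets = [set(m) for m in catalog.members]
    for i in range(n):
        out[i, i] = 100.0
        for j in range(i + 1, n):
            v = 100.0 * len(sets[i] & sets[j]) / min(len(sets[i]), len(sets[j]))
            out[i, j] = out[j, i] = v
    return pd.DataFrame(out, index=catalog.names, columns=catalog.names)


def eliminate_supersets(catalog: PathwayCatalog, candidates=None):
    """Prune candidate pathways that contain another candidate.

    For every pair where one gene set is contained in the other, the
    larger (superset) is removed; chains are handled transitively (every
    strict superset of any surviving set is removed).  Equal sets keep
    the first in catalog order.

    Returns ``(survivor names, removal log DataFrame)`` where the log
    records each removed pathway with a justifying subset.
    """
    names = list(catalog.names) if candidates is None else [
        n for n in catalog.names if n in set(candidates)
    ]
    sets = {n: set(catalog.genes_of(n)) for n in names}
    removed: dict[str, tuple[str, str]] = {}

    # equal sets: keep the first in catalog order
    for i, ni in enumerate(names):
        if ni in removed:
            continue
        for nj in names[i + 1:]:
            if nj not in removed and sets[ni] == sets[nj]:
                removed[nj] = (ni, "equal")
    survivors0 = [n for n in names if n not in removed]
    # strict supersets of any surviving set are removed
    for ni in survivors0:
        subsets = [nj for nj in survivors0
                   if nj != ni and sets[nj] < sets[ni]]
        if subsets:
            smallest = min(subsets, key=lambda n: (len(sets[n]), names.index(n)))
            removed[ni] = (smallest, "superset")
    survivors = [n for n in names if n not in removed]
    log = pd.DataFrame(
        [(n, why, sub) for n, (sub, why) in removed.items()],
        columns=["removed", "relation", "justified_by"],
    )
    return survivors, log
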