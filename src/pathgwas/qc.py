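"""SNP-level quality control: MAF, call rate and exact Hardy-Weinberg test.

Filter semantics (taken literally from the source GWAS conventions):
SNPs with MAF < 5% or call rate < 95% are excluded (boundary values are
kept), and SNPs with exact-HWE p <= 1e-4 are excluded (the boundary value
is dropped).  HWE is computed in controls only by default, the standard
practice for case-control panels, with an all-samples option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .containers import Cohort
from .errors import ValidationError


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Per-SNP QC metrics, pass flags and failure reasons."""

    frame: pd.DataFrame  # snp_id, maf, call_rate, hwe_p, pass, reasons

    @property
    def summary(self) -> dict:
        f = self.frame
        reasons = f["reasons"].str.split(",")
        count = lambda tag: int(sum(tag in r for r in reasons))  # noqa: E731
        return {
            "n_snps": len(f),
            "n_pass": int(f["pass"].sum()),
            "n_fail": int((~f["pass"]).sum()),
            "fail_maf": count("maf"),
            "fail_call_rate": count("call_rate"),
            "fail_hwe": count("hwe"),
        }


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """(n0, n1, n2) non-missing genotype counts of one SNP column."""
    obs = column[~np.isnan(column)]
    return (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))


def snp_maf(column: np.ndarray) -> float:
    """Minor allele frequency min(f, 1-f) with f the coded-allele frequency."""
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValidationError("MAF undefined: all genotypes missing")
    f = (2 * n2 + n1) / (2 * n)
    return min(f, 1.0 - f)


def snp_call_rate(column: np.ndarray) -> float:
    if len(column) == 0:
        raise ValidationError("call rate undefined: empty column")
    return float(np.mean(~np.isnan(column)))


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of every heterozygote count whose conditional probability does not
    exceed that of the observed count.  Computed in log space.
    """
    if min(n0, n1, n2) < 0:
        raise ValidationError("negative genotype counts")
    n = n0 + n1 + n2
    if n < 1:
        raise ValidationError("HWE test needs at least one genotype")
    na = n1 + 2 * n2          # coded-allele count
    nb = n1 + 2 * n0
    if min(na, nb) == 0:      # monomorphic: single attainable configuration
        return 1.0
    rare = min(na, nb)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2          # rare-allele homozygotes
    homc = n - hets - homr
    # P(h | allele counts) up to a shared constant
    logp = hets * np.log(2.0) - (
        gammaln(hets + 1) + gammaln(homr + 1) + gammaln(homc + 1)
    )
    logp -= logsumexp(logp)
    obs = logp[np.searchsorted(hets, n1)]
    tail = logp[logp <= obs + 1e-10]   # tolerance guards float ties
    return float(min(1.0, np.exp(logsumexp(tail))))


def apply_qc(cohort: Cohort, thresholds: QcThresholds = QcThresholds(),
             hwe_stratum: str = "controls") -> tuple[Cohort, QcReport]:
    """Filter SNPs; samples are never dropped (sample QC is upstream).

    A SNP is retained iff maf >= maf_min AND call_rate >= call_rate_min
    AND hwe_p > hwe_p_min.  Failure reasons record every violated filter.
    """
    if hwe_stratum not in ("controls", "all"):
        raise ValidationError(f"unknown hwe_stratum {hwe_stratum!r}")
    g = cohort.genotypes
    hwe_rows = g[cohort.phenotype == 0] if hwe_stratum == "controls" else g

    records = []
    for j, snp in enumerate(cohort.snp_ids):
        col = g[:, j]
        maf = snp_maf(col)
        call = snp_call_rate(col)
        hwe = hwe_exact_p(*genotype_counts(hwe_rows[:, j]))
        reasons = []
        if maf < thresholds.maf_min:
            reasons.append("maf")
        if call < thresholds.call_rate_min:
            reasons.append("call_rate")
        if hwe <= thresholds.hwe_p_min:
            reasons.append("hwe")
        records.append((snp, maf, call, hwe, not reasons, ",".join(reasons)))

    frame = pd.DataFrame(
        records, columns=["snp_id", "maf", "call_rate", "hwe_p", "pass", "reasons"]
    )
    report = QcReport(frame)
    return cohort.subset_snps(frame["pass"].to_numpy()), report
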