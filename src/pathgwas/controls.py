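"""Positive-control gene sets for benchmarking pipeline calibration.

Six custom gene sets built from previously reported lung-cancer
susceptibility genes: a master list (ILCCO candidate oncogenes, NSCLC
driver-mutation genes, GWAS locus genes at 3q28-29 / 5p15 / 6p21 /
15q25, and DNA-repair genes) and five leave-one-locus-out derivatives.

The master list enumerates 32 symbols; the published summary table
counts it as 29 genes.  Both numbers are recorded here as data and the
discrepancy is left unresolved (symbol synonymy is out of scope).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PathwayCatalog
from .errors import ValidationError

MASTER_GENES = (
    "IL1B", "MTHFR", "AKAP9", "CAMKK1", "SEZ6L", "FAS", "FASLG", "TP53",
    "TP53BP1", "EGFR", "KRAS", "ERBB2", "ALK", "BRAF", "PIK3CA", "AKT1",
    "MAP2K1", "MET", "ROS1", "NRAS", "C3ORF21", "TP63", "TERT", "CLPTM1L",
    "BAT3", "MSH5", "CHRNA3", "CHRNA4", "CHRNA5", "XRCC1", "RRM1", "ERCC1",
)

#: published gene count for the master set (differs from len(MASTER_GENES))
MASTER_REPORTED_COUNT = 29

EXCLUSION_GROUPS = {
    "3q28-29": ("C3ORF21", "TP63"),
    "5p15": ("TERT", "CLPTM1L"),
    "6p21": ("BAT3", "MSH5"),
    "15q25": ("CHRNA3", "CHRNA4", "CHRNA5"),
    "dna_repair": ("XRCC1", "RRM1", "ERCC1"),
}

_SET_NAMES = {
    "3q28-29": "LC_WITHOUT_3Q28_29",
    "5p15": "LC_WITHOUT_5P15",
    "6p21": "LC_WITHOUT_6P21",
    "15q25": "LC_WITHOUT_15Q25",
    "dna_repair": "LC_WITHOUT_DNA_REPAIR",
}


def build_control_sets(master=MASTER_GENES, groups=None) -> PathwayCatalog:
    """Master set plus one leave-group-out set per exclusion group."""
    groups = dict(EXCLUSION_GROUPS if groups is None else groups)
    master = tuple(g.upper() for g in master)
    for tag, genes in groups.items():
        stray = [g for g in genes if g.upper() not in master]
        if stray:
            raise ValidationError(
                f"exclusion group {tag!r} has genes outside the master set: {stray}"
            )
    names = ["LC_MASTER"]
    members = [master]
    for tag, genes in groups.items():
        drop = {g.upper() for g in genes}
        names.append(_SET_NAMES.get(tag, f"LC_WITHOUT_{tag.upper()}"))
        members.append(tuple(g for g in master if g not in drop))
    return PathwayCatalog(
        names=names, sources=["positive-control"] * len(names), members=members
    )


def calibrate_thresholds(control_results: pd.DataFrame,
                         p_max: float = 0.025, fdr_max: float = 0.25,
                         artp_max: float = 0.01) -> dict:
    """Descriptive calibration report over evaluated control sets.

    ``control_results`` rows: pathway, model, method ('gsea'|'artp'),
    p, and fdr (NaN for ARTP rows).  Reports the achieved p/FDR ranges
    and the fraction of control sets each default threshold admits;
    never changes any threshold.
    """
    if control_results.empty:
        return {"n_sets": 0}
    gsea = control_results[control_results["method"] == "gsea"]
    artp = control_results[control_results["method"] == "artp"]
    report: dict = {"n_sets": int(control_results["pathway"].nunique())}
    if len(gsea):
        admitted = (
            gsea.assign(ok=(gsea["p"] <= p_max) & (gsea["fdr"] <= fdr_max))
            .groupby("pathway")["ok"].any()
        )
        report["gsea"] = {
            "p_range": (float(gsea["p"].min()), float(gsea["p"].max())),
            "fdr_range": (float(gsea["fdr"].min()), float(gsea["fdr"].max())),
            "admitted_fraction": float(np.mean(admitted)),
        }
    if len(artp):
        admitted = (
            artp.assign(ok=artp["p"] <= artp_max).groupby("pathway")["ok"].any()
        )
        report["artp"] = {
            "p_range": (float(artp["p"].min()), float(artp["p"].max())),
            "admitted_fraction": float(np.mean(admitted)),
        }
    return report
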