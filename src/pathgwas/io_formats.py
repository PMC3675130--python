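"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* genotype matrix: TSV, header row of SNP ids, first column ``sample_id``,
  cells in {0, 1, 2, NA}; optionally VCF (biallelic sites, ``./.`` missing)
* sample sheet: TSV with sample_id, status, age, gender, smoking
* SNP map: TSV with snp_id, chrom, pos (1-based)
* genes: BED (0-based half-open on disk, converted to 1-based inclusive)
* pathways: GMT (name TAB source/description TAB gene symbols)

All writers emit UTF-8 TSV with a single leading ``#`` comment line
recording the package version (and, when supplied, a config hash); all
readers skip ``#`` comment lines, so write-then-read is the identity.

Internally the coded allele is meant to be the *minor* allele.  VCF input
is re-oriented at load time (dosages flipped when the ALT frequency
exceeds 0.5 in the full sample); TSV input is trusted as already
minor-coded so that round-trips are exact.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import Cohort, GeneCatalog, PathwayCatalog
from .errors import ParseError, ReconciliationError, ValidationError

log = logging.getLogger(__name__)

_MISSING_TOKENS = {"NA", "na", "NaN", ""}
_VALID_TOKENS = {"0", "1", "2"}


def _header(config_hash: str | None = None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# pathgwas v{__version__}{tag}\n"


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv"):
    """Read a genotype block.

    Returns ``(sample_ids, snp_ids, genotypes)`` for the TSV dialect and
    ``(sample_ids, snp_ids, genotypes, snp_chrom, snp_pos)`` for VCF.
    Genotypes are float64 with ``NaN`` for missing calls.
    """
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    if dialect == "vcf":
        return _read_genotypes_vcf(path)
    raise ValidationError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path):
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "sample_id":
        raise ParseError(
            f"{path} line 1: malformed header (expected 'sample_id' then SNP ids)"
        )
    snp_ids = header[1:]
    sample_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path} line {lineno}: {len(fields)} fields, expected {len(header)}"
            )
        sample_ids.append(fields[0])
        row = np.empty(len(snp_ids))
        for j, tok in enumerate(fields[1:]):
            if tok in _VALID_TOKENS:
                row[j] = float(tok)
            elif tok in _MISSING_TOKENS:
                row[j] = np.nan
            else:
                raise ValidationError(
                    f"{path}: genotype token {tok!r} outside {{0,1,2,NA}} at "
                    f"row {lineno - 1}, col {j + 1} (sample {fields[0]}, SNP {snp_ids[j]})"
                )
        rows.append(row)
    genotypes = np.vstack(rows) if rows else np.empty((0, len(snp_ids)))
    return np.asarray(sample_ids, dtype=object), np.asarray(snp_ids, dtype=object), genotypes


def _read_genotypes_vcf(path):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF support requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path), gts012=True)
    sample_ids = np.asarray(vcf.samples, dtype=object)
    snp_ids, chroms, poss, cols = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"{path}: site {var.CHROM}:{var.POS} is not biallelic"
            )
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (gts012), 3 unknown
        g = np.asarray(var.gt_types, dtype=np.float64)
        g[g == 3] = np.nan
        cols.append(g)
    genotypes = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    # orient so the coded allele is the minor allele in the full sample
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(genotypes, axis=0) / 2.0
    flip = freq > 0.5
    genotypes[:, flip] = 2.0 - genotypes[:, flip]
    return (
        sample_ids,
        np.asarray(snp_ids, dtype=object),
        genotypes,
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
    )


def write_genotypes(path, sample_ids, snp_ids, genotypes, config_hash=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header(config_hash))
        fh.write("sample_id\t" + "\t".join(map(str, snp_ids)) + "\n")
        for sid, row in zip(sample_ids, genotypes):
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(sid) + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# SNP map / sample sheet
# ---------------------------------------------------------------------------

def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: SNP map missing column {col!r}")
    if (df["pos"] <= 0).any():
        bad = df.loc[df["pos"] <= 0, "snp_id"].tolist()
        raise ValidationError(f"{path}: non-positive positions for {bad[:5]}")
    return df


def write_snp_map(path, snp_ids, snp_chrom, snp_pos, config_hash=None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_header(config_hash))
        pd.DataFrame({"snp_id": snp_ids, "chrom": snp_chrom, "pos": snp_pos}).to_csv(
            fh, sep="\t", index=False
        )


_STATUS_TOKENS = {"case": 1, "control": 0, "1": 1, "0": 0}


def read_samples(path, age_range=(0, 120)) -> pd.DataFrame:
    """Read the sample sheet; returns sample_id/status/age/gender/smoking."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "status", "age", "gender", "smoking"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample sheet missing column {col!r}")
    status = []
    for i, tok in enumerate(df["status"].astype(str)):
        if tok not in _STATUS_TOKENS:
            raise ValidationError(
                f"{path}: unknown status token {tok!r} at data row {i + 1}"
            )
        status.append(_STATUS_TOKENS[tok])
    df = df.assign(status=np.asarray(status, dtype=np.int8))
    lo, hi = age_range
    bad = df[(df["age"] < lo) | (df["age"] > hi)]
    if len(bad):
        raise ValidationError(
            f"{path}: ages outside plausible range [{lo}, {hi}] for samples "
            f"{bad['sample_id'].tolist()[:5]}"
        )
    for col in ("gender", "smoking"):
        vals = set(df[col].unique()) - {0, 1}
        if vals:
            raise ValidationError(f"{path}: {col} values outside {{0,1}}: {sorted(vals)}")
    return df


def write_samples(path, cohort: Cohort, config_hash=None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_header(config_hash))
        cohort.samples_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes (BED)
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> GeneCatalog:
    """Read a BED-like gene file (chrom, start, end, symbol, score, strand).

    BED coordinates are 0-based half-open on disk; they are converted to
    the internal 1-based inclusive convention (start = BED start + 1).
    """
    path = Path(path)
    rows = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path} line {lineno}: expected >=4 BED fields")
            chrom, start, end, symbol = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "."
            if start >= end:
                raise ValidationError(
                    f"{path} line {lineno}: BED start {start} >= end {end}"
                )
            rows.append((symbol, chrom, start + 1, end, strand))
    if not rows:
        log.warning("%s: empty gene file, returning empty catalog", path)
    df = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"])
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    return GeneCatalog(df)


def write_gene_bed(path, catalog: GeneCatalog, config_hash=None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_header(config_hash))
        for row in catalog.frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.symbol}\t.\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# pathways (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayCatalog:
    """Read a GMT gene-set file, preserving file order.

    Duplicate gene symbols within a line are deduplicated with a logged
    warning; a duplicated pathway name is an error on the second line.
    """
    path = Path(path)
    names, sources, members = [], [], []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path} line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, source, genes = fields[0], fields[1], fields[2:]
            if name in names:
                raise ParseError(
                    f"{path} line {lineno}: duplicate pathway name {name!r}"
                )
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                log.warning(
                    "%s line %d: pathway %r has duplicate gene symbols; deduplicated",
                    path, lineno, name,
                )
            names.append(name)
            sources.append(source)
            members.append(deduped)
    return PathwayCatalog(names=names, sources=sources, members=members)


def write_gmt(path, catalog: PathwayCatalog) -> None:
    # GMT has no comment convention; write bare lines for interoperability
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, source, genes in catalog.items():
            fh.write("\t".join([name, source, *genes]) + "\n")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_cohort(sample_ids, snp_ids, genotypes, samples: pd.DataFrame,
                 snp_map: pd.DataFrame) -> Cohort:
    """Reconcile genotype block, sample sheet and SNP map into a Cohort."""
    sheet_ids = samples["sample_id"].tolist()
    geno_ids = list(sample_ids)
    missing = [s for s in geno_ids if s not in set(sheet_ids)]
    extra = [s for s in sheet_ids if s not in set(geno_ids)]
    if missing or extra:
        raise ReconciliationError(
            f"sample id mismatch: {len(missing)} in genotypes but not sample sheet "
            f"{missing[:5]}; {len(extra)} in sample sheet but not genotypes {extra[:5]}"
        )
    samples = samples.set_index("sample_id").loc[geno_ids].reset_index()

    snp_map = snp_map.set_index("snp_id")
    missing_snps = [s for s in snp_ids if s not in snp_map.index]
    if missing_snps:
        raise ReconciliationError(
            f"{len(missing_snps)} SNPs missing from SNP map: {missing_snps[:5]}"
        )
    snp_map = snp_map.loc[list(snp_ids)]

    return Cohort(
        sample_ids=np.asarray(geno_ids, dtype=object),
        phenotype=samples["status"].to_numpy(),
        age=samples["age"].to_numpy(),
        gender=samples["gender"].to_numpy(),
        smoking=samples["smoking"].to_numpy(),
        genotypes=genotypes,
        snp_ids=np.asarray(snp_ids, dtype=object),
        snp_chrom=snp_map["chrom"].to_numpy(dtype=object),
        snp_pos=snp_map["pos"].to_numpy(),
    )


def load_cohort_dir(directory) -> Cohort:
    """Load a cohort from a directory produced by the simulator/CLI."""
    d = Path(directory)
    sample_ids, snp_ids, genotypes = read_genotypes(d / "genotypes.tsv")
    samples = read_samples(d / "samples.tsv")
    snp_map = read_snp_map(d / "snps.tsv")
    return build_cohort(sample_ids, snp_ids, genotypes, samples, snp_map)
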