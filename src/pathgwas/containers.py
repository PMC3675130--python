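"""Core in-memory containers for case-control pathway GWAS.

A :class:`Cohort` bundles the genotype matrix (samples × SNPs, coded as
minor-allele counts 0/1/2 with ``NaN`` for missing calls), the binary
disease phenotype and the three adjusting covariates (age in years,
gender, ever-smoking).  :class:`GeneCatalog` holds gene intervals in the
internal 1-based inclusive coordinate convention, and
:class:`PathwayCatalog` holds named gene sets in file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: covariate column order used by every design matrix in the package
COVARIATES = ("age", "gender", "smoking")


@dataclass
class Cohort:
    """Case-control cohort: phenotype, covariates and genotype matrix.

    Genotypes are stored as ``float64`` so that missing calls can be
    ``NaN``; observed values are restricted to {0, 1, 2} minor-allele
    counts.  SNP coordinates are 1-based.
    """

    sample_ids: np.ndarray
    phenotype: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    smoking: np.ndarray
    genotypes: np.ndarray
    snp_ids: np.ndarray
    snp_chrom: np.ndarray
    snp_pos: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.age = np.asarray(self.age, dtype=np.int64)
        self.gender = np.asarray(self.gender, dtype=np.int8)
        self.smoking = np.asarray(self.smoking, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.snp_chrom = np.asarray(self.snp_chrom, dtype=object)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.genotypes.shape != (n, m):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} samples x {m} SNPs"
            )
        for name, arr in (("phenotype", self.phenotype), ("age", self.age),
                          ("gender", self.gender), ("smoking", self.smoking)):
            if len(arr) != n:
                raise ValidationError(f"{name} has {len(arr)} entries for {n} samples")
        if len(self.snp_chrom) != m or len(self.snp_pos) != m:
            raise ValidationError("SNP map length does not match SNP count")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids")
        if m and (self.snp_pos <= 0).any():
            raise ValidationError("SNP positions must be positive (1-based)")
        bad = set(np.unique(self.phenotype)) - {0, 1}
        if bad:
            raise ValidationError(f"phenotype values outside {{0,1}}: {sorted(bad)}")
        for name, arr in (("gender", self.gender), ("smoking", self.smoking)):
            bad = set(np.unique(arr)) - {0, 1}
            if bad:
                raise ValidationError(f"{name} values outside {{0,1}}: {sorted(bad)}")
        g = self.genotypes
        observed = g[~np.isnan(g)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValidationError(f"genotype values outside {{0,1,2,NA}}: {bad[:5]}")

    def covariate_matrix(self, adjust=COVARIATES) -> np.ndarray:
        """Design columns (no genotype): intercept + requested covariates."""
        cols = [np.ones(self.n_samples)]
        lookup = {"age": self.age, "gender": self.gender, "smoking": self.smoking}
        for name in adjust:
            if name not in lookup:
                raise ValidationError(f"unknown covariate {name!r}")
            cols.append(lookup[name].astype(np.float64))
        return np.column_stack(cols)

    def subset_snps(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        return replace(
            self,
            genotypes=self.genotypes[:, mask],
            snp_ids=self.snp_ids[mask],
            snp_chrom=self.snp_chrom[mask],
            snp_pos=self.snp_pos[mask],
        )

    def subset_samples(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        return replace(
            self,
            sample_ids=self.sample_ids[mask],
            phenotype=self.phenotype[mask],
            age=self.age[mask],
            gender=self.gender[mask],
            smoking=self.smoking[mask],
            genotypes=self.genotypes[mask, :],
        )

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "status": self.phenotype,
                "age": self.age,
                "gender": self.gender,
                "smoking": self.smoking,
            }
        )


@dataclass
class GeneCatalog:
    """Gene intervals, 1-based inclusive, with unique symbols."""

    frame: pd.DataFrame  # columns: symbol, chrom, start, end, strand

    REQUIRED = ("symbol", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"gene catalog missing columns {missing}")
        self.frame = df = df.reset_index(drop=True)
        if df["symbol"].duplicated().any():
            dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "symbol"].tolist()
            raise ValidationError(f"gene start > end for {bad[:5]}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def symbols(self) -> np.ndarray:
        return self.frame["symbol"].to_numpy()


@dataclass
class PathwayCatalog:
    """Ordered collection of named gene sets (GMT semantics).

    Member gene lists are stored deduplicated, in first-seen order.
    """

    names: list = field(default_factory=list)
    sources: list = field(default_factory=list)
    members: list = field(default_factory=list)  # list[tuple[str, ...]]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.sources) == len(self.members)):
            raise ValidationError("pathway catalog fields have unequal lengths")
        if len(set(self.names)) != len(self.names):
            seen, dups = set(), []
            for n in self.names:
                if n in seen:
                    dups.append(n)
                seen.add(n)
            raise ValidationError(f"duplicate pathway names: {dups[:5]}")
        self.members = [tuple(dict.fromkeys(m)) for m in self.members]
        for name, genes in zip(self.names, self.members):
            if not genes:
                raise ValidationError(f"pathway {name!r} has no member genes")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name) -> bool:
        return name in self.names

    def genes_of(self, name) -> tuple:
        try:
            return self.members[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def source_of(self, name) -> str:
        return self.sources[self.names.index(name)]

    def add(self, name, source, genes) -> "PathwayCatalog":
        """Return a new catalog with one pathway appended."""
        if name in self.names:
            raise ValidationError(f"pathway name {name!r} already present")
        return PathwayCatalog(
            names=self.names + [name],
            sources=self.sources + [source],
            members=self.members + [tuple(genes)],
        )

    def subset(self, names) -> "PathwayCatalog":
        """Catalog restricted to ``names``, preserving catalog order."""
        keep = [i for i, n in enumerate(self.names) if n in set(names)]
        return PathwayCatalog(
            names=[self.names[i] for i in keep],
            sources=[self.sources[i] for i in keep],
            members=[self.members[i] for i in keep],
        )

    def items(self):
        return zip(self.names, self.sources, self.members)
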