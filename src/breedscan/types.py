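"""Core in-memory containers shared by every analysis module.

Genotypes are stored as dosage of ``allele2`` (the second allele column of
the variant map) in ``{0, 1, 2}`` with ``-1`` as the missing sentinel.
Phased haplotypes are 0/1 matrices with two consecutive rows per sample.
Coordinates are 1-based inclusive base-pair positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel, distinct from the valid codes 0/1/2

VARIANT_COLUMNS = ["variant_id", "chromosome", "position_bp", "allele1", "allele2"]


def make_variant_map(
    variant_id,
    chromosome,
    position_bp,
    allele1="A",
    allele2="C",
) -> pd.DataFrame:
    """Build a validated variant map DataFrame.

    Parameters accept scalars (broadcast) or sequences of equal length.
    Positions must be strictly increasing within each chromosome and
    variant ids unique.
    """
    variant_id = list(variant_id)
    m = len(variant_id)

    def _bcast(x):
        if np.isscalar(x) or isinstance(x, str):
            return [x] * m
        return list(x)

    vm = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chromosome": _bcast(chromosome),
            "position_bp": np.asarray(_bcast(position_bp), dtype=np.int64),
            "allele1": _bcast(allele1),
            "allele2": _bcast(allele2),
        }
    )
    validate_variant_map(vm)
    return vm


def validate_variant_map(vm: pd.DataFrame) -> None:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in vm.columns]
    if missing_cols:
        raise ValueError(f"variant map lacks columns {missing_cols}")
    if vm["variant_id"].duplicated().any():
        dup = vm.loc[vm["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant_id {dup!r}")
    if (vm["position_bp"] < 1).any():
        raise ValueError("position_bp must be >= 1 (1-based coordinates)")
    for chrom, grp in vm.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"positions not strictly increasing on chromosome {chrom!r}"
            )


@dataclass
class GenotypeMatrix:
    """n samples x m variants dosage matrix counting copies of allele2."""

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # int8, values in {0,1,2,MISSING}

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        validate_variant_map(self.variants)
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but {n} dosage rows"
            )
        if m != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variants but {m} dosage columns"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"dosages contain invalid codes {np.unique(self.dosages[bad])}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosages as float64 with missing as NaN or column-mean imputed."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        if impute_mean:
            col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, vi)],
        )


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix with two consecutive rows per sample."""

    haplotypes: np.ndarray  # (2n, m) int8 in {0,1}
    variants: pd.DataFrame
    samples: list[str]  # length n; haplotype rows 2i, 2i+1 belong to samples[i]

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        validate_variant_map(self.variants)
        h, m = self.haplotypes.shape
        if h != 2 * len(self.samples):
            raise ValueError(
                f"{h} haplotype rows for {len(self.samples)} samples "
                "(need exactly two per sample)"
            )
        if m != len(self.variants):
            raise ValueError("haplotype columns do not match variant map")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_of_haplotype(self, row: int) -> tuple[str, int]:
        """Return (sample_id, phase index 0/1) for a haplotype row."""
        return self.samples[row // 2], row % 2

    def to_genotypes(self) -> GenotypeMatrix:
        dos = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.copy(),
            dosages=dos.astype(np.int8),
        )

    def subset_samples(self, sample_idx) -> "HaplotypePanel":
        si = np.asarray(sample_idx)
        rows = np.empty(2 * len(si), dtype=np.int64)
        rows[0::2] = 2 * si
        rows[1::2] = 2 * si + 1
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in si],
        )


@dataclass
class PhenotypeTable:
    """Case/control status (1/0) plus named numeric covariate columns."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        t = self.table
        for col in ("sample_id", "status"):
            if col not in t.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        if t["status"].isna().any():
            raise ValueError("missing status values are not allowed")
        if not np.isin(t["status"].to_numpy(), (0, 1)).all():
            raise ValueError("status must be coded 0 (control) / 1 (case)")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in phenotype table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def status(self) -> np.ndarray:
        return self.table["status"].to_numpy(dtype=np.int64)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "status")]

    def covariates(self, names=None) -> np.ndarray:
        names = self.covariate_names if names is None else list(names)
        if not names:
            return np.empty((len(self.table), 0))
        return self.table[names].to_numpy(dtype=np.float64)

    def aligned_to(self, samples: list[str]) -> "PhenotypeTable":
        """Reorder rows to a genotype sample order; every sample must be present."""
        t = self.table.set_index("sample_id")
        missing = [s for s in samples if s not in t.index]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped-sample ids absent from table, "
                f"e.g. {missing[:3]}"
            )
        return PhenotypeTable(t.loc[samples].reset_index())
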