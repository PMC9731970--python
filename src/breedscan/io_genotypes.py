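"""Readers/writers for PLINK text/binary and phased haplotype tables, plus QC.

The PLINK v1 binary layout (SNP-major): three magic bytes ``6c 1b 01`` then,
per variant, ``ceil(n/4)`` bytes holding four 2-bit genotype codes each,
sample index increasing from the least significant bit pair::

    00 hom allele1 (dosage 0)   01 missing
    10 heterozygous (dosage 1)  11 hom allele2 (dosage 2)

Dosage counts copies of allele2 throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    PhenotypeTable,
    make_variant_map,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix, ext: str):
    return Path(str(prefix) + ext)


# 2-bit PLINK code -> dosage of allele2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str):
    """Read a cohort from ``plink_text`` (.ped/.map), ``plink_binary``
    (.bed/.bim/.fam) or ``haplotype_table`` (.haps.tsv/.sites.tsv).

    ``path`` is the fileset prefix. Returns a :class:`GenotypeMatrix`
    for the PLINK formats and a :class:`HaplotypePanel` for haplotype tables.
    """
    prefix = Path(path)
    if format == "plink_text":
        return _read_ped(prefix)
    if format == "plink_binary":
        return _read_bed(prefix)
    if format == "haplotype_table":
        return _read_haplotype_table(prefix)
    raise ValueError(f"unknown format {format!r}")


def _read_map(path: Path) -> pd.DataFrame:
    mp = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position_bp"],
        dtype={"chromosome": str, "variant_id": str},
    )
    return mp


def _read_ped(prefix: Path) -> GenotypeMatrix:
    map_path = _ext(prefix, ".map")
    ped_path = _ext(prefix, ".ped")
    mp = _read_map(map_path)
    m = len(mp)

    samples = []
    # .ped carries no allele order, so orient lexicographically:
    # allele1 = the earlier-sorting observed allele
    allele1 = [None] * m
    allele2 = [None] * m
    raw = []
    with open(ped_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            samples.append(fields[1])
            raw.append(fields[6:])
    for alleles in raw:
        for j in range(m):
            for a in (alleles[2 * j], alleles[2 * j + 1]):
                if a == "0":
                    continue
                if allele1[j] is None:
                    allele1[j] = a
                elif a != allele1[j] and allele2[j] is None:
                    allele2[j] = a
                elif a not in (allele1[j], allele2[j]):
                    raise ValueError(
                        f"{ped_path}: variant {mp['variant_id'][j]} has more "
                        f"than two alleles ({allele1[j]},{allele2[j]},{a})"
                    )
    for j in range(m):
        if allele1[j] is None:
            allele1[j] = "A"
        if allele2[j] is None:
            allele2[j] = _other_allele(allele1[j])
        if allele2[j] < allele1[j]:
            allele1[j], allele2[j] = allele2[j], allele1[j]
    dos = np.full((len(samples), m), MISSING, dtype=np.int8)
    for i, alleles in enumerate(raw):
        for j in range(m):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                continue
            dos[i, j] = (a == allele2[j]) + (b == allele2[j])
    vm = make_variant_map(
        mp["variant_id"], mp["chromosome"], mp["position_bp"], allele1, allele2
    )
    return GenotypeMatrix(samples=samples, variants=vm, dosages=dos)


def _other_allele(a1: str) -> str:
    return "C" if a1 != "C" else "A"


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "variant_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"chromosome": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    return bim


def _read_fam(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["fid", "iid", "pat", "mat", "sex", "pheno"],
            dtype={"fid": str, "iid": str},
        )
    except pd.errors.EmptyDataError:  # zero-sample cohort
        return pd.DataFrame(columns=["fid", "iid", "pat", "mat", "sex", "pheno"])


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = _read_bim(_ext(prefix, ".bim"))
    fam = _read_fam(_ext(prefix, ".fam"))
    n, m = len(fam), len(bim)
    payload = Path(_ext(prefix, ".bed")).read_bytes()
    if payload[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic bytes {payload[:3].hex()} "
            f"(expected {_BED_MAGIC.hex()}, SNP-major v1)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(payload) != expected:
        raise ValueError(
            f"{prefix}.bed: payload is {len(payload)} bytes, expected {expected} "
            f"for {n} samples x {m} variants"
        )
    data = np.frombuffer(payload[3:], dtype=np.uint8).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample index from the low bit pair upward
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dos = _BED_DECODE[codes].T  # (n, m)
    vm = make_variant_map(
        bim["variant_id"], bim["chromosome"], bim["position_bp"],
        bim["allele1"], bim["allele2"],
    )
    return GenotypeMatrix(samples=list(fam["iid"]), variants=vm, dosages=dos.copy())


def _read_haplotype_table(prefix: Path) -> HaplotypePanel:
    sites = pd.read_csv(Path(str(prefix) + ".sites.tsv"), sep="\t", dtype=str)
    vm = make_variant_map(
        sites["variant_id"], sites["chromosome"],
        sites["position_bp"].astype(np.int64),
        sites["allele1"], sites["allele2"],
    )
    haps = pd.read_csv(Path(str(prefix) + ".haps.tsv"), sep="\t", dtype=str)
    expected_cols = ["sample_id", "phase"] + list(vm["variant_id"])
    if list(haps.columns) != expected_cols:
        raise ValueError(
            "haplotype table header does not match the site file variant ids"
        )
    hmat = haps[list(vm["variant_id"])].to_numpy(dtype=np.int8)
    samples = list(haps["sample_id"][0::2])
    if list(haps["sample_id"][1::2]) != samples:
        raise ValueError("haplotype rows are not paired per sample")
    return HaplotypePanel(haplotypes=hmat, variants=vm, samples=samples)


# ---------------------------------------------------------------------------
# writers


def write_genotypes(data, path, format: str) -> None:
    """Write a GenotypeMatrix (plink formats) or HaplotypePanel (table)."""
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink_text":
        _write_ped(data, prefix)
    elif format == "plink_binary":
        _write_bed(data, prefix)
    elif format == "haplotype_table":
        _write_haplotype_table(data, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def _map_frame(vm: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": vm["chromosome"],
            "variant_id": vm["variant_id"],
            "cm": 0,
            "position_bp": vm["position_bp"],
        }
    )


def _write_ped(g: GenotypeMatrix, prefix: Path) -> None:
    _map_frame(g.variants).to_csv(
        _ext(prefix, ".map"), sep="\t", header=False, index=False
    )
    a1 = g.variants["allele1"].to_numpy()
    a2 = g.variants["allele2"].to_numpy()
    with open(_ext(prefix, ".ped"), "w") as fh:
        for i, sid in enumerate(g.samples):
            parts = [sid, sid, "0", "0", "0", "-9"]
            for j, d in enumerate(g.dosages[i]):
                if d == MISSING:
                    parts += ["0", "0"]
                elif d == 0:
                    parts += [a1[j], a1[j]]
                elif d == 1:
                    parts += [a1[j], a2[j]]
                else:
                    parts += [a2[j], a2[j]]
            fh.write(" ".join(parts) + "\n")


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    vm = g.variants
    bim = pd.DataFrame(
        {
            "chromosome": vm["chromosome"],
            "variant_id": vm["variant_id"],
            "cm": 0,
            "position_bp": vm["position_bp"],
            "allele1": vm["allele1"],
            "allele2": vm["allele2"],
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)

    n, m = g.dosages.shape
    code = np.empty((m, n), dtype=np.uint8)
    dosT = g.dosages.T
    for d, c in _BED_ENCODE.items():
        code[dosT == d] = c
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = code
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_variant, 4) << shifts).sum(
        axis=2, dtype=np.uint8
    )
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _write_haplotype_table(panel: HaplotypePanel, prefix: Path) -> None:
    panel.variants.to_csv(Path(str(prefix) + ".sites.tsv"), sep="\t", index=False)
    h = panel.haplotypes
    out = pd.DataFrame(h, columns=list(panel.variants["variant_id"]))
    out.insert(0, "phase", np.tile([0, 1], len(panel.samples)))
    out.insert(0, "sample_id", np.repeat(panel.samples, 2))
    out.to_csv(Path(str(prefix) + ".haps.tsv"), sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype/covariate TSV with mandatory sample_id and status."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(t)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and summary statistics


@dataclasses.dataclass
class QCReport:
    removed_variants: pd.DataFrame  # variant_id, reason, value
    removed_samples: pd.DataFrame  # sample_id, reason, value

    def summary(self) -> str:
        return (
            f"removed {len(self.removed_variants)} variants, "
            f"{len(self.removed_samples)} samples"
        )


def qc_filter(
    g: GenotypeMatrix,
    max_variant_missing: float = 0.05,
    max_sample_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard per-breed QC: variant missingness, then sample
    missingness, then MAF recomputed on the surviving samples.

    Thresholds are exclusive bounds: a variant is removed when its missing
    fraction exceeds ``max_variant_missing``, mirroring
    ``plink --geno/--mind/--maf``. Raises if no variant survives.
    """
    for name, v in (
        ("max_variant_missing", max_variant_missing),
        ("max_sample_missing", max_sample_missing),
        ("min_maf", min_maf),
    ):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")

    miss = g.dosages == MISSING
    n, m = g.dosages.shape

    var_missing = miss.mean(axis=0) if n else np.zeros(m)
    keep_v = var_missing <= max_variant_missing
    removed_v = [
        {"variant_id": g.variants["variant_id"].iloc[j], "reason": "missingness",
         "value": var_missing[j]}
        for j in np.flatnonzero(~keep_v)
    ]

    miss2 = miss[:, keep_v]
    samp_missing = miss2.mean(axis=1) if keep_v.any() else np.zeros(n)
    keep_s = samp_missing <= max_sample_missing
    removed_s = [
        {"sample_id": g.samples[i], "reason": "missingness", "value": samp_missing[i]}
        for i in np.flatnonzero(~keep_s)
    ]

    sub = g.subset(np.flatnonzero(keep_s), np.flatnonzero(keep_v))
    freq = _allele2_frequency(sub.dosages)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= min_maf
    removed_v += [
        {"variant_id": sub.variants["variant_id"].iloc[j], "reason": "maf",
         "value": maf[j]}
        for j in np.flatnonzero(~keep_maf)
    ]
    out = sub.subset(variant_idx=np.flatnonzero(keep_maf))
    if out.n_variants == 0:
        raise ValueError("QC removed every variant")
    report = QCReport(
        removed_variants=pd.DataFrame(
            removed_v, columns=["variant_id", "reason", "value"]
        ),
        removed_samples=pd.DataFrame(
            removed_s, columns=["sample_id", "reason", "value"]
        ),
    )
    return out, report


def _allele2_frequency(dos: np.ndarray) -> np.ndarray:
    """Per-variant allele2 frequency ignoring missing dosages."""
    valid = dos != MISSING
    counts = np.where(valid, dos, 0).sum(axis=0)
    denom = 2 * valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)


def allele_stats(
    g: GenotypeMatrix, groups: dict[str, np.ndarray], allele: str = "allele2"
) -> pd.DataFrame:
    """Per-variant, per-group frequency of the named allele.

    ``groups`` maps a label to sample indices; the groups must partition the
    cohort. Frequency = allele count / (2 x non-missing samples in group).
    """
    all_idx = np.concatenate([np.asarray(ix) for ix in groups.values()])
    if len(all_idx) != g.n_samples or len(np.unique(all_idx)) != g.n_samples:
        raise ValueError("groups must partition the samples")
    if allele not in ("allele1", "allele2"):
        raise ValueError("allele must be 'allele1' or 'allele2'")
    out = pd.DataFrame({"variant_id": g.variants["variant_id"]})
    for label, ix in groups.items():
        f2 = _allele2_frequency(g.dosages[np.asarray(ix)])
        out[label] = f2 if allele == "allele2" else 1.0 - f2
    return out


def pca_covariates(g: GenotypeMatrix, k: int) -> pd.DataFrame:
    """First k principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed first. Sign is fixed so each PC's
    largest-magnitude loading is positive (deterministic up to data order).
    """
    n = g.n_samples
    if k == 0:
        return pd.DataFrame({"sample_id": g.samples})
    x = g.dosage_float(impute_mean=True)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the dosage matrix")
    pcs = u[:, :k] * s[:k] / np.sqrt(n)
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    out = pd.DataFrame(pcs, columns=[f"PC{j + 1}" for j in range(k)])
    out.insert(0, "sample_id", g.samples)
    return out


def ld_prune(g: GenotypeMatrix, window: int = 25, step: int = 5, r2_max: float = 0.999):
    """Greedy r^2-window pruning: slide a ``window``-variant window by
    ``step``, dropping the later variant of any kept pair with r^2 > r2_max.

    Returns (pruned GenotypeMatrix, kept variant indices).
    """
    from .assoc import ld_r2_matrix

    x = g.dosage_float(impute_mean=True)
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        if len(idx) > 1:
            r2 = ld_r2_matrix(x[:, idx])
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > r2_max:
                        keep[idx[b]] = False
        start += step
    kept = np.flatnonzero(keep)
    return g.subset(variant_idx=kept), kept
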