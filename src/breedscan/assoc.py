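"""Single-variant association tests, LD, and haplotype-carrier summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import MISSING, GenotypeMatrix, HaplotypePanel, PhenotypeTable


@dataclass
class ContingencyTable2x2:
    """Rows: case/control; columns: two allele (or carrier-class) counts."""

    case_a1: int
    case_a2: int
    control_a1: int
    control_a2: int

    def __post_init__(self):
        cells = (self.case_a1, self.case_a2, self.control_a1, self.control_a2)
        if any(c < 0 for c in cells):
            raise ValueError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_a1, self.case_a2], [self.control_a1, self.control_a2]],
            dtype=np.float64,
        )

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable2x2":
        vals = np.loadtxt(path, dtype=np.int64).ravel()
        if vals.size != 4:
            raise ValueError("expected exactly four counts")
        return cls(*vals.tolist())


def _allele_count_tables(g: GenotypeMatrix, status: np.ndarray):
    """Per-variant 2x2 allele-count tables, missing genotypes excluded.

    Returns (a2_case, a1_case, a2_ctrl, a1_ctrl) count arrays.
    """
    dos = g.dosages
    valid = dos != MISSING
    case = status == 1
    d = np.where(valid, dos, 0)
    a2_case = d[case].sum(axis=0)
    a2_ctrl = d[~case].sum(axis=0)
    n_case = 2 * valid[case].sum(axis=0)
    n_ctrl = 2 * valid[~case].sum(axis=0)
    return a2_case, n_case - a2_case, a2_ctrl, n_ctrl - a2_ctrl


def allelic_chisq_scan(g: GenotypeMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
    """Basic 1-df allelic chi-square test per variant (no continuity
    correction, matching the standard ``--assoc`` allele-count test)."""
    pheno = pheno.aligned_to(g.samples)
    a, b, c, d = _allele_count_tables(g, pheno.status)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    chi2 = np.where((r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0), chi2, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    with np.errstate(divide="ignore"):
        logp = -np.log10(p)
    return pd.DataFrame(
        {
            "variant_id": g.variants["variant_id"],
            "chromosome": g.variants["chromosome"],
            "position_bp": g.variants["position_bp"],
            "chi2": chi2,
            "p": p,
            "logp": logp,
        }
    )


def logistic_scan(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression of status on dosage (+ covariates).

    Reports the dosage log-odds coefficient and two-sided Wald p. Variants
    with constant dosage or a non-converged fit (e.g. complete separation)
    are flagged and get missing p-values.
    """
    pheno = pheno.aligned_to(g.samples)
    y = pheno.status.astype(float)
    C = pheno.covariates(covariates)
    x = g.dosage_float(impute_mean=False)

    rows = []
    for j in range(g.n_variants):
        xj = x[:, j]
        keep = ~np.isnan(xj)
        res = {"variant_id": g.variants["variant_id"].iloc[j],
               "coef": np.nan, "p": np.nan, "converged": False}
        if np.nanstd(xj[keep]) == 0 or keep.sum() < 3:
            rows.append(res)
            continue
        X = np.column_stack([np.ones(keep.sum()), xj[keep], C[keep]])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y[keep], X).fit(disp=0, maxiter=100)
            ok = bool(fit.mle_retvals.get("converged", False))
            # huge SEs signal (quasi-)separation even when IRLS "converges"
            if ok and np.isfinite(fit.bse[1]) and fit.bse[1] < 1e3:
                res.update(coef=fit.params[1], p=fit.pvalues[1], converged=True)
        except Exception:
            pass
        rows.append(res)
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore"):
        out["logp"] = -np.log10(out["p"])
    return out


def yates_chisq(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square with Yates' continuity correction on a 2x2 table.

    The correction is truncated: when |ad - bc| < N/2 the statistic is 0.
    Returns (chi2, p).
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return float(chi2), float(p)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test (two-sided) with Satterthwaite df.

    Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    res = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def ld_r2_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of the columns of x."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    return np.atleast_2d(r) ** 2


def ld_r2(data, pairs) -> pd.DataFrame:
    """r^2 between variant pairs, from dosages or phased haplotype alleles.

    ``data`` is a GenotypeMatrix (genotype mode) or HaplotypePanel (phased
    mode); ``pairs`` is an iterable of (variant_id, variant_id).
    """
    if isinstance(data, HaplotypePanel):
        mat = data.haplotypes.astype(float)
        vm = data.variants
    else:
        mat = data.dosage_float(impute_mean=False)
        vm = data.variants
    index = {v: i for i, v in enumerate(vm["variant_id"])}
    rows = []
    for va, vb in pairs:
        a, b = mat[:, index[va]], mat[:, index[vb]]
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if a.std() == 0 or b.std() == 0:
            raise ValueError(f"monomorphic variant in pair ({va}, {vb})")
        r = np.corrcoef(a, b)[0, 1]
        rows.append({"variant_a": va, "variant_b": vb, "r2": r * r})
    return pd.DataFrame(rows)


def haplotype_carrier_classes(
    panel: HaplotypePanel,
    sites: list[str],
    target: str | list[int],
    status: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-sample copy count of a target haplotype at ordered sites.

    ``target`` is an allele sequence either as 0/1 integers or as allele
    characters resolved against the variant map (allele1/allele2). A sample
    is class 2 when both phased haplotypes match the target exactly at the
    sites, 1 with one matching copy, 0 otherwise. The summary lists class
    counts and percentages (by status group when ``status`` is given) and
    the haplotype frequency = carried copies / 2n.
    """
    vm = panel.variants.set_index("variant_id")
    chroms = {vm.loc[s, "chromosome"] for s in sites}
    if len(chroms) != 1:
        raise ValueError("sites must lie on one chromosome")
    cols = [panel.variants.index[panel.variants["variant_id"] == s][0] for s in sites]

    if isinstance(target, str):
        tgt = []
        for s, ch in zip(sites, target):
            if ch == vm.loc[s, "allele1"]:
                tgt.append(0)
            elif ch == vm.loc[s, "allele2"]:
                tgt.append(1)
            else:
                raise ValueError(f"allele {ch!r} not valid for site {s}")
        target = tgt
    target = np.asarray(target, dtype=np.int8)

    sub = panel.haplotypes[:, cols]
    match = (sub == target).all(axis=1)
    copies = (match[0::2].astype(int) + match[1::2].astype(int)).astype(np.int64)

    n = len(copies)
    groups = {"all": np.arange(n)}
    if status is not None:
        status = np.asarray(status)
        groups = {"cases": np.flatnonzero(status == 1),
                  "controls": np.flatnonzero(status == 0)}
    rows = []
    for label, idx in groups.items():
        cc = copies[idx]
        for k in (0, 1, 2):
            cnt = int((cc == k).sum())
            rows.append(
                {
                    "group": label,
                    "copies": k,
                    "n": cnt,
                    "pct": 100.0 * cnt / len(cc) if len(cc) else np.nan,
                }
            )
        rows.append(
            {
                "group": label,
                "copies": "frequency",
                "n": int(cc.sum()),
                "pct": 100.0 * cc.sum() / (2 * len(cc)) if len(cc) else np.nan,
            }
        )
    return copies, pd.DataFrame(rows)
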