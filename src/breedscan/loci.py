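"""From per-variant posterior effects to associated loci, a per-dog risk
index, and ANOVA variance-explained summaries.

Effect variants are those whose reported mean absolute effect reaches the
1e-4 cutoff (the standard deviation of the smallest non-zero mixture
class). Effect variants closer than 1 Mb on one chromosome are merged by
single linkage into an associated locus; the member with the largest
absolute effect represents the locus, and its risk allele is the allele
more frequent in cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import ld_r2  # noqa: F401  (re-exported convenience)
from .bayesr import BayesRResult
from .io_genotypes import allele_stats
from .types import MISSING, GenotypeMatrix, PhenotypeTable

EFFECT_THRESHOLD = 1e-4
LOCUS_GAP_BP = 1_000_000


@dataclass
class EffectLocus:
    chromosome: str
    start_bp: int
    end_bp: int
    member_ids: list[str]
    top_variant_id: str
    top_effect: float  # signed cross-chain mean effect of the top variant
    effect_allele: str
    other_allele: str
    risk_allele: str
    ea_freq_cases: float
    ea_freq_controls: float
    variance_explained_pct: float = np.nan


def call_effect_variants(
    r: BayesRResult,
    threshold: float = EFFECT_THRESHOLD,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Variants with mean_abs_effect >= threshold, or the top_n by that
    statistic, sorted by |effect| descending (ties by input order, i.e.
    genomic order when the result came from a mapped cohort)."""
    if top_n is None and not threshold > 0:
        raise ValueError("threshold must be positive (or give top_n)")
    t = pd.DataFrame(
        {
            "variant_id": r.variant_ids,
            "beta_mean": r.beta_mean,
            "mean_abs_effect": r.mean_abs_effect,
        }
    )
    t = t.sort_values(
        "mean_abs_effect", ascending=False, kind="stable"
    )
    if top_n is not None:
        t = t.head(top_n)
    else:
        t = t[t["mean_abs_effect"] >= threshold]
    return t.reset_index(drop=True)


def merge_into_loci(
    effect_variants: pd.DataFrame,
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
) -> list[EffectLocus]:
    """Single-linkage merge of effect variants at < 1 Mb gaps into loci.

    Per locus: the top variant is the member with max |effect|; effect
    allele = allele2 (the counted allele) with case/control frequencies
    from :func:`allele_stats`; the risk allele is whichever allele is more
    frequent in cases.
    """
    pheno = pheno.aligned_to(g.samples)
    vm = g.variants.set_index("variant_id")
    ev = effect_variants.copy()
    ev["chromosome"] = [vm.loc[v, "chromosome"] for v in ev["variant_id"]]
    ev["position_bp"] = [vm.loc[v, "position_bp"] for v in ev["variant_id"]]
    ev = ev.sort_values(["chromosome", "position_bp"], kind="stable")

    status = pheno.status
    groups = {
        "cases": np.flatnonzero(status == 1),
        "controls": np.flatnonzero(status == 0),
    }
    freqs = allele_stats(g, groups, allele="allele2").set_index("variant_id")

    loci: list[EffectLocus] = []
    for chrom, grp in ev.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= LOCUS_GAP_BP)
        cluster_id = np.zeros(len(grp), dtype=int)
        for b in breaks:
            cluster_id[b + 1:] += 1
        for cid in np.unique(cluster_id):
            members = grp.iloc[np.flatnonzero(cluster_id == cid)]
            top = members.loc[members["mean_abs_effect"].idxmax()]
            vid = top["variant_id"]
            a1, a2 = vm.loc[vid, "allele1"], vm.loc[vid, "allele2"]
            f_case = float(freqs.loc[vid, "cases"])
            f_ctrl = float(freqs.loc[vid, "controls"])
            risk = a2 if f_case >= f_ctrl else a1
            loci.append(
                EffectLocus(
                    chromosome=str(chrom),
                    start_bp=int(members["position_bp"].min()),
                    end_bp=int(members["position_bp"].max()),
                    member_ids=list(members["variant_id"]),
                    top_variant_id=str(vid),
                    top_effect=float(top["beta_mean"]),
                    effect_allele=str(a2),
                    other_allele=str(a1),
                    risk_allele=str(risk),
                    ea_freq_cases=f_case,
                    ea_freq_controls=f_ctrl,
                )
            )
    loci.sort(key=lambda l: (l.chromosome, l.start_bp))
    return loci


def loci_to_frame(loci: list[EffectLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": l.chromosome,
                "start_bp": l.start_bp,
                "end_bp": l.end_bp,
                "n_effect_variants": len(l.member_ids),
                "top_variant_id": l.top_variant_id,
                "top_effect": l.top_effect,
                "effect_allele": l.effect_allele,
                "other_allele": l.other_allele,
                "risk_allele": l.risk_allele,
                "ea_freq_cases": l.ea_freq_cases,
                "ea_freq_controls": l.ea_freq_controls,
                "variance_explained_pct": l.variance_explained_pct,
            }
            for l in loci
        ],
        columns=[
            "chromosome", "start_bp", "end_bp", "n_effect_variants",
            "top_variant_id", "top_effect", "effect_allele", "other_allele",
            "risk_allele", "ea_freq_cases", "ea_freq_controls",
            "variance_explained_pct",
        ],
    )


@dataclass
class RiskIndex:
    values: np.ndarray  # per-sample index aligned to the genotype samples
    scheme: str  # "half" (0/0.5/1 per locus) or "count" (0/1/2)
    loci: list[str]  # contributing top-variant ids

    def to_frame(self, samples, status=None) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": samples, "risk_index": self.values})
        if status is not None:
            out["status"] = status
        return out


def compute_risk_index(
    g: GenotypeMatrix, loci: list[EffectLocus], scheme: str = "count"
) -> RiskIndex:
    """Sum of risk-allele weights at each locus top variant.

    ``half`` weights a locus 0 / 0.5 / 1 by risk-allele count; ``count``
    weights it 0 / 1 / 2 (so count = 2 x half). A missing genotype
    contributes the locus mean weight over the observed samples.
    """
    if scheme not in ("half", "count"):
        raise ValueError("scheme must be 'half' or 'count'")
    vm = g.variants.reset_index(drop=True)
    index = {v: j for j, v in enumerate(vm["variant_id"])}
    total = np.zeros(g.n_samples)
    for loc in loci:
        j = index[loc.top_variant_id]
        d = g.dosages[:, j].astype(float)
        d[g.dosages[:, j] == MISSING] = np.nan
        # dosage counts allele2; flip when the risk allele is allele1
        risk_count = d if loc.risk_allele == loc.effect_allele else 2.0 - d
        mean = np.nanmean(risk_count) if np.isfinite(risk_count).any() else 0.0
        risk_count = np.where(np.isnan(risk_count), mean, risk_count)
        total += risk_count
    if scheme == "half":
        total = total / 2.0
    return RiskIndex(
        values=total, scheme=scheme, loci=[l.top_variant_id for l in loci]
    )


def variance_explained(
    y: np.ndarray,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA percentages of phenotypic variance.

    Covariate columns enter the linear model first, then each predictor
    column in order; per-term percentage = SS_term / SS_total x 100, so the
    terms plus the residual sum to exactly 100. Collinear terms get 0 df
    and are flagged.
    """
    y = np.asarray(y, dtype=float)
    data = pd.DataFrame({"y": y})
    terms = []
    if covariates is not None:
        for c in covariates.columns:
            data[c] = np.asarray(covariates[c], dtype=float)
            terms.append(c)
    for c in predictors.columns:
        data[c] = np.asarray(predictors[c], dtype=float)
        terms.append(c)
    n, p = len(y), len(terms)
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} model terms")

    ss_total = float(((y - y.mean()) ** 2).sum())
    # sequential sums of squares from nested OLS fits:
    # SS_term = RSS(previous model) - RSS(model + term)
    X = np.ones((n, 1))
    rss_prev = ss_total
    rank_prev = 1
    rows = []
    for t in terms:
        X = np.hstack([X, data[[t]].to_numpy()])
        fit = sm.OLS(y, X).fit()
        rank = np.linalg.matrix_rank(X)
        rss = float(fit.ssr)
        collinear = rank == rank_prev
        ss = 0.0 if collinear else max(rss_prev - rss, 0.0)
        rows.append(
            {
                "term": t,
                "df": 0.0 if collinear else 1.0,
                "sum_sq": ss,
                "pct_variance": 100.0 * ss / ss_total if ss_total > 0 else 0.0,
                "collinear": collinear,
            }
        )
        if not collinear:
            rss_prev = rss
        rank_prev = rank
    rows.append(
        {
            "term": "residual",
            "df": float(n - rank_prev),
            "sum_sq": rss_prev,
            "pct_variance": 100.0 * rss_prev / ss_total if ss_total > 0 else 0.0,
            "collinear": False,
        }
    )
    return pd.DataFrame(rows)
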