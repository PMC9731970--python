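"""Synthetic within-breed case/control cohorts for end-to-end testing.

Haplotypes are generated by a Li-Stephens-style copying process: each new
haplotype is a mosaic of a small founder pool, switching template with a
per-site probability (creating block-wise LD that decays with distance) and
mutating each copied allele with a per-site probability. Two-subpopulation
structure ("breed types") is produced by drifting the founder allele
frequencies with a Balding-Nichols model. Binary phenotypes follow a
liability threshold model whose genetic effects are drawn from the same
four-component normal mixture the GWAS model assumes, and a localized
selective sweep can be copied into one phenotype group to create an
XP-EHH contrast. Every output is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, HaplotypePanel, PhenotypeTable, make_variant_map


@dataclass
class SweepConfig:
    """Localized haplotype sweep copied into one phenotype group."""

    group: str = "none"  # {"cases", "controls", "none"}
    core_index: int = 0
    carrier_target_frequency: float = 0.8
    # the copied span (core +/- flank) is the physical scale of the sweep;
    # scores plateau across it, so it sets the scan's localization scale
    flank_length_bp: int = 100_000


@dataclass
class SimulationConfig:
    n_samples: int = 300
    m_variants: int = 2000
    n_founder_haplotypes: int = 20
    mutation_rate_per_site: float = 0.002
    switch_rate_per_site: float = 0.05
    spacing_bp: int = 5000
    subpop_fraction: float = 0.0  # fraction of samples in subpopulation 2
    subpop_divergence: float = 0.0  # Balding-Nichols drift (Fst-like) in [0,1]
    # four-class effect mixture: (zero, small, medium, large)
    mixture_proportions: tuple = (0.99, 0.006, 0.003, 0.001)
    variance_coefficients: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    heritability_liability: float = 0.4
    prevalence: float = 0.5
    covariate_effects: dict = field(default_factory=dict)  # e.g. {"subpop": 0.5}
    # variant indices forced into the largest effect class (fixed-magnitude
    # effects, random sign) for recovery experiments
    planted_causal_indices: tuple = ()
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.sweep, dict):
            self.sweep = SweepConfig(**self.sweep)
        probs = np.asarray(self.mixture_proportions, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("mixture_proportions must be a probability simplex")
        for name in ("mutation_rate_per_site", "switch_rate_per_site",
                     "subpop_fraction", "subpop_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.sweep.core_index < self.m_variants:
            raise ValueError("sweep core_index outside the variant map")


@dataclass
class SyntheticTruth:
    causal_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    causal_classes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    liability: np.ndarray | None = None
    subpop_labels: np.ndarray | None = None  # 0/1 per sample
    sweep_donor_haplotype: np.ndarray | None = None
    sweep_span: tuple | None = None  # (start_bp, end_bp) inclusive
    sweep_core_index: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "causal_index": self.causal_indices,
                "effect": self.causal_effects,
                "mixture_class": self.causal_classes,
            }
        )


def simulate_haplotype_panel(
    cfg: SimulationConfig,
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Generate a phased panel of 2*n_samples haplotypes by founder copying."""
    if cfg.n_founder_haplotypes < 2:
        raise ValueError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(cfg.seed)
    n, m, f = cfg.n_samples, cfg.m_variants, cfg.n_founder_haplotypes

    # ancestral allele frequencies, kept away from fixation
    p_anc = rng.uniform(0.1, 0.9, size=m)
    founders = {0: (rng.random((f, m)) < p_anc).astype(np.int8)}

    n_sub2 = int(round(cfg.subpop_fraction * n))
    labels = np.zeros(n, dtype=np.int64)
    if n_sub2 > 0:
        labels[n - n_sub2:] = 1
        # Balding-Nichols drifted frequencies for the second breed type
        d = cfg.subpop_divergence
        if d > 0:
            shape = (1.0 - d) / d
            p_drift = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        else:
            p_drift = p_anc
        founders[1] = (rng.random((f, m)) < p_drift).astype(np.int8)

    haps = np.empty((2 * n, m), dtype=np.int8)
    cols = np.arange(m)
    for i in range(2 * n):
        pool = founders[labels[i // 2]]
        template0 = rng.integers(f)
        switch = rng.random(m) < cfg.switch_rate_per_site
        new_templates = rng.integers(f, size=m)
        # forward-fill the template index from the most recent switch point
        last_switch = np.maximum.accumulate(np.where(switch, cols, -1))
        template = np.where(
            last_switch >= 0, new_templates[np.maximum(last_switch, 0)], template0
        )
        hap = pool[template, cols].copy()
        flips = rng.random(m) < cfg.mutation_rate_per_site
        hap[flips] ^= 1
        haps[i] = hap

    positions = (np.arange(m) + 1) * cfg.spacing_bp
    vm = make_variant_map(
        [f"snp{j + 1}" for j in range(m)], "1", positions, "A", "C"
    )
    samples = [f"dog{i + 1}" for i in range(n)]
    panel = HaplotypePanel(haplotypes=haps, variants=vm, samples=samples)
    truth = SyntheticTruth(subpop_labels=labels)
    return panel, truth


def pair_to_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Collapse consecutive haplotype pairs into per-sample dosages."""
    if panel.n_haplotypes % 2:
        raise ValueError("odd haplotype count")
    return panel.to_genotypes()


def simulate_phenotype(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Liability-threshold case/control phenotypes with mixture effects.

    Per-variant mixture classes are drawn from ``mixture_proportions``;
    class-k effects from N(0, gamma_k * sigma2_g). The realized genetic and
    covariate-free noise components are rescaled so that genetic variance /
    total variance equals ``heritability_liability``; cases are the top
    ``prevalence`` fraction of realized liabilities (empirical quantile, so
    case counts are exact at small n).
    """
    if not 0 < cfg.prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if (g.dosages == -1).any():
        raise ValueError("simulate_phenotype requires complete genotypes")
    truth = truth if truth is not None else SyntheticTruth()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    n, m = g.dosages.shape

    probs = np.asarray(cfg.mixture_proportions, dtype=float)
    gamma = np.asarray(cfg.variance_coefficients, dtype=float)
    classes = rng.choice(len(probs), size=m, p=probs)
    beta = np.zeros(m)
    nz = classes > 0
    beta[nz] = rng.normal(0.0, np.sqrt(gamma[classes[nz]]), size=nz.sum())
    planted = np.asarray(cfg.planted_causal_indices, dtype=int)
    if len(planted):
        classes[planted] = len(probs) - 1
        beta[planted] = np.sqrt(gamma[-1]) * rng.choice([-1.0, 1.0], len(planted))
        nz = classes > 0

    x = g.dosages.astype(np.float64)
    x -= x.mean(axis=0)
    gv = x @ beta
    h2 = cfg.heritability_liability
    sd_g = gv.std()
    if h2 > 0 and sd_g > 0:
        scale = np.sqrt(h2) / sd_g
        gv *= scale
        beta *= scale
    else:
        gv = np.zeros(n)
        beta[:] = 0.0
    noise = rng.normal(0.0, np.sqrt(max(1.0 - h2, 1e-12)), size=n)

    cov_term = np.zeros(n)
    cov_cols = {}
    for name, eff in cfg.covariate_effects.items():
        if name == "subpop":
            if truth.subpop_labels is None:
                raise ValueError("subpop covariate effect needs subpop labels")
            z = truth.subpop_labels.astype(float)
        else:
            z = rng.normal(size=n)
            cov_cols[name] = z
        cov_term += eff * z

    liability = gv + cov_term + noise
    cutoff = np.quantile(liability, 1.0 - cfg.prevalence)
    # strict ">" plus exact top-k fallback keeps case counts exact under ties
    order = np.argsort(-liability, kind="stable")
    n_cases = int(round(cfg.prevalence * n))
    status = np.zeros(n, dtype=np.int64)
    status[order[:n_cases]] = 1

    tab = pd.DataFrame({"sample_id": g.samples, "status": status})
    for name, z in cov_cols.items():
        tab[name] = z
    pheno = PhenotypeTable(tab)
    new_truth = replace(
        truth,
        causal_indices=np.flatnonzero(nz),
        causal_effects=beta[nz],
        causal_classes=classes[nz],
        liability=liability,
    )
    del cutoff
    return pheno, new_truth


def inject_sweep(
    panel: HaplotypePanel,
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    status: np.ndarray | None = None,
) -> tuple[HaplotypePanel, SyntheticTruth]:
    """Copy one donor haplotype over a window into the target group until its
    frequency there reaches ``carrier_target_frequency``.

    ``status`` (0/1 per sample) defines the case/control groups; required
    unless ``sweep.group == "none"``. Haplotypes outside the span and outside
    the target group are untouched.
    """
    sw = cfg.sweep
    if sw.group == "none":
        return panel, truth
    if status is None:
        raise ValueError("status vector required when sweep group is set")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))

    pos = panel.variants["position_bp"].to_numpy()
    core_pos = pos[sw.core_index]
    span_mask = (pos >= core_pos - sw.flank_length_bp) & (
        pos <= core_pos + sw.flank_length_bp
    )
    span_cols = np.flatnonzero(span_mask)

    want_case = 1 if sw.group == "cases" else 0
    sample_idx = np.flatnonzero(np.asarray(status) == want_case)
    hap_rows = np.concatenate([[2 * i, 2 * i + 1] for i in sample_idx])

    sub = panel.haplotypes[np.ix_(hap_rows, span_cols)]
    donor_row = hap_rows[rng.integers(len(hap_rows))]
    donor = panel.haplotypes[donor_row, span_cols].copy()

    carries = (sub == donor).all(axis=1)
    current = carries.mean()
    target = sw.carrier_target_frequency
    if target < current - 1e-12:
        raise ValueError(
            f"target frequency {target} below current donor frequency {current:.3f}"
        )
    n_want = int(np.ceil(target * len(hap_rows)))
    deficit = n_want - int(carries.sum())
    haps = panel.haplotypes.copy()
    if deficit > 0:
        non_carriers = hap_rows[~carries]
        chosen = rng.choice(non_carriers, size=deficit, replace=False)
        for r in chosen:
            haps[r, span_cols] = donor

    out = HaplotypePanel(
        haplotypes=haps, variants=panel.variants.copy(), samples=list(panel.samples)
    )
    new_truth = replace(
        truth,
        sweep_donor_haplotype=donor,
        sweep_span=(int(pos[span_cols[0]]), int(pos[span_cols[-1]])),
        sweep_core_index=sw.core_index,
    )
    return out, new_truth


def simulate_cohort(cfg: SimulationConfig):
    """Panel -> genotypes -> phenotypes -> optional sweep, in one call.

    Returns (panel, genotypes, phenotypes, truth). When a sweep is injected
    the genotype matrix is regenerated from the post-sweep panel.
    """
    panel, truth = simulate_haplotype_panel(cfg)
    g = pair_to_genotypes(panel)
    pheno, truth = simulate_phenotype(g, cfg, truth)
    if cfg.sweep.group != "none":
        panel, truth = inject_sweep(panel, truth, cfg, status=pheno.status)
        g = pair_to_genotypes(panel)
    return panel, g, pheno, truth


def load_config(path) -> SimulationConfig:
    """Read a flat ``key = value`` config file (/-separated tuples allowed)."""
    kwargs = {}
    sweep_kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key.startswith("sweep."):
                sweep_kwargs[key[6:]] = _parse_scalar(val)
            elif key in ("mixture_proportions", "variance_coefficients"):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key == "covariate_effects":
                eff = {}
                for item in val.split(","):
                    if item.strip():
                        k, v = item.split(":")
                        eff[k.strip()] = float(v)
                kwargs[key] = eff
            else:
                kwargs[key] = _parse_scalar(val)
    if sweep_kwargs:
        kwargs["sweep"] = SweepConfig(**sweep_kwargs)
    return SimulationConfig(**kwargs)


def _parse_scalar(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val
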