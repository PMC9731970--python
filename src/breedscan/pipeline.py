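"""Config-driven orchestration: QC -> PCA covariates -> mixture-model GWAS
-> locus calling -> risk index -> XP-EHH -> region calling.

The config is a flat ``key = value`` text file; one global seed is expanded
deterministically into per-stage seeds so stages can be rerun in isolation.
Each stage reads and writes interface files under the output directory and
appends to a run log; rerunning with the same config and seed reproduces
every output.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import welch_t_test
from .bayesr import BayesRConfig, fit_bayesr
from .io_genotypes import (
    pca_covariates,
    qc_filter,
    read_genotypes,
    read_phenotypes,
)
from .loci import (
    call_effect_variants,
    compute_risk_index,
    loci_to_frame,
    merge_into_loci,
    variance_explained,
)
from .selection import call_candidate_regions, regions_to_frame, xpehh_scan
from .types import HaplotypePanel

log = logging.getLogger("breedscan")


@dataclass
class PipelineConfig:
    genotype_prefix: str = ""
    genotype_format: str = "plink_binary"
    haplotype_prefix: str = ""  # optional, enables the XP-EHH stages
    pheno_path: str = ""
    out_dir: str = "breedscan_out"
    seed: int = 0
    # QC
    max_variant_missing: float = 0.05
    max_sample_missing: float = 0.05
    min_maf: float = 0.05
    # covariates
    n_pcs: int = 2
    extra_covariates: str = ""  # comma-separated phenotype columns
    # GWAS
    iterations: int = 20_000
    burn_in: int = 5_000
    chains: int = 3
    effect_threshold: float = 1e-4
    top_n: int = 0  # 0 -> use the threshold
    risk_scheme: str = "count"
    # selection scan
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 0  # 0 -> unlimited
    threshold_logp: float = 4.0
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_n_extreme: int = 2

    def validate(self) -> None:
        if not self.genotype_prefix:
            raise ValueError("config field 'genotype_prefix' is required")
        if not self.pheno_path:
            raise ValueError("config field 'pheno_path' is required")
        probe = {
            "plink_binary": [".bed", ".bim", ".fam"],
            "plink_text": [".ped", ".map"],
        }[self.genotype_format]
        for ext in probe:
            p = Path(self.genotype_prefix + ext)
            if not p.exists():
                raise FileNotFoundError(
                    f"genotype_prefix: missing input file {p}"
                )
        if not Path(self.pheno_path).exists():
            raise FileNotFoundError(f"pheno_path: missing input {self.pheno_path}")
        if self.haplotype_prefix:
            for ext in (".haps.tsv", ".sites.tsv"):
                p = Path(self.haplotype_prefix + ext)
                if not p.exists():
                    raise FileNotFoundError(
                        f"haplotype_prefix: missing input file {p}"
                    )


def load_pipeline_config(path) -> PipelineConfig:
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"unknown config field {key!r}")
            current = getattr(PipelineConfig(), key)
            kwargs[key] = type(current)(val) if not isinstance(current, str) else val
    return PipelineConfig(**kwargs)


def _stage_seed(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a dict of result tables and output paths."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers[:-1]):
        log.addHandler(logging.StreamHandler(sys.stderr))
    results: dict = {}
    try:
        log.info("breedscan %s; config: %s", __version__, cfg)

        stage = "load"
        g = read_genotypes(cfg.genotype_prefix, cfg.genotype_format)
        pheno = read_phenotypes(cfg.pheno_path)
        log.info("loaded %d samples x %d variants", g.n_samples, g.n_variants)

        stage = "qc"
        g, report = qc_filter(
            g, cfg.max_variant_missing, cfg.max_sample_missing, cfg.min_maf
        )
        report.removed_variants.to_csv(out / "qc_removed_variants.tsv",
                                       sep="\t", index=False)
        report.removed_samples.to_csv(out / "qc_removed_samples.tsv",
                                      sep="\t", index=False)
        log.info("qc: %s -> %d x %d", report.summary(), g.n_samples, g.n_variants)
        pheno = pheno.aligned_to(g.samples)

        stage = "pca"
        pcs = pca_covariates(g, cfg.n_pcs)
        pcs.to_csv(out / "pcs.tsv", sep="\t", index=False)
        cov = pcs.drop(columns=["sample_id"])
        for name in filter(None, cfg.extra_covariates.split(",")):
            cov[name] = pheno.table[name].to_numpy(dtype=float)

        stage = "bayesr"
        bcfg = BayesRConfig(
            n_iterations=cfg.iterations,
            burn_in=cfg.burn_in,
            n_chains=cfg.chains,
            seed=_stage_seed(cfg.seed, "bayesr"),
        )
        fit = fit_bayesr(pheno.status, g, cov, bcfg)
        fit.to_frame().to_csv(out / "effects.tsv", sep="\t", index=False)
        fit.model_summary().to_csv(out / "model_summary.tsv", sep="\t", index=False)
        log.info("bayesr: pi=%s sigma2_g=%.4g sigma2_e=%.4g",
                 np.round(fit.pi, 4), fit.sigma2_g, fit.sigma2_e)

        stage = "loci"
        ev = call_effect_variants(
            fit,
            threshold=cfg.effect_threshold,
            top_n=cfg.top_n or None,
        )
        loci = merge_into_loci(ev, g, pheno)
        log.info("loci: %d effect variants -> %d loci", len(ev), len(loci))

        stage = "riskindex"
        ri = compute_risk_index(g, loci, scheme=cfg.risk_scheme)
        ri_frame = ri.to_frame(g.samples, pheno.status)
        ri_frame.to_csv(out / "risk_index.tsv", sep="\t", index=False)
        cases = ri.values[pheno.status == 1]
        controls = ri.values[pheno.status == 0]
        if len(cases) > 1 and len(controls) > 1 and loci:
            tstat, df, p = welch_t_test(cases, controls)
            log.info("risk index cases %.2f vs controls %.2f: t=%.2f p=%.3g",
                     cases.mean(), controls.mean(), tstat, p)
            ve = variance_explained(
                pheno.status.astype(float),
                pd.DataFrame({"risk_index": ri.values}),
                cov if len(cov.columns) else None,
            )
            ve.to_csv(out / "variance_explained.tsv", sep="\t", index=False)
            ri_pct = float(
                ve.loc[ve["term"] == "risk_index", "pct_variance"].iloc[0]
            )
            for l in loci:
                l.variance_explained_pct = ri_pct if len(loci) == 1 else np.nan
            results["variance_explained"] = ve
            results["welch"] = {"t": tstat, "df": df, "p": p}
        locus_table = loci_to_frame(loci)
        locus_table.to_csv(out / "loci.tsv", sep="\t", index=False)
        results.update(loci=locus_table, risk_index=ri_frame)

        if cfg.haplotype_prefix:
            stage = "xpehh"
            panel = read_genotypes(cfg.haplotype_prefix, "haplotype_table")
            assert isinstance(panel, HaplotypePanel)
            keep = [i for i, s in enumerate(panel.samples) if s in set(g.samples)]
            panel = panel.subset_samples(np.asarray(keep))
            pheno_h = pheno.aligned_to(panel.samples)
            case_idx = np.flatnonzero(pheno_h.status == 1)
            ctrl_idx = np.flatnonzero(pheno_h.status == 0)
            scan = xpehh_scan(
                panel.subset_samples(case_idx),
                panel.subset_samples(ctrl_idx),
                cutoff=cfg.ehh_cutoff,
                max_gap_bp=cfg.max_gap_bp or None,
            )
            scan.table.to_csv(out / "xpehh.tsv", sep="\t", index=False)
            log.info("xpehh: %d variants scored, %d dropped",
                     len(scan.table), len(scan.dropped))

            stage = "regions"
            regions = call_candidate_regions(
                scan,
                threshold_logp=cfg.threshold_logp,
                window_bp=cfg.window_bp,
                step_bp=cfg.step_bp,
                min_n_extreme=cfg.min_n_extreme,
            )
            region_table = regions_to_frame(regions)
            region_table.to_csv(out / "regions.tsv", sep="\t", index=False)
            log.info("regions: %d candidate regions", len(regions))
            results.update(xpehh=scan.table, regions=region_table)
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
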