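"""Extended haplotype homozygosity statistics and sweep-region calling.

EHH at a flanking marker is the probability that two randomly drawn
haplotypes (without replacement) are identical at every site from the core
to that marker. Two focal definitions are provided:

* allele-specific — restricted to carriers of a chosen core allele,
  EHH(d) = sum_h n_h (n_h - 1) / (n_c (n_c - 1)) over the distinct extended
  haplotypes among the n_c carriers; EHH(core) = 1. Used for decay plots
  around a focal allele.
* site-level — the pooled-haplotype homozygosity decay over all n
  haplotypes, including the core site itself in the identity requirement,
  normalized by its value at the core so EHH(core) = 1. This is the
  substrate of the two-population iHH comparison.

iHH is the trapezoidal integral of the EHH curve over physical distance
(bp), in both directions, with EHH values below the cutoff set to zero
before integration. XP-EHH at a variant is ln(iHH_A / iHH_B) standardized
to genome-wide mean 0 / variance 1; two-sided normal p-values. Candidate
regions are sliding windows holding at least ``min_n_extreme`` variants
beyond the -log10(p) threshold, merged when they overlap or touch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .types import HaplotypePanel


@dataclass
class EHHCurve:
    core_id: str
    core_pos: int
    focal: str  # "site" or the core allele as "0"/"1"
    positions: np.ndarray  # ascending, includes the core position
    ehh: np.ndarray  # aligned with positions; 1.0 at the core
    cutoff: float
    truncated_left: bool = False  # chromosome border reached
    truncated_right: bool = False
    gap_stopped_left: bool = False
    gap_stopped_right: bool = False

    @property
    def core_index(self) -> int:
        return int(np.searchsorted(self.positions, self.core_pos))


@dataclass
class XPEHHResult:
    table: pd.DataFrame  # variant_id, chromosome, position_bp, ihh_a, ihh_b,
    #                      raw, standardized, logp
    dropped: pd.DataFrame  # variants with zero iHH in either population
    n_haplotypes_a: int = 0
    n_haplotypes_b: int = 0


@dataclass
class SelectionRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    n_variants: int
    n_extreme: int
    pct_extreme: float
    top_variant_id: str
    top_score: float
    top_logp: float


# ---------------------------------------------------------------------------
# single-core EHH curves


def ehh_curve(
    panel: HaplotypePanel,
    core: str,
    focal="site",
    cutoff: float = 0.05,
    max_gap_bp: int | None = None,
) -> EHHCurve:
    """EHH decay curve around one core variant.

    ``focal`` is ``"site"`` for the pooled site-level definition, or an
    allele (0 or 1) for allele-specific EHH among carriers. Extension in
    each direction stops when EHH drops below ``cutoff`` (the first
    below-cutoff marker is kept on the curve), at the chromosome border,
    or at an inter-marker gap exceeding ``max_gap_bp``.
    """
    vm = panel.variants
    idx = vm.index[vm["variant_id"] == core]
    if len(idx) == 0:
        raise KeyError(f"core variant {core!r} not in the variant map")
    j = int(idx[0])
    chrom = vm["chromosome"].iloc[j]
    on_chrom = np.flatnonzero((vm["chromosome"] == chrom).to_numpy())
    haps = panel.haplotypes[:, on_chrom]
    pos = vm["position_bp"].to_numpy()[on_chrom]
    jc = int(np.searchsorted(on_chrom, j))

    if focal == "site":
        rows = np.arange(haps.shape[0])
        labels0 = haps[:, jc].astype(np.int64)
        focal_name = "site"
    else:
        a = int(focal)
        rows = np.flatnonzero(haps[:, jc] == a)
        if len(rows) < 2:
            raise ValueError(
                f"core {core!r} allele {a} has {len(rows)} carriers "
                "(allele-specific EHH needs at least 2)"
            )
        labels0 = np.zeros(len(rows), dtype=np.int64)
        focal_name = str(a)

    h = haps[rows]
    hom0 = _homozygosity(labels0)
    if focal == "site" and hom0 == 0.0:
        # every haplotype unique at the core: degenerate but well-defined
        hom0 = 1.0
    gap = np.inf if max_gap_bp is None else max_gap_bp

    out_pos = [int(pos[jc])]
    out_ehh = [1.0]
    flags = {}
    for direction, name in ((1, "right"), (-1, "left")):
        labels = labels0.copy()
        k = jc
        trunc = gapstop = False
        side_pos, side_ehh = [], []
        while True:
            nk = k + direction
            if nk < 0 or nk >= h.shape[1]:
                trunc = True
                break
            if abs(int(pos[nk]) - int(pos[k])) > gap:
                gapstop = True
                break
            labels = _refine(labels, h[:, nk])
            e = _homozygosity(labels) / hom0
            side_pos.append(int(pos[nk]))
            side_ehh.append(e)
            k = nk
            if e < cutoff:
                break
        flags[f"truncated_{name}"] = trunc
        flags[f"gap_stopped_{name}"] = gapstop
        if direction == 1:
            out_pos += side_pos
            out_ehh += side_ehh
        else:
            out_pos = side_pos[::-1] + out_pos
            out_ehh = side_ehh[::-1] + out_ehh

    return EHHCurve(
        core_id=core,
        core_pos=int(pos[jc]),
        focal=focal_name,
        positions=np.asarray(out_pos, dtype=np.int64),
        ehh=np.asarray(out_ehh, dtype=np.float64),
        cutoff=cutoff,
        **flags,
    )


def _refine(labels: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Split identity groups by the alleles at one more marker."""
    key = labels * 2 + alleles.astype(np.int64)
    _, new = np.unique(key, return_inverse=True)
    return new


def _homozygosity(labels: np.ndarray) -> float:
    n = len(labels)
    if n < 2:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def integrate_ihh(curve: EHHCurve) -> tuple[float, dict]:
    """Trapezoidal iHH (bp) of an EHH curve, both directions pooled.

    EHH values below the curve's cutoff are set to zero before
    integrating. Curves truncated at a border integrate over the observed
    support; the flags are passed through for the caller to filter on.
    """
    flags = {
        "truncated": curve.truncated_left or curve.truncated_right,
        "gap_stopped": curve.gap_stopped_left or curve.gap_stopped_right,
        "empty": len(curve.positions) <= 1,
    }
    if flags["empty"]:
        return 0.0, flags
    e = np.where(curve.ehh >= curve.cutoff, curve.ehh, 0.0)
    ci = curve.core_index
    total = 0.0
    for seg_pos, seg_e in (
        (curve.positions[ci:], e[ci:]),
        (curve.positions[: ci + 1][::-1], e[: ci + 1][::-1]),
    ):
        if len(seg_pos) > 1:
            d = np.abs(np.diff(seg_pos.astype(np.float64)))
            total += float(np.sum(d * (seg_e[:-1] + seg_e[1:]) / 2.0))
    return total, flags


# ---------------------------------------------------------------------------
# whole-panel site-level iHH (numba)


@njit(cache=True)
def _site_ihh_all(haps, pos, cutoff, max_gap):  # pragma: no cover
    """Site-level iHH at every variant of one chromosome.

    Returns (ihh, border) where border[j] is 1 if either direction hit the
    chromosome end before the EHH curve fell below the cutoff.
    """
    H, m = haps.shape
    ihh = np.zeros(m)
    border = np.zeros(m, dtype=np.int8)
    labels = np.empty(H, dtype=np.int64)
    remap = np.full(2 * H + 2, -1, dtype=np.int64)
    counts = np.zeros(H, dtype=np.int64)
    denom = H * (H - 1)

    for j in range(m):
        # core homozygosity from the two core-allele groups
        n1 = 0
        for i in range(H):
            labels[i] = haps[i, j]
            n1 += haps[i, j]
        n0 = H - n1
        hom0 = (n0 * (n0 - 1) + n1 * (n1 - 1)) / denom
        if hom0 == 0.0:
            hom0 = 1.0

        total = 0.0
        for direction in (1, -1):
            # reset labels to the core partition
            for i in range(H):
                labels[i] = haps[i, j]
            ng = 2
            prev_e = 1.0
            k = j
            while True:
                nk = k + direction
                if nk < 0 or nk >= m:
                    border[j] = 1
                    break
                step = pos[nk] - pos[k]
                if step < 0:
                    step = -step
                if step > max_gap:
                    break
                # refine groups by the allele at nk; keys use the current
                # labels, so clear exactly that key range first
                for key in range(2 * ng + 2):
                    remap[key] = -1
                next_id = 0
                for i in range(H):
                    key = labels[i] * 2 + haps[i, nk]
                    if remap[key] == -1:
                        remap[key] = next_id
                        next_id += 1
                    labels[i] = remap[key]
                for g in range(next_id):
                    counts[g] = 0
                for i in range(H):
                    counts[labels[i]] += 1
                s = 0
                for g in range(next_id):
                    s += counts[g] * (counts[g] - 1)
                e = (s / denom) / hom0
                ng = next_id

                e_lo = prev_e if prev_e >= cutoff else 0.0
                e_hi = e if e >= cutoff else 0.0
                total += step * (e_lo + e_hi) / 2.0
                prev_e = e
                k = nk
                if e < cutoff:
                    break
        ihh[j] = total
    return ihh, border


def site_ihh(
    panel: HaplotypePanel, cutoff: float = 0.05, max_gap_bp: int | None = None
) -> pd.DataFrame:
    """Site-level iHH at every variant, chromosome by chromosome."""
    vm = panel.variants
    gap = np.float64(max_gap_bp if max_gap_bp is not None else 2**62)
    rows = []
    for chrom, grp in vm.groupby("chromosome", sort=False):
        cols = grp.index.to_numpy()
        haps = np.ascontiguousarray(panel.haplotypes[:, cols])
        pos = grp["position_bp"].to_numpy(dtype=np.float64)
        ihh, border = _site_ihh_all(haps, pos, cutoff, gap)
        rows.append(
            pd.DataFrame(
                {
                    "variant_id": grp["variant_id"].to_numpy(),
                    "chromosome": chrom,
                    "position_bp": grp["position_bp"].to_numpy(),
                    "ihh": ihh,
                    "border": border.astype(bool),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def xpehh_scan(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    cutoff: float = 0.05,
    max_gap_bp: int | None = None,
    discard_border: bool = False,
) -> XPEHHResult:
    """Cross-population XP-EHH: ln(iHH_A / iHH_B) per variant, standardized
    genome-wide; positive scores mean longer haplotypes in panel A (cases).

    Variants with zero iHH in either population (or truncated at a border
    when ``discard_border``) are dropped and reported separately. Raises if
    the raw scores have zero spread (e.g. identical panels).
    """
    if not panel_a.variants[["variant_id", "chromosome", "position_bp"]].equals(
        panel_b.variants[["variant_id", "chromosome", "position_bp"]]
    ):
        raise ValueError("panels must share an identical variant map")
    ta = site_ihh(panel_a, cutoff, max_gap_bp)
    tb = site_ihh(panel_b, cutoff, max_gap_bp)
    t = ta.rename(columns={"ihh": "ihh_a", "border": "border_a"})
    t["ihh_b"] = tb["ihh"]
    t["border_b"] = tb["border"]

    bad = (t["ihh_a"] <= 0) | (t["ihh_b"] <= 0)
    if discard_border:
        bad |= t["border_a"] | t["border_b"]
    dropped = t[bad].copy()
    t = t[~bad].copy()
    if len(t) == 0:
        raise ValueError("no variant has positive iHH in both populations")

    # log difference (not log of the quotient) so that swapping the two
    # panels negates every raw score bit-exactly
    raw = np.log(t["ihh_a"].to_numpy()) - np.log(t["ihh_b"].to_numpy())
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError(
            "raw XP-EHH has zero spread (identical panels?); "
            "standardization undefined"
        )
    z = (raw - raw.mean()) / sd
    logp = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
    t["raw"] = raw
    t["standardized"] = z
    t["logp"] = logp
    t = t.drop(columns=["border_a", "border_b"])
    return XPEHHResult(
        table=t.reset_index(drop=True),
        dropped=dropped.reset_index(drop=True),
        n_haplotypes_a=panel_a.n_haplotypes,
        n_haplotypes_b=panel_b.n_haplotypes,
    )


def call_candidate_regions(
    scores: XPEHHResult | pd.DataFrame,
    threshold_logp: float = 4.0,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_n_extreme: int = 2,
) -> list[SelectionRegion]:
    """Sliding-window candidate sweep regions.

    Windows of ``window_bp`` start on the ``step_bp`` grid; a window
    qualifies when it holds at least ``min_n_extreme`` variants with
    -log10(p) >= ``threshold_logp``. Overlapping or touching qualifying
    windows merge into one region, whose bounds stay grid-aligned.
    """
    t = scores.table if isinstance(scores, XPEHHResult) else scores
    regions: list[SelectionRegion] = []
    for chrom, grp in t.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        logp = grp["logp"].to_numpy()
        z = grp["standardized"].to_numpy()
        vid = grp["variant_id"].to_numpy()
        order = np.argsort(pos)
        pos, logp, z, vid = pos[order], logp[order], z[order], vid[order]

        ext = logp >= threshold_logp
        if ext.sum() < min_n_extreme:
            continue
        w0 = (int(pos.min()) - window_bp) // step_bp * step_bp
        w0 = max(w0, 0)
        starts = np.arange(w0, int(pos.max()) + step_bp, step_bp)
        qualify = []
        for w in starts:
            in_w = (pos > w) & (pos <= w + window_bp)
            if (ext & in_w).sum() >= min_n_extreme:
                qualify.append(int(w))
        if not qualify:
            continue
        # merge windows that overlap or touch
        merged = [[qualify[0], qualify[0] + window_bp]]
        for w in qualify[1:]:
            if w <= merged[-1][1]:
                merged[-1][1] = w + window_bp
            else:
                merged.append([w, w + window_bp])
        for start, end in merged:
            in_r = (pos > start) & (pos <= end)
            n_var = int(in_r.sum())
            n_ext = int((ext & in_r).sum())
            sub = np.flatnonzero(in_r)
            top = sub[np.argmax(np.abs(z[sub]))]
            regions.append(
                SelectionRegion(
                    chromosome=str(chrom),
                    start_bp=start,
                    end_bp=end,
                    n_variants=n_var,
                    n_extreme=n_ext,
                    pct_extreme=100.0 * n_ext / n_var if n_var else 0.0,
                    top_variant_id=str(vid[top]),
                    top_score=float(z[top]),
                    top_logp=float(logp[top]),
                )
            )
    return regions


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_variants": r.n_variants,
                "n_extreme": r.n_extreme,
                "pct_extreme": r.pct_extreme,
                "top_variant_id": r.top_variant_id,
                "top_score": r.top_score,
                "top_logp": r.top_logp,
            }
            for r in regions
        ],
        columns=[
            "chromosome", "start_bp", "end_bp", "n_variants", "n_extreme",
            "pct_extreme", "top_variant_id", "top_score", "top_logp",
        ],
    )
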