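import numpy as np
import pytest

from breedscan.types import GenotypeMatrix, HaplotypePanel, make_variant_map


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """3 samples x 2 variants with one missing call."""
    vm = make_variant_map(["v1", "v2"], "1", [1000, 2000], ["A", "G"], ["C", "T"])
    dos = np.array([[0, 1], [2, -1], [1, 0]], dtype=np.int8)
    return GenotypeMatrix(samples=["s1", "s2", "s3"], variants=vm, dosages=dos)


@pytest.fixture
def random_panel_factory():
    """Factory for small random phased panels (deterministic per seed)."""

    def make(n_samples=6, m=20, seed=0, chrom="1", spacing=1000):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, size=(2 * n_samples, m)).astype(np.int8)
        vm = make_variant_map(
            [f"s{j}" for j in range(m)], chrom,
            (np.arange(m) + 1) * spacing,
        )
        return HaplotypePanel(
            haplotypes=haps, variants=vm,
            samples=[f"d{i}" for i in range(n_samples)],
        )

    return make


def brute_force_ehh(haps: np.ndarray, core: int, rows=None, site_level=True):
    """Independent EHH oracle: exhaustive enumeration of extended
    haplotypes as tuples, at every marker distance out to the panel edge.

    Returns (left, right) lists of EHH values at 1, 2, ... markers from the
    core (no cutoff applied).
    """
    if rows is None:
        rows = np.arange(haps.shape[0])
    h = haps[rows]
    n = len(rows)

    def hom(strings):
        counts = {}
        for s in strings:
            counts[s] = counts.get(s, 0) + 1
        return sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))

    hom0 = hom([tuple(row[core: core + 1]) for row in h]) if site_level else 1.0
    if hom0 == 0.0:
        hom0 = 1.0
    lo = core if site_level else core + 1  # carriers share the core allele

    right = []
    for d in range(core + 1, haps.shape[1]):
        right.append(hom([tuple(row[lo: d + 1]) for row in h]) / hom0)
    left = []
    hi = core + 1 if site_level else core
    for d in range(core - 1, -1, -1):
        left.append(hom([tuple(row[d:hi]) for row in h]) / hom0)
    return left, right


def brute_force_site_ihh(haps, pos, core, cutoff=0.05):
    """Oracle iHH: brute-force site-level EHH plus trapezoid with the
    below-cutoff-to-zero rule, stopping after the first sub-cutoff marker."""
    left, right = brute_force_ehh(haps, core, site_level=True)
    total = 0.0
    for vals, coords in (
        (right, pos[core + 1:]),
        (left, pos[:core][::-1]),
    ):
        prev_e, prev_p = 1.0, pos[core]
        for e, p in zip(vals, coords):
            e_lo = prev_e if prev_e >= cutoff else 0.0
            e_hi = e if e >= cutoff else 0.0
            total += abs(int(p) - int(prev_p)) * (e_lo + e_hi) / 2.0
            prev_e, prev_p = e, p
            if e < cutoff:
                break
    return total
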