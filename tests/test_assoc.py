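import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from breedscan.assoc import (
    ContingencyTable2x2,
    allelic_chisq_scan,
    haplotype_carrier_classes,
    ld_r2,
    logistic_scan,
    welch_t_test,
    yates_chisq,
)
from breedscan.synthetic_cohort import SimulationConfig, simulate_cohort
from breedscan.types import (
    GenotypeMatrix,
    HaplotypePanel,
    PhenotypeTable,
    make_variant_map,
)


def _pheno(status, **cov):
    t = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(status))],
                      "status": status})
    for k, v in cov.items():
        t[k] = v
    return PhenotypeTable(t)


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    vm = make_variant_map([f"v{j}" for j in range(m)], "1",
                          (np.arange(m) + 1) * 10)
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          variants=vm, dosages=dosages)


class TestAllelicChisq:
    def test_equal_frequencies_give_zero(self):
        g = _geno([[1], [1], [1], [1]])
        pheno = _pheno([1, 1, 0, 0])
        out = allelic_chisq_scan(g, pheno)
        assert out["chi2"].iloc[0] == pytest.approx(0.0)

    def test_matches_textbook_expected_counts_formula(self):
        # cases a1/a2 = 70/30, controls 90/10 (allele counts)
        g = _geno(
            [[1]] * 30 + [[0]] * 35  # cases: 30 het + 35 hom-a1
            + [[1]] * 10 + [[0]] * 45  # controls: 10 het + 45 hom-a1
        )
        pheno = _pheno([1] * 65 + [0] * 55)
        out = allelic_chisq_scan(g, pheno)
        table = np.array([[30, 100], [10, 100]], dtype=float)
        # independent oracle: sum (O-E)^2 / E over the 2x2 allele table
        expected = stats.chi2_contingency(table, correction=False)[0]
        assert out["chi2"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_planted_causal_variant_is_top_hit(self):
        wins = 0
        for seed in range(10):
            planted = (50,)
            cfg = SimulationConfig(n_samples=300, m_variants=200, seed=seed,
                                   heritability_liability=0.5,
                                   mixture_proportions=(1.0, 0, 0, 0),
                                   planted_causal_indices=planted)
            _, g, pheno, _ = simulate_cohort(cfg)
            scan = allelic_chisq_scan(g, pheno)
            wins += int(np.nanargmax(scan["chi2"].to_numpy()) == 50)
        assert wins >= 8

    def test_invariant_to_swapping_case_control_labels(self):
        _, g, pheno, _ = simulate_cohort(
            SimulationConfig(n_samples=60, m_variants=30, seed=4)
        )
        flipped = PhenotypeTable(
            pheno.table.assign(status=1 - pheno.table["status"])
        )
        a = allelic_chisq_scan(g, pheno)["chi2"]
        b = allelic_chisq_scan(g, flipped)["chi2"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestLogisticScan:
    def test_confounded_signal_absorbed_by_covariate(self):
        """A variant associated only through substructure loses
        significance once the structure covariate enters the model."""
        cfg = SimulationConfig(n_samples=400, m_variants=300, seed=6,
                               subpop_fraction=0.5, subpop_divergence=0.5,
                               heritability_liability=0.0,
                               covariate_effects={"subpop": 2.0})
        panel, g, pheno, truth = simulate_cohort(cfg)
        chis = allelic_chisq_scan(g, pheno)
        j = int(np.nanargmax(chis["chi2"].to_numpy()))
        assert chis["logp"].iloc[j] > 3  # confounding creates association
        sub = g.subset(variant_idx=[j])
        pheno_cov = PhenotypeTable(
            pheno.table.assign(subpop=truth.subpop_labels.astype(float))
        )
        out = logistic_scan(sub, pheno_cov, covariates=["subpop"])
        assert out["p"].iloc[0] > 1e-3

    def test_wald_z_squared_tracks_allelic_chisq(self):
        _, g, pheno, _ = simulate_cohort(
            SimulationConfig(n_samples=2000, m_variants=5, seed=8)
        )
        chis = allelic_chisq_scan(g, pheno)
        logi = logistic_scan(g, pheno)
        for j in range(5):
            if not logi["converged"].iloc[j] or chis["chi2"].iloc[j] < 0.5:
                continue
            z2 = stats.norm.isf(logi["p"].iloc[j] / 2) ** 2
            assert z2 == pytest.approx(chis["chi2"].iloc[j], rel=0.15)

    def test_constant_dosage_flagged(self):
        g = _geno([[1], [1], [1], [1], [1], [1]])
        pheno = _pheno([1, 0, 1, 0, 1, 0])
        out = logistic_scan(g, pheno)
        assert not out["converged"].iloc[0]
        assert np.isnan(out["p"].iloc[0])


class TestYatesChisq:
    def test_equal_proportions_give_zero_and_p_one(self):
        t = ContingencyTable2x2(20, 30, 40, 60)
        chi2, p = yates_chisq(t)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        a, b, c, d = 20, 80, 40, 60
        n = a + b + c + d
        num = n * (abs(a * d - b * c) - n / 2) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2, p = yates_chisq(ContingencyTable2x2(a, b, c, d))
        assert chi2 == pytest.approx(num / den, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(num / den, 1), rel=1e-12)

    def test_correction_truncates_at_zero(self):
        # |ad - bc| < N/2 -> statistic clamped to 0, never negative
        chi2, p = yates_chisq(ContingencyTable2x2(5, 5, 5, 6))
        assert chi2 == 0.0 and p == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_invariant_to_transposition(self, cells):
        a, b, c, d = cells
        x = yates_chisq(ContingencyTable2x2(a, b, c, d))[0]
        y = yates_chisq(ContingencyTable2x2(a, c, b, d))[0]
        assert x == pytest.approx(y, rel=1e-9)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_closed_form_small_example(self):
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        t, df, p = welch_t_test(x, y)
        se = np.sqrt(x.var(ddof=1) / 3 + y.var(ddof=1) / 3)
        assert t == pytest.approx((x.mean() - y.mean()) / se)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestLDr2:
    def test_duplicated_variant_r2_one(self):
        g = _geno([[0, 0], [1, 1], [2, 2], [1, 1], [0, 0]])
        out = ld_r2(g, [("v0", "v1")])
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(2000, 2)).astype(np.int8)
        out = ld_r2(_geno(dos), [("v0", "v1")])
        assert out["r2"].iloc[0] < 0.01

    def test_haplotype_counts_match_d_squared_oracle(self):
        # 6 haplotypes with counts AB:3, Ab:1, aB:1, ab:1 (A=a1=0, B=0)
        rows = [[0, 0], [0, 0], [0, 0], [0, 1], [1, 0], [1, 1]]
        vm = make_variant_map(["x", "y"], "1", [1, 2])
        panel = HaplotypePanel(haplotypes=np.asarray(rows, dtype=np.int8),
                               variants=vm, samples=["a", "b", "c"])
        pA, pB, pAB = 4 / 6, 4 / 6, 3 / 6
        D = pAB - pA * pB
        expected = D**2 / (pA * (1 - pA) * pB * (1 - pB))
        out = ld_r2(panel, [("x", "y")])
        assert out["r2"].iloc[0] == pytest.approx(expected, rel=1e-12)
        # symmetry
        assert ld_r2(panel, [("y", "x")])["r2"].iloc[0] == pytest.approx(
            expected, rel=1e-12
        )

    def test_monomorphic_rejected(self):
        g = _geno([[0, 1], [0, 0], [0, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(g, [("v0", "v1")])


class TestHaplotypeCarrierClasses:
    def _panel(self, per_sample_copies, seed=0):
        """Panel over three sites where sample i carries the target
        haplotype (1,1,1) on the requested number of its two haplotypes."""
        rng = np.random.default_rng(seed)
        rows = []
        for c in per_sample_copies:
            for k in range(2):
                if k < c:
                    rows.append([1, 1, 1])
                else:
                    row = [1, 1, 1]
                    row[rng.integers(3)] = 0
                    rows.append(row)
        vm = make_variant_map(["a", "b", "c"], "1", [10, 20, 30])
        return HaplotypePanel(
            haplotypes=np.asarray(rows, dtype=np.int8), variants=vm,
            samples=[f"s{i}" for i in range(len(per_sample_copies))],
        )

    def test_copy_count_definition(self):
        panel = self._panel([2, 1, 0])
        copies, summary = haplotype_carrier_classes(panel, ["a", "b", "c"],
                                                    [1, 1, 1])
        np.testing.assert_array_equal(copies, [2, 1, 0])
        freq = summary[summary["copies"] == "frequency"]
        assert freq["pct"].iloc[0] == pytest.approx(100 * 3 / 6)

    def test_one_mismatching_haplotype_gives_class_one(self):
        rows = [[1, 1, 1], [1, 0, 1]]
        vm = make_variant_map(["a", "b", "c"], "1", [10, 20, 30])
        panel = HaplotypePanel(haplotypes=np.asarray(rows, dtype=np.int8),
                               variants=vm, samples=["s"])
        copies, _ = haplotype_carrier_classes(panel, ["a", "b", "c"], [1, 1, 1])
        assert copies[0] == 1

    def test_class_counts_sum_and_frequency_identity(self):
        per = [2, 2, 1, 0, 1, 2, 0]
        panel = self._panel(per, seed=3)
        copies, summary = haplotype_carrier_classes(
            panel, ["a", "b", "c"], [1, 1, 1]
        )
        n = len(per)
        counts = summary[summary["copies"] != "frequency"]
        assert counts["n"].sum() == n
        n2 = int((copies == 2).sum())
        n1 = int((copies == 1).sum())
        freq = summary[summary["copies"] == "frequency"]["pct"].iloc[0]
        assert freq == pytest.approx(100 * (2 * n2 + n1) / (2 * n))

    def test_allele_characters_resolved_against_map(self):
        rows = [[1, 0], [1, 0]]
        vm = make_variant_map(["a", "b"], "1", [10, 20],
                              ["T", "C"], ["C", "G"])
        panel = HaplotypePanel(haplotypes=np.asarray(rows, dtype=np.int8),
                               variants=vm, samples=["s"])
        copies, _ = haplotype_carrier_classes(panel, ["a", "b"], "CC")
        assert copies[0] == 2

    def test_sites_must_share_chromosome(self):
        rows = [[1, 0], [1, 0]]
        vm = make_variant_map(["a", "b"], ["1", "2"], [10, 10])
        panel = HaplotypePanel(haplotypes=np.asarray(rows, dtype=np.int8),
                               variants=vm, samples=["s"])
        with pytest.raises(ValueError, match="one chromosome"):
            haplotype_carrier_classes(panel, ["a", "b"], [1, 1])
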