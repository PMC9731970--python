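import numpy as np
import pandas as pd
import pytest

from breedscan.bayesr import BayesRResult
from breedscan.loci import (
    EffectLocus,
    call_effect_variants,
    compute_risk_index,
    merge_into_loci,
    variance_explained,
)
from breedscan.types import GenotypeMatrix, PhenotypeTable, make_variant_map


def _result(effects, ids=None):
    effects = np.asarray(effects, dtype=float)
    m = len(effects)
    ids = ids or [f"v{j}" for j in range(m)]
    return BayesRResult(
        variant_ids=ids,
        beta_mean=effects,
        mean_abs_effect=np.abs(effects),
        class_prob=np.zeros((m, 4)),
        pi=np.array([1.0, 0, 0, 0]),
        sigma2_g=0.0, sigma2_e=0.0, mu=0.0,
        fixed_effects=np.zeros(1),
    )


def _cohort(positions, dosages, status, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    vm = make_variant_map([f"v{j}" for j in range(m)], chrom, positions,
                          ["A"] * m, ["C"] * m)
    g = GenotypeMatrix(samples=[f"s{i}" for i in range(n)], variants=vm,
                       dosages=dosages)
    pheno = PhenotypeTable(pd.DataFrame(
        {"sample_id": g.samples, "status": status}
    ))
    return g, pheno


class TestCallEffectVariants:
    def test_effect_at_published_scale_included(self):
        # 0.000104 clears the 1e-4 reporting cutoff
        r = _result([0.000104, 0.00009999, -0.0002])
        out = call_effect_variants(r, threshold=1e-4)
        assert set(out["variant_id"]) == {"v0", "v2"}

    def test_boundary_is_inclusive_at_threshold(self):
        r = _result([1e-4, 9.999e-5])
        out = call_effect_variants(r, threshold=1e-4)
        assert list(out["variant_id"]) == ["v0"]

    def test_top_n_mode_with_genomic_tie_break(self):
        effects = np.full(60, 5e-4)
        effects[:5] = 1e-3  # five clear leaders
        r = _result(effects)
        out = call_effect_variants(r, top_n=50)
        assert len(out) == 50
        # ties resolved by input (genomic) order: v5..v49 precede v50..
        assert list(out["variant_id"][:5]) == [f"v{j}" for j in range(5)]
        assert list(out["variant_id"][5:]) == [f"v{j}" for j in range(5, 50)]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_effect_variants(_result([1e-3]), threshold=0.0)


class TestMergeIntoLoci:
    def test_sub_megabase_gap_merges(self):
        g, pheno = _cohort([1_000_000, 1_900_000],
                           [[0, 0], [1, 1], [2, 2], [0, 1]],
                           [1, 1, 0, 0])
        ev = call_effect_variants(_result([2e-4, 3e-4]), threshold=1e-4)
        loci = merge_into_loci(ev, g, pheno)
        assert len(loci) == 1
        assert loci[0].member_ids == ["v0", "v1"]
        assert loci[0].top_variant_id == "v1"

    def test_exact_megabase_gap_splits(self):
        g, pheno = _cohort([1_000_000, 2_000_000],
                           [[0, 0], [1, 1], [2, 2], [0, 1]],
                           [1, 1, 0, 0])
        ev = call_effect_variants(_result([2e-4, 3e-4]), threshold=1e-4)
        assert len(merge_into_loci(ev, g, pheno)) == 2

    def test_recovers_planted_clusters(self):
        rng = np.random.default_rng(0)
        # 11 clusters of 3 variants, cluster starts 5 Mb apart
        positions, effects = [], []
        for c in range(11):
            base = 1_000_000 + c * 5_000_000
            positions += [base, base + 200_000, base + 400_000]
            effects += [2e-4, 5e-4, 1.5e-4]
        m = len(positions)
        dosages = rng.integers(0, 3, size=(40, m)).astype(np.int8)
        g, pheno = _cohort(positions, dosages, [1] * 20 + [0] * 20)
        ev = call_effect_variants(_result(effects), threshold=1e-4)
        loci = merge_into_loci(ev, g, pheno)
        assert len(loci) == 11
        assert all(len(l.member_ids) == 3 for l in loci)

    def test_invariant_to_input_order(self):
        g, pheno = _cohort([1_000_000, 1_500_000, 9_000_000],
                           np.random.default_rng(1).integers(0, 3, (20, 3)),
                           [1] * 10 + [0] * 10)
        ev = call_effect_variants(_result([2e-4, 3e-4, 4e-4]), threshold=1e-4)
        a = merge_into_loci(ev, g, pheno)
        b = merge_into_loci(ev.iloc[::-1], g, pheno)
        assert [l.member_ids for l in a] == [l.member_ids for l in b]

    def test_risk_allele_is_the_case_enriched_allele(self):
        # allele2 (C) more frequent in cases at v0; allele1 (A) at v1
        g, pheno = _cohort(
            [1_000_000, 9_000_000],
            [[2, 0], [2, 0], [0, 2], [0, 2]],
            [1, 1, 0, 0],
        )
        ev = call_effect_variants(_result([2e-4, 2e-4]), threshold=1e-4)
        loci = merge_into_loci(ev, g, pheno)
        assert loci[0].risk_allele == "C"
        assert loci[1].risk_allele == "A"


def _loci_for_index(n_loci, positions=None):
    return [
        EffectLocus(
            chromosome="1", start_bp=(j + 1) * 10, end_bp=(j + 1) * 10,
            member_ids=[f"v{j}"], top_variant_id=f"v{j}", top_effect=1e-3,
            effect_allele="C", other_allele="A", risk_allele="C",
            ea_freq_cases=0.5, ea_freq_controls=0.3,
        )
        for j in range(n_loci)
    ]


class TestRiskIndex:
    def _geno(self, dosages):
        dosages = np.asarray(dosages, dtype=np.int8)
        n, m = dosages.shape
        vm = make_variant_map([f"v{j}" for j in range(m)], "1",
                              (np.arange(m) + 1) * 10, ["A"] * m, ["C"] * m)
        return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                              variants=vm, dosages=dosages)

    def test_all_non_risk_gives_zero(self):
        g = self._geno(np.zeros((3, 11), dtype=np.int8))
        ri = compute_risk_index(g, _loci_for_index(11), scheme="half")
        np.testing.assert_array_equal(ri.values, 0.0)

    def test_all_homozygous_risk_maxima(self):
        g = self._geno(np.full((2, 11), 2, dtype=np.int8))
        half = compute_risk_index(g, _loci_for_index(11), scheme="half")
        count = compute_risk_index(g, _loci_for_index(11), scheme="count")
        np.testing.assert_array_equal(half.values, 11.0)
        np.testing.assert_array_equal(count.values, 22.0)

    def test_hand_sum_mixed_genotypes(self):
        # het at 3 of 5 loci, hom-risk at 2: half-scheme 3*0.5 + 2*1 = 3.5
        g = self._geno(np.array([[1, 1, 1, 2, 2]], dtype=np.int8))
        ri = compute_risk_index(g, _loci_for_index(5), scheme="half")
        assert ri.values[0] == pytest.approx(3.5)

    def test_count_scheme_is_exactly_double_half(self):
        rng = np.random.default_rng(2)
        g = self._geno(rng.integers(0, 3, size=(20, 7)).astype(np.int8))
        half = compute_risk_index(g, _loci_for_index(7), scheme="half")
        count = compute_risk_index(g, _loci_for_index(7), scheme="count")
        np.testing.assert_allclose(count.values, 2 * half.values, atol=0)

    def test_risk_allele1_flips_dosage(self):
        g = self._geno(np.array([[0], [2]], dtype=np.int8))
        loci = _loci_for_index(1)
        loci[0].risk_allele = "A"  # allele1 carries the risk
        ri = compute_risk_index(g, loci, scheme="count")
        np.testing.assert_array_equal(ri.values, [2.0, 0.0])

    def test_missing_contributes_locus_mean(self):
        g = self._geno(np.array([[2], [0], [-1]], dtype=np.int8))
        ri = compute_risk_index(g, _loci_for_index(1), scheme="count")
        assert ri.values[2] == pytest.approx(1.0)  # mean of (2, 0)


class TestVarianceExplained:
    def test_self_prediction_explains_everything(self):
        y = np.arange(10.0)
        out = variance_explained(y, pd.DataFrame({"x": y}))
        row = out[out["term"] == "x"].iloc[0]
        assert row["pct_variance"] == pytest.approx(100.0)

    def test_orthogonal_predictor_explains_nearly_nothing(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10_000)
        x = rng.normal(size=10_000)
        out = variance_explained(y, pd.DataFrame({"x": x}))
        assert out[out["term"] == "x"]["pct_variance"].iloc[0] < 0.1

    def test_recovers_known_variance_shares(self):
        rng = np.random.default_rng(4)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + x2 + rng.normal(size=n)  # thirds of the variance each
        out = variance_explained(y, pd.DataFrame({"x1": x1, "x2": x2}))
        for term in ("x1", "x2"):
            pct = out[out["term"] == term]["pct_variance"].iloc[0]
            assert pct == pytest.approx(100 / 3, abs=2.0)

    def test_type_one_terms_sum_to_hundred(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=200)
        preds = pd.DataFrame(rng.normal(size=(200, 3)),
                             columns=["a", "b", "c"])
        cov = pd.DataFrame({"pc1": rng.normal(size=200)})
        out = variance_explained(y, preds, cov)
        assert out["pct_variance"].sum() == pytest.approx(100.0)

    def test_covariates_enter_first(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=3000)
        y = z + rng.normal(size=3000) * 0.1
        x = z + rng.normal(size=3000) * 0.1  # proxy for the covariate
        with_cov = variance_explained(
            y, pd.DataFrame({"x": x}), pd.DataFrame({"z": z})
        )
        alone = variance_explained(y, pd.DataFrame({"x": x}))
        pct_with = with_cov[with_cov["term"] == "x"]["pct_variance"].iloc[0]
        pct_alone = alone[alone["term"] == "x"]["pct_variance"].iloc[0]
        assert pct_with < 2.0 < pct_alone

    def test_collinear_term_flagged_with_zero_df(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        out = variance_explained(
            y, pd.DataFrame({"x": x, "x_dup": x.copy()})
        )
        dup = out[out["term"] == "x_dup"].iloc[0]
        assert dup["collinear"] and dup["df"] == 0.0
        assert out["pct_variance"].sum() == pytest.approx(100.0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            variance_explained(
                np.arange(3.0), pd.DataFrame({"a": [1.0, 2, 3],
                                              "b": [2.0, 1, 0]})
            )
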