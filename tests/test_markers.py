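"""Genotype parsing, call/marker/genet filters, dosage coding, imputation, PCA."""

import numpy as np
import pytest

from gsblup import (
    DepthUnavailableError,
    FilterSpec,
    NonBiallelicError,
    ValidationError,
    apply_depth_rules,
    apply_filters,
    filter_genets,
    filter_markers,
    impute_naive,
    pca,
    read_genotypes,
    to_dosage,
)
from gsblup.markers import HET, HOM_ALT, HOM_REF, MISSING, MarkerMatrix

from conftest import make_callset


class TestReadGenotypes:
    def test_vcf_parse_calls_and_depth(self, toy_vcf):
        cs = read_genotypes(toy_vcf, format="vcf")
        assert cs.genet_ids == ["g1", "g2", "g3"]
        assert cs.marker_ids == ["m1", "m2", "m3", "m4"]
        expected = np.array(
            [[0, 1, 2, 0], [1, 0, 1, 0], [2, -1, 0, 1]], dtype=np.int8
        )
        np.testing.assert_array_equal(cs.calls, expected)
        assert cs.has_depth and cs.has_allele_depth
        assert cs.depth[0, 0] == 10 and cs.depth[2, 1] == 0
        assert cs.alt_depth[1, 0] == 4

    def test_hapmap_matches_vcf(self, toy_vcf, toy_hapmap):
        vcf = read_genotypes(toy_vcf, format="vcf")
        hmp = read_genotypes(toy_hapmap, format="hapmap")
        np.testing.assert_array_equal(vcf.calls, hmp.calls)
        assert hmp.depth is None

    def test_multiallelic_site_retained_but_flagged(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t1\ts1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
            "1\t2\ts2\tA\tG,T\t.\t.\t.\tGT\t0/1\t1/2\n"
        )
        p = tmp_path / "multi.vcf"
        p.write_text(text)
        cs = read_genotypes(p, format="vcf")
        assert cs.n_markers == 2
        np.testing.assert_array_equal(cs.is_biallelic(), [True, False])

    def test_duplicate_genet_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,m1,m2\ng1,0,1\ng1,2,1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_genotypes(p, format="tabular")

    def test_csv_roundtrip_codes(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("id,m1,m2\ng1,0,2\ng2,1,\n")
        cs = read_genotypes(p, format="tabular")
        np.testing.assert_array_equal(
            cs.calls, np.array([[0, 2], [1, -1]], dtype=np.int8)
        )


class TestDepthRules:
    spec = FilterSpec(min_hom_depth=4, min_het_contrasting=2)

    def test_hom_below_four_reads_set_missing(self):
        cs = make_callset([[HOM_REF]], depth=[[3]], ref_depth=[[3]], alt_depth=[[0]])
        out = apply_depth_rules(cs, self.spec)
        assert out.calls[0, 0] == MISSING

    def test_hom_at_four_reads_unchanged(self):
        cs = make_callset([[HOM_ALT]], depth=[[4]], ref_depth=[[0]], alt_depth=[[4]])
        out = apply_depth_rules(cs, self.spec)
        assert out.calls[0, 0] == HOM_ALT

    def test_het_without_two_contrasting_reads_set_missing(self):
        cs = make_callset([[HET, HET]], depth=[[6, 4]],
                          ref_depth=[[5, 2]], alt_depth=[[1, 2]])
        out = apply_depth_rules(cs, self.spec)
        assert out.calls[0, 0] == MISSING
        assert out.calls[0, 1] == HET

    def test_depth_unavailable_is_explicit_error(self):
        cs = make_callset([[HOM_REF]])
        with pytest.raises(DepthUnavailableError):
            apply_depth_rules(cs, self.spec)

    def test_total_depth_only_skips_het_rule_with_warning(self):
        cs = make_callset([[HET]], depth=[[6]])
        with pytest.warns(UserWarning, match="contrasting"):
            out = apply_depth_rules(cs, self.spec)
        assert out.calls[0, 0] == HET


class TestMarkerAndGenetFilters:
    def test_low_call_rate_marker_removed(self):
        # 2 of 10 genets called: call rate 0.2 < 0.30
        calls = np.full((10, 1), MISSING, dtype=np.int8)
        calls[:2, 0] = HET
        out, rep = filter_markers(make_callset(calls), FilterSpec())
        assert out.n_markers == 0
        assert rep.markers_removed_call_rate == 1

    def test_maf_strictly_above_threshold(self):
        # marker 0: alt freq 0.005 (1 het in 100) -> removed; marker 1: 0.02 kept
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[0, 0] = HET
        calls[:4, 1] = HET
        out, rep = filter_markers(make_callset(calls), FilterSpec(min_maf=0.01))
        assert out.marker_ids == ["m1"]
        assert rep.markers_removed_maf == 1

    def test_monomorphic_marker_removed(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        out, _ = filter_markers(make_callset(calls), FilterSpec())
        assert out.n_markers == 0

    def test_all_removed_warns_not_crashes(self):
        calls = np.zeros((5, 2), dtype=np.int8)
        with pytest.warns(UserWarning, match="all markers"):
            out, _ = filter_markers(make_callset(calls), FilterSpec())
        assert out.n_markers == 0 and out.n_genets == 5

    @pytest.mark.parametrize(
        "n_missing, retained", [(96, False), (95, True), (0, True)]
    )
    def test_genet_missingness_is_strict(self, n_missing, retained):
        calls = np.ones((2, 100), dtype=np.int8)
        calls[0, :n_missing] = MISSING
        out, rep = filter_genets(
            make_callset(calls), FilterSpec(max_genet_missing=0.95)
        )
        assert ("g0" in out.genet_ids) is retained
        if not retained:
            assert rep.removed_genet_ids == ["g0"]

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.choice(
            [-1, 0, 1, 2], p=[0.3, 0.3, 0.2, 0.2], size=(40, 60)
        ).astype(np.int8)
        spec = FilterSpec(min_maf=0.05, min_marker_call_rate=0.5,
                          max_genet_missing=0.6)
        once, _ = apply_filters(make_callset(calls), spec)
        twice, _ = apply_filters(once, spec)
        assert once.genet_ids == twice.genet_ids
        assert once.marker_ids == twice.marker_ids
        np.testing.assert_array_equal(once.calls, twice.calls)


class TestDosage:
    def test_coding_and_freq(self):
        cs = make_callset([[HOM_REF], [HET], [HOM_ALT]])
        m = to_dosage(cs)
        np.testing.assert_array_equal(m.dosage[:, 0], [0, 1, 2])
        assert m.allele_freq[0] == 0.5

    def test_all_ref_with_missing_freq_zero(self):
        cs = make_callset([[HOM_REF], [HOM_REF], [MISSING]])
        m = to_dosage(cs)
        assert m.allele_freq[0] == 0.0
        assert np.isnan(m.dosage[2, 0])

    def test_hand_matrix(self):
        cs = make_callset([[HET, HOM_ALT], [HOM_REF, MISSING]])
        m = to_dosage(cs)
        np.testing.assert_array_equal(m.dosage[0], [1, 2])
        assert m.dosage[1, 0] == 0 and np.isnan(m.dosage[1, 1])

    def test_non_biallelic_named_in_error(self):
        cs = make_callset([[HOM_REF, HET]],
                          alleles=[("A", "G"), ("A", "G,T")])
        with pytest.raises(NonBiallelicError, match="m1"):
            to_dosage(cs)


class TestImputation:
    def test_marker_mean_fills_2p(self):
        cs = make_callset([[HOM_REF], [HOM_ALT], [MISSING]])
        m = impute_naive(to_dosage(cs))
        assert m.dosage[2, 0] == pytest.approx(1.0)

    def test_p_zero_fills_zero(self):
        cs = make_callset([[HOM_REF], [HOM_REF], [MISSING]])
        for method in ("marker_mean", "random_hwe"):
            m = impute_naive(to_dosage(cs), method=method, seed=1)
            assert m.dosage[2, 0] == 0.0

    def test_random_hwe_moments(self):
        # p = 0.25: mean dosage of imputed entries ~ 0.5 within 3 SE
        n = 10_000
        calls = np.full((n, 1), MISSING, dtype=np.int8)
        calls[:4, 0] = [0, 0, 0, HOM_ALT]  # p = 2/8 = 0.25
        m = impute_naive(to_dosage(make_callset(calls)),
                         method="random_hwe", seed=7)
        imputed = m.dosage[4:, 0]
        se = np.sqrt(2 * 0.25 * 0.75 / imputed.size)
        assert abs(imputed.mean() - 0.5) < 3 * se

    def test_column_means_equal_2p_after_mean_imputation(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([-1, 0, 1, 2], size=(50, 30)).astype(np.int8)
        calls[0] = np.maximum(calls[0], 0)  # keep every marker observed
        m0 = to_dosage(make_callset(calls))
        m = impute_naive(m0)
        np.testing.assert_allclose(m.dosage.mean(axis=0), 2 * m0.allele_freq,
                                   atol=1e-12)

    def test_all_missing_marker_is_error(self):
        cs = make_callset([[MISSING], [MISSING]])
        with pytest.raises(ValidationError, match="no observed"):
            impute_naive(to_dosage(cs))


class TestPca:
    def _matrix(self, dosage, call_rate=None):
        dosage = np.asarray(dosage, float)
        return MarkerMatrix(
            genet_ids=[f"g{i}" for i in range(dosage.shape[0])],
            marker_ids=[f"m{j}" for j in range(dosage.shape[1])],
            dosage=dosage,
            allele_freq=dosage.mean(axis=0) / 2,
            call_rate=np.ones(dosage.shape[1]) if call_rate is None else call_rate,
        )

    def test_identical_genets_identical_scores(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.5, size=(6, 40)).astype(float)
        d[1] = d[0]
        res = pca(self._matrix(d), n_components=3)
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_rank_one_matrix_explains_everything(self):
        # centered matrix is rank one: a single axis carries all variance
        d = 1.0 + np.outer([-0.5, 0.0, 0.5], [1.0, 0.8, 0.6, 0.4])
        res = pca(self._matrix(d), n_components=2, maf_subset=0.0,
                  call_rate_subset=0.0)
        assert res.var_explained[0] == pytest.approx(1.0)

    def test_scores_match_eigen_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(5, 4)).astype(float)
        res = pca(self._matrix(d), n_components=3, maf_subset=0.0,
                  call_rate_subset=0.0)
        xc = d - d.mean(axis=0)
        w, v = np.linalg.eigh(xc @ xc.T)
        order = np.argsort(w)[::-1]
        for j in range(3):
            score = res.scores[:, j]
            oracle = v[:, order[j]] * np.sqrt(max(w[order[j]], 0))
            assert min(np.abs(score - oracle).max(),
                       np.abs(score + oracle).max()) < 1e-8

    def test_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(12, 30)).astype(float)
        m = self._matrix(d)
        res = pca(m, n_components=2)
        perm = rng.permutation(12)
        m2 = self._matrix(d[perm])
        res2 = pca(m2, n_components=2)
        for j in range(2):
            a, b = res.scores[perm, j], res2.scores[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_var_explained_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.5, size=(20, 50)).astype(float)
        res = pca(self._matrix(d), n_components=5)
        ve = res.var_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert np.all((ve >= 0) & (ve <= 1)) and ve.sum() <= 1 + 1e-12

    def test_overlong_component_request_truncates(self):
        d = np.array([[0.0, 1], [1, 0], [2, 1]])
        with pytest.warns(UserWarning, match="truncating"):
            res = pca(self._matrix(d), n_components=10, maf_subset=0.0,
                      call_rate_subset=0.0)
        assert res.scores.shape[1] <= 2
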