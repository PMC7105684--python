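"""Cross-validation schemes, correlation CIs, PCA splits and model comparison."""

import numpy as np
import pandas as pd
import pytest

from gsblup import (
    EligibilityError,
    KinshipMatrix,
    PredictionResult,
    ValidationError,
    across_cycle,
    best_model,
    correlation_ci,
    leave_one_cycle_out,
    pca,
    pca_split,
    within_cycle_cv,
)
from gsblup.simulate import SimConfig, simulate_two_programs

from conftest import random_kinship


class TestCorrelationCi:
    def test_closed_form_r0_n103(self):
        lo, hi = correlation_ci(0.0, 103)
        assert lo == pytest.approx(-np.tanh(1.96 / 10), abs=1e-4)
        assert hi == pytest.approx(0.1935, abs=5e-4)

    def test_large_n_collapses_to_r(self):
        lo, hi = correlation_ci(0.5, 10_000_000)
        assert lo == pytest.approx(0.5, abs=1e-3)
        assert hi == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("r", [-0.9, -0.3, 0.0, 0.42, 0.99])
    @pytest.mark.parametrize("n", [4, 10, 500])
    def test_interval_contains_r(self, r, n):
        lo, hi = correlation_ci(r, n)
        assert -1 <= lo <= r <= hi <= 1

    def test_degenerate_at_unit_correlation(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert correlation_ci(1.0, 50) == (1.0, 1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            correlation_ci(0.5, 3)


def _structured_blups(n=60, seed=0, cycles=("C1", "C2"), k=None):
    """Phenotypes generated from a known kinship so GEBVs are informative."""
    rng = np.random.default_rng(seed)
    k = k or random_kinship(n * len(cycles), m=400, seed=seed)
    L = np.linalg.cholesky(k.values + 1e-8 * np.eye(k.n))
    g = L @ rng.normal(size=k.n)
    y = g + rng.normal(0, 0.5, k.n)
    cyc = np.repeat(list(cycles), n)
    df = pd.DataFrame({"genet_id": k.genet_ids, "cycle": cyc,
                       "trait": "t", "value": y})
    return df, k


class TestWithinCycleCv:
    def test_sanity_harness_interpolation_r_is_one(self):
        # with y in range(K) and training = all genets, the GEBVs reproduce
        # the centered phenotype exactly, so r(GEBV, y) = 1; held-out CV on
        # the same data stays high but below that ceiling
        from gsblup import fit_gblup

        rng = np.random.default_rng(5)
        k = random_kinship(50, m=400, seed=5)
        y = k.values @ rng.normal(size=50)
        df = pd.DataFrame({"genet_id": k.genet_ids, "cycle": "C1",
                           "trait": "t", "value": y})
        fit = fit_gblup(df, k)
        r_all = np.corrcoef(fit.gebv.loc[k.genet_ids], y)[0, 1]
        assert r_all == pytest.approx(1.0, abs=1e-6)
        res = within_cycle_cv(df, k, "t", "C1", reps=2, seed=1)
        assert 0.3 < res.r < r_all

    def test_determinism_under_seed(self):
        df, k = _structured_blups(seed=6)
        a = within_cycle_cv(df, k, "t", "C1", reps=3, seed=11)
        b = within_cycle_cv(df, k, "t", "C1", reps=3, seed=11)
        assert a.r == b.r and a.sd_over_reps == b.sd_over_reps

    def test_different_seeds_differ(self):
        df, k = _structured_blups(seed=7)
        a = within_cycle_cv(df, k, "t", "C1", reps=2, seed=1)
        b = within_cycle_cv(df, k, "t", "C1", reps=2, seed=2)
        assert a.r != b.r

    def test_too_few_genets(self):
        k = random_kinship(3, seed=8)
        df = pd.DataFrame({"genet_id": k.genet_ids, "cycle": "C1",
                           "trait": "t", "value": [1.0, 2, 3]})
        with pytest.raises(ValidationError, match="folds"):
            within_cycle_cv(df, k, "t", "C1")

    def test_fold_pooling_mode_runs(self):
        df, k = _structured_blups(seed=9)
        res = within_cycle_cv(df, k, "t", "C1", reps=2, seed=3,
                              pooling="fold")
        assert -1 <= res.r <= 1


class TestAcrossCycle:
    def test_self_prediction_routed_to_cv_and_flagged(self):
        df, k = _structured_blups(seed=10, n=110)
        out = across_cycle(df, k, "t", "C1", ["C1"], min_train=100)
        assert out[0].scheme == "within_cv"
        assert any("within-cycle CV" in f for f in out[0].flags)

    def test_disjoint_qtl_sets_r_near_zero(self):
        # one genotype space, but the two cycles' traits are driven by
        # disjoint marker sets: across-cycle CI should cover 0
        rng = np.random.default_rng(11)
        n, m = 120, 600
        dosage = rng.binomial(2, rng.uniform(0.1, 0.9, m),
                              size=(2 * n, m)).astype(float)
        p = dosage.mean(axis=0) / 2
        mc = dosage - 2 * p
        kv = mc @ mc.T / (2 * np.sum(p * (1 - p)))
        k = KinshipMatrix([f"g{i}" for i in range(2 * n)],
                          0.5 * (kv + kv.T), 1.0)
        beta1 = np.zeros(m)
        beta1[:50] = rng.normal(0, 1, 50)
        beta2 = np.zeros(m)
        beta2[50:100] = rng.normal(0, 1, 50)
        y = np.r_[mc[:n] @ beta1, mc[n:] @ beta2]
        df = pd.DataFrame({"genet_id": k.genet_ids,
                           "cycle": ["C1"] * n + ["C2"] * n,
                           "trait": "t", "value": y})
        res = across_cycle(df, k, "t", "C1", ["C2"], min_train=100)[0]
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_min_train_rule(self):
        df, k = _structured_blups(seed=13, n=40)
        with pytest.raises(EligibilityError, match="< 100"):
            across_cycle(df, k, "t", "C1", ["C2"], min_train=100)

    def test_missing_trait_cycle_skipped(self):
        df, k = _structured_blups(seed=14, n=110)
        out = across_cycle(df, k, "t", "C1", ["C9"], min_train=100)
        assert out == []


class TestLeaveOneCycleOut:
    def test_single_training_cycle_flagged_degenerate(self):
        df, k = _structured_blups(seed=15, n=110)
        res = leave_one_cycle_out(df, k, "t", "C2", min_train=100)
        assert res.scheme == "leave_one_out"
        assert any("degenerates" in f for f in res.flags)

    def test_training_union_below_floor_ineligible(self):
        df, k = _structured_blups(seed=16, n=30, cycles=("C1", "C2", "C3"))
        with pytest.raises(EligibilityError, match="< 100"):
            leave_one_cycle_out(df, k, "t", "C3", min_train=100)

    def test_multi_cycle_training_improves_or_matches(self):
        df, k = _structured_blups(seed=17, n=110, cycles=("C1", "C2", "C3"))
        res = leave_one_cycle_out(df, k, "t", "C3", min_train=100)
        assert res.n >= 3 and -1 <= res.r <= 1
        assert not res.flags  # two training cycles: not degenerate


class TestPcaSplit:
    def test_median_threshold_halves_population(self):
        rng = np.random.default_rng(18)
        from gsblup.markers import MarkerMatrix

        d = rng.binomial(2, rng.uniform(0.2, 0.8, 100), size=(21, 100)).astype(float)
        m = MarkerMatrix(genet_ids=[f"g{i}" for i in range(21)],
                         marker_ids=[f"m{j}" for j in range(100)],
                         dosage=d, allele_freq=d.mean(0) / 2,
                         call_rate=np.ones(100))
        res = pca(m, n_components=3)
        med = float(np.median(res.component(2)))
        low, high = pca_split(res, component=2, threshold=med)
        assert abs(len(low) - len(high)) <= 1

    def test_threshold_beyond_range_warns(self):
        rng = np.random.default_rng(19)
        from gsblup.markers import MarkerMatrix

        d = rng.binomial(2, 0.5, size=(10, 50)).astype(float)
        m = MarkerMatrix(genet_ids=[f"g{i}" for i in range(10)],
                         marker_ids=[f"m{j}" for j in range(50)],
                         dosage=d, allele_freq=d.mean(0) / 2,
                         call_rate=np.ones(50))
        res = pca(m, n_components=2)
        with pytest.warns(UserWarning, match="one side"):
            low, high = pca_split(res, component=1, threshold=1e9)
        assert high == []

    def test_split_recovers_program_labels(self):
        agree = []
        for s in range(3):
            pops, m = simulate_two_programs(
                SimConfig(seed=500 + s, n_cycles=2, genets_per_cycle=120,
                          n_markers=500, selection_fraction=0.1)
            )
            res = pca(m, n_components=2)
            labels = np.array(
                [p.startswith("UMN") for p in m.metadata["program"]]
            )
            best = 0.0
            for comp in (1, 2):
                s_ = res.component(comp)
                for thr_side in (s_ > np.median(s_), s_ <= np.median(s_)):
                    best = max(best, (thr_side == labels).mean())
            agree.append(best)
        assert np.median(agree) >= 0.9


class TestBestModel:
    def _res(self, r, lo, hi, label="cand"):
        return PredictionResult(trait="t", predict_cycle="C1",
                                train_label=label, scheme="across_cycle",
                                r=r, ci_low=lo, ci_high=hi, n=100)

    def test_non_overlapping_better_and_worse(self):
        ref = self._res(0.2, 0.1, 0.3, "ref")
        out = best_model([self._res(0.6, 0.5, 0.7), self._res(-0.1, -0.2, 0.0)],
                         ref)
        v = out.set_index("train_label")["vs_reference"]
        assert v["cand"].tolist() == ["better", "worse"] or set(
            out[out.train_label == "cand"]["vs_reference"]
        ) == {"better", "worse"}

    def test_overlap_is_indistinguishable(self):
        ref = self._res(0.6, 0.5, 0.7, "ref")
        out = best_model([self._res(0.4, 0.2, 0.6)], ref)
        assert (out.loc[out.train_label == "cand", "vs_reference"]
                == "indistinguishable").all()

    def test_identical_results_indistinguishable(self):
        ref = self._res(0.5, 0.4, 0.6, "ref")
        out = best_model([self._res(0.5, 0.4, 0.6)], ref)
        assert (out.loc[out.train_label == "cand", "vs_reference"]
                == "indistinguishable").all()

    def test_mismatched_target_rejected(self):
        ref = self._res(0.5, 0.4, 0.6, "ref")
        other = self._res(0.5, 0.4, 0.6)
        other.predict_cycle = "C9"
        with pytest.raises(ValidationError):
            best_model([other], ref)

    def test_sorted_best_first(self):
        ref = self._res(0.2, 0.1, 0.3, "ref")
        out = best_model([self._res(0.7, 0.6, 0.8, "a"),
                          self._res(0.4, 0.3, 0.5, "b")], ref)
        assert out.iloc[0]["train_label"] == "a"
        assert list(out["r"]) == sorted(out["r"], reverse=True)
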