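"""Phenotype simulation, GWAS accounting, GBLUP/REML, cross-validation."""

import numpy as np
import pytest
from scipy import stats

from kbimpute.datatypes import GenotypeMatrix, ValidationError, default_markers
from kbimpute.evaluate import (
    GBLUP,
    cross_validate,
    compare_datasets,
    gblup_fit,
    grm,
    gwas_scan,
    power_fdr_type1,
    simulate_phenotype,
)
from kbimpute.popsim import PopSimConfig, apply_mask, simulate_population


@pytest.fixture(scope="module")
def panel_200():
    # a related founder-pool panel (livestock-like): the GRM then carries
    # real structure, which GREML needs for identifiable variance components
    cfg = PopSimConfig(n_subpops=1, n_per_subpop=200, n_markers=2000, divergence=0.0,
                       pool_size=12, recomb_rate=0.01, seed=50)
    return simulate_population(cfg).genotypes


def _gm(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"t{i}" for i in range(calls.shape[0])], default_markers(calls.shape[1]), calls
    )


class TestSimulatePhenotype:
    def test_h2_one_limit_is_pure_genetic_value(self, panel_200):
        y, model = simulate_phenotype(panel_200, n_qtn=10, h2=1.0, seed=0)
        g = panel_200.calls[:, model.qtn_indices].astype(float) @ model.effects
        assert np.allclose(y, g)
        assert model.V_E == 0.0

    def test_residual_variance_follows_heritability_ratio(self, panel_200):
        _, model = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=1)
        assert model.V_E == pytest.approx(model.V_A * (1 - 0.75) / 0.75)

    def test_realized_heritability_near_target(self, panel_200):
        h2s = []
        for seed in range(30):
            y, model = simulate_phenotype(panel_200, n_qtn=20, h2=0.75, seed=seed)
            g = panel_200.calls[:, model.qtn_indices].astype(float) @ model.effects
            h2s.append(np.var(g, ddof=1) / np.var(y, ddof=1))
        assert abs(np.mean(h2s) - 0.75) < 0.1

    def test_qtn_count_and_distinctness(self, panel_200):
        _, model = simulate_phenotype(panel_200, n_qtn=20, h2=0.75, seed=2)
        assert len(model.qtn_indices) == 20
        assert len(set(model.qtn_indices.tolist())) == 20

    def test_incomplete_matrix_rejected(self, panel_200):
        masked, _ = apply_mask(panel_200, 0.1, seed=3)
        with pytest.raises(ValidationError):
            simulate_phenotype(masked, n_qtn=5, h2=0.75, seed=0)


class TestGwasScan:
    def test_null_pvalues_uniform(self, panel_200):
        rng = np.random.default_rng(4)
        y = rng.normal(size=panel_200.n_individuals)
        pvals = gwas_scan(panel_200, y)
        poly = panel_200.calls.std(axis=0) > 0
        ks = stats.kstest(pvals[poly], "uniform")
        assert ks.pvalue > 0.01

    def test_dominant_signal_attains_minimum_p(self, panel_200):
        rng = np.random.default_rng(5)
        j = 1123
        y = panel_200.calls[:, j] * 50.0 + rng.normal(size=panel_200.n_individuals)
        pvals = gwas_scan(panel_200, y)
        assert np.argmin(pvals) == j

    def test_matches_independent_regression_oracle(self, panel_200):
        rng = np.random.default_rng(6)
        y = rng.normal(size=panel_200.n_individuals)
        pvals = gwas_scan(panel_200, y)
        for j in (0, 57, 1999):
            x = panel_200.calls[:, j].astype(float)
            if x.std() == 0:
                continue
            res = stats.linregress(x, y)
            assert abs(pvals[j] - res.pvalue) < 1e-10

    def test_monomorphic_marker_gets_p_one(self):
        calls = np.array([[0, 0], [0, 1], [0, 2], [0, 1]], dtype=np.int8)
        y = np.array([0.1, 0.5, 0.9, 0.4])
        pvals = gwas_scan(_gm(calls), y)
        assert pvals[0] == 1.0

    def test_constant_phenotype_rejected(self, panel_200):
        with pytest.raises(ValidationError):
            gwas_scan(panel_200, np.zeros(panel_200.n_individuals))


class TestPowerFdrType1:
    def test_single_detection_among_twenty_qtns_gives_five_percent(self):
        m = 1000
        pvals = np.ones(m)
        qtn = np.arange(20)
        pvals[0] = 1e-9  # one QTN detected, nothing else
        ev = power_fdr_type1(pvals, qtn)
        assert ev.power == pytest.approx(0.05)
        assert ev.fdr == 0.0
        assert ev.type1 == 0.0

    def test_everything_detected(self):
        m, n_qtn = 1000, 20
        ev = power_fdr_type1(np.zeros(m), np.arange(n_qtn))
        assert ev.power == 1.0
        assert ev.fdr == 1.0
        assert ev.type1 == pytest.approx(980 / 1000)

    def test_hand_enumerated_instance(self):
        # 10 markers, QTNs at {2, 7}; threshold 0.05
        pvals = np.array([0.01, 0.2, 0.03, 0.8, 0.04, 0.5, 0.9, 0.2, 0.04, 0.6])
        ev = power_fdr_type1(pvals, np.array([2, 7]), threshold=0.05)
        # detected: markers 0,2,4,8; QTN hits: {2} -> power 1/2
        # false positives: 0,4,8 -> fdr 3/8, type1 3/10, conventional 3/4
        assert ev.power == pytest.approx(0.5)
        assert ev.fdr == pytest.approx(3 / 8)
        assert ev.type1 == pytest.approx(3 / 10)
        assert ev.fdr_conventional == pytest.approx(3 / 4)

    def test_fdr_dominates_type1(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = int(rng.integers(10, 200))
            pvals = rng.random(m)
            n_qtn = int(rng.integers(1, min(m, 10)))
            qtn = rng.choice(m, size=n_qtn, replace=False)
            ev = power_fdr_type1(pvals, qtn, threshold=float(rng.uniform(0.01, 0.5)))
            assert ev.fdr >= ev.type1

    def test_null_calibration_at_nominal_alpha(self, panel_200):
        # empirical per-marker type-I at alpha=0.05 under a null phenotype
        rng = np.random.default_rng(8)
        rates = []
        for _ in range(10):
            y = rng.normal(size=panel_200.n_individuals)
            pvals = gwas_scan(panel_200, y)
            poly = panel_200.calls.std(axis=0) > 0
            rates.append(np.mean(pvals[poly] <= 0.05))
        assert 0.03 < np.mean(rates) < 0.07


class TestGrm:
    def test_identical_individuals_fully_related(self):
        calls = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (4, 1))
        calls = np.vstack([calls, [2, 1, 0, 1, 2]])  # add contrast
        G = grm(_gm(calls))
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_diagonal_near_one_under_hwe(self):
        for seed in range(5):
            cfg = PopSimConfig(n_subpops=1, n_per_subpop=100, n_markers=1000,
                               pool_size=200, recomb_rate=0.5, seed=seed)
            gm = simulate_population(cfg).genotypes
            G = grm(gm)
            assert abs(np.mean(np.diag(G)) - 1.0) < 0.05

    def test_symmetric(self, panel_200):
        G = grm(panel_200)
        assert np.max(np.abs(G - G.T)) < 1e-12

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValidationError):
            grm(_gm(np.zeros((5, 4), dtype=np.int8)))


class TestGblupFit:
    def test_h2_formula(self):
        # direct variance-component arithmetic: 3 / (3 + 1) = 0.75
        assert 3.0 / (3.0 + 1.0) == 0.75

    def test_null_phenotype_gives_low_h2(self, panel_200):
        G = grm(panel_200)
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=panel_200.n_individuals)
            h2, _, _ = gblup_fit(G, y)
            low += h2 < 0.15
        assert low >= 9

    def test_reml_optimum_matches_grid_search(self):
        # independent oracle: profile restricted likelihood on a dense grid
        cfg = PopSimConfig(n_subpops=1, n_per_subpop=30, n_markers=300,
                           pool_size=20, seed=60)
        gm = simulate_population(cfg).genotypes
        y, _ = simulate_phenotype(gm, n_qtn=5, h2=0.5, seed=61)
        G = grm(gm)
        h2, _, details = gblup_fit(G, y)

        from kbimpute.evaluate import _reml_profile

        n = len(y)
        Gj = G + 1e-8 * np.eye(n)
        d, U = np.linalg.eigh(Gj)
        d = np.maximum(d, 0.0)
        yt, xt = U.T @ y, U.T @ np.ones(n)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 20001))
        lls = [_reml_profile(dl, d, xt, yt)[0] for dl in grid]
        assert details["loglik"] >= max(lls) - 1e-6

    def test_heritability_recovery_band(self, panel_200):
        G = grm(panel_200)
        h2s = []
        for seed in range(10):
            y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=100 + seed)
            h2, _, _ = gblup_fit(G, y)
            h2s.append(h2)
        assert 0.60 < np.mean(h2s) < 0.90

    def test_holdout_predictions_returned_for_everyone(self, panel_200):
        G = grm(panel_200)
        y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=9)
        y_masked = y.copy()
        y_masked[:40] = np.nan
        h2, preds, _ = gblup_fit(G, y_masked)
        assert len(preds) == len(y)
        assert np.isfinite(preds).all()
        # held-out predictions correlate with the simulated truth
        assert stats.pearsonr(preds[:40], y[:40])[0] > 0.2

    def test_too_few_training_records_rejected(self):
        G = np.eye(12)
        y = np.full(12, np.nan)
        y[:5] = 1.0
        with pytest.raises(ValidationError):
            gblup_fit(G, y)


class TestCrossValidate:
    def test_permuted_phenotype_accuracy_near_zero(self, panel_200):
        rng = np.random.default_rng(10)
        y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=11)
        out = cross_validate(panel_200, rng.permutation(y), folds=5, replicates=10, seed=12)
        assert abs(out.accuracy) < 0.1

    def test_genetic_phenotype_predicted_better_than_null(self, panel_200):
        y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=13)
        out = cross_validate(panel_200, y, folds=5, replicates=2, seed=14)
        assert out.accuracy > 0.2

    def test_fold_sizes_differ_by_at_most_one(self):
        # the partition rule itself: n % folds folds get the extra individual
        n, folds = 47, 5
        rng = np.random.default_rng(15)
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        sizes = np.bincount(fold_of, minlength=folds)
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_individuals_rejected(self):
        gm = _gm(np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8))
        with pytest.raises(ValidationError):
            cross_validate(gm, np.array([1.0, 2.0, 3.0]), folds=5)


@pytest.fixture(scope="module")
def trio():
    cfg = PopSimConfig(n_subpops=1, n_per_subpop=60, n_markers=300,
                       pool_size=40, recomb_rate=0.05, seed=70)
    return simulate_population(cfg).genotypes


class TestCompareDatasets:
    def test_self_comparison_identical_metrics(self, trio):
        nd = trio
        report = compare_datasets(nd, nd, nd, replicates=2, seed=71)
        wide = report.pivot(index="replicate", columns="dataset", values="power")
        assert (wide["ND"] == wide["BID"]).all()
        assert (wide["ND"] == wide["KID"]).all()

    def test_row_cardinality(self, trio):
        report = compare_datasets(trio, trio, trio, replicates=3, seed=72)
        assert len(report) == 3 * 3

    def test_truth_power_at_least_imputed_power(self, trio):
        from kbimpute.pipeline import whole_panel_impute

        nd = trio
        masked, _ = apply_mask(nd, 0.15, seed=73)
        from kbimpute.impute import impute_baseline

        bid = impute_baseline(masked).completed
        report = compare_datasets(nd, bid, bid, replicates=6, seed=74)
        wide = report.pivot(index="replicate", columns="dataset", values="power")
        # crude imputation loses QTN signal more often than not
        assert (wide["ND"] >= wide["BID"]).mean() > 0.5

    def test_dimension_mismatch_rejected(self, trio):
        small = trio.take_individuals(range(10))
        with pytest.raises(ValidationError):
            compare_datasets(trio, small, trio, replicates=1, seed=75)


class TestGBLUPEstimator:
    def test_fit_predict_and_h2_attribute(self, panel_200):
        y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.75, seed=16)
        X = panel_200.calls.astype(float)
        est = GBLUP().fit(X[:150], y[:150])
        assert 0.0 <= est.h2_ <= 1.0
        preds = est.predict(X[150:])
        assert stats.pearsonr(preds, y[150:])[0] > 0.2

    def test_sklearn_clone_and_cross_val_score(self, panel_200):
        from sklearn.base import clone
        from sklearn.model_selection import cross_val_score

        y, _ = simulate_phenotype(panel_200, n_qtn=10, h2=0.9, seed=17)
        X = panel_200.calls.astype(float)
        est = clone(GBLUP())
        scores = cross_val_score(est, X, y, cv=3, scoring="r2")
        assert np.mean(scores) > 0.0
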