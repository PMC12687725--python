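import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from oomethkit import cgi_model, synthetic_data as synth
from oomethkit.cgi_model import (
    CGILassoModel,
    bin_equal_count,
    differential_lasso,
    default_lambda_grid,
    kkt_violation,
    lasso_path_cv,
    nearest_gene,
    select_lambda_1se,
    split_by_mark,
    standardize,
    trinuc_freq,
)


class TestTrinuc:
    def test_overlap_counting_example(self):
        assert trinuc_freq("CCGCGG") == pytest.approx(2 * 100 / 6)

    def test_reverse_complement_invariance(self):
        assert trinuc_freq("AACCGTT") == pytest.approx(1 * 100 / 7)
        assert trinuc_freq("AACGGTT") == pytest.approx(trinuc_freq("AACCGTT"))

    def test_motif_free(self):
        assert trinuc_freq("AAAA") == 0.0

    def test_n_never_matches(self):
        assert trinuc_freq("CNGCCG") == pytest.approx(1 * 100 / 6)

    def test_short_sequence_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert trinuc_freq("CC") == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_reverse_complement_property_random(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert trinuc_freq(seq) == pytest.approx(trinuc_freq(rc))


class TestStandardize:
    def test_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(3, 7, size=(40, 3)), columns=list("abc"))
        ft = standardize(df)
        np.testing.assert_allclose(ft.x.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(ft.x.std(ddof=0), 1, atol=1e-12)

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        ft = standardize(df)
        assert ft.dropped == ["flat"]
        assert list(ft.x.columns) == ["a"]


class TestNearestGene:
    def test_matches_bruteforce_on_toy_layout(self):
        from oomethkit.core_io import CpGIsland, Gene

        genes = [Gene("chr1", s, s + 10_000, strand="+", id=f"g{i}",
                      exonic_length=5_000)
                 for i, s in enumerate((0, 50_000, 200_000))]
        cgis = [CpGIsland("chr1", s, s + 400, id=f"c{i}")
                for i, s in enumerate((4_000, 61_000, 140_000))]
        got = nearest_gene(cgis, genes)
        for c in cgis:
            dists = {g.id: abs(g.midpoint - c.midpoint) for g in genes}
            assert got[c.id] == min(dists, key=dists.get)


class TestFeatureTable:
    def test_assembly_standardization_and_gene_mapping(self, annotation):
        import pandas as pd

        cgi_ids = [c.id for c in annotation.cgis]
        rng = np.random.default_rng(0)
        marks = {
            "h3k4me3": pd.Series(rng.lognormal(0, 1, len(cgi_ids)), index=cgi_ids),
            "flat": pd.Series(1.0, index=cgi_ids),  # constant -> dropped
        }
        gene_ids = [g.id for g in annotation.genes]
        gb = {"h3k36me3": pd.Series(rng.lognormal(0, 1, len(gene_ids)),
                                    index=gene_ids)}
        expr = pd.Series(rng.lognormal(0, 1, len(gene_ids)), index=gene_ids)
        ft = cgi_model.build_feature_table(annotation, marks, gb, expr)
        assert "flat" in ft.dropped
        for col in ("h3k4me3", "ccg_cgg_per_100bp", "gb_h3k36me3",
                    "gb_expression"):
            assert col in ft.x.columns
        np.testing.assert_allclose(ft.x.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(ft.x.std(ddof=0), 1, atol=1e-9)

    def test_distant_cgis_dropped_with_gene_radius(self, annotation):
        import pandas as pd

        cgi_ids = [c.id for c in annotation.cgis]
        rng = np.random.default_rng(1)
        marks = {"m": pd.Series(rng.normal(size=len(cgi_ids)), index=cgi_ids)}
        gene_ids = [g.id for g in annotation.genes]
        expr = pd.Series(rng.lognormal(0, 1, len(gene_ids)), index=gene_ids)
        ft_all = cgi_model.build_feature_table(annotation, marks, expression=expr)
        ft_near = cgi_model.build_feature_table(annotation, marks, expression=expr,
                                                max_gene_distance=5_000)
        assert len(ft_near.x) <= len(ft_all.x)


class TestLambdaRule:
    def test_enumeration_example(self):
        lambdas = np.array([1.0, 0.5, 0.1, 0.05, 0.01])
        cv = np.array([1.0, 0.8, 0.5, 0.52, 0.6])
        se = np.array([0.08, 0.06, 0.05, 0.05, 0.07])
        lmin, l1se = select_lambda_1se(lambdas, cv, se)
        assert lmin == 0.1
        # largest lambda with error <= 0.55
        assert l1se == 0.1

    def test_1se_bound_holds(self):
        rng = np.random.default_rng(1)
        lambdas = np.sort(rng.uniform(0.001, 1, 30))[::-1]
        cv = rng.uniform(0.5, 1.5, 30)
        se = rng.uniform(0.01, 0.1, 30)
        lmin, l1se = select_lambda_1se(lambdas, cv, se)
        i_min = np.argmin(cv)
        i_1se = list(lambdas).index(l1se)
        assert cv[i_1se] <= cv[i_min] + se[i_min]
        assert l1se >= lmin


def _lasso_cd_oracle(x, y, lam, n_iter=5_000):
    """Plain coordinate descent for (1/2n)||y-b0-Xb||^2 + lam||b||_1."""
    n, p = x.shape
    b = np.zeros(p)
    b0 = y.mean()
    for _ in range(n_iter):
        b0 = (y - x @ b).mean()
        for j in range(p):
            r = y - b0 - x @ b + x[:, j] * b[j]
            rho = x[:, j] @ r / n
            z = (x[:, j] ** 2).mean()
            b[j] = np.sign(rho) * max(0.0, abs(rho) - lam) / z
    return b0, b


class TestLasso:
    @staticmethod
    def _xy(seed=0, n=120, p=5, beta=None, noise=0.1):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        ft = standardize(x)
        if beta is None:
            beta = np.zeros(p)
        y = ft.x.to_numpy() @ beta + rng.normal(0, noise, n)
        return ft, pd.Series(y, index=x.index)

    def test_single_true_predictor_selected(self):
        beta = np.array([1.0, 0, 0, 0, 0])
        ft, y = self._xy(seed=2, beta=beta, noise=0.0)
        fit = lasso_path_cv(ft, y, seed=0)
        nz = fit.nonzero()
        assert list(nz.index) == ["f0"]
        # brute-force best single-predictor OLS agrees on the choice
        best = max(
            range(5),
            key=lambda j: abs(np.corrcoef(ft.x.iloc[:, j], y)[0, 1]),
        )
        assert best == 0

    def test_large_lambda_shrinks_everything(self):
        ft, y = self._xy(seed=3, beta=np.array([0.5, -0.5, 0, 0, 0]))
        fit = lasso_path_cv(ft, y, grid=np.array([10.0, 20.0]), seed=0)
        assert (fit.coef == 0).all()
        assert fit.r_squared == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_kkt_conditions_vs_coordinate_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 6
        x = rng.normal(size=(n, p))
        x = (x - x.mean(0)) / x.std(0)
        y = x[:, 0] * 0.8 - x[:, 2] * 0.4 + rng.normal(0, 0.3, n)
        lam = 0.05
        from sklearn.linear_model import Lasso

        m = Lasso(alpha=lam, max_iter=50_000, tol=1e-10).fit(x, y)
        assert kkt_violation(x, y, m.intercept_, m.coef_, lam) < 1e-6
        b0o, bo = _lasso_cd_oracle(x, y, lam)
        np.testing.assert_allclose(m.coef_, bo, atol=1e-6)
        assert kkt_violation(x, y, b0o, bo, lam) < 1e-6

    def test_r2_invariant_to_affine_response_rescaling(self):
        ft, y = self._xy(seed=4, beta=np.array([0.7, 0.3, 0, 0, 0]), noise=0.3)
        f1 = lasso_path_cv(ft, y, seed=1)
        f2 = lasso_path_cv(ft, 10.0 * y + 3.0, seed=1,
                           grid=default_lambda_grid() * 10.0)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-6)

    def test_cv_curve_satisfies_1se_inequality(self):
        ft, y = self._xy(seed=5, beta=np.array([0.5, 0, 0, 0, 0]), noise=0.5)
        fit = lasso_path_cv(ft, y, seed=2)
        i_min = np.argmin(fit.cv_mean)
        i_sel = list(fit.lambdas).index(fit.lambda_1se)
        assert fit.cv_mean[i_sel] <= fit.cv_mean[i_min] + fit.cv_se[i_min]
        assert fit.lambda_1se >= fit.lambda_min


class TestDifferentialLasso:
    @staticmethod
    def _truths(annotation, noise_target=None, seed=3):
        params = synth.EffectParams(noise_sd=0.0)
        ctrl = synth.simulate_truth(annotation, "ctrl", params, seed=seed)
        mut = synth.simulate_truth(annotation, "aKO_bKO", params, seed=seed)
        cgis = ctrl.regions.query("kind == 'cgi'").index
        feats = ctrl.regions.loc[
            cgis, ["h3k4me3", "h3k36me3", "h2ak119u1", "h3k27me3"]
        ]
        return ctrl, mut, cgis, feats

    def test_identical_responses_give_no_differential_signal(self, annotation):
        ctrl, mut, cgis, feats = self._truths(annotation)
        y_wt = ctrl.regions.loc[cgis, "h3k36me2"]
        fit = differential_lasso(y_wt, standardize(feats), y_wt, seed=0)
        assert (fit.nonzero(exclude=("wt_level",)).abs() < 1e-8).all()

    def test_planted_gain_signs_recovered(self, annotation):
        """The planted mutant rule (gain ~ +H2AK119u1, gated by low
        H3K4me3) surfaces as a positive H2AK119u1 and negative H3K4me3
        coefficient."""
        ctrl, mut, cgis, feats = self._truths(annotation)
        y_wt = ctrl.regions.loc[cgis, "h3k36me2"]
        y_mut = mut.regions.loc[cgis, "h3k36me2"]
        fit = differential_lasso(y_mut, standardize(feats), y_wt, seed=0)
        nz = fit.nonzero(exclude=("wt_level",))
        assert nz["h2ak119u1"] > 0
        assert nz["h3k4me3"] < 0
        assert abs(nz["h2ak119u1"]) == nz.abs().max()

    def test_primary_and_residualization_modes_agree_on_top_predictors(
        self, annotation
    ):
        ctrl, mut, cgis, feats = self._truths(annotation)
        y_wt = ctrl.regions.loc[cgis, "h3k36me2"]
        y_mut = mut.regions.loc[cgis, "h3k36me2"]
        ft = standardize(feats)
        f1 = differential_lasso(y_mut, ft, y_wt, seed=0, mode="wt_as_predictor")
        f2 = differential_lasso(y_mut, ft, y_wt, seed=0, mode="residualize")
        top1 = set(f1.nonzero(exclude=("wt_level",)).index[:3])
        top2 = set(f2.nonzero().index[:3])
        assert len(top1 & top2) >= 2

    def test_constant_wt_falls_back_with_warning(self, annotation, caplog):
        ctrl, mut, cgis, feats = self._truths(annotation)
        y_mut = mut.regions.loc[cgis, "h3k36me2"]
        flat = pd.Series(1.0, index=cgis)
        with caplog.at_level("WARNING"):
            fit = differential_lasso(y_mut, standardize(feats), flat, seed=0)
        assert "wt_level" not in fit.coef.index


class TestBinning:
    def test_even_split_without_ties(self):
        labels = bin_equal_count(np.arange(10), n_bins=5)
        sizes = np.bincount(labels)
        assert (sizes == 2).all()

    def test_pigeonhole_sizes(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.linspace(0, 1, 10_023))
        sizes = np.bincount(bin_equal_count(x, 10))
        assert set(sizes) <= {1002, 1003}

    def test_ties_share_a_bin(self, caplog):
        with caplog.at_level("WARNING"):
            labels = bin_equal_count(np.ones(50), n_bins=10)
        assert len(np.unique(labels)) == 1

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            bin_equal_count([1, 2], 0)


class TestSplitByMark:
    def test_bimodal_split_matches_truth(self):
        rng = np.random.default_rng(1)
        low = rng.lognormal(np.log(0.5), 0.2, 300)
        high = rng.lognormal(np.log(8.0), 0.2, 200)
        labels = split_by_mark(np.concatenate([low, high]))
        assert (labels[:300] == "low").all()
        assert (labels[300:] == "high").all()

    def test_log_transform_stability(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.lognormal(0, 0.2, 100),
                            rng.lognormal(3, 0.2, 100)])
        a = split_by_mark(v, log=True)
        b = split_by_mark(np.log(v + 1e-6), log=False)
        assert (a == b).all()

    def test_constant_input_single_group(self, caplog):
        with caplog.at_level("WARNING"):
            labels = split_by_mark(np.full(10, 2.0))
        assert (labels == "low").all()


class TestModelFacade:
    def test_planted_r2_recovered_at_high_snr(self, annotation):
        params = synth.EffectParams(noise_sd=0.0)
        truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        reg = truth.regions.query("kind == 'cgi' and ~clamped")
        lin = reg["meth_frac"].to_numpy()
        noise_sd = np.sqrt(lin.var() * 0.25)  # planted R^2 = 0.8
        rng = np.random.default_rng(11)
        y = pd.Series(lin + rng.normal(0, noise_sd, len(lin)), index=reg.index)
        feats = reg[["h3k36me2", "h3k36me3", "h3k4me3", "h2ak119u1", "h3k27me3"]]
        fit = CGILassoModel.from_dataframe(feats, y).fit(seed=1)
        assert fit.r_squared == pytest.approx(0.8, abs=0.07)
        nz = fit.coef
        assert nz["h3k36me2"] > 0 and nz["h3k36me3"] > 0 and nz["h3k4me3"] < 0

    def test_correlation_audit_shape(self, annotation):
        params = synth.EffectParams()
        truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        reg = truth.regions.query("kind == 'cgi'")
        feats = reg[["h3k36me2", "h3k36me3", "h3k4me3"]]
        m = CGILassoModel.from_dataframe(feats, reg["meth_frac"])
        corr = m.predictor_correlations()
        assert corr.shape == (3, 3)
        np.testing.assert_allclose(np.diag(corr), 1.0)
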