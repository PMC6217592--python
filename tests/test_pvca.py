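import numpy as np
import pandas as pd
import pytest

from xplat.core import ExpressionMatrix, StudyDesign
from xplat.pvca import (
    _indicator,
    _neg2_restricted_loglik,
    fit_variance_components,
    pvca,
    sample_correlation_pca,
    select_k,
)


def ratio_matrix(design, values):
    treated = list(design.treated["sample_id"])
    return ExpressionMatrix([f"g{i}" for i in range(values.shape[0])], treated,
                            values, "log2ratio")


class TestSampleCorrelationPca:
    def test_eigenvalue_sum_equals_sample_count(self, design):
        rng = np.random.default_rng(0)
        m = ratio_matrix(design, rng.normal(0, 1, (500, 45)))
        eigvals, vecs = sample_correlation_pca(m)
        assert eigvals.sum() == pytest.approx(45, rel=1e-9)
        assert np.all(eigvals > -1e-10)
        assert np.all(np.diff(eigvals) <= 1e-12)

    def test_white_noise_spectrum_is_flat(self, design):
        rng = np.random.default_rng(1)
        m = ratio_matrix(design, rng.normal(0, 1, (20000, 45)))
        eigvals, _ = sample_correlation_pca(m)
        assert np.all(np.abs(eigvals - 1.0) < 0.35)

    def test_duplicated_sample_loads_leading_pc(self, design):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (300, 45))
        x[:, 1] = x[:, 0]  # two perfectly correlated samples
        eigvals, vecs = sample_correlation_pca(ratio_matrix(design, x))
        lead = np.abs(vecs[:, 0])
        assert {int(np.argsort(lead)[-1]), int(np.argsort(lead)[-2])} == {0, 1}

    def test_constant_sample_rejected(self, design):
        x = np.random.default_rng(3).normal(0, 1, (50, 45))
        x[:, 7] = 2.5
        with pytest.raises(ValueError, match="constant sample"):
            sample_correlation_pca(ratio_matrix(design, x))


class TestSelectK:
    @pytest.mark.parametrize("props,threshold,expected", [
        ([0.6, 0.4], 0.5876, 1),
        ([0.3, 0.3, 0.3, 0.1], 0.5876, 2),
        ([0.25, 0.25, 0.25, 0.25], 1.0, 4),
    ])
    def test_examples(self, props, threshold, expected):
        assert select_k(np.array(props), threshold) == expected

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            select_k(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            select_k(np.array([1.0]), 1.2)


class TestRemlVarianceComponents:
    def test_response_constant_within_chemicals(self, design):
        # all variance lies between chemicals: chemical component ~ total
        levels = design.factor("chemical", list(design.treated["sample_id"]))
        rng = np.random.default_rng(4)
        chem_effect = {c: rng.normal(0, 1) for c in levels.unique()}
        y = np.array([chem_effect[c] for c in levels])
        comps = fit_variance_components(y, design, ("chemical", "moa", "route"),
                                        list(design.treated["sample_id"]))
        assert comps["residual"] < 0.05 * y.var()
        explained = comps["chemical"] + comps["moa"] + comps["route"]
        assert explained > 0.8 * y.var()

    def test_iid_noise_attributed_to_residual(self, design):
        rng = np.random.default_rng(5)
        sample_ids = list(design.treated["sample_id"])
        resid, factors = [], []
        for _ in range(200):
            y = rng.normal(0, 1, 45)
            comps = fit_variance_components(y, design, ("chemical", "moa", "route"),
                                            sample_ids)
            resid.append(comps["residual"])
            factors.append(comps["chemical"] + comps["moa"] + comps["route"])
        # mean residual near sigma^2=1; factor components near zero on average
        assert abs(np.mean(resid) - 1.0) < 0.08
        assert np.mean(factors) < 0.15

    def test_single_factor_ratio_recovery(self, design):
        # sigma_u^2 / sigma_e^2 = 2 with 15 groups x 3 replicates
        rng = np.random.default_rng(6)
        sample_ids = list(design.treated["sample_id"])
        chem = design.factor("chemical", sample_ids)
        ratios = []
        for _ in range(200):
            effects = {c: rng.normal(0, np.sqrt(2.0)) for c in chem.unique()}
            y = np.array([effects[c] for c in chem]) + rng.normal(0, 1, 45)
            comps = fit_variance_components(y, design, ("chemical",), sample_ids)
            if comps["residual"] > 0:
                ratios.append(comps["chemical"] / comps["residual"])
        assert abs(np.median(ratios) - 2.0) < 0.5

    def test_statsmodels_never_beats_restricted_likelihood(self, design):
        """Independent mixed-model oracle: our optimizer's REML objective is
        at least as good as statsmodels MixedLM's on the same fits."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(7)
        sample_ids = list(design.treated["sample_id"])
        meta = design.treated.set_index("sample_id").loc[sample_ids]
        zzt = []
        for colname in ("chemical", "moa", "route_class"):
            z = _indicator(meta[colname])
            zzt.append(z @ z.T)
        for _ in range(5):
            y = rng.normal(0, 1, 45) + np.array(
                [hash(c) % 7 / 7 for c in meta["chemical"]])
            comps = fit_variance_components(y, design, ("chemical", "moa", "route"),
                                            sample_ids)
            scale = y.var()
            ys = (y - y.mean()) / np.sqrt(scale)
            mine = np.array([comps["chemical"], comps["moa"], comps["route"],
                             comps["residual"]]) / scale
            df = pd.DataFrame({"y": y, "chemical": meta["chemical"].values,
                               "moa": meta["moa"].values,
                               "route": meta["route_class"].values, "g": 1})
            md = smf.mixedlm("y ~ 1", df, groups="g", vc_formula={
                "chemical": "0 + C(chemical)", "moa": "0 + C(moa)",
                "route": "0 + C(route)"})
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = md.fit(reml=True, method="lbfgs")
            theirs = np.clip(np.array(list(fit.vcomp) + [fit.scale]) / scale,
                             1e-12, None)
            assert (_neg2_restricted_loglik(mine, zzt, ys)
                    <= _neg2_restricted_loglik(theirs, zzt, ys) + 1e-4)

    def test_too_few_levels_rejected(self, design):
        y = np.zeros(45)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_variance_components(y, design, ("is_control",),
                                    list(design.treated["sample_id"]))


class TestPvca:
    def test_proportions_sum_to_one_and_lie_in_unit_interval(self, design):
        rng = np.random.default_rng(8)
        m = ratio_matrix(design, rng.normal(0, 1, (400, 45)))
        res = pvca(m, design)
        vals = list(res.weighted_average_proportions.values())
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert set(res.weighted_average_proportions) == {"chemical", "moa", "route", "residual"}

    def test_pure_noise_attributed_to_residual(self, design):
        rng = np.random.default_rng(9)
        m = ratio_matrix(design, rng.normal(0, 1, (3000, 45)))
        res = pvca(m, design, threshold=1.0)
        assert res.weighted_average_proportions["residual"] >= 0.9

    def test_sample_permutation_invariance(self, design):
        rng = np.random.default_rng(10)
        m = ratio_matrix(design, rng.normal(0, 1, (300, 45)))
        res = pvca(m, design, threshold=1.0)
        perm = rng.permutation(45)
        m2 = ExpressionMatrix(list(m.gene_ids), [m.sample_ids[i] for i in perm],
                              m.values[:, perm], "log2ratio")
        res2 = pvca(m2, design, threshold=1.0)
        for key in res.weighted_average_proportions:
            assert res.weighted_average_proportions[key] == pytest.approx(
                res2.weighted_average_proportions[key], abs=1e-6)

    def test_recovery_tightens_with_more_genes(self, design):
        """MSE against the estimator's large-sample limit shrinks over a
        3-point gene-count sweep (the limit itself carries the method's
        attribution conventions, so it is the right convergence target)."""
        from xplat.preprocess import log2_ratio
        from xplat.simulate import default_truth, simulate_log2_dataset
        keys = ("moa", "chemical", "route", "residual")
        estimates = {}
        for n_genes in (100, 600, 3000):
            rows = []
            for seed in (0, 1, 2):
                t = default_truth(n_genes, seed=seed, de_fraction=0.0)
                ratio = log2_ratio(simulate_log2_dataset(n_genes, design, t), design)
                res = pvca(ratio, design, threshold=1.0)
                rows.append([res.weighted_average_proportions[k] for k in keys])
            estimates[n_genes] = np.array(rows)
        reference = estimates[3000].mean(axis=0)
        mses = [((estimates[n] - reference) ** 2).mean() for n in (100, 600, 3000)]
        assert mses[0] > mses[2] and mses[1] > mses[2]
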