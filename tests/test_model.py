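import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from pathdose import (
    GeneSet,
    GeneSetSim,
    SimulationSpec,
    adjust_pvalues,
    fit_candidate,
    fit_pathway,
    lrt_against_null,
    predict_curves,
    select_best,
    simulate_dataset,
    transform_dataset,
)
from pathdose.mixedlm import fit_weighted_lmm
from pathdose.splines import linear_basis


def _simulate(shape="linear", effect=2.0, sigma=0.3, n_genes=12, seed=0, **kw):
    spec = SimulationSpec(
        genesets=(GeneSetSim("s", n_genes, shape, effect),),
        sigma=sigma,
        seed=seed,
        **kw,
    )
    dataset, sets, truth = simulate_dataset(spec)
    return transform_dataset(dataset, use_log10=True), sets["s"], truth


class TestFitCandidate:
    def test_linear_slope_recovered(self):
        # Y = 2 + b0j + 1.5*D + noise on the natural dose scale
        rng = np.random.default_rng(42)
        doses = np.repeat(np.arange(6, dtype=float), 3)
        genes = [f"g{i}" for i in range(20)]
        b0 = rng.normal(0, 1, 20)
        Y = 2.0 + b0[:, None] + 1.5 * doses[None, :] + rng.normal(0, 0.3, (20, 18))
        from pathdose.preprocess import DoseScale, TransformedDataset

        samples = [f"S{i}" for i in range(18)]
        td = TransformedDataset(
            values=pd.DataFrame(Y, index=genes, columns=samples),
            doses=pd.Series(doses, index=samples),
            model_doses=doses,
            dose_scale=DoseScale("natural"),
            omics_type="log_intensity",
        )
        cand = fit_candidate(td, GeneSet("s", frozenset(genes)), "linear_mixed")
        beta1 = cand.fixed_dose_params[0]
        assert 1.3 < beta1 < 1.7

    def test_single_gene_set_rejected(self, linear_pathway):
        td, sets, _ = linear_pathway
        lone = GeneSet("one", frozenset([sets["lin"].intersect(td.features)[0]]))
        with pytest.raises(ValueError, match=">= 2"):
            fit_candidate(td, lone, "null")

    def test_uniform_weights_absorbed_by_profiled_variance(self):
        """A constant precision weight only rescales sigma^2: same fit."""
        rng = np.random.default_rng(3)
        D = np.repeat(np.linspace(0, 1, 6), 3)
        X = np.column_stack([np.ones(18), D])
        Y = 1 + rng.normal(0, 1, (6, 1)) + D[None, :] + rng.normal(0, 0.4, (6, 18))
        f1 = fit_weighted_lmm(Y, X, X)
        f2 = fit_weighted_lmm(Y, X, X, weights=np.full_like(Y, 2.0))
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-5)
        assert np.allclose(f1.beta, f2.beta, atol=1e-5)

    def test_nonuniform_weights_shift_the_fit(self):
        """Down-weighting half the observations moves the fixed effects."""
        rng = np.random.default_rng(3)
        D = np.repeat(np.linspace(0, 1, 6), 3)
        X = np.column_stack([np.ones(18), D])
        Y = 1 + rng.normal(0, 1, (6, 1)) + D[None, :] + rng.normal(0, 0.4, (6, 18))
        w = np.ones_like(Y)
        w[:, D > 0.5] = 0.05   # nearly ignore the high-dose half
        f1 = fit_weighted_lmm(Y, X, X)
        f2 = fit_weighted_lmm(Y, X, X, weights=w)
        assert abs(f1.beta[1] - f2.beta[1]) > 1e-3

    def test_nesting_loglik_ordering(self):
        td, gs, _ = _simulate(shape="bell", seed=5)
        fm = fit_pathway(td, gs)
        ll = {c.kind: c.log_likelihood for c in fm.all_candidates}
        tol = 1e-4
        assert ll["nonlinear_mixed"] >= ll["nonlinear_fixed"] - tol
        assert ll["nonlinear_fixed"] >= ll["null"] - tol
        assert ll["linear_mixed"] >= ll["null"] - tol

    def test_spline_restricted_to_linear_matches_linear(self):
        td, gs, _ = _simulate(shape="linear", seed=6)
        lin = fit_candidate(td, gs, "linear_mixed")
        restricted = fit_candidate(
            td, gs, "nonlinear_mixed", basis=linear_basis(td.model_doses)
        )
        assert restricted.log_likelihood == pytest.approx(
            lin.log_likelihood, abs=1e-4
        )


class TestLRT:
    def test_candidate_equal_to_null_gives_p_one(self, linear_pathway):
        td, sets, _ = linear_pathway
        null = fit_candidate(td, sets["flat"], "null")
        assert lrt_against_null(null_candidate(null), null) == pytest.approx(1.0)

    def test_chi2_quantile(self):
        # the 0.05 critical value of chi2(1) back through the survival function
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_mismatched_data_rejected(self, linear_pathway):
        td, sets, _ = linear_pathway
        null_lin = fit_candidate(td, sets["lin"], "null")
        cand_flat = fit_candidate(td, sets["flat"], "linear_mixed")
        with pytest.raises(ValueError, match="different data"):
            lrt_against_null(cand_flat, null_lin)

    def test_strong_effect_always_significant(self):
        # beta1 = 5 sigma: every seed rejects decisively
        for seed in range(50):
            td, gs, _ = _simulate(
                shape="linear", effect=1.5, sigma=0.3, n_genes=8, seed=seed,
                doses=tuple(10.0 ** np.linspace(-2, 1, 4)), reps_per_dose=3,
            )
            null = fit_candidate(td, gs, "null")
            lin = fit_candidate(td, gs, "linear_mixed")
            assert lrt_against_null(lin, null) < 0.001


def null_candidate(c):
    """A candidate structurally identical to the null (for the p=1 case)."""
    return c


class TestSelection:
    def test_only_passing_candidate_wins_regardless_of_aic(self, linear_pathway):
        td, sets, _ = linear_pathway
        fm = fit_pathway(td, sets["lin"])
        null = next(c for c in fm.all_candidates if c.kind == "null")
        lin = next(c for c in fm.all_candidates if c.kind == "linear_mixed")
        spl = next(c for c in fm.all_candidates if c.kind == "nonlinear_mixed")
        lin.lrt_p, spl.lrt_p = 0.01, 0.5   # only linear passes the gate
        best, _ = select_best([null, lin, spl], alpha=0.05)
        assert best.kind == "linear_mixed"

    def test_aic_tie_broken_toward_fewer_parameters(self, linear_pathway):
        td, sets, _ = linear_pathway
        fm = fit_pathway(td, sets["lin"])
        null = next(c for c in fm.all_candidates if c.kind == "null")
        lin = next(c for c in fm.all_candidates if c.kind == "linear_mixed")
        spl = next(c for c in fm.all_candidates if c.kind == "nonlinear_mixed")
        lin.lrt_p = spl.lrt_p = 0.001
        spl.fit.log_likelihood = (
            lin.log_likelihood + (spl.n_params - lin.n_params)
        )  # forces equal AIC
        best, _ = select_best([null, lin, spl], alpha=0.05)
        assert best.kind == "linear_mixed"

    def test_flat_pathway_selects_null(self, linear_pathway):
        td, sets, _ = linear_pathway
        fm = fit_pathway(td, sets["flat"])
        assert fm.best.kind == "null"
        assert not fm.significant_raw

    def test_missing_null_rejected(self, linear_pathway):
        td, sets, _ = linear_pathway
        lin = fit_candidate(td, sets["lin"], "linear_mixed")
        with pytest.raises(ValueError, match="null"):
            select_best([lin])


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        adj = adjust_pvalues([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = adjust_pvalues(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


class TestPredictCurves:
    def test_null_curve_is_flat_at_intercept(self, linear_pathway):
        td, sets, _ = linear_pathway
        null = fit_candidate(td, sets["flat"], "null")
        curve, gene_curves, _ = predict_curves(null, td)
        assert np.allclose(curve.response, null.beta0)
        assert len(curve.doses) == 200

    def test_linear_gene_curves_are_lines_with_own_slopes(self, linear_pathway):
        td, sets, _ = linear_pathway
        lin = fit_candidate(td, sets["lin"], "linear_mixed")
        _, gene_curves, _ = predict_curves(lin, td)
        G = gene_curves.to_numpy()
        x = gene_curves.columns.to_numpy(dtype=float)
        # each gene curve is exactly affine in dose
        slopes = (G[:, -1] - G[:, 0]) / (x[-1] - x[0])
        fitted_lines = G[:, [0]] + slopes[:, None] * (x - x[0])[None, :]
        assert np.allclose(G, fitted_lines, atol=1e-8)
        assert np.unique(np.round(slopes, 6)).size > 1

    def test_noiseless_linear_interpolated_exactly(self):
        td, gs, _ = _simulate(sigma=0.0, sd_gene_slope=0.0, seed=7)
        fm = fit_pathway(td, gs)
        assert fm.rmse < 1e-6

    def test_statsmodels_agrees_on_unweighted_fit(self):
        """Independent oracle: statsmodels MixedLM, same ML objective."""
        from statsmodels.regression.mixed_linear_model import (
            MixedLM,
            MixedLMParams,
        )

        rng = np.random.default_rng(11)
        J, n = 8, 15
        D = np.repeat(np.linspace(0, 1, 5), 3)
        Y = (
            1.0
            + rng.normal(0, 0.8, (J, 1))
            + (2.0 + rng.normal(0, 0.3, (J, 1))) * D[None, :]
            + rng.normal(0, 0.25, (J, n))
        )
        X = np.column_stack([np.ones(n), D])
        ours = fit_weighted_lmm(Y, X, X)
        m = MixedLM(
            Y.ravel(), np.tile(X, (J, 1)), np.repeat(np.arange(J), n),
            exog_re=np.tile(X, (J, 1)),
        )
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
        ref = m.fit(reml=False, free=free, method="lbfgs", maxiter=500)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-4)
        assert np.allclose(ours.beta, ref.fe_params, atol=1e-3)
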