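"""Penalized additive-model engine: design, fitting, inference, diagnostics."""

import shutil
import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from photogam.gam import (
    GamError,
    ModelSpec,
    SmoothTerm,
    build_design,
    check_basis_dimension,
    compare_models_aic,
    fit_gam,
    predict,
    term_tests,
)


def _spec(k=10, by="geno", re="assay_id", factors=("geno",)):
    return ModelSpec(
        parametric_factors=list(factors),
        smooth_terms=[SmoothTerm(var="time_s", k=k, by=by)],
        random_effect=re,
    )


def _toy_frame(n_t=60, genos=("WT", "HM"), assays=3, noise=0.4, seed=0,
               offsets=None):
    rng = np.random.default_rng(seed)
    offsets = offsets or {g: -1.0 * i for i, g in enumerate(genos)}
    rows = []
    for j in range(assays):
        aeff = rng.normal(0, 0.3)
        for g in genos:
            t = np.arange(n_t, dtype=float)
            y = 5 + offsets[g] + np.sin(t / 9) + aeff
            if noise:
                y = y + rng.normal(0, noise, n_t)
            rows.append(pd.DataFrame(
                {"assay_id": f"a{j}", "geno": g, "time_s": t, "rsums": y}))
    return pd.concat(rows, ignore_index=True)


class TestDesign:
    def test_by_smooth_block_dimensions(self):
        df = _toy_frame(genos=("WT", "HT", "HM"))
        des = build_design(_spec(k=10), df)
        smooth_blocks = [b for b in des.blocks if b.kind == "smooth"]
        assert len(smooth_blocks) == 3  # one per genotype
        assert all(b.size == 9 for b in smooth_blocks)  # k-1 after centering

    def test_k_below_three_rejected(self):
        with pytest.raises(GamError):
            SmoothTerm(var="time_s", k=2)

    def test_random_effect_block_is_indicator_with_identity_penalty(self):
        df = _toy_frame(assays=5)
        des = build_design(_spec(), df)
        re_block = [b for b in des.blocks if b.kind == "random"][0]
        assert re_block.size == 5
        assert np.array_equal(re_block.S, np.eye(5))
        cols = des.X[:, re_block.sl]
        assert np.array_equal(np.unique(cols), [0.0, 1.0])
        assert np.allclose(cols.sum(axis=1), 1.0)

    def test_by_factor_must_be_parametric(self):
        with pytest.raises(GamError):
            ModelSpec(parametric_factors=[],
                      smooth_terms=[SmoothTerm(by="geno")])

    def test_too_few_time_values_rejected(self):
        df = _toy_frame(n_t=8)
        with pytest.raises(GamError):
            build_design(_spec(k=10), df)

    def test_smooth_columns_sum_to_zero(self):
        df = _toy_frame()
        des = build_design(_spec(), df)
        for b in des.blocks:
            if b.kind == "smooth":
                assert np.allclose(des.X[:, b.sl].sum(axis=0), 0.0, atol=1e-8)


class TestFixedLambda:
    def test_matches_direct_generalized_ridge_solve(self):
        """Frozen-lambda fit equals the dense normal-equations solution."""
        rng = np.random.default_rng(10)
        for trial in range(5):
            df = _toy_frame(n_t=40, seed=trial)
            des = build_design(_spec(k=8), df)
            lam = rng.uniform(0.01, 100, size=len(des.penalized_blocks))
            fit = fit_gam(des, lambdas=lam)
            S = np.zeros((des.n_coef, des.n_coef))
            for l, b in zip(lam, des.penalized_blocks):
                S[b.sl, b.sl] += l * b.S
            beta_direct = np.linalg.solve(des.X.T @ des.X + S, des.X.T @ des.y)
            denom = np.linalg.norm(beta_direct)
            assert np.linalg.norm(fit.beta - beta_direct) / denom < 1e-8

    def test_lambda_count_checked(self):
        des = build_design(_spec(), _toy_frame())
        with pytest.raises(GamError):
            fit_gam(des, lambdas=[1.0])


class TestFitProperties:
    def test_constant_response_gives_null_fit(self):
        df = _toy_frame(noise=0.0)
        df["rsums"] = 3.25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gam(build_design(_spec(), df))
        # the second-order difference penalty leaves one unpenalized linear
        # direction per centered smooth, so the floor of each smooth's edf
        # is 1, not 0; the penalized part shrinks to nothing
        for b in fit.design.blocks:
            if b.kind == "smooth":
                assert fit.edf_by_term[b.name] <= 1.01
        assert fit.deviance_explained <= 1e-6
        assert np.allclose(fit.fitted, 3.25, atol=1e-6)

    def test_noiseless_smooth_recovered(self):
        df = _toy_frame(noise=0.0)
        fit = fit_gam(build_design(_spec(k=14), df))
        assert fit.deviance_explained >= 0.999

    def test_edf_additivity(self, small_fit):
        """Sum of term edfs equals the trace of the influence matrix."""
        des = small_fit.design
        lam = np.array([small_fit.lambdas[b.name] for b in des.penalized_blocks])
        S = np.zeros((des.n_coef, des.n_coef))
        for l, b in zip(lam, des.penalized_blocks):
            S[b.sl, b.sl] += l * b.S
        XtX = des.X.T @ des.X
        A = np.linalg.solve(XtX + S, XtX)
        assert small_fit.total_edf == pytest.approx(np.trace(A), abs=1e-6)

    def test_edf_monotone_in_lambda(self):
        df = _toy_frame()
        des = build_design(_spec(k=10), df)
        names = [b.name for b in des.penalized_blocks]
        smooth_name = names[0]
        edfs = []
        for lam in (1e-3, 1e-1, 1e1, 1e3, 1e5):
            vals = {n: 1.0 for n in names}
            vals[smooth_name] = lam
            fit = fit_gam(des, lambdas=vals)
            edfs.append(fit.edf_by_term[smooth_name])
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_gcv_selection_also_works(self):
        df = _toy_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gam(build_design(_spec(k=8), df), selection="GCV")
        assert 0.5 < fit.deviance_explained <= 1.0


class TestPredict:
    def test_prediction_at_observed_points_equals_fitted(self, toy_fit):
        des = toy_fit.design
        newdata = des.rows.copy()
        pred = predict(toy_fit, newdata, include_random=True)
        assert np.allclose(pred["mean"].to_numpy(), toy_fit.fitted, atol=1e-8)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"rsums": rng.normal(5, 1, 40)})
        spec = ModelSpec(parametric_factors=[], smooth_terms=[],
                         random_effect=None)
        fit = fit_gam(build_design(spec, df))
        pred = predict(fit, pd.DataFrame(index=[0]))
        y = df["rsums"].to_numpy()
        assert pred["mean"].iloc[0] == pytest.approx(y.mean())
        assert pred["se"].iloc[0] == pytest.approx(y.std(ddof=1) / np.sqrt(40))

    def test_se_matches_dense_delta_method(self, toy_fit):
        newdata = pd.DataFrame(
            {"geno": ["WT", "HM"], "time_s": [10.0, 30.0],
             "assay_id": ["a1", "a2"]}
        )
        from photogam.gam import build_prediction_matrix

        X = build_prediction_matrix(toy_fit, newdata)
        pred = predict(toy_fit, newdata)
        for i in range(len(newdata)):
            se = np.sqrt(X[i] @ toy_fit.V_beta @ X[i])
            assert pred["se"].iloc[i] == pytest.approx(se, rel=1e-10)

    def test_extrapolation_guard(self, toy_fit):
        newdata = pd.DataFrame(
            {"geno": ["WT"], "time_s": [1e6], "assay_id": ["a1"]}
        )
        with pytest.raises(GamError):
            predict(toy_fit, newdata)
        out = predict(toy_fit, newdata, allow_extrapolation=True)
        assert np.isfinite(out["mean"].iloc[0])


class TestTermTests:
    def test_injected_deficit_detected(self, toy_fit):
        tests = {t.term: t for t in term_tests(toy_fit)}
        assert tests["genoHM"].p_value < 1e-4
        assert tests["genoHM"].statistic < 0  # HM moves less

    def test_flat_by_level_smooth_not_significant(self):
        # WT follows a sine, HM is flat: HM's smooth should test weak
        rng = np.random.default_rng(21)
        rows = []
        for j in range(4):
            for g in ("WT", "HM"):
                t = np.arange(80, dtype=float)
                mu = 5 + (np.sin(t / 9) if g == "WT" else 0.0)
                rows.append(pd.DataFrame(
                    {"assay_id": f"a{j}", "geno": g, "time_s": t,
                     "rsums": mu + rng.normal(0, 0.5, 80)}))
        df = pd.concat(rows, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gam(build_design(_spec(k=10), df))
        tests = {t.term: t for t in term_tests(fit)}
        assert tests["s(time_s):genoWT"].p_value < 1e-6
        assert tests["s(time_s):genoHM"].p_value > 0.1


class TestBasisCheck:
    def test_white_noise_residuals_pass(self, toy_fit):
        checks = check_basis_dimension(toy_fit, n_shuffles=300,
                                       rng=np.random.default_rng(0))
        assert len(checks) == 2
        for c in checks:
            assert not c.flagged
            assert 0.5 < c.k_index < 2.0

    def test_undersized_basis_flagged(self):
        # fast oscillation with k=4: strong unmodeled trend in residuals
        rng = np.random.default_rng(5)
        t = np.arange(120, dtype=float)
        df = pd.DataFrame({
            "assay_id": "a1", "geno": "WT", "time_s": t,
            "rsums": 5 + 2 * np.sin(t / 2.5) + rng.normal(0, 0.3, 120),
        })
        spec = ModelSpec(parametric_factors=["geno"],
                         smooth_terms=[SmoothTerm(var="time_s", k=4, by=None)],
                         random_effect=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_gam(build_design(spec, df))
        checks = check_basis_dimension(fit, n_shuffles=300,
                                       rng=np.random.default_rng(1))
        assert checks[0].flagged
        assert checks[0].p_value < 0.05
        assert checks[0].k_index < 1.0

    def test_noiseless_fit_unflagged(self):
        df = _toy_frame(noise=0.0)
        fit = fit_gam(build_design(_spec(k=14), df))
        checks = check_basis_dimension(fit, n_shuffles=200,
                                       rng=np.random.default_rng(2))
        assert not any(c.flagged for c in checks)


class TestAic:
    def test_same_model_same_aic(self, toy_fit):
        table = compare_models_aic([toy_fit, toy_fit])
        assert table["aic"].iloc[0] == table["aic"].iloc[1]

    def test_true_model_beats_intercept_only(self):
        df = _toy_frame(noise=0.3)
        full = fit_gam(build_design(_spec(k=10), df))
        null_spec = ModelSpec(parametric_factors=[], smooth_terms=[],
                              random_effect=None)
        null = fit_gam(build_design(null_spec, df))
        table = compare_models_aic([null, full])
        assert table["aic"].iloc[0] < table["aic"].iloc[1]
        assert table["model"].iloc[0] != "(intercept)"

    def test_mismatched_data_rejected(self, toy_fit):
        df = _toy_frame(n_t=30)
        other = fit_gam(build_design(_spec(k=8), df))
        with pytest.raises(GamError):
            compare_models_aic([toy_fit, other])


R_SCRIPT = textwrap.dedent(
    """
    suppressMessages(library(mgcv))
    args <- commandArgs(trailingOnly=TRUE)
    X <- as.matrix(read.csv(args[1], header=FALSE)); dimnames(X) <- NULL
    y <- scan(args[2], quiet=TRUE)
    Ss <- list()
    i <- 0
    repeat {
      f <- sprintf("%s/S%d.csv", args[3], i)
      if (!file.exists(f)) break
      S <- as.matrix(read.csv(f, header=FALSE)); dimnames(S) <- NULL
      Ss[[length(Ss)+1]] <- (S + t(S)) / 2
      i <- i + 1
    }
    m <- gam(y ~ X - 1, paraPen=list(X=Ss), method="REML")
    out <- c(m$sp, sum(m$edf), m$sig2, coef(m)[1:3])
    cat(format(out, digits=12), sep="\\n")
    """
)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_reml_matches_mgcv_parapen(tmp_path):
    """Independent cross-check: mgcv REML on the identical design/penalties.

    The exact design matrix and penalty blocks are handed to mgcv via
    paraPen, so its REML smoothing parameters, edf, residual variance and
    coefficients must agree with this fitter's.
    """
    df = _toy_frame(n_t=60, seed=42)
    des = build_design(_spec(k=10), df)
    fit = fit_gam(des)

    np.savetxt(tmp_path / "X.csv", des.X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", des.y)
    for i, b in enumerate(des.penalized_blocks):
        S = np.zeros((des.n_coef, des.n_coef))
        S[b.sl, b.sl] = b.S
        np.savetxt(tmp_path / f"S{i}.csv", S, delimiter=",")
    script = tmp_path / "check.R"
    script.write_text(R_SCRIPT)
    res = subprocess.run(
        ["Rscript", str(script), str(tmp_path / "X.csv"),
         str(tmp_path / "y.csv"), str(tmp_path)],
        capture_output=True, text=True, timeout=300, check=True,
    )
    vals = [float(v) for v in res.stdout.split()]
    n_pen = len(des.penalized_blocks)
    sp_mgcv = np.array(vals[:n_pen])
    edf_mgcv, sig2_mgcv = vals[n_pen], vals[n_pen + 1]
    beta_mgcv = np.array(vals[n_pen + 2:n_pen + 5])

    sp_mine = np.array([fit.lambdas[b.name] for b in des.penalized_blocks])
    assert np.allclose(np.log(sp_mine), np.log(sp_mgcv), atol=0.05)
    assert fit.total_edf == pytest.approx(edf_mgcv, abs=0.02)
    assert fit.sigma2 == pytest.approx(sig2_mgcv, rel=1e-3)
    assert np.allclose(fit.beta[:3], beta_mgcv, rtol=1e-4, atol=1e-6)
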