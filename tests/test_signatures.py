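"""Elastic-net diet signatures, bootstrap CIs, enrichment, log fits.

The coordinate-descent fit is cross-checked against the glmnet reference
implementation (via Rscript) on a small fixture.
"""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import metaboflow as mf
from metaboflow.signatures import elastic_net_binomial, _standardize

from conftest import tiny_table


def small_fly_table(seed=0, n_ions=60, n_signal=8, effect=3.0):
    """20 fly samples, 2 diets, a block of elevated signal ions."""
    rng = np.random.default_rng(seed)
    diets = ["cherry"] * 10 + ["cranberry"] * 10
    areas = np.exp(np.log(5e4) + 0.4 * rng.standard_normal((n_ions, 20)))
    areas[:n_signal, :10] *= effect
    df = pd.DataFrame(areas, index=[f"M{100 + i}T{i}" for i in range(n_ions)],
                      columns=[f"s{i}" for i in range(20)])
    meta = pd.DataFrame({
        "sample_id": df.columns, "kind": "fly", "diet": diets,
        "generation": 1, "replicate": range(1, 21),
    })
    return mf.FeatureTable(areas=df, samples=meta)


class TestElasticNetFit:
    def test_full_shrinkage_at_huge_lambda(self):
        t = small_fly_table()
        m = mf.fit_diet_signature(t, "cherry", mf.SignatureParams(alpha=0.5, lam=50.0))
        assert m.n_selected == 0
        assert m.deviance_ratio == pytest.approx(0.0, abs=1e-3)

    def test_signal_ions_selected_on_separable_data(self):
        t = small_fly_table()
        m = mf.fit_diet_signature(t, "cherry", mf.SignatureParams(alpha=0.5, lam=0.01))
        signal = {f"M{100 + i}T{i}" for i in range(8)}
        assert signal <= set(m.selected_ions)
        assert m.deviance_ratio >= 0.98
        assert m.training_accuracy == 1.0

    def test_single_class_labels_raise(self):
        t = small_fly_table()
        with pytest.raises(ValueError, match="single-class"):
            mf.fit_diet_signature(t, "blackcurrant", mf.SignatureParams.large())

    def test_large_params_on_default_synthetic(self, default_pipeline):
        """The optimal-classification parameter set separates every diet
        with deviance ratio above 98% (the regime of the reference
        study) and perfect one-vs-rest classification."""
        models = mf.fit_all_diets(default_pipeline["fly_corrected"], mf.SignatureParams.large())
        for m in models.values():
            assert m.deviance_ratio >= 0.98
            assert m.training_accuracy == 1.0
            assert 0.0 <= m.deviance_ratio <= 1.0

    def test_compact_lists_shorter_than_large(self, default_pipeline):
        fly = default_pipeline["fly_corrected"]
        large = mf.fit_all_diets(fly, mf.SignatureParams.large())
        compact = mf.fit_all_diets(fly, mf.SignatureParams.compact())
        for d in large:
            assert compact[d].n_selected <= large[d].n_selected

    def test_selection_nested_along_lambda_path(self):
        t = small_fly_table()
        sets = {}
        for lam in (0.2, 0.05, 0.01):
            m = mf.fit_diet_signature(t, "cherry", mf.SignatureParams(alpha=0.5, lam=lam))
            sets[lam] = set(m.selected_ions)
        assert sets[0.2] <= sets[0.05] | sets[0.01]

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_matches_glmnet_reference(self, tmp_path):
        """Independent oracle: glmnet on the same standardized problem."""
        t = small_fly_table(seed=3)
        m = mf.fit_diet_signature(t, "cherry", mf.SignatureParams(alpha=0.5, lam=0.02))
        x_path, y_path, out = tmp_path / "X.csv", tmp_path / "y.csv", tmp_path / "out.csv"
        t.areas.T.to_csv(x_path, index=False)
        y = (t.samples["diet"] == "cherry").astype(int)
        y.to_csv(y_path, index=False)
        script = f"""
        suppressMessages(library(glmnet))
        X <- as.matrix(read.csv('{x_path}'))
        y <- read.csv('{y_path}')[[1]]
        fit <- glmnet(X, y, family='binomial', alpha=0.5, lambda=0.02,
                      standardize=TRUE, thresh=1e-11, maxit=1e7)
        co <- as.numeric(coef(fit))[-1]
        write.csv(data.frame(sel=which(co != 0) - 1, dev=fit$dev.ratio),
                  '{out}', row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        ref_sel = {t.areas.index[i] for i in ref["sel"]}
        assert set(m.selected_ions) == ref_sel
        assert m.deviance_ratio == pytest.approx(float(ref["dev"].iloc[0]), abs=1e-4)

    def test_solver_reduces_to_unpenalized_logit_limit(self):
        """At tiny lambda on a well-conditioned low-dimensional problem
        the fit approaches the maximum-likelihood logistic slope sign."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        logit = 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-logit))).astype(float)
        Xs, _ = _standardize(X)
        _, beta, conv = elastic_net_binomial(Xs, y, alpha=0.5, lam=1e-4)
        assert conv
        assert beta[0] > 0 and beta[1] < 0 and abs(beta[2]) < 0.3


class TestBootstrapCI:
    def test_constant_vector_zero_width(self):
        ci = mf.bootstrap_median_ci([5.0, 5.0, 5.0], seed=0)
        assert (ci.lower, ci.statistic, ci.upper) == (5.0, 5.0, 5.0)

    def test_endpoints_are_attainable_medians_n3(self):
        """Exhaustive oracle: all 3^3 resamples of a 3-vector."""
        values = [1.0, 4.0, 9.0]
        attainable = {
            float(np.median(pick))
            for pick in itertools.product(values, repeat=3)
        }
        ci = mf.bootstrap_median_ci(values, n_boot=2000, seed=1)
        assert ci.lower in attainable and ci.upper in attainable
        assert ci.lower <= ci.statistic <= ci.upper

    def test_same_seed_identical(self):
        a = mf.bootstrap_median_ci([1.0, 2.0, 3.0, 8.0], seed=7)
        b = mf.bootstrap_median_ci([1.0, 2.0, 3.0, 8.0], seed=7)
        assert a == b

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mf.bootstrap_median_ci([])


def manual_model(ions, diet="cherry"):
    return mf.SignatureModel(
        diet=diet,
        params=mf.SignatureParams(alpha=0.5, lam=0.01),
        coefficients=pd.Series(1.0, index=ions),
        intercept=0.0,
        deviance_ratio=1.0,
        fitted_prob=pd.Series(dtype=float),
        labels=pd.Series(dtype=int),
    )


def two_diet_tables(fly_areas, fruit_areas, ions):
    def build(areas, kind, gen):
        cols = {}
        diets = []
        for diet, block in areas.items():
            for r, col in enumerate(block, 1):
                cols[f"{kind[:2]}_{diet}_{r}"] = col
                diets.append(diet)
        df = pd.DataFrame(cols, index=ions)
        meta = pd.DataFrame({
            "sample_id": df.columns, "kind": kind, "diet": diets,
            "generation": gen, "replicate": range(1, len(diets) + 1),
        })
        return mf.FeatureTable(areas=df, samples=meta)

    return build(fly_areas, "fly", 1), build(fruit_areas, "fruit", None)


class TestEnrichment:
    def test_planted_enrichment_both_flags(self):
        rng = np.random.default_rng(0)
        ions = [f"M{100 + i}T{i}" for i in range(5)]
        hi = lambda: (10_000 * np.exp(0.05 * rng.standard_normal(5))).tolist()
        lo = lambda: (1_000 * np.exp(0.05 * rng.standard_normal(5))).tolist()
        fly, fruit = two_diet_tables(
            {"cherry": [hi() for _ in range(6)], "cranberry": [lo() for _ in range(6)]},
            {"cherry": [hi() for _ in range(3)], "cranberry": [lo() for _ in range(3)]},
            ions,
        )
        flags = mf.signature_enrichment(manual_model(ions), fly, fruit, seed=0)
        assert flags["fly_enriched"].all()
        assert flags["fruit_enriched"].all()

    def test_identical_groups_rarely_flagged(self):
        """Null calibration: with focal and alternate drawn from the same
        distribution, strict CI separation fires in at most 5% of ions."""
        rng = np.random.default_rng(1)
        n_ions = 1000
        ions = [f"M{100 + i}T{i}" for i in range(n_ions)]
        draw = lambda: np.exp(np.log(1e4) + 0.4 * rng.standard_normal(n_ions)).tolist()
        fly, fruit = two_diet_tables(
            {"cherry": [draw() for _ in range(6)], "cranberry": [draw() for _ in range(6)]},
            {"cherry": [draw() for _ in range(3)], "cranberry": [draw() for _ in range(3)]},
            ions,
        )
        flags = mf.signature_enrichment(manual_model(ions), fly, fruit, n_boot=1000, seed=2)
        assert flags["fly_enriched"].mean() <= 0.05

    def test_zero_variance_identical_groups_not_flagged(self):
        ions = ["M100T0", "M101T1"]
        col = [5000.0, 7000.0]
        fly, fruit = two_diet_tables(
            {"cherry": [col] * 3, "cranberry": [col] * 3},
            {"cherry": [col] * 3, "cranberry": [col] * 3},
            ions,
        )
        flags = mf.signature_enrichment(manual_model(ions), fly, fruit, seed=0)
        assert not flags["fly_enriched"].any()
        assert not flags["fruit_enriched"].any()


class TestLogFit:
    def test_proportional_means_give_r2_one_slope_one(self):
        rng = np.random.default_rng(2)
        ions = [f"M{100 + i}T{i}" for i in range(10)]
        base = rng.uniform(1e3, 1e6, 10)
        fly, fruit = two_diet_tables(
            {"cherry": [(3.0 * base).tolist()] * 3},
            {"cherry": [base.tolist()] * 3},
            ions,
        )
        fit = mf.fly_fruit_log_fit(manual_model(ions), fly, fruit)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)

    def test_pseudo_count_inert_without_zeros(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        ions = [f"M{100 + i}T{i}" for i in range(12)]
        fruit_m = rng.uniform(1e3, 1e6, 12)
        fly_m = rng.uniform(1e3, 1e6, 12)
        fly, fruit = two_diet_tables(
            {"cherry": [fly_m.tolist()] * 3}, {"cherry": [fruit_m.tolist()] * 3}, ions
        )
        fit = mf.fly_fruit_log_fit(manual_model(ions), fly, fruit)
        direct = stats.linregress(np.log10(fruit_m), np.log10(fly_m))
        assert fit.slope == pytest.approx(direct.slope)
        assert fit.r_squared == pytest.approx(direct.rvalue**2)

    def test_permuted_means_give_low_r2(self):
        """Independent permutation simulation: with fly means a random
        permutation of fruit means, R^2 stays below 0.1 almost always."""
        rng = np.random.default_rng(4)
        n_ions, n_draws = 100, 200
        ions = [f"M{100 + i}T{i}" for i in range(n_ions)]
        fruit_m = rng.uniform(1e3, 1e6, n_ions)
        low = 0
        for _ in range(n_draws):
            fly_m = rng.permutation(fruit_m)
            fly, fruit = two_diet_tables(
                {"cherry": [fly_m.tolist()]}, {"cherry": [fruit_m.tolist()]}, ions
            )
            fit = mf.fly_fruit_log_fit(manual_model(ions), fly, fruit)
            low += fit.r_squared < 0.1
        assert low / n_draws >= 0.95

    def test_too_few_positive_ions_raises(self):
        ions = ["M100T0", "M101T1", "M102T2"]
        fly, fruit = two_diet_tables(
            {"cherry": [[0.0, 0.0, 5.0]] * 3}, {"cherry": [[1.0, 2.0, 3.0]] * 3}, ions
        )
        with pytest.raises(ValueError, match=">= 3"):
            mf.fly_fruit_log_fit(manual_model(ions), fly, fruit)
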