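"""GOS-E dichotomy, design building, logistic fits, LR tests."""

import numpy as np
import pandas as pd
import pytest

from comorbidx import (
    MODEL_SPECS,
    ModelSpec,
    RecoveryModel,
    SeparationError,
    build_design,
    dichotomize_gose,
    fit_logistic,
    lr_test,
    prepare_analysis_table,
)


@pytest.mark.parametrize("gose,expected", [(8, True), (7, True), (6, False), (2, False)])
def test_dichotomize(gose, expected):
    assert dichotomize_gose(gose) is expected


@pytest.mark.parametrize("bad", [1, 0, 9, -3])
def test_dichotomize_rejects(bad):
    with pytest.raises(ValueError):
        dichotomize_gose(bad)


def _toy_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "injury_group": rng.choice(["a", "b", "c"], size=n, p=[0.5, 0.3, 0.2]),
            "age_group": rng.choice(["young", "mid", "old"], size=n),
            "head_injury": rng.integers(0, 2, n),
            "rib_fractures": rng.integers(0, 2, n),
            "organ_injury": rng.integers(0, 2, n),
            "burns": rng.integers(0, 2, n),
            "chapter_category": rng.choice(["0", "1", "2+"], size=n, p=[0.5, 0.3, 0.2]),
        }
    )
    return df


class TestBuildDesign:
    def test_injury_only_columns(self):
        df = _toy_frame()
        X, refs, dropped = build_design(df, ModelSpec("injury", include_age=False))
        # const + (3-1) injury dummies + 4 flags
        assert X.shape[1] == 1 + 2 + 4
        assert refs["injury_group"] == "a"  # most frequent level
        assert dropped == []

    def test_category_term_adds_two_dummies(self):
        df = _toy_frame()
        X0, _, _ = build_design(df, ModelSpec("injury_age"))
        X1, refs, _ = build_design(
            df, ModelSpec("m", comorbidity="chapter_count_category")
        )
        assert X1.shape[1] == X0.shape[1] + 2
        assert refs["chapter_category"] == "0"

    def test_ten_level_injury_dummy_count(self, small_cohort):
        data = prepare_analysis_table(small_cohort.patients, small_cohort.diagnoses)
        X, _, _ = build_design(data, ModelSpec("injury", include_age=False))
        # const + 9 injury dummies + 4 flags
        assert X.shape[1] == 14
        X2, _, _ = build_design(data, ModelSpec("injury_age"))
        assert X2.shape[1] == 14 + 7

    def test_unseen_level_at_prediction_errors(self):
        df = _toy_frame()
        X, refs, _ = build_design(df, ModelSpec("injury", include_age=False))
        new = df.copy()
        new.loc[0, "injury_group"] = "zzz"
        with pytest.raises(ValueError, match="unseen"):
            build_design(
                new, ModelSpec("injury", include_age=False),
                references=refs, columns=list(X.columns),
            )

    def test_constant_column_dropped_when_requested(self):
        df = _toy_frame()
        df["burns"] = 0
        X, _, dropped = build_design(
            df, ModelSpec("injury", include_age=False), drop_constant=True
        )
        assert dropped == ["burns"] and "burns" not in X.columns


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        X = pd.DataFrame({"const": np.ones(10)})
        fit = fit_logistic(X, y)
        p = y.mean()
        assert fit.params["const"] == pytest.approx(np.log(p / (1 - p)), abs=1e-6)
        assert fit.llf <= 0 and fit.converged

    def test_single_class_outcomes_error(self):
        X = pd.DataFrame({"const": np.ones(20)})
        with pytest.raises(SeparationError):
            fit_logistic(X, np.ones(20))

    def test_perfect_separation_names_column(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 100)
        X = pd.DataFrame({"const": 1.0, "sep": x.astype(float)})
        with pytest.raises(SeparationError):
            fit_logistic(X, x.astype(float))

    def test_rank_deficiency_error(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 60).astype(float)
        X = pd.DataFrame({"const": 1.0, "a": a, "b": 2 * a})
        y = (rng.random(60) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(X, y)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=500)})
        y = (rng.random(500) < 1 / (1 + np.exp(-X["x"]))).astype(float)
        fit = fit_logistic(X, y)
        c = fit.cov.to_numpy()
        assert np.allclose(c, c.T)
        assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_saturated_one_way_fit_equals_cell_means(self):
        # a saturated categorical design reproduces cell-wise outcome means
        rng = np.random.default_rng(4)
        lev = rng.choice(["a#x", "a#y", "b#x", "b#y"], size=800)
        df = pd.DataFrame(
            {
                "injury_group": lev,
                "head_injury": 0, "rib_fractures": 0, "organ_injury": 0, "burns": 0,
            }
        )
        p_map = {"a#x": 0.2, "a#y": 0.5, "b#x": 0.6, "b#y": 0.8}
        y = (rng.random(800) < pd.Series(lev).map(p_map).to_numpy()).astype(float)
        m = RecoveryModel(include_age=False).fit(df, y)
        fitted = m.predict_proba(df)[:, 1]
        for g in p_map:
            sel = lev == g
            assert fitted[sel][0] == pytest.approx(y[sel].mean(), abs=1e-6)
            assert np.allclose(fitted[sel], fitted[sel][0])


class TestLRTest:
    def test_identical_models(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=200)})
        y = (rng.random(200) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        stat, df, p = lr_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-9) and df == 0 and p == 1.0

    def test_df_is_parameter_difference(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=300), "b": rng.normal(size=300)})
        y = (rng.random(300) < 0.5).astype(float)
        nested = fit_logistic(X[["const"]], y)
        full = fit_logistic(X, y)
        stat, df, p = lr_test(nested, full)
        assert df == 2 and stat >= 0 and 0 <= p <= 1

    def test_non_nested_errors(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=100), "b": rng.normal(size=100)})
        y = (rng.random(100) < 0.5).astype(float)
        fa = fit_logistic(X[["const", "a"]], y)
        fb = fit_logistic(X[["const", "b"]], y)
        with pytest.raises(ValueError):
            lr_test(fa, fb)

    def test_invariant_to_reference_level(self):
        df = _toy_frame(600, seed=8)
        rng = np.random.default_rng(81)
        y = (rng.random(600) < 0.45).astype(float)
        stats = []
        for ref in ("a", "b"):
            Xn, _, _ = build_design(
                df, ModelSpec("injury", include_age=False),
                references={"injury_group": ref},
            )
            Xf, _, _ = build_design(
                df, ModelSpec("m", comorbidity="chapter_count_category"),
                references={"injury_group": ref, "chapter_category": "0"},
            )
            stats.append(lr_test(fit_logistic(Xn, y), fit_logistic(Xf, y))[0])
        assert stats[0] == pytest.approx(stats[1], rel=1e-6)


def test_nesting_monotonicity_across_specs(small_cohort):
    """More columns never lower the maximised log-likelihood."""
    data = prepare_analysis_table(small_cohort.patients, small_cohort.diagnoses)
    y = data["recovered"].to_numpy()
    fits = {
        s.name: RecoveryModel(
            comorbidity=s.comorbidity, include_age=s.include_age, name=s.name
        ).fit(data, y)
        for s in MODEL_SPECS
    }
    base = fits["injury"].llf_
    base_age = fits["injury_age"].llf_
    assert base_age >= base
    for name, f in fits.items():
        if name not in ("injury", "injury_age"):
            assert f.llf_ >= base_age


def test_recovery_model_sklearn_protocol(small_cohort):
    from sklearn.base import clone

    data = prepare_analysis_table(small_cohort.patients, small_cohort.diagnoses)
    y = data["recovered"].to_numpy()
    m = RecoveryModel(comorbidity="cci_category")
    m2 = clone(m)
    m2.fit(data, y)
    proba = m2.predict_proba(data)
    assert proba.shape == (len(data), 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert set(m2.predict(data)) <= {0, 1}
    assert m2.llf_ <= 0 and m2.n_obs_ == len(data)
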