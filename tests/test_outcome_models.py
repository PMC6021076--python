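"""t-tests, outcome correlations, matched-pair mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircluster.clustering import ClusterMap
from mircluster.factors import ClusterScores, cluster_scores
from mircluster.io_types import ExpressionMatrix, SampleMetadata
from mircluster.outcome_models import (
    fit_mixed_outcome,
    outcome_correlations,
    per_mirna_ttest,
    term_only_regression,
)


def _expr(data, mirnas=None):
    data = np.asarray(data, dtype=float)
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(data.shape[0])],
        mirna_ids=mirnas or [f"m{j}" for j in range(data.shape[1])],
        dct=data,
        missing=~np.isfinite(data),
    )


def _meta(n, ga=None, extra=None):
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": ["term", "PTB"] * (n // 2),
            "pair_id": [f"p{i // 2}" for i in range(n)],
            "gestational_age_birth": ga if ga is not None else [38.0, 35.0] * (n // 2),
            "birth_weight": 3000.0,
            "head_circumference": 33.0,
            "bmi": 25.0,
            "gravida": 2,
            "history_ptb": False,
            "fetal_sex": [0, 1] * (n // 2),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return SampleMetadata(df)


def _scores(values, clusters=("c14mc",)):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    return ClusterScores(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        cluster_names=list(clusters),
        scores=values,
        n_used=np.ones_like(values, dtype=int),
    )


class TestPerMirnaTtest:
    def test_identical_groups(self):
        data = np.tile([[1.0], [1.0]], (6, 1))
        out = per_mirna_ttest(_expr(data), _meta(12))
        row = out[out.mirna_id == "m0"].iloc[0]
        assert row.t == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_textbook_hand_case(self):
        # term (1,2,3) vs PTB (4,5,6): pooled t = -3.674, df 4
        data = np.array([[1.0], [4.0], [2.0], [5.0], [3.0], [6.0]])
        out = per_mirna_ttest(_expr(data), _meta(6))
        row = out[out.mirna_id == "m0"].iloc[0]
        assert abs(row.t) == pytest.approx(3.674, abs=1e-3)
        assert row.df == 4
        assert (row.mean_term, row.mean_ptb) == (2.0, 5.0)

    def test_shifted_mirnas_detected(self, rng):
        n, p = 42, 10
        data = rng.standard_normal((n, p)) * 0.3
        meta = _meta(n)
        ptb_rows = [i for i in range(n) if i % 2 == 1]
        data[ptb_rows, :3] += 2.0  # strong shift in first three miRNAs
        out = per_mirna_ttest(_expr(data), meta)
        hits = set(out[out.p < 0.05].mirna_id) - {"__total__"}
        assert {"m0", "m1", "m2"} <= hits

    def test_insufficient_data_row(self):
        data = np.full((6, 1), np.nan)
        data[0, 0] = 1.0
        out = per_mirna_ttest(_expr(data), _meta(6))
        row = out[out.mirna_id == "m0"].iloc[0]
        assert np.isnan(row.t) and row.note == "insufficient data"

    def test_welch_variant_differs(self, rng):
        data = np.concatenate(
            [rng.normal(0, 0.2, (21, 1)), rng.normal(1, 2.0, (21, 1))]
        )
        order = np.empty(42, dtype=int)
        order[::2] = np.arange(21)
        order[1::2] = 21 + np.arange(21)
        expr = _expr(data[order])
        meta = _meta(42)
        student = per_mirna_ttest(expr, meta).iloc[0]
        welch = per_mirna_ttest(expr, meta, variant="welch").iloc[0]
        assert student.df == 40
        assert welch.df < 40

    def test_matches_scipy_oracle_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12)) * 2
            data = rng.standard_normal((n, 1))
            out = per_mirna_ttest(_expr(data), _meta(n)).iloc[0]
            a = data[::2, 0]
            b = data[1::2, 0]
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert out.t == pytest.approx(ref.statistic, abs=1e-12)
            assert out.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestOutcomeCorrelations:
    def _cmap(self, p):
        return ClusterMap(
            clusters=[("c14mc", [f"m{j}" for j in range(p)])], unclustered=[]
        )

    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        expr = _expr(x[:, None])
        meta = _meta(10, ga=list(x))
        out = outcome_correlations(expr, meta, self._cmap(1))
        assert out.iloc[0]["r_gestational_age_birth"] == pytest.approx(1.0)
        assert out.iloc[0]["sig01_gestational_age_birth"]

    def test_matches_scipy_oracle(self, rng):
        x = rng.standard_normal(6)
        ga = rng.standard_normal(6)
        out = outcome_correlations(_expr(x[:, None]), _meta(6, ga=list(ga)), self._cmap(1))
        r_ref, p_ref = stats.pearsonr(x, ga)
        assert out.iloc[0]["r_gestational_age_birth"] == pytest.approx(r_ref, abs=1e-12)
        assert out.iloc[0]["p_gestational_age_birth"] == pytest.approx(p_ref, abs=1e-12)

    def test_constant_outcome_gives_na(self):
        expr = _expr(np.arange(6, dtype=float)[:, None])
        out = outcome_correlations(expr, _meta(6), self._cmap(1))
        assert np.isnan(out.iloc[0]["r_birth_weight"])

    def test_schema_one_row_per_mirna_with_cluster(self, rng):
        expr = _expr(rng.standard_normal((8, 4)))
        out = outcome_correlations(expr, _meta(8), self._cmap(4))
        assert list(out.mirna_id) == ["m0", "m1", "m2", "m3"]
        assert set(out.cluster) == {"c14mc"}
        assert {"q_gestational_age_birth", "sig05_birth_weight"} <= set(out.columns)


class TestMixedOutcome:
    def test_noiseless_linear_recovery(self, rng):
        n = 42
        score = rng.standard_normal(n)
        bmi = rng.normal(25, 4, n)
        ga = 30 + 2.0 * score + 0.1 * bmi
        meta = _meta(n, ga=list(ga), extra={"bmi": bmi})
        (res,) = fit_mixed_outcome(
            _scores(score), meta, "gestational_age_birth", cluster="c14mc"
        )
        assert res.estimate == pytest.approx(2.0, abs=1e-6)
        assert res.z == pytest.approx(res.estimate / res.std_err)
        assert res.ci95_low == pytest.approx(res.estimate - 1.96 * res.std_err)
        assert res.n_pairs == 21

    def test_balanced_zero_pair_variance_matches_ols(self, rng):
        import statsmodels.api as sm

        n = 42
        score = rng.standard_normal(n)
        ga = 37 + 0.8 * score + rng.normal(0, 1.0, n)
        meta = _meta(n, ga=list(ga))
        (res,) = fit_mixed_outcome(
            _scores(score), meta, "gestational_age_birth", cluster="c14mc"
        )
        # constant covariates are dropped by the model; mirror that here
        df = pd.DataFrame({"score": score, "fetal_sex": [0, 1] * 21})
        X = sm.add_constant(df[["score", "fetal_sex"]])
        ols = sm.OLS(ga, X.to_numpy(dtype=float)).fit()
        assert res.estimate == pytest.approx(float(ols.params[1]), abs=1e-4)

    def test_pair_effects_absorbed(self, rng):
        # strong pair-level intercepts: the mixed model should still
        # recover the within-pair slope
        n_pairs = 21
        pair_effect = rng.normal(0, 3.0, n_pairs)
        score = rng.standard_normal(2 * n_pairs)
        ga = np.repeat(pair_effect, 2) + 1.5 * score + rng.normal(0, 0.3, 2 * n_pairs)
        meta = _meta(2 * n_pairs, ga=list(ga + 37))
        (res,) = fit_mixed_outcome(
            _scores(score), meta, "gestational_age_birth", cluster="c14mc"
        )
        assert res.estimate == pytest.approx(1.5, abs=0.2)
        assert res.random_effect_var is None or res.random_effect_var >= 0

    def test_logistic_family_on_ptb_status(self, rng):
        n = 42
        score = rng.standard_normal(n)
        meta = _meta(n)
        (res,) = fit_mixed_outcome(
            _scores(score), meta, "ptb_status", cluster="c14mc", family="logistic"
        )
        assert res.family == "logistic"
        assert np.isfinite(res.estimate) and res.std_err > 0

    def test_separation_warns(self):
        n = 42
        # score perfectly separates PTB (odd rows) from term
        score = np.array([0.0, 10.0] * 21) + np.arange(n) * 1e-3
        meta = _meta(n)
        with pytest.warns(UserWarning, match="separat"):
            fit_mixed_outcome(
                _scores(score), meta, "ptb_status", cluster="c14mc", family="logistic"
            )


class TestTermOnlyRegression:
    def test_outcome_equal_to_covariate_r2_one(self, rng):
        n = 42
        score = rng.standard_normal(n)
        ga = rng.normal(38, 1, n)
        meta = _meta(n, ga=list(ga))
        meta.table["head_circumference"] = meta.table["gestational_age_birth"]
        summary = term_only_regression(_scores(score), meta, "c14mc")
        assert summary.r_squared == pytest.approx(1.0)

    def test_known_coefficients_recovered(self, rng):
        n = 84
        score = rng.standard_normal(n)
        ga = rng.normal(38, 1.2, n)
        bw = rng.normal(3000, 300, n)
        hc = 20 + 0.5 * score + 0.3 * ga + 0.001 * bw + rng.normal(0, 0.05, n)
        meta = _meta(n, ga=list(ga), extra={"birth_weight": bw})
        meta.table["head_circumference"] = hc
        summary = term_only_regression(_scores(score), meta, "c14mc")
        assert summary.coefficients.loc["score", "estimate"] == pytest.approx(
            0.5, abs=0.05
        )
        # score + GA + birth weight; every clinical covariate is constant
        # within the term subset and gets dropped
        assert summary.df_num == 3

    def test_report_tuple_schema(self, rng):
        n = 42
        meta = _meta(n, ga=list(rng.normal(38, 1, n)))
        meta.table["head_circumference"] = rng.normal(33, 1, n)
        s = term_only_regression(_scores(rng.standard_normal(n)), meta, "c14mc")
        text = s.format()
        assert "R^2" in text and "F(" in text and "p =" in text
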