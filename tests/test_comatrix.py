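"""Correlation matrices, the Jennrich test, and coefficient-set ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mircluster.clustering import ClusterMap
from mircluster.comatrix import (
    GroupCorrelation,
    compare_coefficient_sets,
    compare_groups,
    correlation_matrix,
    jennrich_test,
    nearest_positive_definite,
    submatrix_coefficients,
)
from mircluster.io_types import ExpressionMatrix, ValidationError


def _expr(data):
    data = np.asarray(data, dtype=float)
    return ExpressionMatrix(
        sample_ids=[f"s{i}" for i in range(data.shape[0])],
        mirna_ids=[f"m{j}" for j in range(data.shape[1])],
        dct=data,
        missing=~np.isfinite(data),
    )


def _cmap(groups):
    return ClusterMap(clusters=groups, unclustered=[])


def naive_pearson(x, y):
    """Two-pass textbook Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        x = np.arange(5, dtype=float)
        expr = _expr(np.column_stack([x, x, -x]))
        gc = correlation_matrix(expr, _cmap([("c", ["m0", "m1", "m2"])]), min_pairs=3)
        assert gc.R[0, 1] == pytest.approx(1.0)
        assert gc.R[0, 2] == pytest.approx(-1.0)

    def test_toy_vectors_match_naive_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        gc = correlation_matrix(
            _expr(np.column_stack([x, y])), _cmap([("c", ["m0", "m1"])]), min_pairs=3
        )
        assert gc.R[0, 1] == pytest.approx(naive_pearson(x, y), abs=1e-12)

    def test_agrees_with_naive_oracle_on_complete_data(self, rng):
        data = rng.standard_normal((20, 6))
        gc = correlation_matrix(
            _expr(data), _cmap([("c", [f"m{j}" for j in range(6)])]), min_pairs=3
        )
        for i in range(6):
            for j in range(i + 1, 6):
                assert gc.R[i, j] == pytest.approx(
                    naive_pearson(data[:, i], data[:, j]), abs=1e-12
                )

    def test_min_pairs_masks_sparse_entries(self):
        data = np.full((12, 2), np.nan)
        data[:12, 0] = np.arange(12)
        data[:5, 1] = [2, 1, 4, 3, 6]  # only 5 complete pairs
        gc = correlation_matrix(
            _expr(data), _cmap([("c", ["m0", "m1"])]), min_pairs=10
        )
        assert np.isnan(gc.R[0, 1])
        assert gc.n_pairs[0, 1] == 5

    def test_cluster_ordering(self, default_expression, default_cluster_map):
        gc = correlation_matrix(default_expression, default_cluster_map, min_pairs=5)
        clusters_seen = [gc.cluster_of[m] for m in gc.mirna_ids]
        # members are contiguous per cluster (cluster-ordered layout)
        boundaries = [
            i for i in range(1, len(clusters_seen))
            if clusters_seen[i] != clusters_seen[i - 1]
        ]
        assert len(boundaries) == len(set(clusters_seen)) - 1

    def test_empty_group_selector(self, default_expression, default_cluster_map):
        with pytest.raises(ValidationError):
            correlation_matrix(
                default_expression, default_cluster_map, group="nope", metadata=None
            )


class TestJennrich:
    def test_equal_matrices_give_zero(self, rng):
        for p in (2, 4, 7):
            A = rng.standard_normal((30, p))
            R = np.corrcoef(A, rowvar=False)
            res = jennrich_test(R, R.copy(), 21, 21)
            assert res.chi2 == pytest.approx(0.0, abs=1e-10)
            assert res.df == p * (p - 1) // 2
            assert res.p_value == pytest.approx(1.0)

    def test_equal_2x2_unequal_n(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        res = jennrich_test(R, R.copy(), 15, 40)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_symmetry_under_group_exchange(self, rng):
        for _ in range(5):
            A = rng.standard_normal((40, 4))
            B = rng.standard_normal((40, 4))
            R1 = np.corrcoef(A, rowvar=False)
            R2 = np.corrcoef(B, rowvar=False)
            a = jennrich_test(R1, R2, 25, 25)
            b = jennrich_test(R2, R1, 25, 25)
            assert a.chi2 == pytest.approx(b.chi2, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            jennrich_test(np.eye(3), np.eye(4), 10, 10)

    def test_distinct_matrices_give_positive_statistic(self):
        R1 = np.array([[1.0, 0.8], [0.8, 1.0]])
        R2 = np.array([[1.0, -0.3], [-0.3, 1.0]])
        res = jennrich_test(R1, R2, 21, 21)
        assert res.chi2 > 10
        assert res.p_value < 0.01

    def test_singular_input_repaired_and_flagged(self):
        R1 = np.ones((3, 3))  # rank 1
        R2 = np.eye(3)
        res = jennrich_test(R1, R2, 21, 21)
        assert res.pd_repaired

    def test_null_calibration_small(self, rng):
        # empirical mean of the statistic under the null ≈ df
        p, n, reps = 3, 80, 300
        chis = []
        for _ in range(reps):
            A = rng.standard_normal((n, p))
            B = rng.standard_normal((n, p))
            chis.append(
                jennrich_test(
                    np.corrcoef(A, rowvar=False), np.corrcoef(B, rowvar=False), n, n
                ).chi2
            )
        df = p * (p - 1) // 2
        assert np.mean(chis) == pytest.approx(df, rel=0.2)


def test_nearest_pd_is_pd_and_close(rng):
    R = np.corrcoef(rng.standard_normal((10, 6)), rowvar=False)
    R[0, 1] = R[1, 0] = 1.5  # corrupt
    fixed = nearest_positive_definite(R)
    assert np.linalg.eigvalsh(fixed).min() > 0
    assert np.allclose(np.diag(fixed), 1.0)


class TestSubmatrixCoefficients:
    def _gc(self, sizes):
        ids, cluster_of = [], {}
        for name, k in sizes.items():
            for i in range(k):
                mid = f"{name}_{i}"
                ids.append(mid)
                cluster_of[mid] = name
        p = len(ids)
        rng = np.random.default_rng(1)
        R = np.corrcoef(rng.standard_normal((p + 5, p)), rowvar=False)
        return GroupCorrelation(
            group="all",
            mirna_ids=ids,
            R=R,
            n_pairs=np.full((p, p), 20),
            n_nominal=20,
            cluster_of=cluster_of,
        )

    @pytest.mark.parametrize(
        "k,expected", [(2, 1), (5, 10), (15, 105), (8, 28)]
    )
    def test_within_counts(self, k, expected):
        gc = self._gc({"a": k, "b": 3})
        assert len(submatrix_coefficients(gc, "a")) == expected

    def test_between_counts(self):
        gc = self._gc({"a": 3, "b": 4})
        assert len(submatrix_coefficients(gc, "a", "b")) == 12

    def test_exhaustive_against_enumeration(self):
        # brute force: count unordered within pairs / ordered block cells
        for ka in range(2, 9):
            for kb in range(2, 9):
                gc = self._gc({"a": ka, "b": kb})
                within = len(submatrix_coefficients(gc, "a"))
                between = len(submatrix_coefficients(gc, "a", "b"))
                brute_within = len(
                    [(i, j) for i in range(ka) for j in range(i + 1, ka)]
                )
                assert within == brute_within == ka * (ka - 1) // 2
                assert between == ka * kb

    def test_values_match_matrix_entries(self):
        gc = self._gc({"a": 4, "b": 2})
        vals = submatrix_coefficients(gc, "a")
        expected = gc.R[:4, :4][np.triu_indices(4, 1)]
        assert np.array_equal(np.sort(vals), np.sort(expected))

    def test_unknown_region(self):
        gc = self._gc({"a": 3})
        with pytest.raises(ValidationError):
            submatrix_coefficients(gc, "zzz")


class TestCompareCoefficientSets:
    def test_identical_sets_F_zero(self):
        r = np.array([0.1, 0.2, 0.3])
        F, df1, df2, p, _ = compare_coefficient_sets(r, r.copy())
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_F_equals_t_squared_hand_case(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.4, 0.5, 0.6])
        F, df1, df2, p, (ma, mb) = compare_coefficient_sets(a, b)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t.statistic**2, abs=1e-12)
        assert p == pytest.approx(t.pvalue, abs=1e-12)
        assert (df1, df2) == (1, 4)
        assert (ma, mb) == (pytest.approx(0.2), pytest.approx(0.5))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=40),
        st.lists(st.floats(-0.99, 0.99), min_size=2, max_size=40),
    )
    def test_F_equals_t_squared_property(self, a, b):
        a, b = np.array(a), np.array(b)
        if np.allclose(np.concatenate([a, b]).var(), 0):
            return
        F, df1, df2, p, _ = compare_coefficient_sets(a, b)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t.statistic**2, rel=1e-9, abs=1e-9)
        assert df2 == len(a) + len(b) - 2

    def test_df2_for_45_coefficient_sets(self, rng):
        a = rng.uniform(-0.5, 0.9, 45)
        b = rng.uniform(-0.5, 0.9, 45)
        _, df1, df2, _, _ = compare_coefficient_sets(a, b)
        assert (df1, df2) == (1, 88)

    def test_zero_variance_reported_nan(self):
        F, _, _, p, _ = compare_coefficient_sets(
            np.array([0.5, 0.5]), np.array([0.5, 0.5])
        )
        assert np.isnan(F) and np.isnan(p)

    def test_fisher_z_transform_changes_scale_not_means(self):
        a = np.array([0.8, 0.85, 0.9])
        b = np.array([0.1, 0.15, 0.2])
        _, _, _, _, (ma, mb) = compare_coefficient_sets(a, b, transform="fisher_z")
        assert ma == pytest.approx(a.mean())
        assert mb == pytest.approx(b.mean())


class TestCompareGroups:
    def test_attenuated_ptb_within_cluster(
        self, default_cluster_map, default_cohort
    ):
        # generator truth: PTB c14mc loadings attenuated → lower within-r.
        # Checked on the latent −∆CT scale; the per-sample global-mean
        # centering can invert this contrast (see docs/methods.md).
        from conftest import raw_expression

        comp = compare_groups(
            raw_expression(default_cohort["truth"]),
            default_cluster_map,
            default_cohort["metadata"],
            ["c14mc", "c19mc", "miR-17/92"],
        )
        within_c14 = next(
            a for a in comp.anova_results
            if a.region_a == "c14mc" and a.region_b == "c14mc"
        )
        assert within_c14.mean_r_term > within_c14.mean_r_ptb

    def test_two_mirna_region_df(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((12, 2))
        import pandas as pd

        from mircluster.io_types import SampleMetadata

        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(12)],
                    "group": ["term", "PTB"] * 6,
                    "pair_id": [f"p{i // 2}" for i in range(12)],
                }
            )
        )
        comp = compare_groups(
            _expr(data),
            _cmap([("tiny", ["m0", "m1"])]),
            meta,
            ["tiny"],
            min_pairs=3,
            include_full_matrix_jennrich=False,
        )
        assert comp.jennrich[0].df == 1
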