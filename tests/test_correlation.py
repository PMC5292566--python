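"""Rank transform, partial Spearman (vs independent oracles), Fisher z."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sertnet.correlation import (
    batch_partial_spearman_matrices,
    correlation_matrix,
    fisher_z,
    partial_spearman,
    rank_transform,
)
from sertnet.errors import SertnetError, UndefinedCorrelationError
from sertnet.types import RegionSet

from conftest import make_cohort


def oracle_partial_spearman(x, y, cov) -> float:
    """Brute-force reference: ranks -> explicit normal equations -> Pearson.

    Kept deliberately independent of the implementation: ranks via argsort
    with explicit tie averaging, residualization via solving X'Xb = X'y.
    """

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    if cov is not None and np.size(cov):
        cov = np.atleast_2d(np.asarray(cov, float))
        if cov.shape[0] != len(rx):
            cov = cov.T
        design = np.column_stack(
            [np.ones(len(rx))] + [ranks(c) for c in cov.T]
        )
        beta_x = np.linalg.solve(design.T @ design, design.T @ rx)
        beta_y = np.linalg.solve(design.T @ design, design.T @ ry)
        rx = rx - design @ beta_x
        ry = ry - design @ beta_y
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestRankTransform:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 7], [1.5, 1.5, 3]),
            ([3, 1, 2, 2], [4, 1, 2.5, 2.5]),
        ],
    )
    def test_examples(self, x, expected):
        np.testing.assert_allclose(rank_transform(np.array(x)), expected)

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rank_sum_invariant(self, values):
        # sum of average-tie ranks is always n(n+1)/2
        assert rank_transform(np.array(values, float)).sum() == pytest.approx(21.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(SertnetError):
            rank_transform(np.array([1.0, np.inf, 2.0]))


class TestPartialSpearman:
    def test_perfect_monotone(self):
        assert partial_spearman(
            np.array([1, 2, 3, 4, 5]), np.array([2, 4, 6, 8, 10])
        ) == pytest.approx(1.0)
        assert partial_spearman(
            np.array([1, 2, 3, 4, 5]), np.array([5, 4, 3, 2, 1])
        ) == pytest.approx(-1.0)

    def test_one_covariate_example_matches_oracle(self):
        x = np.array([1, 2, 3, 4, 5, 6], float)
        y = np.array([6, 3, 5, 1, 4, 2], float)
        c = np.array([1, 1, 2, 2, 3, 3], float)
        assert partial_spearman(x, y, c) == pytest.approx(
            oracle_partial_spearman(x, y, c), abs=1e-10
        )

    @pytest.mark.parametrize("n,m,with_ties", [
        (8, 0, False), (12, 1, False), (19, 2, False),
        (10, 1, True), (25, 2, True), (40, 2, True),
    ])
    def test_random_datasets_match_oracle(self, n, m, with_ties):
        rng = np.random.default_rng(n * 100 + m * 10 + with_ties)
        for _ in range(25):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            cov = rng.normal(size=(n, m)) if m else None
            if with_ties:
                x = np.round(x * 2) / 2
                y = np.round(y * 2) / 2
                if cov is not None:
                    cov = np.round(cov)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            got = partial_spearman(x, y, cov)
            want = oracle_partial_spearman(x, y, cov)
            assert got == pytest.approx(want, abs=1e-10)

    def test_no_covariates_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert partial_spearman(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_matches_pingouin_partial_spearman(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        for _ in range(5):
            df = pd.DataFrame(
                rng.normal(size=(20, 4)), columns=["x", "y", "c1", "c2"]
            )
            got = partial_spearman(
                df.x.values, df.y.values, df[["c1", "c2"]].values
            )
            want = pingouin.partial_corr(
                df, x="x", y="y", covar=["c1", "c2"], method="spearman"
            )["r"].iloc[0]
            assert got == pytest.approx(float(want), abs=1e-8)

    def test_recursion_formula_one_covariate_no_ties(self):
        # residualization equals the first-order partial-correlation
        # recursion on simple Spearman rhos when no ties are present
        rng = np.random.default_rng(3)
        x, y, c = rng.normal(size=(3, 24))
        r_xy = partial_spearman(x, y)
        r_xc = partial_spearman(x, c)
        r_yc = partial_spearman(y, c)
        expected = (r_xy - r_xc * r_yc) / np.sqrt(
            (1 - r_xc**2) * (1 - r_yc**2)
        )
        assert partial_spearman(x, y, c) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 15))
        cov = rng.normal(size=(15, 1))
        base = partial_spearman(x, y, cov)
        assert partial_spearman(y, x, cov) == pytest.approx(base, abs=1e-12)
        # strictly monotone transforms leave ranks unchanged
        assert partial_spearman(np.exp(x), y**3, cov) == pytest.approx(
            base, abs=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(np.ones(10), np.arange(10.0))

    def test_too_few_subjects_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(UndefinedCorrelationError):
            partial_spearman(x, x[::-1], np.ones((5, 2)))


class TestCorrelationMatrix:
    def test_equals_entrywise_partial_spearman(self, small_regions):
        cohort = make_cohort(small_regions, n=12, seed=2)
        cm = correlation_matrix(cohort, ("age", "gender"))
        cov = cohort.covariate_matrix(("age", "gender"))
        bp = cohort.bp_matrix
        for i in range(4):
            for j in range(i + 1, 4):
                assert cm.rho[i, j] == pytest.approx(
                    partial_spearman(bp[:, i], bp[:, j], cov), abs=1e-12
                )

    def test_duplicated_region_gives_unit_correlation(self, small_regions):
        cohort = make_cohort(small_regions, n=10, seed=4)
        for r in cohort.records:
            r.bp[1] = r.bp[0]
        cm = correlation_matrix(cohort, ())
        assert cm.rho[0, 1] == pytest.approx(1.0)

    def test_invariants_over_random_cohorts(self, small_regions):
        for seed in range(30):
            cohort = make_cohort(small_regions, n=10, seed=seed)
            cm = correlation_matrix(cohort, ("age",))
            cm.validate()  # symmetric, unit diagonal, entries in [-1, 1]

    def test_batch_path_agrees_with_scalar_path(self, small_regions):
        cohort = make_cohort(small_regions, n=14, seed=8)
        cov = cohort.covariate_matrix(("age", "gender"))
        rho_batch, degenerate = batch_partial_spearman_matrices(
            cohort.bp_matrix[None], cov
        )
        cm = correlation_matrix(cohort, ("age", "gender"))
        assert not degenerate[0]
        np.testing.assert_allclose(rho_batch[0], cm.rho, atol=1e-12)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_endpoint_clamped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))
        assert 8 < z < 9

    @given(st.floats(min_value=-1, max_value=1, allow_nan=False))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_odd_and_monotone(self, r):
        assert fisher_z(-r) == -fisher_z(r)
        eps = 1e-3
        if r + eps <= 1:
            assert fisher_z(r + eps) > fisher_z(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(SertnetError):
            fisher_z(1.2)
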