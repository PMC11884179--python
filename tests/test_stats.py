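"""Permutation inference, FDR, demographic tests, dispersion summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from fwdmri.stats import (
    PermutationPlan,
    StatResult,
    apply_family_fdr,
    bh_fdr,
    chi_square_counts,
    dispersion_summary,
    permutation_ancova,
    permutation_partial_correlation,
    quadratic_age_model,
    trait_correlation,
    ttest_from_summary,
)


def _toy_table(n=40, seed=0, effect=0.0, slope=0.0):
    rng = np.random.default_rng(seed)
    group = np.array(["ASD", "NT"] * (n // 2))
    age = rng.uniform(30, 73, n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    y = rng.normal(0, 1, n) + effect * (group == "NT") + slope * age
    return pd.DataFrame(
        {"group": group, "age_years": age, "sex": sex, "y": y}
    )


class TestDemographicTests:
    """Pooled t and Pearson chi-square on summary data."""

    @pytest.mark.parametrize(
        "summary,expected",
        [
            ((47.21, 10.86, 43, 49.79, 12.01, 43), -1.05),   # age
            ((107.44, 13.71, 43, 107.87, 11.02, 43), -0.16),  # full-scale IQ
            ((1555.34, 161.11, 43, 1515.17, 146.34, 43), 1.21),  # brain volume
            ((1.13, 1.03, 43, 0.75, 0.50, 43), 2.17),        # head motion
        ],
    )
    def test_pooled_t_reproduces_matched_cohort_rows(self, summary, expected):
        t, _ = ttest_from_summary(*summary)
        assert t == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[25, 18], [23, 20]], 0.19),       # sex M/F
            ([[39, 3, 1], [39, 4, 0]], 1.14),   # handedness R/L/B
        ],
    )
    def test_chi_square_reproduces_matched_cohort_rows(self, counts, expected):
        chi2, _ = chi_square_counts(counts)
        assert chi2 == pytest.approx(expected, abs=0.01)

    def test_identical_summaries_give_zero_t(self):
        t, p = ttest_from_summary(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert t == 0.0 and p == 1.0

    def test_equal_rows_give_zero_chi2(self):
        chi2, _ = chi_square_counts([[10, 5], [10, 5]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.0, 10, 1.0, 0.0, 10)
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [1, 2]])


class TestPartialCorrelation:
    def test_hand_residualized_eight_row_table(self):
        """partial r equals the correlation of explicit OLS residuals."""
        df = pd.DataFrame(
            {
                "group": ["NT"] * 8,
                "age_years": [31.0, 35.0, 42.0, 47.0, 55.0, 60.0, 66.0, 71.0],
                "sex": ["M", "F", "M", "F", "M", "F", "M", "F"],
                "y": [0.12, 0.09, 0.16, 0.13, 0.22, 0.17, 0.25, 0.21],
            }
        )
        res = permutation_partial_correlation(
            df, "y", PermutationPlan(n_permutations=0, seed=0)
        )
        Z = np.column_stack([np.ones(8), (df["sex"] == "M").astype(float)])
        ry = df["y"] - Z @ np.linalg.lstsq(Z, df["y"], rcond=None)[0]
        rx = df["age_years"] - Z @ np.linalg.lstsq(Z, df["age_years"], rcond=None)[0]
        r_hand = float(ry @ rx / np.sqrt((ry @ ry) * (rx @ rx)))
        assert res.statistic == pytest.approx(r_hand, abs=1e-12)
        beta_hand = float(ry @ rx / (rx @ rx))
        assert res.beta == pytest.approx(beta_hand, abs=1e-12)
        assert res.r2 == pytest.approx(r_hand**2, abs=1e-12)

    def test_perfect_linear_dependence(self):
        df = _toy_table(n=20, seed=1)
        df["y"] = 2.0 * df["age_years"]
        res = permutation_partial_correlation(
            df, "y", PermutationPlan(n_permutations=100, seed=0)
        )
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.beta == pytest.approx(2.0, abs=1e-9)

    def test_zero_variance_response_flagged(self):
        df = _toy_table(n=20, seed=2)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="zero residual variance"):
            permutation_partial_correlation(df, "y", PermutationPlan(100, 0))

    def test_strong_effect_hits_permutation_floor(self):
        df = _toy_table(n=60, seed=3)
        df["y"] = df["age_years"] * 0.1 + np.random.default_rng(0).normal(0, 0.01, 60)
        plan = PermutationPlan(n_permutations=500, seed=1)
        res = permutation_partial_correlation(df, "y", plan)
        assert res.p_perm == pytest.approx(1 / 501)

    def test_seeded_streams_reproducible(self):
        df = _toy_table(n=30, seed=4, slope=0.01)
        plan = PermutationPlan(n_permutations=200, seed=9)
        a = permutation_partial_correlation(df, "y", plan)
        b = permutation_partial_correlation(df, "y", plan)
        assert a.p_perm == b.p_perm


class TestAncova:
    def test_zero_permutations_reduce_to_parametric_t(self):
        df = _toy_table(n=50, seed=5, effect=0.8)
        res = permutation_ancova(df, "y", PermutationPlan(n_permutations=0))
        X = pd.DataFrame(
            {
                "const": 1.0,
                "age": df["age_years"],
                "sex": (df["sex"] == "M").astype(float),
                "group": (df["group"] == "NT").astype(float),
            }
        )
        ols = sm.OLS(df["y"], X).fit()
        assert res.statistic == pytest.approx(ols.tvalues["group"], abs=1e-10)
        assert res.beta == pytest.approx(ols.params["group"], abs=1e-10)

    def test_strong_effect_hits_permutation_floor(self):
        df = _toy_table(n=60, seed=6, effect=5.0)
        res = permutation_ancova(df, "y", PermutationPlan(n_permutations=500, seed=0))
        assert res.p_perm == pytest.approx(1 / 501)

    def test_single_group_rejected(self):
        df = _toy_table(n=20, seed=7)
        df["group"] = "NT"
        with pytest.raises(ValueError, match="two groups"):
            permutation_ancova(df, "y", PermutationPlan(100, 0))

    def test_null_calibration(self):
        """Type-I error near nominal 5% on independent null variables."""
        rng = np.random.default_rng(42)
        n, n_vars = 60, 400
        base = _toy_table(n=n, seed=8)
        plan_n = 199
        rejections = 0
        for j in range(n_vars):
            df = base.copy()
            df["y"] = rng.normal(0, 1, n)
            res = permutation_ancova(
                df, "y", PermutationPlan(n_permutations=plan_n, seed=j)
            )
            rejections += res.p_perm < 0.05
        assert 0.02 <= rejections / n_vars <= 0.09


class TestQuadraticModel:
    def test_quadratic_signal_detected(self):
        df = _toy_table(n=60, seed=9)
        rng = np.random.default_rng(1)
        age_c = df["age_years"] - df["age_years"].mean()
        df["y"] = 0.01 * age_c**2 + rng.normal(0, 0.1, 60)
        res = quadratic_age_model(df, "y", PermutationPlan(500, 3))
        assert res.p_perm < 0.01

    def test_linear_signal_null_calibrated(self):
        base = _toy_table(n=50, seed=10)
        rng = np.random.default_rng(2)
        rejections = 0
        n_sims = 300
        for j in range(n_sims):
            df = base.copy()
            df["y"] = 0.01 * df["age_years"] + rng.normal(0, 0.1, 50)
            res = quadratic_age_model(df, "y", PermutationPlan(99, seed=j))
            rejections += res.p_perm < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_constant_response_not_rejected(self):
        df = _toy_table(n=30, seed=11)
        df["y"] = 5.0
        res = quadratic_age_model(df, "y", PermutationPlan(200, 0))
        assert res.p_perm > 0.5


def _brute_force_bh(p, q=0.05):
    m = len(p)
    order = np.argsort(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBhFdr:
    def test_worked_example(self):
        flags = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, True, False])

    def test_all_small_all_rejected(self):
        assert bh_fdr([0.001] * 32).all()

    def test_all_one_none_rejected(self):
        assert not bh_fdr([1.0] * 10).any()

    def test_empty_family(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_array_equal(bh_fdr(p), _brute_force_bh(np.array(p)))

    def test_family_partitioning(self):
        results = [
            StatResult(f"v{i}", 0.0, 0.0, 0.0, p, 32, family=fam)
            for i, (p, fam) in enumerate(
                [(0.001, "a"), (0.5, "a"), (0.04, "b"), (0.04, "b"), (0.04, "b")]
            )
        ]
        apply_family_fdr(results, q=0.05)
        # in family b, p=(0.04,0.04,0.04): all ranks pass at 3*q/3
        assert [r.q_flag for r in results] == [True, False, True, True, True]


class TestPermutationPValues:
    def test_null_p_values_uniform_on_grid(self):
        """KS distance to uniform stays small under an exchangeable null."""
        rng = np.random.default_rng(7)
        n, n_sims, n_perm = 30, 1000, 99
        base = _toy_table(n=n, seed=12)
        pvals = []
        for j in range(n_sims):
            df = base.copy()
            df["y"] = rng.normal(0, 1, n)
            res = permutation_partial_correlation(
                df, "y", PermutationPlan(n_permutations=n_perm, seed=j)
            )
            pvals.append(res.p_perm)
        from scipy.stats import kstest

        stat = kstest(pvals, "uniform").statistic
        # achievable grid spacing is 1/(N+1) = 0.01; allow sampling noise
        assert stat < 0.06


class TestDispersionAndTrait:
    def _fake_results(self, group, r2, beta):
        from fwdmri.roi import ROI_NAMES

        return [
            StatResult(
                f"fw_wm_{n}", statistic=np.sign(beta) * np.sqrt(r2), beta=beta,
                r2=r2, p_perm=0.5, n=43, family="fw_wm", group=group,
            )
            for n in ROI_NAMES
        ]

    def test_identical_groups_give_zero_difference(self):
        res = self._fake_results("NT", 0.3, 0.002) + self._fake_results("ASD", 0.3, 0.002)
        summary = dispersion_summary(res)
        diff = summary[(summary["group"] == "NT-ASD") & (summary["lobe"] == "all")]
        assert diff["R2_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert diff["beta_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_lobe_rows_present_with_correct_counts(self):
        summary = dispersion_summary(self._fake_results("NT", 0.2, 0.001))
        counts = summary.set_index("lobe")["n"]
        assert counts["frontal"] == 17
        assert counts["temporal"] == 3
        assert counts["parietal"] == 6
        assert counts["occipital"] == 6
        assert counts["all"] == 32

    def test_trait_constructed_dependence(self, cohort_table):
        df = cohort_table.copy()
        rng = np.random.default_rng(3)
        asd = df["group"] == "ASD"
        df.loc[asd, "ados"] = -df.loc[asd, "fw_wm_GR"] * 100 + rng.normal(
            0, 0.1, int(asd.sum())
        )
        res = trait_correlation(
            df, "ados", ["fw_wm_GR"], PermutationPlan(500, 1)
        )
        assert res[0].statistic < -0.9
        assert res[0].p_perm < 0.01

    def test_trait_family_size_seven(self, cohort_table):
        variables = [f"fw_wm_{n}" for n in
                     ("GR", "mOG", "OC", "PMd", "PMv", "preSMA", "SMA")]
        res = trait_correlation(
            cohort_table, "ados", variables, PermutationPlan(99, 2)
        )
        assert len(res) == 7
        assert all(r.family == "trait:ados" for r in res)

    def test_missing_trait_rejected(self, cohort_table):
        with pytest.raises(ValueError, match="trait"):
            trait_correlation(cohort_table, "nope", ["fw_wm_GR"], PermutationPlan(9, 0))
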