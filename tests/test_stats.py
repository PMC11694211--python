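import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from snatchlab.simulate import CohortParams, simulate_variable_tables
from snatchlab.stats import (
    ConditionStudy,
    DegenerateDataError,
    PowerQuery,
    analyze_variable,
    choose_test,
    friedman,
    min_sample_size,
    posthoc,
    rm_anova,
    rmanova_power,
)


def brute_force_rm_anova(arr: np.ndarray) -> tuple[float, float]:
    """Independent oracle: explicit two-way sums-of-squares decomposition."""
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * ((arr.mean(0) - grand) ** 2).sum()
    resid = arr - arr.mean(1, keepdims=True) - arr.mean(0) + grand
    ss_err = (resid ** 2).sum()
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    eta_p2 = ss_cond / (ss_cond + ss_err)
    return F, eta_p2


def exhaustive_friedman(arr: np.ndarray) -> float:
    """Independent oracle: within-row mid-ranks and the classic chi-square."""
    n, k = arr.shape
    ranks = np.empty_like(arr, dtype=float)
    for i, row in enumerate(arr):
        order = np.argsort(row)
        r = np.empty(k)
        r[order] = np.arange(1, k + 1, dtype=float)
        # mid-rank ties
        for val in np.unique(row):
            mask = row == val
            r[mask] = r[mask].mean()
        ranks[i] = r
    rj = ranks.sum(0)
    chi2 = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts ** 3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    return chi2 / correction


class TestChooseTest:
    def test_normal_tables_route_to_rm_anova_most_of_the_time(self):
        hits = 0
        for seed in range(100):
            tab = np.random.default_rng(seed).normal(size=(16, 4))
            hits += choose_test(tab) == "rm_anova"
        # four Shapiro gates at alpha 0.05: expect ~81% pass-through
        assert hits >= 70

    def test_lognormal_column_routes_to_friedman_in_majority(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            tab = rng.normal(size=(16, 4))
            tab[:, 2] = np.exp(2.0 * rng.normal(size=16))
            hits += choose_test(tab) == "friedman"
        assert hits > 30

    def test_constant_column_is_a_normality_failure(self):
        tab = np.random.default_rng(0).normal(size=(10, 4))
        tab[:, 1] = 3.0
        assert choose_test(tab) == "friedman"


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        base = np.random.default_rng(3).normal(size=10)
        tab = np.tile(base[:, None], (1, 4))
        res = rm_anova(tab)
        assert res.statistic == 0.0
        assert res.effect_size == 0.0
        assert res.p_value == 1.0

    def test_constant_table_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rm_anova(np.full((6, 4), 2.0))

    def test_matches_brute_force_sums_of_squares(self):
        for seed in range(100):
            tab = np.random.default_rng(seed).normal(size=(5, 4))
            res = rm_anova(tab)
            F, eta = brute_force_rm_anova(tab)
            assert res.statistic == pytest.approx(F, rel=1e-10)
            assert res.effect_size == pytest.approx(eta, rel=1e-10)
            assert res.df == (3.0, 12.0)
            assert res.p_value == pytest.approx(sps.f.sf(F, 3, 12), rel=1e-9)

    def test_per_subject_offsets_leave_f_unchanged(self, rng):
        tab = rng.normal(size=(8, 4))
        offsets = rng.normal(0, 10, size=(8, 1))
        r1, r2 = rm_anova(tab), rm_anova(tab + offsets)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        base = np.random.default_rng(3).normal(size=8)
        res = friedman(np.tile(base[:, None], (1, 4)))
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_matches_exhaustive_rank_arithmetic_on_3x3(self):
        tables = [
            np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0]]),
            np.array([[5.0, 5.0, 1.0], [2.0, 4.0, 4.0], [3.0, 1.0, 2.0]]),  # ties
            np.random.default_rng(7).normal(size=(3, 3)),
        ]
        for tab in tables:
            res = friedman(tab)
            assert res.statistic == pytest.approx(exhaustive_friedman(tab), rel=1e-10)

    def test_column_permutation_invariance(self, rng):
        tab = pd.DataFrame(rng.normal(size=(9, 4)), columns=list("abcd"))
        r1 = friedman(tab)
        r2 = friedman(tab[["c", "a", "d", "b"]])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_kendalls_w_normalisation(self, rng):
        tab = rng.normal(size=(12, 4))
        res = friedman(tab)
        assert res.effect_size == pytest.approx(res.statistic / (12 * 3))
        assert 0.0 <= res.effect_size <= 1.0


class TestPosthoc:
    def test_bonferroni_multiplies_by_six_and_caps(self, rng):
        tab = rng.normal(size=(10, 4))
        pairs = posthoc(tab, "rm_anova")
        assert len(pairs) == 6
        for p in pairs:
            assert p.p_adjusted == pytest.approx(min(1.0, 6 * p.p_raw))

    def test_identical_pair_has_p_one(self, rng):
        tab = rng.normal(size=(10, 4))
        tab[:, 3] = tab[:, 0]
        pairs = posthoc(tab, "friedman")
        same = [p for p in pairs if set(p.pair) == {"RL", "DL"}]
        assert same[0].p_raw == 1.0

    def test_planted_shift_flagged_in_most_seeds(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tab = rng.normal(size=(16, 4))
            tab[:, 3] += 2.0  # d = 2 shift in the last condition
            res = analyze_variable(tab, alpha=0.05)
            flagged = {frozenset(p.pair) for p in res.posthoc
                       if p.p_adjusted < 0.05}
            cols = ["RL", "bCI", "sCI", "DL"]
            target = {frozenset({c, "DL"}) for c in cols[:3]}
            hits += target <= flagged
        assert hits >= 0.8 * n_seeds

    def test_posthoc_only_when_omnibus_significant(self, rng):
        null_tab = rng.normal(size=(12, 4))
        res = analyze_variable(null_tab, alpha=1e-6)  # effectively never
        assert res.posthoc == []


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            q = PowerQuery(f=0.0, alpha=alpha)
            assert rmanova_power(q, 12) == pytest.approx(alpha, abs=1e-6)

    def test_power_monotone_in_n(self):
        q = PowerQuery()
        powers = [rmanova_power(q, n) for n in range(3, 51)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_min_sample_size_is_exact_argmin(self):
        q = PowerQuery()
        n = min_sample_size(q)
        assert rmanova_power(q, n) >= q.target_power
        assert rmanova_power(q, n - 1) < q.target_power

    def test_smaller_effect_needs_more_subjects(self):
        n_large = min_sample_size(PowerQuery(f=0.5))
        n_small = min_sample_size(PowerQuery(f=0.25))
        assert n_small > n_large

    def test_raising_target_never_lowers_n(self):
        q_lo = PowerQuery(f=1.5, target_power=0.5)
        q_hi = PowerQuery(f=1.5, target_power=0.99)
        assert 2 <= min_sample_size(q_lo) <= min_sample_size(q_hi)

    def test_formula_agrees_with_monte_carlo(self):
        """Dual route: the noncentral-F power against simulated RM-ANOVAs
        under compound symmetry (f=0.5, rho=0.5, m=4, n=10)."""
        q = PowerQuery(f=0.5, rho=0.5, m=4)
        predicted = rmanova_power(q, 10)
        rng = np.random.default_rng(99)
        n, m, nsim = 10, 4, 20_000
        mus = np.array([-1.5, -0.5, 0.5, 1.5])
        mus = mus / mus.std() * q.f
        crit = sps.f.isf(q.alpha, m - 1, (n - 1) * (m - 1))
        subj = rng.normal(0, np.sqrt(q.rho), (nsim, n, 1))
        eps = rng.normal(0, np.sqrt(1 - q.rho), (nsim, n, m))
        y = mus + subj + eps
        gm = y.mean(axis=(1, 2), keepdims=True)
        rm = y.mean(axis=2, keepdims=True)
        cm = y.mean(axis=1, keepdims=True)
        ssc = n * ((cm - gm) ** 2).sum(axis=(1, 2))
        sse = ((y - rm - cm + gm) ** 2).sum(axis=(1, 2))
        F = (ssc / (m - 1)) / (sse / ((n - 1) * (m - 1)))
        observed = float(np.mean(F > crit))
        se = np.sqrt(predicted * (1 - predicted) / nsim)
        assert observed == pytest.approx(predicted, abs=4 * se)

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            PowerQuery(f=-0.1)
        with pytest.raises(ValueError):
            PowerQuery(rho=1.0)
        with pytest.raises(ValueError):
            rmanova_power(PowerQuery(), 1)


class TestBatteryCalibration:
    def test_type_one_error_on_iid_normal_tables(self):
        """Full battery (normality gate -> omnibus) holds its nominal size."""
        n_tables, rejections = 2000, 0
        root = np.random.default_rng(2024)
        for _ in range(n_tables):
            tab = root.normal(size=(16, 4))
            res = analyze_variable(tab, alpha=0.05)
            rejections += res.p_value < 0.05
        assert rejections / n_tables == pytest.approx(0.05, abs=0.02)


class TestConditionStudy:
    def _features(self, rng, n_sub=6, shift=0.0):
        rows = []
        for s in range(n_sub):
            for cond in ("RL", "bCI", "sCI", "DL"):
                for k in (1, 2, 3):
                    rows.append({
                        "subject_id": f"S{s:02d}", "condition": cond, "trial": k,
                        "V-max": rng.normal(3.15, 0.4)
                        + (shift if cond == "DL" else 0.0),
                        "X1": rng.normal(0, 7),
                    })
        return pd.DataFrame(rows)

    def test_subject_mean_collapse(self, rng):
        df = self._features(rng)
        study = ConditionStudy.from_features(df, variables=["V-max", "X1"])
        tab = study.tables["V-max"]
        assert tab.shape == (6, 4)
        one = df[(df.subject_id == "S00") & (df.condition == "DL")]["V-max"].mean()
        assert tab.loc["S00", "DL"] == pytest.approx(one)

    def test_fit_summary_and_json(self, rng, tmp_path):
        res = ConditionStudy.from_features(self._features(rng)).fit()
        summary = res.summary()
        assert set(summary.index) == {"V-max", "X1"}
        assert {"test", "statistic", "p"} <= set(summary.columns)
        text = res.to_json(tmp_path / "stats.json")
        import json

        payload = json.loads(text)
        assert payload["V-max"]["test_used"] in ("rm_anova", "friedman")
        assert 0 <= payload["V-max"]["p"] <= 1

    def test_large_planted_shift_is_detected(self, rng):
        df = self._features(rng, n_sub=12, shift=1.0)
        res = ConditionStudy.from_features(df, variables=["V-max"]).fit()
        assert res["V-max"].p_value < 0.01
        assert len(res["V-max"].posthoc) == 6

    def test_variable_tables_reach_the_battery(self):
        c = CohortParams(n_subjects=8, seed=5)
        tab = next(simulate_variable_tables(c, "y_max", 1))
        res = analyze_variable(tab)
        assert res.n_units == 8
        assert list(tab.columns) == ["RL", "bCI", "sCI", "DL"]
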