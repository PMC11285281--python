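import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lprx.scan import (
    ThresholdGrid,
    battery_table,
    binary_mann_whitney,
    chi2_2x2,
    dichotomize_gos,
    mann_whitney_compare,
    run_scan_battery,
    scan_thresholds,
    select_best,
)


class TestDichotomizeGos:
    @pytest.mark.parametrize("gos,expected", [(1, 1), (2, 0), (3, 0), (4, 0), (5, 0)])
    def test_survival(self, gos, expected):
        assert dichotomize_gos(gos, "survival") == expected

    @pytest.mark.parametrize("gos,expected", [(1, 1), (2, 1), (3, 1), (4, 0), (5, 0)])
    def test_favorable(self, gos, expected):
        assert dichotomize_gos(gos, "favorable") == expected

    @pytest.mark.parametrize("gos", [0, 6, -1])
    def test_domain_error(self, gos):
        with pytest.raises(ValueError, match="GOS"):
            dichotomize_gos(gos, "survival")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            dichotomize_gos(3, "mortality")


class TestChi2:
    def test_epidural_hematoma_table(self):
        # 2x2 from published counts: dead 4/80, alive 64/287
        chi2, p, valid = chi2_2x2(4, 80, 64, 287)
        assert valid
        assert chi2 == pytest.approx(9.327094, abs=1e-5)
        assert p == pytest.approx(0.0022579, abs=1e-6)
        assert round(p, 4) == 0.0023

    def test_hypoxia_table(self):
        # uncorrected Pearson dialect; p ~ 0.0091-0.0092
        chi2, p, valid = chi2_2x2(36, 48, 99, 252)
        assert valid
        assert chi2 == pytest.approx(6.798535, abs=1e-5)
        assert p == pytest.approx(0.0091233, abs=1e-6)

    def test_perfect_independence(self):
        chi2, p, valid = chi2_2x2(10, 10, 10, 10)
        assert valid and chi2 == 0.0 and p == 1.0

    def test_zero_marginal_invalid_not_exception(self):
        chi2, p, valid = chi2_2x2(0, 0, 10, 20)
        assert not valid and np.isnan(chi2) and np.isnan(p)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 0, 0)

    def test_label_swap_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            s1 = chi2_2x2(a, b, c, d)[0]
            s2 = chi2_2x2(d, c, b, a)[0]  # both row and column labels swapped
            assert s1 == pytest.approx(s2, rel=1e-12)

    def test_matches_scipy_uncorrected(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            chi2, p, _ = chi2_2x2(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)


def brute_force_scan(values, classes, grid_values):
    """Independent oracle: re-dichotomize and run scipy at each threshold."""
    best = (None, -1.0)
    for thr in grid_values:
        above = values > thr
        tab = np.array(
            [
                [(above & (classes == 1)).sum(), (above & (classes == 0)).sum()],
                [(~above & (classes == 1)).sum(), (~above & (classes == 0)).sum()],
            ]
        )
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            continue
        chi2 = stats.chi2_contingency(tab, correction=False).statistic
        if chi2 > best[1]:
            best = (thr, chi2)
    return best


class TestScanThresholds:
    def test_perfect_separation(self):
        # 50 patients at 0.1 all alive, 50 at 0.5 all dead; strict ">"
        # dichotomization separates perfectly from theta=0.10 upward, so the
        # lowest-tie rule selects 0.10 (chi2 = n = 100).
        values = np.r_[np.full(50, 0.1), np.full(50, 0.5)]
        classes = np.r_[np.zeros(50, int), np.ones(50, int)]
        grid = ThresholdGrid.for_kind("lprx")
        res = scan_thresholds(values, classes, grid)
        assert res.usable
        assert res.best_chi2 == pytest.approx(100.0)
        assert res.best_threshold == pytest.approx(0.10)
        thr_oracle, chi2_oracle = brute_force_scan(values, classes, grid.values)
        assert res.best_threshold == pytest.approx(thr_oracle)
        assert res.best_chi2 == pytest.approx(chi2_oracle)

    def test_matches_brute_force_on_random_data(self, rng):
        values = rng.normal(0.1, 0.3, 120)
        classes = (rng.random(120) < 0.4).astype(int)
        grid = ThresholdGrid.for_kind("lprx")
        res = scan_thresholds(values, classes, grid)
        thr_oracle, chi2_oracle = brute_force_scan(values, classes, grid.values)
        assert res.best_threshold == pytest.approx(thr_oracle)
        assert res.best_chi2 == pytest.approx(chi2_oracle, rel=1e-10)

    def test_all_same_class_unusable(self):
        values = np.linspace(0, 1, 30)
        classes = np.ones(30, int)
        res = scan_thresholds(values, classes, ThresholdGrid.for_kind("lprx"))
        assert not res.usable
        assert not res.table["valid"].any()
        assert res.best_threshold is None

    def test_cell_conservation_every_grid_point(self, rng):
        values = rng.normal(0, 0.3, 75)
        classes = (rng.random(75) < 0.3).astype(int)
        res = scan_thresholds(values, classes, ThresholdGrid.for_kind("lprx"))
        totals = res.table[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == res.n_patients).all()

    def test_missing_values_excluded(self):
        values = np.array([0.1, np.nan, 0.5, 0.4, np.nan, 0.0])
        classes = np.array([0, 1, 1, 1, 0, 0])
        res = scan_thresholds(values, classes, ThresholdGrid.for_kind("lprx"))
        assert res.n_patients == 4

    def test_grid_dialects(self):
        g = ThresholdGrid.for_kind("lprx")
        np.testing.assert_allclose(g.values[[0, -1]], [-0.5, 0.7])
        assert g.values.size == 25
        g = ThresholdGrid.for_kind("icp")
        np.testing.assert_allclose(g.values[[0, -1]], [0.0, 40.0])
        assert g.values.size == 81
        g = ThresholdGrid.for_kind("pct_time")
        assert g.values.size == 21


class TestSelectBest:
    def _result_with_chi2(self, chi2_by_thr):
        rows = [
            {"threshold": t, "a": 1, "b": 1, "c": 1, "d": 1,
             "chi2": c, "p": 0.5, "valid": np.isfinite(c)}
            for t, c in chi2_by_thr.items()
        ]
        from lprx.scan import ThresholdScanResult

        return ThresholdScanResult(
            grid=ThresholdGrid("lprx", -0.5, 0.7, 0.05),
            table=pd.DataFrame(rows), n_patients=4, usable=True,
        )

    def test_unimodal_peak(self):
        res = self._result_with_chi2({0.1: 1.0, 0.15: 5.0, 0.2: 2.0})
        thr, chi2, _ = select_best(res)
        assert thr == 0.15 and chi2 == 5.0

    def test_tie_rules(self):
        res = self._result_with_chi2({0.2: 1.0, 0.25: 7.0, 0.30: 7.0})
        assert select_best(res, "lowest")[0] == 0.25
        assert select_best(res, "highest")[0] == 0.30

    def test_no_valid_point(self):
        res = self._result_with_chi2({0.1: np.nan})
        assert select_best(res) is None

    def test_unknown_tie_rule(self):
        res = self._result_with_chi2({0.1: 1.0})
        with pytest.raises(ValueError):
            select_best(res, "median")


class TestMannWhitney:
    def test_identical_groups(self):
        u, p = mann_whitney_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_groups(self):
        # exact test over C(6,3)=20 arrangements: two-sided p = 2/20
        u, p = mann_whitney_compare([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_compare([], [1.0])

    def test_binary_rank_dialect_reproduces_published_values(self):
        # frozen from the printed demographic table (counts -> p-values)
        assert round(binary_mann_whitney(4, 84, 64, 351), 4) == 0.0023
        assert round(binary_mann_whitney(36, 84, 99, 351), 4) == 0.0092
        assert round(binary_mann_whitney(68, 84, 270, 351), 4) == 0.4264
        assert round(binary_mann_whitney(13, 84, 22, 351), 4) == 0.0054

    def test_binary_count_validation(self):
        with pytest.raises(ValueError):
            binary_mann_whitney(5, 4, 1, 10)


class TestScanBattery:
    def _summaries_and_cohort(self, rng, n=40):
        rhos = rng.uniform(-0.3, 0.7, n)
        gos = np.where(rhos > 0.3, 1, 5)
        rows = []
        for i in range(n):
            rows.append(
                {"patient_id": f"p{i}", "segment": "full", "metric": "mean_lprx",
                 "window_minutes": 10, "threshold": np.nan,
                 "value": rhos[i] + rng.normal(0, 0.02), "n_valid": 1000}
            )
        summaries = pd.DataFrame(rows)
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "gos": gos,
                "monitor_type": rng.choice(["EVD", "IPD"], n),
                "dc_primary": rng.random(n) < 0.1,
                "dc_secondary": False,
            }
        )
        return summaries, cohort

    def test_single_cell_matches_direct_scan(self, rng):
        summaries, cohort = self._summaries_and_cohort(rng)
        results = run_scan_battery(
            summaries, cohort, schemes=("survival",), subgroups=("all",)
        )
        assert len(results) == 1
        direct = scan_thresholds(
            summaries["value"].to_numpy(),
            cohort["gos"].map(lambda g: dichotomize_gos(g, "survival")).to_numpy(),
            ThresholdGrid.for_kind("lprx"),
        )
        pd.testing.assert_frame_equal(results[0].table, direct.table)
        assert results[0].best_threshold == direct.best_threshold

    def test_completeness_row_per_cell(self, rng):
        summaries, cohort = self._summaries_and_cohort(rng)
        results = run_scan_battery(summaries, cohort)
        # 2 schemes x 4 subgroups x 1 metric cell
        assert len(results) == 8
        tab = battery_table(results)
        assert set(tab["scheme"]) == {"survival", "favorable"}
        assert set(tab["subgroup"]) == {"all", "evd", "ipd", "no_dc"}

    def test_empty_stratum_marked_unusable_battery_continues(self, rng):
        summaries, cohort = self._summaries_and_cohort(rng)
        cohort["monitor_type"] = "IPD"
        results = run_scan_battery(
            summaries, cohort, schemes=("survival",), subgroups=("evd", "ipd")
        )
        by_sub = {r.stratum["subgroup"]: r for r in results}
        assert not by_sub["evd"].usable
        assert by_sub["ipd"].usable
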